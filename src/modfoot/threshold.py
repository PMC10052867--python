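"""Probability-distribution modelling and binarization of per-call m6A.

A modified-base caller emits, per adenine per read, a modification
probability in [0, 1]. Over a labeled sample this distribution is
bimodal: a sharp component near zero (unmodified adenines) and a broad
component at high probability (truly modified adenines). A
two-component Gaussian mixture is fitted to the pooled probabilities
and the binarization cut-off is taken as the point between the two
component means where the weighted component densities are equal
(posterior 0.5). Calls strictly above the cut-off are flagged
methylated.

Typical cut-offs for this kind of data are ~0.5 for bulk signal tracks
and 0.8 for high-confidence single-molecule work; both are exposed as
plain parameters downstream, so a fitted or a fixed cut-off can be used
interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp
from scipy.stats import norm

from .errors import DegenerateFitError, InsufficientDataError, NoBoundaryError
from .io import Molecule

_SD_FLOOR = 1e-4


@dataclass
class MixtureFit:
    """A fitted k-component 1-D Gaussian mixture on call probabilities.

    Components are ordered by ascending mean (ties by ascending sd), so
    for k=2 component 0 is the unmodified ("sharp") peak and component 1
    the modified ("wide") peak. ``cutoff`` is filled by
    :func:`derive_cutoff`.
    """

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    cutoff: float | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    @property
    def k(self) -> int:
        return len(self.means)

    def component_density(self, x, j: int) -> np.ndarray:
        """Weighted density of component j: w_j * N(x; mu_j, sd_j)."""
        return self.weights[j] * norm.pdf(x, self.means[j], self.sds[j])

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return sum(self.component_density(x, j) for j in range(self.k))

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "cutoff": self.cutoff,
        }


@dataclass
class ConfusionCounts:
    """TP/FP/TN/FN tallies with the derived rate metrics.

    Zero-denominator metrics are returned as NaN and listed in
    ``undefined`` instead of silently defaulting.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def precision(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    # true-negative rate is a synonym for specificity; kept for symmetry
    tnr = specificity

    @property
    def undefined(self) -> set[str]:
        out = set()
        if self.tp + self.fn == 0:
            out.add("sensitivity")
        if self.tp + self.fp == 0:
            out.add("precision")
        if self.tn + self.fp == 0:
            out.update({"specificity", "tnr"})
        return out

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")


@dataclass
class RocResult:
    """ROC points (monotone in both axes) and the trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def _em(x: np.ndarray, means0: np.ndarray, tol: float, max_iter: int):
    """Run EM from the given component means; x must be sorted."""
    k = len(means0)
    n = len(x)
    means = means0.astype(float).copy()
    sds = np.full(k, max(float(x.std()), 10 * _SD_FLOOR))
    weights = np.full(k, 1.0 / k)
    ll_prev = -np.inf
    ll = ll_prev
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        logp = np.log(weights) + norm.logpdf(x[:, None], means, sds)
        log_tot = logsumexp(logp, axis=1)
        ll = float(log_tot.mean())
        resp = np.exp(logp - log_tot[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
        sds = np.maximum(np.sqrt(var), _SD_FLOOR)
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
    return weights, means, sds, ll, it, converged


def fit_probability_mixture(
    probs,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 3,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MixtureFit:
    """Fit a k-component Gaussian mixture to call probabilities by EM.

    Deterministic given ``seed`` and invariant to input order (the data
    are sorted internally). The first restart initializes component
    means at evenly spaced quantiles (25th/75th percentile for k=2);
    the remaining restarts draw random quantiles from a seeded
    generator. The best final log-likelihood wins; components are
    ordered by ascending mean.
    """
    x = np.sort(np.asarray(probs, dtype=float))
    if len(x) < 10 * k:
        raise InsufficientDataError(
            f"need at least {10 * k} observations for a {k}-component fit, got {len(x)}"
        )
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if x[0] == x[-1]:
        raise DegenerateFitError("all input values identical; no mixture can be fitted")

    rng = np.random.default_rng(seed)
    quantile_sets = [np.linspace(0, 1, 2 * k + 1)[1::2]]  # 25th/75th for k=2
    for _ in range(max(0, n_restarts - 1)):
        quantile_sets.append(np.sort(rng.uniform(0.02, 0.98, size=k)))

    best = None
    for qs in quantile_sets:
        means0 = np.quantile(x, qs)
        weights, means, sds, ll, it, converged = _em(x, means0, tol, max_iter)
        if best is None or ll > best[3]:
            best = (weights, means, sds, ll, it, converged)
    weights, means, sds, ll, it, converged = best

    order = np.lexsort((sds, means))
    return MixtureFit(
        weights=weights[order],
        means=means[order],
        sds=sds[order],
        loglik=ll,
        n_iter=it,
        converged=converged,
    )


def derive_cutoff(fit: MixtureFit) -> float:
    """Equal-weighted-density point between the two component means.

    Solves w0*N(x; m0, s0) = w1*N(x; m1, s1) for x strictly between the
    means (the posterior-0.5 decision boundary). If the weighted
    densities do not cross between the means — which happens when the
    components are nearly coincident or one weight dominates —
    :class:`NoBoundaryError` is raised and a manual cut-off should be
    supplied. The result is also stored on ``fit.cutoff``.
    """
    if fit.k != 2:
        raise ValueError("cut-off derivation requires a two-component fit")
    m0, m1 = fit.means
    if m1 - m0 <= 0:
        raise NoBoundaryError("component means coincide; no boundary exists")

    def diff(x):
        return fit.component_density(x, 0) - fit.component_density(x, 1)

    grid = np.linspace(m0, m1, 2049)
    vals = diff(grid)
    sign = np.sign(vals)
    changes = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    if len(changes) == 0:
        exact = np.flatnonzero(vals == 0)
        if len(exact):
            cutoff = float(grid[exact[0]])
            fit.cutoff = cutoff
            return cutoff
        raise NoBoundaryError(
            "weighted component densities do not cross between the means; "
            "supply a manual cut-off"
        )
    i = int(changes[0])  # first crossing scanning up from the low mean
    cutoff = float(brentq(diff, grid[i], grid[i + 1], xtol=1e-12))
    fit.cutoff = cutoff
    return cutoff


def cutoff_from_control(control_probs, quantile: float = 0.99) -> float:
    """Alternative cut-off: a high quantile of a no-antibody control.

    Calibrates the threshold so that at most ``1 - quantile`` of control
    (background-noise) calls exceed it. Provided as a second method, not
    the default.
    """
    x = np.asarray(control_probs, dtype=float)
    if len(x) == 0:
        raise InsufficientDataError("control sample is empty")
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    return float(np.quantile(x, quantile))


def binarize_calls(molecules, cutoff: float):
    """Flag calls methylated iff prob > cutoff (strict inequality).

    Returns ``(molecules, n_flagged, n_total)`` with new Molecule
    objects carrying a boolean ``meth`` array. Calls exactly at the
    cut-off are unmethylated, so the decision is deterministic.
    """
    if not 0 < cutoff < 1:
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    out = []
    n_flagged = 0
    n_total = 0
    for m in molecules:
        meth = m.prob > cutoff
        n_flagged += int(meth.sum())
        n_total += len(meth)
        out.append(replace(m, meth=meth))
    return out, n_flagged, n_total


def confusion_metrics(truth, predicted) -> ConfusionCounts:
    """Tally TP/FP/TN/FN between boolean truth and prediction vectors."""
    t = np.asarray(truth, dtype=bool)
    p = np.asarray(predicted, dtype=bool)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: truth {t.shape} vs predicted {p.shape}")
    if t.size == 0:
        raise ValueError("empty input")
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def roc_curve(truth, probs) -> RocResult:
    """ROC points and trapezoidal AUC (both classes must be present)."""
    from sklearn import metrics as _metrics

    t = np.asarray(truth, dtype=bool)
    s = np.asarray(probs, dtype=float)
    if t.shape != s.shape:
        raise ValueError("length mismatch between truth and probabilities")
    if t.all() or not t.any():
        raise ValueError("ROC requires both classes in the truth vector")
    fpr, tpr, thresholds = _metrics.roc_curve(t, s)
    auc = float(_metrics.auc(fpr, tpr))
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def binarize_probs(probs, cutoff: float) -> np.ndarray:
    """Vector form of the strict-inequality binarization rule."""
    if not 0 < cutoff < 1:
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    return np.asarray(probs, dtype=float) > cutoff


__all__ = [
    "MixtureFit",
    "ConfusionCounts",
    "RocResult",
    "fit_probability_mixture",
    "derive_cutoff",
    "cutoff_from_control",
    "binarize_calls",
    "binarize_probs",
    "confusion_metrics",
    "roc_curve",
    "Molecule",
]
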