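"""Fit the per-call probability mixture and derive a binarization cut-off.

Simulates a labeled sample (a protein footprint over background), pools
the per-adenine modification probabilities, fits the two-component
Gaussian mixture, and reports the equal-density cut-off together with
a control-quantile alternative.
"""

import numpy as np

from modfoot import simulate, threshold

cfg = simulate.SimConfig(
    genome_length=50_000,
    footprints=((10_000, 12_000), (30_000, 31_000)),
    depth=15,
    seed=7,
)
molecules, truth = simulate.simulate_molecules(cfg)
probs = np.concatenate([m.prob for m in molecules])
print(f"{len(molecules)} molecules, {len(probs)} adenine calls")

fit = threshold.fit_probability_mixture(probs, seed=7)
cutoff = threshold.derive_cutoff(fit)
print(f"unmodified component: mean={fit.means[0]:.3f} sd={fit.sds[0]:.3f} "
      f"weight={fit.weights[0]:.3f}")
print(f"modified component:   mean={fit.means[1]:.3f} sd={fit.sds[1]:.3f} "
      f"weight={fit.weights[1]:.3f}")
print(f"equal-density cut-off: {cutoff:.3f}")

# alternative: calibrate against a no-antibody control (background only)
igg_cfg = simulate.SimConfig(genome_length=50_000, depth=5, p_bg=0.0, seed=8)
igg, _ = simulate.simulate_molecules(igg_cfg)
control = np.concatenate([m.prob for m in igg])
q_cut = threshold.cutoff_from_control(control, quantile=0.99)
print(f"control 99th-percentile cut-off: {q_cut:.3f}")

# how well does the derived cut-off separate truth?
binarized, n_flagged, n_total = threshold.binarize_calls(molecules, cutoff)
pred = np.concatenate([m.meth for m in binarized])
conf = threshold.confusion_metrics(truth.calls["modified"].to_numpy(), pred)
print(f"flagged {n_flagged}/{n_total} calls; "
      f"sensitivity={conf.sensitivity:.3f} precision={conf.precision:.3f} "
      f"specificity={conf.specificity:.3f}")
# The two component means sit near the emission defaults (0.15 / 0.80);
# the cut-off lands between them where the weighted densities cross.
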