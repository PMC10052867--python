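"""Co-labeling coefficient: pair formula, matrices, upstream scan."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from modfoot import colabel, simulate
from modfoot.io import GenomicBin


class TestCcPair:
    @pytest.mark.parametrize(
        "ai,aj,expected",
        [(3, 3, 0.5), (4, 0, -0.5), (0, 4, -0.5), (3, 1, 0.0), (1, 1, 0.5)],
    )
    def test_direct_formula(self, ai, aj, expected):
        assert colabel.cc_pair(ai, aj) == pytest.approx(expected)

    def test_mutual_absence_excluded(self):
        assert np.isnan(colabel.cc_pair(0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            colabel.cc_pair(-1, 2)

    @given(st.integers(0, 100), st.integers(0, 100), st.integers(1, 5))
    def test_symmetry_and_ratio_scale_invariance(self, ai, aj, c):
        if ai == 0 and aj == 0:
            return
        v = colabel.cc_pair(ai, aj)
        assert v == pytest.approx(colabel.cc_pair(aj, ai))
        assert v == pytest.approx(colabel.cc_pair(c * ai, c * aj))
        assert -0.5 <= v <= 0.5


class TestWindowVector:
    def test_counting(self, make_molecule, region):
        m = make_molecule([10, 60], [0.9, 0.9])
        wv = colabel.window_vector(m, region(end=100), w=50, cutoff=0.8)
        assert wv.A.tolist() == [1, 1]
        assert wv.defined.tolist() == [True, True]

    def test_covered_but_unflagged_window(self, make_molecule, region):
        m = make_molecule([10, 60], [0.1, 0.1])
        wv = colabel.window_vector(m, region(end=100), w=50, cutoff=0.8)
        assert wv.A.tolist() == [0, 0]
        assert wv.defined.all()

    def test_uncovered_window_masked(self, make_molecule, region):
        m = make_molecule([10, 20], [0.9, 0.9])
        wv = colabel.window_vector(m, region(end=100), w=50, cutoff=0.8)
        assert wv.defined.tolist() == [True, False]

    def test_binary_mode_applies_bin_rule(self, make_molecule, region):
        m = make_molecule([10, 20, 30, 60], [0.9, 0.9, 0.1, 0.9], read_id="r")
        wv = colabel.window_vector(m, region(end=100), w=50, cutoff=0.8, binary=True)
        # window 0: 2/3 flagged, >=2 sites -> 1; window 1: single site -> 0
        assert wv.A.tolist() == [1, 0]


class TestCcMatrix:
    def test_single_molecule_entries(self, make_molecule, region):
        # A = (2, 2, 0) over three windows
        m = make_molecule([10, 20, 60, 70, 110], [0.9, 0.9, 0.9, 0.9, 0.1])
        mat = colabel.cc_matrix([m], region(end=150), w=50, cutoff=0.8)
        assert mat.cc[0, 1] == pytest.approx(0.5)
        assert mat.cc[0, 2] == pytest.approx(-0.5)
        assert mat.cc[1, 2] == pytest.approx(-0.5)
        assert np.allclose(mat.cc, mat.cc.T, equal_nan=True)
        assert mat.cc[0, 0] == pytest.approx(0.5)  # diagonal, support > 0

    def test_identical_molecules_equal_single(self, make_molecule, region):
        m1 = make_molecule([10, 20, 60, 70, 110], [0.9] * 4 + [0.1], read_id="a")
        m2 = make_molecule([10, 20, 60, 70, 110], [0.9] * 4 + [0.1], read_id="b")
        one = colabel.cc_matrix([m1], region(end=150), w=50, cutoff=0.8)
        two = colabel.cc_matrix([m1, m2], region(end=150), w=50, cutoff=0.8)
        assert np.allclose(one.cc, two.cc, equal_nan=True)
        assert two.support[0, 1] == 2

    def test_aggregate_is_sum_of_defined_entries(self, make_molecule, region):
        m = make_molecule([10, 20, 60, 70, 110], [0.9] * 4 + [0.1])
        mat = colabel.cc_matrix([m], region(end=150), w=50, cutoff=0.8)
        assert mat.aggregate == pytest.approx(np.nansum(mat.cc))

    def test_coin_flip_enumeration_oracle(self):
        # all-A genome, + strand only, noiseless full labeling: a window
        # is either fully labeled (50 calls) or empty, by a fair coin.
        # Enumerating flip outcomes for an off-diagonal pair:
        #   on/on (1/4) -> 0.5, on/off (1/2) -> -0.5, off/off excluded
        # so E[cc] = (0.25*0.5 - 0.5*0.5) / 0.75 = -1/6.
        cfg = simulate.SimConfig(
            mode="correlated_windows",
            genome_length=500,
            base_composition=(1, 0, 0, 0),
            fixed_read_length=500,
            n_molecules=500,
            strands=("+",),
            p_fg=1.0,
            p_bg=0.0,
            noiseless=True,
            window_pairs=(),
            seed=11,
        )
        mols, _ = simulate.simulate_molecules(cfg)
        mat = colabel.cc_matrix(mols, GenomicBin("chrSim", 0, 500), w=50, cutoff=0.8)
        off_diag = ~np.eye(len(mat.starts), dtype=bool)
        assert np.nanmean(mat.cc[off_diag]) == pytest.approx(-1 / 6, abs=0.05)
        assert np.allclose(np.diag(mat.cc), 0.5)

    def test_min_reads_masks_low_support(self, make_molecule, region):
        from modfoot.errors import DataQualityWarning

        m = make_molecule([10, 60], [0.9, 0.9])
        with pytest.warns(DataQualityWarning, match="support"):
            mat = colabel.cc_matrix([m], region(end=100), w=50, cutoff=0.8, min_reads=2)
        assert np.isnan(mat.cc).all()

    def test_region_too_short(self, make_molecule, region):
        m = make_molecule([10], [0.9])
        with pytest.raises(ValueError):
            colabel.cc_matrix([m], region(end=60), w=50, cutoff=0.8)


class TestDistanceWeighted:
    def _matrix(self, cc, starts, n):
        return colabel.CCMatrix(
            region=GenomicBin("chr1", 0, n),
            w=50,
            n=n,
            starts=np.asarray(starts),
            cc=np.asarray(cc, dtype=float),
            support=np.ones_like(np.asarray(cc), dtype=np.int64),
            aggregate=float(np.nansum(cc)),
        )

    def test_adjacent_windows_nearly_unchanged(self):
        mat = self._matrix([[0.5, 0.4], [0.4, 0.5]], [0, 50], 10_000)
        dw = colabel.cc_distance_weighted(mat)
        assert dw.cc[0, 1] == pytest.approx(0.4 * (50 / 10_000 + 1))

    def test_direct_formula(self):
        mat = self._matrix([[0.5, 0.4], [0.4, 0.5]], [0, 500], 1000)
        dw = colabel.cc_distance_weighted(mat)
        assert dw.cc[0, 1] == pytest.approx(0.6)  # 0.4 * (0.5 + 1)

    def test_bounds_approach_but_never_reach_minus_one(self):
        starts = [0, 950]
        mat = self._matrix([[0.5, -0.5], [-0.5, 0.5]], starts, 1000)
        dw = colabel.cc_distance_weighted(mat)
        assert -1.0 < dw.cc[0, 1] <= -0.5
        assert dw.distance_weighted


def _toggle_molecule(make_molecule, read_id, chrom, on, windows, span_end, planted=None):
    """Calls every 5 bp over [0, span_end); flagged only in 'on' windows.

    ``windows`` is the window width; ``planted`` windows copy the 'on'
    state exactly.
    """
    pos = np.arange(0, span_end, 5)
    probs = np.full(len(pos), 0.05)
    if on:
        for w_start in planted or []:
            sel = (pos >= w_start) & (pos < w_start + windows)
            probs[sel] = 0.95
    return make_molecule(pos, probs, read_id=read_id, chrom=chrom)


class TestUpstreamScan:
    def _planted_gene(self, make_molecule, chrom, n_mol=30):
        # promoter [2050, 2550) on +: anchor window [2050, 2100);
        # planted upstream window [1000, 1050) copies the anchor state
        mols = []
        for k in range(n_mol):
            on = k % 2 == 0
            mols.append(
                _toggle_molecule(
                    make_molecule, f"{chrom}_r{k}", chrom, on, 50, 2600,
                    planted=[2050, 1000],
                )
            )
        prom = GenomicBin(chrom, 2050, 2550, strand="+")
        return mols, prom

    def _flat_gene(self, make_molecule, chrom, n_mol=30):
        mols = [
            _toggle_molecule(make_molecule, f"{chrom}_r{k}", chrom, True, 50, 2600,
                             planted=[2050])
            for k in range(n_mol)
        ]
        return mols, GenomicBin(chrom, 2050, 2550, strand="+")

    def test_planted_copy_window_is_maximal(self, make_molecule):
        mols, prom = self._planted_gene(make_molecule, "c1")
        res = colabel.upstream_cc_scan(mols, {"g1": prom}, span=2000, w=50, cutoff=0.8)
        row = res.profiles.loc["g1"]
        # anchor at 2050; planted window 1000 is 1050 bp upstream -> up1050
        assert row["up1050"] == pytest.approx(0.5)
        assert row.idxmax() == "up1050"

    def test_variance_selects_planted_over_flat_genes(self, make_molecule):
        molecules = []
        promoters = {}
        for i in range(2):
            mols, prom = self._planted_gene(make_molecule, f"p{i}")
            molecules += mols
            promoters[f"planted{i}"] = prom
        for i in range(6):
            mols, prom = self._flat_gene(make_molecule, f"f{i}")
            molecules += mols
            promoters[f"flat{i}"] = prom
        res = colabel.upstream_cc_scan(molecules, promoters, span=2000, w=50, cutoff=0.8)
        assert set(res.selected) == {"planted0", "planted1"}
        assert all(
            res.variance[g] <= res.variance["planted0"] for g in promoters
        )

    def test_selection_invariant_to_gene_order(self, make_molecule):
        molecules = []
        promoters = {}
        for i in range(2):
            mols, prom = self._planted_gene(make_molecule, f"p{i}")
            molecules += mols
            promoters[f"planted{i}"] = prom
        for i in range(2):
            mols, prom = self._flat_gene(make_molecule, f"f{i}")
            molecules += mols
            promoters[f"flat{i}"] = prom
        fwd = colabel.upstream_cc_scan(molecules, promoters, span=2000, w=50, cutoff=0.8)
        rev = colabel.upstream_cc_scan(
            molecules, dict(reversed(list(promoters.items()))), span=2000, w=50, cutoff=0.8
        )
        assert set(fwd.selected) == set(rev.selected)

    def test_candidate_runs_cover_planted_window(self, make_molecule):
        mols, prom = self._planted_gene(make_molecule, "c1")
        res = colabel.upstream_cc_scan(mols, {"g1": prom}, span=2000, w=50, cutoff=0.8)
        runs = res.candidates["g1"]
        assert any(start <= 1050 <= end for start, end in runs)
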