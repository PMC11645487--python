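"""Repeatability statistics: oracles by brute force and scipy cross-checks."""

from itertools import permutations, product

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ketospec.quantification import QuantResult
from ketospec.repeatability_stats import (
    PairedSeries,
    bland_altman,
    build_report,
    coefficient_of_variation,
    correlate_kb_volumes,
    p_stars,
    spearman_rho,
    wilcoxon_signed_rank,
)
from ketospec.synthetic_data import SegMask


def brute_force_wilcoxon(diffs):
    """Independent enumeration oracle: exact two-sided sign-flip p-value."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    dist = [np.sum([r for r, s in zip(ranks, signs) if s])
            for signs in product([0, 1], repeat=len(d))]
    dist = np.asarray(dist, float)
    p_le = np.mean(dist <= w_obs + 1e-12)
    p_ge = np.mean(dist >= w_obs - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))


def brute_force_ranks(x):
    """Mid-ranks computed directly from pairwise comparisons."""
    x = np.asarray(x, float)
    out = np.empty(x.size)
    for i, v in enumerate(x):
        less = np.sum(x < v)
        equal = np.sum(x == v)
        out[i] = less + (equal + 1) / 2
    return out


class TestWilcoxon:
    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_signed_rank(np.zeros(6))
        assert res.pvalue == 1.0 and res.degenerate

    def test_n5_all_positive_exact(self):
        res = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert res.pvalue == pytest.approx(2 / 32)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 11)
        d = rng.integers(-4, 5, size=n).astype(float)  # ties and zeros likely
        if np.all(d == 0):
            d[0] = 1.0
        ours = wilcoxon_signed_rank(d)
        assert ours.pvalue == pytest.approx(brute_force_wilcoxon(d), abs=1e-12)

    def test_matches_scipy_exact_on_tie_free_data(self):
        rng = np.random.default_rng(3)
        d = rng.standard_normal(12)
        ours = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, method="exact")
        assert ours.pvalue == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_close_to_normal_approximation_at_n15(self):
        rng = np.random.default_rng(9)
        d = rng.standard_normal(15)
        exact = wilcoxon_signed_rank(d).pvalue
        approx = sps.wilcoxon(d, method="approx", correction=True).pvalue
        assert abs(exact - approx) < 0.01

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(5)
        d = rng.standard_normal(40) + 0.5
        ours = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, method="approx", correction=True)
        assert ours.pvalue == pytest.approx(ref.pvalue, rel=0.05)

    def test_paired_series_direction_s2_minus_s1(self):
        s = PairedSeries(subject=np.arange(4), value_s1=np.ones(4),
                         value_s2=np.array([2.0, 3.0, 4.0, 5.0]))
        assert np.all(s.differences > 0)


class TestBlandAltman:
    def test_identical_sessions(self):
        res = bland_altman(np.zeros(5))
        assert res == (0.0, 0.0, 0.0)

    def test_constant_difference(self):
        res = bland_altman(np.array([1.0, 3.0]), np.array([2.0, 4.0]))
        assert res.bias == pytest.approx(1.0)
        assert res.loa_low == pytest.approx(1.0)
        assert res.loa_high == pytest.approx(1.0)

    def test_sign_convention_antisymmetric(self):
        s1 = np.array([1.0, 2.0, 4.0])
        s2 = np.array([2.0, 1.0, 7.0])
        fwd = bland_altman(s1, s2)
        rev = bland_altman(s2, s1)
        assert fwd.bias == pytest.approx(-rev.bias)
        assert fwd.loa_low == pytest.approx(-rev.loa_high)

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            bland_altman(np.array([1.0]))


class TestCv:
    def test_two_sessions_arithmetic(self):
        assert coefficient_of_variation([[9.0, 11.0]]) == \
            pytest.approx(100 * np.sqrt(2) / 10)

    def test_identical_values_zero(self):
        assert coefficient_of_variation([[5.0, 5.0], [2.0, 2.0]]) == 0.0

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([[1.0, -1.0]])

    def test_lognormal_cohort_recovers_target_cv(self):
        """Subjects generated with ~12% multiplicative session noise yield a
        mean CV near 12%."""
        rng = np.random.default_rng(21)
        sigma = np.sqrt(np.log(1 + 0.12 ** 2))
        # several sessions per subject so the sample-sd bias (c4) is small
        values = 5.0 * np.exp(sigma * rng.standard_normal((50, 8)))
        assert coefficient_of_variation(values) == pytest.approx(12.0, abs=2.0)


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman_rho([1, 2, 3, 4, 5], [10, 20, 40, 80, 160])
        assert rho == 1.0
        assert p == pytest.approx(2 / 120)  # two orderings out of 5!

    def test_three_point_example(self):
        rho, _ = spearman_rho([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)

    @pytest.mark.parametrize("seed", range(6))
    def test_rho_matches_brute_force_ranks_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 12)
        x = rng.integers(0, 5, n).astype(float)
        y = rng.integers(0, 5, n).astype(float)
        if np.unique(x).size < 2:
            x[0] += 1
        if np.unique(y).size < 2:
            y[0] += 1
        rho, _ = spearman_rho(x, y)
        rx, ry = brute_force_ranks(x), brute_force_ranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal(9), rng.standard_normal(9)
        rho0, p0 = spearman_rho(x, y)
        rho1, p1 = spearman_rho(np.exp(x), y ** 3)
        assert rho1 == pytest.approx(rho0, abs=1e-12)
        assert p1 == pytest.approx(p0, abs=1e-12)

    def test_permutation_p_matches_exhaustive_small_n(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        rho, p = spearman_rho(x, y)
        rx = brute_force_ranks(x) - 3.0
        target = abs(np.sum(rx * (brute_force_ranks(y) - 3.0)))
        count = sum(
            abs(np.sum(rx * (brute_force_ranks(np.array(perm)) - 3.0)))
            >= target - 1e-9
            for perm in permutations(y)
        )
        assert p == pytest.approx(count / 120)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])


def _stub_quant(bhb, acac=None):
    rows = [dict(row=0, col=0, metabolite="bhb", concentration_mM=bhb,
                 accepted=True, tissue="necrotic_core")]
    rows.append(dict(row=0, col=1, metabolite="acac",
                     concentration_mM=acac if acac is not None else bhb / 2,
                     accepted=True, tissue="ce_tumor"))
    return QuantResult(table=pd.DataFrame(rows), grid_dims=(1, 2))


def _stub_mask(n_necrotic, n_ce=4):
    labels = np.zeros((10, 10), int)
    labels.flat[:n_necrotic] = 2
    labels.flat[50:50 + n_ce] = 3
    return SegMask(labels=labels, voxel_size=(6.0, 6.0, 12.0))


class TestKbVolumeCorrelation:
    def test_proportional_cohort_gives_rho_one(self):
        vols = np.array([3, 5, 8, 11, 15])
        quants = [_stub_quant(0.35 * v * 0.432) for v in vols]
        masks = [_stub_mask(v, n_ce=v + 2) for v in vols]
        table = correlate_kb_volumes(quants, masks)
        nec = table[(table.metabolite == "bhb")
                    & (table.volume_class == "necrotic_core")]
        assert nec.rho.iloc[0] == pytest.approx(1.0)

    def test_null_cohort_rarely_significant(self):
        rng = np.random.default_rng(17)
        n_sig = 0
        for _ in range(100):
            vols = rng.integers(2, 30, size=8)
            quants = [_stub_quant(float(rng.uniform(0.5, 3.0))) for _ in vols]
            masks = [_stub_mask(int(v)) for v in vols]
            table = correlate_kb_volumes(quants, masks, kb_names=("bhb",),
                                         volume_classes=("necrotic_core",))
            if table.p.iloc[0] < 0.05:
                n_sig += 1
        assert n_sig <= 10

    def test_requires_three_subjects(self):
        quants = [_stub_quant(1.0), _stub_quant(2.0)]
        masks = [_stub_mask(3), _stub_mask(5)]
        with pytest.raises(ValueError):
            correlate_kb_volumes(quants, masks)

    def test_correlated_cohort_structure_at_n13(self):
        """Thirteen subjects with beta-OHB proportional to necrotic volume
        plus 10% noise: Spearman rho stays high (the generator's rule behind
        the volume-correlation analysis)."""
        rng = np.random.default_rng(33)
        vols = rng.uniform(2, 25, size=13)
        quants = [_stub_quant(0.35 * v * (1 + 0.1 * rng.standard_normal()))
                  for v in vols]
        masks = [_stub_mask(int(round(v))) for v in vols]
        table = correlate_kb_volumes(quants, masks, kb_names=("bhb",),
                                     volume_classes=("necrotic_core",))
        assert table.rho.iloc[0] >= 0.7
        assert table.p.iloc[0] < 0.05


class TestReport:
    def test_p_stars_thresholds(self):
        assert p_stars(0.2) == "ns"
        assert p_stars(0.04) == "*"
        assert p_stars(0.009) == "**"
        assert p_stars(0.0009) == "***"
        assert p_stars(0.00009) == "****"

    def test_build_report_columns_and_invariants(self):
        rng = np.random.default_rng(2)
        series = [
            PairedSeries(subject=np.arange(8),
                         value_s1=rng.uniform(1, 5, 8),
                         value_s2=rng.uniform(1, 5, 8),
                         name="naa", region="tumor")
        ]
        rep = build_report(series)
        row = rep.summary.iloc[0]
        assert row.loa_low <= row.bias <= row.loa_high
        assert row.mean_cv_pct >= 0
        assert "multiple-testing" in rep.note.lower() or \
            "correction" in rep.note.lower()
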