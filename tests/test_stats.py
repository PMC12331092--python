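"""Mann-Whitney U, boxplot summaries, and the differential HDX significance rule."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from argswitch.errors import DataCompletenessError, EmptyInputError
from argswitch.stats import (
    HDXPeptide,
    box_summary,
    hdx_classify_regions,
    hdx_compare_peptide,
    mann_whitney_u,
    read_hdx_csv,
)


def exact_mw_oracle(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of arrangements.

    Assigns the pooled values to the two groups in every possible way and
    counts arrangements at least as extreme (two-sided, via the symmetric
    tail) as the observed U.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    u_obs = sum(
        1.0 if xi > yj else 0.5 if xi == yj else 0.0 for xi in x for yj in y
    )
    u_low = min(u_obs, n1 * n2 - u_obs)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum(
            1.0 if xi > yj else 0.5 if xi == yj else 0.0 for xi in xs for yj in ys
        )
        if u <= u_low or u >= n1 * n2 - u_low:
            count += 1
        total += 1
    return u_obs, min(1.0, count / total)


class TestMannWhitney:
    def test_disjoint_pairs_exact_third(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1.0 / 3.0, abs=1e-15)

    def test_identical_multisets_tie_path(self):
        res = mann_whitney_u([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert res.method == "normal-approximation"
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_exact_path_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(1, 7, size=2)
        # continuous draws: no ties, exact path
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        res = mann_whitney_u(x, y)
        u_ref, p_ref = exact_mw_oracle(x, y)
        assert res.method == "exact"
        assert res.statistic == u_ref
        assert res.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_u_identity(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n1, n2 = rng.integers(1, 20, size=2)
            x, y = rng.normal(size=n1), rng.integers(0, 5, size=n2).astype(float)
            u_xy = mann_whitney_u(x, y).statistic
            u_yx = mann_whitney_u(y, x).statistic
            assert u_xy + u_yx == pytest.approx(n1 * n2, abs=1e-9)

    def test_invariant_under_shift_and_scale(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=30), rng.normal(size=25) + 0.5
        base = mann_whitney_u(x, y)
        moved = mann_whitney_u(3.0 * x + 7.0, 3.0 * y + 7.0)
        assert moved.p_value == pytest.approx(base.p_value, rel=1e-12)
        assert moved.statistic == base.statistic

    def test_approximation_agrees_with_scipy(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=40)
        y = rng.normal(size=35) + 0.4
        res = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.method == "normal-approximation"
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)
        assert res.statistic == ref.statistic

    def test_empty_sample_rejected(self):
        with pytest.raises(EmptyInputError):
            mann_whitney_u([], [1.0])


class TestBoxSummary:
    def test_one_to_nine(self):
        b = box_summary(range(1, 10))
        assert (b.median, b.q1, b.q3) == (5.0, 3.0, 7.0)
        assert b.outliers == ()
        assert (b.whisker_low, b.whisker_high) == (1.0, 9.0)

    def test_far_point_is_outlier(self):
        b = box_summary([1, 1, 1, 1, 100])
        assert b.outliers == (100.0,)
        assert b.whisker_high == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quantile_definition(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=rng.integers(5, 200))
        b = box_summary(v)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        assert (b.q1, b.median, b.q3) == (q1, med, q3)
        iqr = q3 - q1
        inside = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
        assert b.whisker_low == inside.min()
        assert b.whisker_high == inside.max()
        assert sorted(b.outliers) == sorted(v[(v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)])
        # ordering invariants
        assert b.q1 <= b.median <= b.q3


def _peptide(uptake_a, uptake_b, start=292, end=302):
    times = [10.0, 100.0, 1000.0, 10000.0]
    return HDXPeptide(
        start_res=start,
        end_res=end,
        uptake={
            "apo": {t: np.asarray(u) for t, u in zip(times, uptake_a)},
            "bound": {t: np.asarray(u) for t, u in zip(times, uptake_b)},
        },
    )


class TestHDXCompare:
    def test_small_delta_never_significant(self):
        # delta 0.15 Da with essentially zero variance: p tiny, still ns
        a = [[1.0, 1.0001, 0.9999]] * 4
        b = [[1.15, 1.1501, 1.1499]] * 4
        rows = hdx_compare_peptide(_peptide(a, b), "apo", "bound")
        assert all(r.p_value < 0.001 for r in rows)
        assert not any(r.significant for r in rows)

    def test_identical_states_not_significant(self):
        a = [[1.0, 1.1, 0.9]] * 4
        rows = hdx_compare_peptide(_peptide(a, a), "apo", "bound")
        assert all(r.delta_Da == 0.0 and not r.significant for r in rows)

    def test_half_dalton_shift_called_at_every_timepoint(self):
        rng = np.random.default_rng(31)
        a = [list(1.0 + rng.normal(0, 0.05, 3)) for _ in range(4)]
        b = [list(1.5 + rng.normal(0, 0.05, 3)) for _ in range(4)]
        rows = hdx_compare_peptide(_peptide(a, b), "apo", "bound")
        assert all(r.significant and r.delta_Da > 0 for r in rows)

    def test_pooled_t_equals_anova(self):
        # two-group one-way ANOVA and the pooled t test are the same test
        rng = np.random.default_rng(7)
        a = rng.normal(1.0, 0.1, 3)
        b = rng.normal(1.6, 0.1, 3)
        row = hdx_compare_peptide(
            _peptide([a] * 4, [b] * 4), "apo", "bound"
        )[0]
        assert row.p_value == pytest.approx(sps.f_oneway(a, b).pvalue, rel=1e-10)

    def test_missing_state_is_error(self):
        p = _peptide([[1, 1, 1]] * 4, [[1, 1, 1]] * 4)
        with pytest.raises(DataCompletenessError, match="holo"):
            hdx_compare_peptide(p, "apo", "holo")

    def test_single_replicate_is_error(self):
        p = _peptide([[1.0]] * 4, [[1.0, 1.1]] * 4)
        with pytest.raises(DataCompletenessError, match="replicates"):
            hdx_compare_peptide(p, "apo", "bound")


class TestHDXClassify:
    def _rows(self, deltas_sig):
        from argswitch.stats import HDXComparisonRow

        return [
            HDXComparisonRow(292, 302, 10.0 ** (i + 1), d, 0.01 if s else 0.5, s)
            for i, (d, s) in enumerate(deltas_sig)
        ]

    def test_all_positive_significant(self):
        rows = self._rows([(0.5, True)] * 4)
        assert hdx_classify_regions(rows) == {"292-302": "increased"}

    def test_none_significant(self):
        rows = self._rows([(0.5, False), (0.1, False)])
        assert hdx_classify_regions(rows) == {"292-302": "ns"}

    def test_mixed_signs(self):
        rows = self._rows([(0.5, True), (-0.4, True)])
        assert hdx_classify_regions(rows) == {"292-302": "mixed"}

    def test_decreased(self):
        rows = self._rows([(-0.5, True), (-0.1, False)])
        assert hdx_classify_regions(rows) == {"292-302": "decreased"}

    def test_permutation_invariant_over_timepoints(self):
        rows = self._rows([(0.5, True), (-0.4, True), (0.2, False), (0.6, True)])
        for perm in itertools.permutations(rows):
            assert hdx_classify_regions(list(perm)) == {"292-302": "mixed"}


class TestBenjaminiHochberg:
    def test_adjustment_matches_scipy_and_keeps_floor(self):
        from argswitch.stats import HDXComparisonRow, benjamini_hochberg

        rows = [
            HDXComparisonRow(292, 302, 10.0, 0.5, 0.01, True),
            HDXComparisonRow(292, 302, 100.0, 0.5, 0.04, True),
            HDXComparisonRow(119, 133, 10.0, 0.15, 0.001, False),  # below floor
            HDXComparisonRow(119, 133, 100.0, -0.4, 0.8, False),
        ]
        adjusted = benjamini_hochberg(rows)
        ref = sps.false_discovery_control([r.p_value for r in rows], method="bh")
        assert [r.p_value for r in adjusted] == pytest.approx(list(ref))
        # the 0.2 Da floor still vetoes regardless of adjusted p
        assert not adjusted[2].significant
        # raw deltas carried through
        assert [r.delta_Da for r in adjusted] == [0.5, 0.5, 0.15, -0.4]


class TestHDXCSV:
    def test_round_trip_through_csv(self, tmp_path):
        from argswitch.synth import HDXPeptideSpec, HDXSimParams, gen_hdx_dataset

        spec = HDXPeptideSpec(
            start_res=292, end_res=302, n_exchangeable=8, k_int=0.5,
            protection={"apo": 100.0, "bound": 50.0},
        )
        df, _ = gen_hdx_dataset(HDXSimParams(peptides=(spec,), seed=1))
        path = tmp_path / "uptake.csv"
        df.to_csv(path, index=False)
        peptides = read_hdx_csv(str(path))
        assert len(peptides) == 1
        assert peptides[0].start_res == 292
        assert set(peptides[0].uptake) == {"apo", "bound"}
        assert all(len(v) == 3 for v in peptides[0].uptake["apo"].values())

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("peptide_start,peptide_end,state\n1,2,apo\n")
        with pytest.raises(DataCompletenessError, match="timepoint_s"):
            read_hdx_csv(str(path))
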