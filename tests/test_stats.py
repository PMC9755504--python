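"""Region statistics: CV, ICC(A,1) against independent oracles, RAD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kmdev as km
from kmdev.stats import SubjectSessionTable, icc_a1


def icc_a1_bruteforce(x):
    """Independent sums-of-squares oracle for the absolute-agreement
    single-rater two-way ICC, written from the ANOVA identity directly."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)


class TestCoefficientOfVariation:
    def test_hand_computed_values(self):
        assert km.coefficient_of_variation([1, 1, 1]) == 0.0
        assert km.coefficient_of_variation([1.0, 1.2]) == pytest.approx(
            12.856487, abs=1e-6
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            km.coefficient_of_variation([1.0])
        with pytest.raises(ValueError):
            km.coefficient_of_variation([1.0, -1.0])

    @given(
        st.lists(st.floats(0.5, 2.0), min_size=3, max_size=12),
        st.floats(0.1, 50.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, values, c):
        base = km.coefficient_of_variation(values)
        scaled = km.coefficient_of_variation([v * c for v in values])
        assert scaled == pytest.approx(base, abs=1e-8)


class TestIcc:
    def test_perfect_agreement(self):
        t = SubjectSessionTable(np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]))
        r = icc_a1(t)
        assert r.icc == pytest.approx(1.0)

    def test_matches_bruteforce_oracle_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = rng.integers(3, 12)
            k = rng.integers(2, 5)
            x = rng.normal(0, 1, (n, k)) + rng.normal(0, 1, (n, 1))
            r = icc_a1(SubjectSessionTable(x))
            assert r.icc == pytest.approx(icc_a1_bruteforce(x), abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        x = rng.normal(1.2, 0.1, (11, 2)) + rng.normal(0, 0.05, (11, 1))
        r = icc_a1(SubjectSessionTable(x))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(11), 2),
                "session": np.tile(np.arange(2), 11),
                "value": x.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="subject", raters="session", ratings="value"
        ).set_index("Type")
        row = ref.loc["ICC(A,1)"] if "ICC(A,1)" in ref.index else ref.loc["ICC2"]
        ci_col = "CI95" if "CI95" in ref.columns else "CI95%"
        assert r.icc == pytest.approx(row["ICC"], abs=1e-8)
        assert r.ci_low == pytest.approx(row[ci_col][0], abs=5e-3)
        assert r.ci_high == pytest.approx(row[ci_col][1], abs=5e-3)

    def test_destroyed_agreement_low_icc(self):
        rng = np.random.default_rng(3)
        base = rng.normal(1.2, 0.1, 50)
        x = np.column_stack(
            [rng.permutation(base), rng.permutation(base)]
        )
        assert icc_a1(SubjectSessionTable(x)).icc <= 0.2

    def test_parameter_recovery(self):
        """ICC → σ_b²/(σ_b²+σ_w²) for large n."""
        rng = np.random.default_rng(17)
        sigma_b, sigma_w = 0.08, 0.04
        n = 200
        subj = rng.normal(1.25, sigma_b, (n, 1))
        x = subj + rng.normal(0, sigma_w, (n, 2))
        expected = sigma_b**2 / (sigma_b**2 + sigma_w**2)
        assert icc_a1(SubjectSessionTable(x)).icc == pytest.approx(expected, abs=0.05)

    def test_degenerate_table(self):
        r = icc_a1(SubjectSessionTable(np.full((4, 2), 1.3)))
        assert r.icc == 1.0 and r.degenerate

    def test_invariances(self):
        rng = np.random.default_rng(9)
        x = rng.normal(1.2, 0.1, (10, 2)) + rng.normal(0, 0.03, (10, 1))
        base = icc_a1(SubjectSessionTable(x)).icc
        assert icc_a1(SubjectSessionTable(x + 5.0)).icc == pytest.approx(base, abs=1e-10)
        assert icc_a1(SubjectSessionTable(x * 3.0)).icc == pytest.approx(base, abs=1e-10)

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            icc_a1(SubjectSessionTable(np.ones((2, 2))))


class TestRad:
    def test_hand_computed_values(self):
        assert km.relative_absolute_difference([1.0], [1.0]).mean == 0.0
        assert km.relative_absolute_difference([1.0], [1.01]).mean == pytest.approx(
            0.995025, abs=1e-6
        )
        assert km.relative_absolute_difference([2.0], [1.0]).mean == pytest.approx(
            66.6667, abs=1e-3
        )

    def test_mean_and_sd_across_subjects(self):
        r = km.relative_absolute_difference([1.0, 2.0], [1.01, 2.0])
        assert r.per_subject.shape == (2,)
        assert r.mean == pytest.approx(r.per_subject.mean())

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            km.relative_absolute_difference([1.0, -1.0], [1.0, 1.0])

    @given(st.floats(0.5, 2.0), st.floats(0.5, 2.0), st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, a, b, c):
        base = km.relative_absolute_difference([a], [b]).mean
        scaled = km.relative_absolute_difference([a * c], [b * c]).mean
        assert scaled == pytest.approx(base, abs=1e-8)


class TestRegionMean:
    def test_uniform_and_mixed_regions(self, small_grid):
        labels = np.zeros(small_grid.shape, np.int32)
        labels[:8] = 1
        labels[8:16] = 2
        mask = km.RegionMask(labels=labels, names={1: "DGM", 2: "mix"})
        sws = np.ones(small_grid.shape)
        sws[labels == 1] = 1.42
        sws[8:12] = 1.0
        sws[12:16] = 2.0
        pm = km.ParameterMap(
            grid=small_grid,
            sws=sws,
            pr=np.ones(small_grid.shape),
            valid_mask=np.ones(small_grid.shape, bool),
            mode="2d",
        )
        assert km.region_mean(pm, mask, 1)[0] == pytest.approx(1.42)
        assert km.region_mean(pm, mask, 2)[0] == pytest.approx(1.5)

    def test_region_in_trimmed_slices_errors(self, small_grid):
        labels = np.zeros(small_grid.shape, np.int32)
        labels[:, :, 0] = 1
        mask = km.RegionMask(labels=labels, names={1: "edge"})
        valid = np.ones(small_grid.shape, bool)
        valid[:, :, 0] = False
        ones = np.ones(small_grid.shape)
        pm = km.ParameterMap(
            grid=small_grid, sws=ones, pr=ones, valid_mask=valid, mode="2d"
        )
        with pytest.raises(ValueError, match="no valid voxels"):
            km.region_mean(pm, mask, 1)
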