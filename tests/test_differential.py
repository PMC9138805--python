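"""Preprocessing, screening, BH adjustment and cohort generation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lipidmrm.cohort import CohortDesign, default_cohort_species, generate_cohort
from lipidmrm.differential import (
    LipidMatrix,
    abundance_shares,
    bh_adjust,
    class_sum_normalize,
    preprocess,
    wilcoxon_screen,
)


def toy_matrix(values, groups=None, classes=None):
    df = pd.DataFrame(values)
    df.index = [f"s{i}" for i in range(df.shape[0])]
    meta = pd.DataFrame(
        {
            "group": groups or ["deficient"] * (df.shape[0] // 2)
            + ["normal"] * (df.shape[0] - df.shape[0] // 2)
        },
        index=df.index,
    )
    cls = pd.Series(classes or {c: "PC" for c in df.columns})
    return LipidMatrix(df, meta, cls)


class TestPreprocess:
    def cohort_with_missing(self, n_missing):
        rng = np.random.default_rng(0)
        values = rng.uniform(10, 100, (93, 3))
        df = pd.DataFrame(values, columns=["keep", "edge", "full"])
        df.iloc[:n_missing, 1] = np.nan
        mat = toy_matrix(df.to_numpy())
        mat.areas.columns = ["keep", "edge", "full"]
        mat = LipidMatrix(
            mat.areas, mat.sample_meta,
            pd.Series({"keep": "PC", "edge": "PC", "full": "PC"}),
        )
        return mat

    def test_species_missing_in_ten_samples_removed(self):
        out = preprocess(self.cohort_with_missing(10))
        assert "edge" not in out.areas.columns

    def test_species_missing_in_nine_samples_imputed(self):
        mat = self.cohort_with_missing(9)
        median = mat.areas["edge"].median()
        out = preprocess(mat)
        assert "edge" in out.areas.columns
        assert not out.areas.isna().any().any()
        # the imputed rows carry the species median before normalization
        raw = mat.areas.fillna(mat.areas.median())
        assert np.allclose(raw["edge"].iloc[:9], median)

    def test_class_columns_sum_to_one_per_sample(self):
        out = preprocess(self.cohort_with_missing(3))
        sums = out.areas.sum(axis=1)  # single class here
        assert np.allclose(sums, 1.0)

    def test_hand_computed_toy_imputation(self):
        values = np.array([[2.0, 6.0], [np.nan, 4.0], [4.0, 2.0]])
        mat = toy_matrix(values, groups=["deficient", "deficient", "normal"])
        out = preprocess(mat, missing_sample_cutoff=2)
        # species 0 median of (2, 4) = 3 -> rows (2,6), (3,4), (4,2)
        expected = np.array([[2 / 8, 6 / 8], [3 / 7, 4 / 7], [4 / 6, 2 / 6]])
        assert np.allclose(out.areas.to_numpy(), expected)

    def test_normalization_preserves_within_class_ratios(self, rng):
        values = rng.uniform(1, 50, (6, 4))
        mat = toy_matrix(values)
        out = class_sum_normalize(mat)
        before = values[:, 0] / values[:, 1]
        after = out.areas.iloc[:, 0] / out.areas.iloc[:, 1]
        assert np.allclose(before, after)


class TestWilcoxonScreen:
    def test_fully_separated_three_vs_three_exact_p(self):
        """All of one group above the other: exact two-sided p = 2/C(6,3)."""
        values = np.array([[10.0], [11.0], [12.0], [1.0], [2.0], [3.0]])
        mat = toy_matrix(values, groups=["deficient"] * 3 + ["normal"] * 3)
        out = wilcoxon_screen(mat)
        assert out["p_value"].iloc[0] == pytest.approx(0.10, abs=1e-12)
        assert not out["candidate"].iloc[0]  # p gate fails at 0.05

    def test_fold_change_gate_blocks_small_effects(self, rng):
        base = rng.normal(100, 0.5, 30)
        values = np.column_stack([np.r_[base[:15] * 1.2, base[15:]]])
        mat = toy_matrix(values, groups=["deficient"] * 15 + ["normal"] * 15)
        out = wilcoxon_screen(mat)
        assert out["p_value"].iloc[0] < 0.001
        assert 1.1 < out["fold_change"].iloc[0] < 1.3
        assert not out["candidate"].iloc[0]

    def test_identical_groups_p_one(self):
        values = np.full((10, 1), 7.0)
        mat = toy_matrix(values)
        out = wilcoxon_screen(mat)
        assert out["p_value"].iloc[0] == 1.0
        assert out["fold_change"].iloc[0] == 1.0
        assert not out["candidate"].iloc[0]


def brute_force_bh(p):
    """Step-up definition: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1]
    )[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_reference_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.all(bh_adjust(np.ones(5)) == 1.0)

    def test_oracle_equivalence_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestAbundanceShares:
    def test_single_species_single_isomer(self):
        df = pd.DataFrame({"species": ["a"], "isomer": ["a/1"], "area": [42.0]})
        sp, iso = abundance_shares(df)
        assert sp["a"] == 1.0
        assert iso[("a", "a/1")] == 1.0

    def test_two_isomer_split(self):
        df = pd.DataFrame({
            "species": ["a", "a"], "isomer": ["a/1", "a/2"],
            "area": [52.4, 47.6],
        })
        sp, iso = abundance_shares(df)
        assert iso[("a", "a/1")] == pytest.approx(0.524)
        assert iso[("a", "a/2")] == pytest.approx(0.476)

    def test_shares_sum_to_one_at_both_levels(self, rng):
        df = pd.DataFrame({
            "species": [f"s{i // 3}" for i in range(60)],
            "isomer": [f"s{i // 3}/i{i % 3}" for i in range(60)],
            "area": rng.uniform(1, 100, 60),
        })
        sp, iso = abundance_shares(df)
        assert sp.sum() == pytest.approx(1.0, abs=1e-12)
        for s, sub in iso.groupby(level=0):
            assert sub.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_rejected(self):
        df = pd.DataFrame({"species": ["a"], "isomer": ["a/1"], "area": [0.0]})
        with pytest.raises(ValueError, match="zero grand total"):
            abundance_shares(df)


class TestGenerateCohort:
    def test_same_seed_identical(self):
        a = generate_cohort(CohortDesign(seed=3))
        b = generate_cohort(CohortDesign(seed=3))
        pd.testing.assert_frame_equal(a.areas, b.areas)
        pd.testing.assert_frame_equal(a.sample_meta, b.sample_meta)

    def test_default_shape_mirrors_study(self):
        mat = generate_cohort(CohortDesign(seed=1))
        assert mat.areas.shape == (93, 759)
        assert (mat.sample_meta["group"] == "deficient").sum() == 47
        assert (mat.sample_meta["group"] == "normal").sum() == 46
        assert mat.sample_meta["batch"].nunique() == 2

    def test_null_design_groups_exchangeable(self):
        design = CohortDesign(seed=5, planted=(), batch_loc_sd=0.0,
                              batch_scale_sd=0.0, missing_rate=0.0,
                              sex_effect_sd=0.0)
        mat = generate_cohort(design)
        logs = np.log(mat.areas.to_numpy())
        centered = logs - logs.mean(axis=0)
        g = mat.sample_meta["group"].to_numpy()
        ks = sps.ks_2samp(
            centered[g == "deficient"].ravel(), centered[g == "normal"].ravel()
        )
        assert ks.pvalue > 0.01

    def test_planted_fold_change_realized(self):
        """Across seeds, the realized group-mean ratio tracks the design FC."""
        species = default_cohort_species()
        target = species.index[0]
        ratios = []
        for seed in range(5):
            design = CohortDesign(
                n_deficient=40, n_normal=40, seed=seed,
                planted=((target, 2.0),), missing_rate=0.0,
                batch_loc_sd=0.0, batch_scale_sd=0.0,
            )
            mat = generate_cohort(design)
            g = mat.sample_meta["group"]
            ratios.append(
                mat.areas.loc[g == "deficient", target].mean()
                / mat.areas.loc[g == "normal", target].mean()
            )
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.1)

    def test_missingness_rate_near_design(self):
        mat = generate_cohort(CohortDesign(seed=2, missing_rate=0.01))
        frac = mat.areas.isna().to_numpy().mean()
        assert frac == pytest.approx(0.01, rel=0.3)
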