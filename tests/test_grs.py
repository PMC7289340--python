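"""Genetic risk score construction: orientation, scaling, calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bmigrowth.grs import (
    build_grs,
    compute_raw_score,
    load_weight_table,
    scale_scores,
    synthetic_weight_table,
)


def _weights(w_m, w_f=None, alleles=None):
    n = len(w_m)
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(n)],
            "effect_allele": alleles or ["A"] * n,
            "weight_male": w_m,
            "weight_female": w_f if w_f is not None else w_m,
        }
    )


def _dosages(mat, n_snps):
    df = pd.DataFrame(np.asarray(mat, dtype=float), columns=[f"s{i}" for i in range(n_snps)])
    df.insert(0, "child_id", [f"c{i}" for i in range(len(df))])
    return df


def _sexes(n, sex="male"):
    return pd.Series([sex] * n, index=[f"c{i}" for i in range(n)])


class TestRawScore:
    def test_zero_dosages_give_zero_score(self):
        w = _weights([0.1, 0.2, 0.3])
        d = _dosages(np.zeros((4, 3)), 3)
        raw = compute_raw_score(d, w, _sexes(4))
        assert np.all(raw.to_numpy() == 0.0)

    def test_three_snp_hand_arithmetic(self):
        w = _weights([0.1, 0.2, 0.3])
        d = _dosages([[2.0, 1.0, 0.0]], 3)
        raw = compute_raw_score(d, w, _sexes(1))
        assert abs(raw.iloc[0] - 0.4) < 1e-12

    def test_sex_specific_weight_column_used(self):
        w = _weights([0.1, 0.2], w_f=[0.4, 0.5])
        d = _dosages([[1.0, 1.0], [1.0, 1.0]], 2)
        sex = pd.Series(["male", "female"], index=["c0", "c1"])
        raw = compute_raw_score(d, w, sex)
        assert abs(raw.loc["c0"] - 0.3) < 1e-12
        assert abs(raw.loc["c1"] - 0.9) < 1e-12

    def test_orientation_flip_is_invariant(self):
        """Negating a stored weight while counting the opposite allele
        leaves every child's raw score unchanged."""
        rng = np.random.default_rng(0)
        d0 = rng.integers(0, 3, size=(20, 3)).astype(float)
        w = _weights([0.1, 0.2, 0.3])
        raw0 = compute_raw_score(_dosages(d0, 3), w, _sexes(20))
        w_flip = _weights([0.1, -0.2, 0.3])
        d_flip = d0.copy()
        d_flip[:, 1] = 2.0 - d_flip[:, 1]
        raw1 = compute_raw_score(_dosages(d_flip, 3), w_flip, _sexes(20))
        np.testing.assert_allclose(raw0.to_numpy(), raw1.to_numpy(), atol=1e-12)

    def test_snp_column_permutation_invariant(self):
        rng = np.random.default_rng(1)
        d = _dosages(rng.integers(0, 3, size=(10, 4)), 4)
        w = _weights([0.1, 0.2, 0.3, 0.4])
        raw0 = compute_raw_score(d, w, _sexes(10))
        shuffled = d[["child_id", "s2", "s0", "s3", "s1"]]
        raw1 = compute_raw_score(shuffled, w, _sexes(10))
        np.testing.assert_allclose(raw0.to_numpy(), raw1.to_numpy(), atol=1e-14)

    def test_unmatched_snp_ids_rejected(self):
        w = _weights([0.1, 0.2])
        d = _dosages(np.ones((2, 2)), 2).rename(columns={"s1": "sX"})
        with pytest.raises(ValueError, match="mismatch"):
            compute_raw_score(d, w, _sexes(2))

    def test_missing_dosage_cell_rejected(self):
        w = _weights([0.1, 0.2])
        d = _dosages(np.ones((2, 2)), 2)
        d.loc[0, "s1"] = np.nan
        with pytest.raises(ValueError, match="missing dosage"):
            compute_raw_score(d, w, _sexes(2))


class TestWeightTable:
    def test_negative_weights_oriented_nonnegative(self):
        w = load_weight_table(_weights([0.1, -0.2], w_f=[0.15, -0.1]))
        assert (w["weight_male"] >= 0).all() and (w["weight_female"] >= 0).all()
        assert list(w["flipped"]) == [False, True]

    def test_sex_sign_disagreement_rejected(self):
        with pytest.raises(ValueError, match="disagree in sign"):
            load_weight_table(_weights([0.1, -0.2], w_f=[0.15, 0.1]))

    def test_duplicate_snp_rejected(self):
        w = _weights([0.1, 0.2])
        w.loc[1, "snp_id"] = "s0"
        with pytest.raises(ValueError, match="duplicate"):
            load_weight_table(w)


class TestScaling:
    def test_affine_map_on_three_scores(self):
        raw = pd.Series([1.0, 2.0, 3.0], index=["c0", "c1", "c2"])
        out = scale_scores(raw, _sexes(3))
        np.testing.assert_allclose(sorted(out["scaled_score"]), [0.0, 5.0, 10.0])

    def test_scaled_range_exact_per_sex(self):
        rng = np.random.default_rng(2)
        idx = [f"c{i}" for i in range(100)]
        raw = pd.Series(rng.normal(size=100), index=idx)
        sex = pd.Series(["male"] * 50 + ["female"] * 50, index=idx)
        out = scale_scores(raw, sex)
        for s in ("male", "female"):
            grp = out.loc[out["sex"] == s, "scaled_score"]
            assert grp.min() == 0.0 and grp.max() == 10.0

    def test_additive_shift_leaves_scaled_unchanged(self):
        rng = np.random.default_rng(3)
        raw = pd.Series(rng.normal(size=30), index=[f"c{i}" for i in range(30)])
        a = scale_scores(raw, _sexes(30))["scaled_score"]
        b = scale_scores(raw + 13.7, _sexes(30))["scaled_score"]
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_identical_scores_rejected(self):
        raw = pd.Series([1.0, 1.0], index=["c0", "c1"])
        with pytest.raises(ValueError, match="identical"):
            scale_scores(raw, _sexes(2))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=40, unique=True))
    def test_scaling_is_monotone_in_raw_score(self, values):
        idx = [f"c{i}" for i in range(len(values))]
        raw = pd.Series(values, index=idx)
        out = scale_scores(raw, _sexes(len(values)))
        order = np.argsort(raw.to_numpy(), kind="stable")
        assert np.all(np.diff(out["scaled_score"].to_numpy()[order]) >= 0.0)

    def test_single_sex_input_handled(self):
        raw = pd.Series([0.0, 1.0, 4.0], index=["c0", "c1", "c2"])
        out = scale_scores(raw, _sexes(3, "female"))
        assert out["scaled_score"].max() == 10.0


class TestCalibration:
    def test_alleles_per_unit_is_count_range_over_ten(self):
        """With equal weights the raw score is proportional to the allele
        count, so alleles-per-unit equals exactly (max-min)/10."""
        rng = np.random.default_rng(4)
        n = 200
        dos = rng.binomial(2, 0.4, size=(n, 10)).astype(float)
        d = _dosages(dos, 10)
        w = _weights([0.05] * 10)
        out = build_grs(d, w, _sexes(n))
        counts = dos.sum(axis=1)
        expected = (counts.max() - counts.min()) / 10.0
        np.testing.assert_allclose(out["alleles_per_unit"].to_numpy(), expected)

    def test_synthetic_panel_shape(self):
        t = synthetic_weight_table()
        assert len(t) == 94
        assert (t["weight_male"] > 0).all() and (t["weight_female"] > 0).all()
        assert t["allele_freq"].between(0.01, 0.99).all()

    def test_realistic_panel_allele_count_distribution(self):
        """The default synthetic panel should put per-child risk-allele
        counts on the scale reported for 94-SNP adult-BMI panels (mean in
        the 90s, range spanning roughly 70-120)."""
        from bmigrowth import default_truth, generate_cohort

        truth = default_truth(n_children=800, seed=9)
        w = synthetic_weight_table()
        _, dos = generate_cohort(truth, snp_ids=list(w["snp_id"]))
        counts = dos.drop(columns="child_id").to_numpy().sum(axis=1)
        assert 88 < counts.mean() < 100
        assert counts.max() - counts.min() > 30
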