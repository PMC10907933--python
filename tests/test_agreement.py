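"""Bland-Altman, ICC(2,1), MAE and subgroup statistics against oracles."""

import numpy as np
import pandas as pd
import pytest

from radarbreath import (
    DeviceErrorLaw,
    bland_altman,
    generate_paired_measurements,
    icc_absolute_agreement,
    mae,
    subgroup_agreement,
)


def pairs_from_diffs(diffs, reference=15.0, subject="s0"):
    diffs = np.asarray(diffs, dtype=float)
    return pd.DataFrame(
        {
            "subject_id": subject,
            "time_s": np.arange(diffs.size) * 900.0,
            "rr_device": reference + diffs,
            "rr_reference": reference,
            "sex": "female",
            "dx_group": "cardiopulmonary",
        }
    )


def icc21_oracle(y):
    """Brute-force two-way ANOVA ICC(2,1) from explicit sums of squares."""
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    grand = y.mean()
    msr = k * ((y.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((y.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    resid = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + grand
    mse = (resid**2).sum() / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestBlandAltman:
    def test_hand_computed_example(self):
        """Differences [1,-1,2,-2]: bias 0, sd sqrt(10/3), LoA +-3.579."""
        report = bland_altman(pairs_from_diffs([1, -1, 2, -2]))
        assert report.bias == pytest.approx(0.0, abs=1e-12)
        assert report.sd_diff == pytest.approx(np.sqrt(10.0 / 3.0), abs=1e-9)
        assert report.loa_high == pytest.approx(1.96 * np.sqrt(10.0 / 3.0), abs=1e-6)
        assert report.pct_within_clinical == 100.0

    def test_identical_columns(self):
        report = bland_altman(pairs_from_diffs(np.zeros(5)))
        assert report.bias == 0.0 and report.sd_diff == 0.0
        assert report.loa_low == report.loa_high == 0.0
        assert report.pct_within_clinical == 100.0

    def test_clinical_fraction_30_of_88(self):
        diffs = np.concatenate([np.full(30, 1.0), np.full(58, 5.0)])
        report = bland_altman(pairs_from_diffs(diffs))
        assert report.pct_within_clinical == pytest.approx(100 * 30 / 88, abs=1e-9)
        assert round(report.pct_within_clinical) == 34

    def test_midpoint_identity(self):
        rng = np.random.default_rng(0)
        report = bland_altman(pairs_from_diffs(rng.normal(size=40)))
        assert (report.loa_low + report.loa_high) / 2 == pytest.approx(report.bias, abs=1e-12)

    def test_pct_within_monotone_in_limit(self):
        rng = np.random.default_rng(1)
        pairs = pairs_from_diffs(rng.normal(0, 3, 60))
        pcts = [bland_altman(pairs, clinical_limit=c).pct_within_clinical for c in (1, 2, 4, 8)]
        assert all(a <= b for a, b in zip(pcts, pcts[1:]))

    def test_proportional_bias_slope(self):
        ref = np.linspace(8, 28, 40)
        dev = ref - 0.5 * (ref - 18.0)  # slope of d on ref is -0.5
        pairs = pairs_from_diffs(np.zeros(40))
        pairs["rr_reference"], pairs["rr_device"] = ref, dev
        report = bland_altman(pairs)
        # d = -0.5 (ref - 18); mean = ref - 0.25 (ref - 18) => d = -2/3 (mean - 18)
        assert report.slope_vs_mean == pytest.approx(-2.0 / 3.0, abs=1e-9)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="2 pairs"):
            bland_altman(pairs_from_diffs([1.0]))


class TestIcc:
    def test_perfect_agreement(self):
        pairs = pairs_from_diffs(np.zeros(5))
        pairs["rr_reference"] = [10.0, 14.0, 18.0, 22.0, 26.0]
        pairs["rr_device"] = pairs["rr_reference"]
        assert icc_absolute_agreement(pairs).icc == pytest.approx(1.0, abs=1e-12)

    def test_reversed_ranks_match_anova_oracle(self):
        pairs = pairs_from_diffs(np.zeros(3))
        pairs["rr_reference"] = [1.0, 2.0, 3.0]
        pairs["rr_device"] = [3.0, 2.0, 1.0]
        y = np.column_stack([pairs.rr_device, pairs.rr_reference])
        oracle = icc21_oracle(y)
        assert oracle < 0
        assert icc_absolute_agreement(pairs).icc == pytest.approx(oracle, abs=1e-9)

    def test_random_tables_match_anova_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            ref = rng.normal(18, 4, 6)
            dev = ref + rng.normal(0.5, 2, 6)
            pairs = pairs_from_diffs(np.zeros(6))
            pairs["rr_reference"], pairs["rr_device"] = ref, dev
            report = icc_absolute_agreement(pairs)
            assert report.icc == pytest.approx(
                icc21_oracle(np.column_stack([dev, ref])), abs=1e-9
            )
            assert report.ci_low <= report.icc <= report.ci_high

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        n = 30
        ref = rng.normal(18, 4, n)
        dev = ref + rng.normal(-0.7, 3.0, n)
        pairs = pairs_from_diffs(np.zeros(n))
        pairs["rr_reference"], pairs["rr_device"] = ref, dev
        mine = icc_absolute_agreement(pairs)
        long = pd.DataFrame(
            {
                "targets": np.tile(np.arange(n), 2),
                "raters": ["dev"] * n + ["ref"] * n,
                "scores": np.concatenate([dev, ref]),
            }
        )
        table = pg.intraclass_corr(long, targets="targets", raters="raters", ratings="scores")
        row = table[table.Type == "ICC2"].iloc[0] if "ICC2" in set(table.Type) else table[
            table.Type == "ICC(A,1)"
        ].iloc[0]
        assert mine.icc == pytest.approx(float(row.ICC), abs=1e-9)
        assert mine.ci_low == pytest.approx(row.CI95[0], abs=0.01)
        assert mine.ci_high == pytest.approx(row.CI95[1], abs=0.01)

    def test_variance_component_recovery(self):
        """ICC converges to sigma_row^2 / (sigma_row^2 + sigma_err^2)."""
        rng = np.random.default_rng(6)
        n = 4000
        truth = rng.normal(18, 4, n)  # sigma_row^2 = 16
        noise = 2.0  # sigma_err^2 = 4 per method
        pairs = pairs_from_diffs(np.zeros(n))
        pairs["rr_reference"] = truth + rng.normal(0, noise, n)
        pairs["rr_device"] = truth + rng.normal(0, noise, n)
        expected = 16.0 / (16.0 + 4.0)
        assert icc_absolute_agreement(pairs).icc == pytest.approx(expected, abs=0.03)

    def test_common_constant_invariance_and_offset_penalty(self):
        rng = np.random.default_rng(7)
        ref = rng.normal(18, 4, 20)
        dev = ref + rng.normal(0, 1, 20)
        pairs = pairs_from_diffs(np.zeros(20))
        pairs["rr_reference"], pairs["rr_device"] = ref, dev
        base = icc_absolute_agreement(pairs).icc
        shifted = pairs.copy()
        shifted["rr_reference"] += 5.0
        shifted["rr_device"] += 5.0
        assert icc_absolute_agreement(shifted).icc == pytest.approx(base, abs=1e-9)
        offset = pairs.copy()
        offset["rr_device"] += 3.0
        assert icc_absolute_agreement(offset).icc < base

    def test_degenerate_table_rejected(self):
        pairs = pairs_from_diffs(np.zeros(4))  # all cells identical
        with pytest.raises(ValueError, match="undefined"):
            icc_absolute_agreement(pairs)


class TestMae:
    def test_single_subject(self):
        report = mae(pairs_from_diffs([1.0, -1.0, 2.0]))
        assert report.mae_overall == pytest.approx(4.0 / 3.0, abs=1e-12)

    def test_two_subjects_unweighted_mean_and_range(self):
        a = pairs_from_diffs([1.0, -1.0], subject="a")
        b = pairs_from_diffs([3.0, -3.0], subject="b")
        report = mae(pd.concat([a, b], ignore_index=True))
        assert report.mae_overall == pytest.approx(2.0)
        assert report.mae_range == (1.0, 3.0)
        assert report.per_subject_mae == {"a": 1.0, "b": 3.0}

    def test_folded_normal_expectation(self):
        """With d ~ N(0, s), E|d| = s sqrt(2/pi)."""
        rng = np.random.default_rng(8)
        s = 3.0
        report = mae(pairs_from_diffs(rng.normal(0, s, 20000)))
        assert report.mae_overall == pytest.approx(s * np.sqrt(2 / np.pi), rel=0.03)


class TestSubgroups:
    def test_single_group_equals_pooled(self):
        rng = np.random.default_rng(9)
        pairs = pairs_from_diffs(rng.normal(0, 2, 30))
        groups = subgroup_agreement(pairs, "sex")
        assert list(groups) == ["female"]
        pooled = bland_altman(pairs)
        assert groups["female"]["bland_altman"] == pooled

    def test_group_biases_recovered(self):
        """Two diagnosis groups with distinct generating biases separate cleanly."""
        law_cp = DeviceErrorLaw(bias_bpm=-2.39, sd_bpm=2.0)
        law_ncp = DeviceErrorLaw(bias_bpm=1.21, sd_bpm=2.0)
        cp = generate_paired_measurements(40, 8, device_error=law_cp, p_cardiopulmonary=1.0, seed=1)
        ncp = generate_paired_measurements(
            40, 8, device_error=law_ncp, p_cardiopulmonary=0.0, seed=2
        )
        ncp["subject_id"] = "n" + ncp["subject_id"]
        groups = subgroup_agreement(pd.concat([cp, ncp], ignore_index=True), "dx_group")
        se = 2.0 / np.sqrt(320)  # Monte-Carlo tolerance ~3 SE
        assert groups["cardiopulmonary"]["bland_altman"].bias == pytest.approx(-2.39, abs=3 * se)
        assert groups["noncardiopulmonary"]["bland_altman"].bias == pytest.approx(1.21, abs=3 * se)

    def test_size_one_group_skipped_with_flag(self):
        big = pairs_from_diffs(np.arange(5, dtype=float), subject="a")
        solo = pairs_from_diffs([1.0], subject="b")
        solo["sex"] = "male"
        groups = subgroup_agreement(pd.concat([big, solo], ignore_index=True), "sex")
        assert groups["male"]["bland_altman"] is None
        assert "group_too_small" in groups["male"]["flags"]

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown grouping key"):
            subgroup_agreement(pairs_from_diffs([1.0, 2.0]), "age")
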