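"""Synthetic cohort generator: determinism, distributional recovery,
missingness, fixtures and CSV round-trips."""

import io

import numpy as np
import pandas as pd
import pytest

from cytoratio import (DEFAULT_PANEL, GroupEffectConfig, RatioSpec,
                       generate_cohort, load_fixture, read_cohort,
                       write_cohort)
from cytoratio.synthetic_cohort import ConfigurationError, lognormal_sigma


def _csv_bytes(cohort: pd.DataFrame) -> bytes:
    buf = io.StringIO()
    write_cohort(cohort, buf)
    return buf.getvalue().encode()


class TestPanel:
    def test_partition(self):
        assert len(DEFAULT_PANEL.names) == 21
        assert len(DEFAULT_PANEL.pro) == 14
        assert len(DEFAULT_PANEL.anti) == 6
        assert DEFAULT_PANEL.unassigned == ("MIP-3α",)
        assert not set(DEFAULT_PANEL.pro) & set(DEFAULT_PANEL.anti)

    def test_invalid_panels_rejected(self):
        from cytoratio import CytokinePanel

        with pytest.raises(ValueError):
            CytokinePanel(names=("A", "A"))
        with pytest.raises(ValueError):
            CytokinePanel(names=("A", "B"), pro=("A",), anti=("A",))
        with pytest.raises(ValueError):
            CytokinePanel(names=("A",), pro=("Z",))


class TestGenerate:
    def test_group_sizes_and_labels(self, default_cohort):
        assert len(default_cohort) == 45
        assert (default_cohort["bsi"] == "yes").sum() == 22
        assert (default_cohort["gram"] == "negative").sum() == 7
        assert (default_cohort["gram"] == "positive").sum() == 15
        # gram is n/a exactly for the non-BSI samples
        assert ((default_cohort["gram"] == "n/a")
                == (default_cohort["bsi"] == "no")).all()

    def test_cytokines_complete_and_positive(self, default_cohort):
        cyt = default_cohort[list(DEFAULT_PANEL.names)]
        assert not cyt.isna().any().any()
        assert (cyt > 0).all().all()

    def test_seed_determinism_byte_identical(self):
        a = _csv_bytes(generate_cohort(GroupEffectConfig(seed=3)))
        b = _csv_bytes(generate_cohort(GroupEffectConfig(seed=3)))
        c = _csv_bytes(generate_cohort(GroupEffectConfig(seed=4)))
        assert a == b
        assert a != c

    def test_median_recovery_il6_fold_change(self):
        """At n = 10⁴ per arm the empirical IL-6 median fold change between
        BSI and non-BSI converges to the configured 21.50/2.78 ≈ 7.73."""
        t3 = load_fixture("table3_bsi")
        med = {
            "no_bsi": t3["median_no_bsi"].to_dict(),
            "gram_negative": t3["median_bsi"].to_dict(),
            "gram_positive": t3["median_bsi"].to_dict(),
        }
        iqr = {
            "no_bsi": t3["iqr_no_bsi"].to_dict(),
            "gram_negative": t3["iqr_bsi"].to_dict(),
            "gram_positive": t3["iqr_bsi"].to_dict(),
        }
        cfg = GroupEffectConfig(
            sizes={"no_bsi": 10_000, "gram_negative": 5_000,
                   "gram_positive": 5_000},
            medians=med, iqrs=iqr, seed=11)
        cohort = generate_cohort(cfg)
        bsi = cohort.loc[cohort["bsi"] == "yes", "IL-6"].median()
        no = cohort.loc[cohort["bsi"] == "no", "IL-6"].median()
        assert bsi / no == pytest.approx(7.73, rel=0.05)

    def test_all_group_medians_recovered(self):
        """Every configured median is recovered at n = 10⁴ within 5% or,
        for the heaviest-tailed printed dispersions, within four asymptotic
        standard errors of the sample median (1.2533·σ/√n on the log scale),
        whichever is wider — the generator is median-unbiased throughout."""
        n = 10_000
        cfg = GroupEffectConfig(
            sizes={"no_bsi": n, "gram_negative": n, "gram_positive": n},
            seed=5)
        cohort = generate_cohort(cfg)
        for group, rows in (("no_bsi", cohort["bsi"] == "no"),
                            ("gram_negative", cohort["gram"] == "negative"),
                            ("gram_positive", cohort["gram"] == "positive")):
            for cyt in DEFAULT_PANEL.names:
                emp = cohort.loc[rows, cyt].median()
                target = cfg.medians[group][cyt]
                sigma = lognormal_sigma(target, cfg.iqrs[group][cyt])
                tol = max(0.05, 4 * 1.2533 * sigma / np.sqrt(n))
                assert emp == pytest.approx(target, rel=tol), (group, cyt)

    def test_no_effect_config_fold_change_one(self):
        cfg = GroupEffectConfig.uniform(
            sizes={"no_bsi": 4000, "gram_negative": 2000,
                   "gram_positive": 2000}, median=10.0, iqr=8.0, seed=2)
        cohort = generate_cohort(cfg)
        bsi = cohort.loc[cohort["bsi"] == "yes", "IL-6"].median()
        no = cohort.loc[cohort["bsi"] == "no", "IL-6"].median()
        assert bsi / no == pytest.approx(1.0, rel=0.05)

    def test_missingness_within_binomial_ci(self):
        cfg = GroupEffectConfig.uniform(
            sizes={"no_bsi": 10_000, "gram_negative": 5_000,
                   "gram_positive": 5_000},
            missingness={"no_bsi": 0.826, "gram_negative": 0.286,
                         "gram_positive": 0.05},
            seed=13)
        cohort = generate_cohort(cfg)
        for group, rows, p in (
                ("no_bsi", cohort["bsi"] == "no", 0.826),
                ("gram_negative", cohort["gram"] == "negative", 0.286),
                ("gram_positive", cohort["gram"] == "positive", 0.05)):
            n = int(rows.sum())
            frac = cohort.loc[rows, "crp"].isna().mean()
            half = 2.576 * np.sqrt(p * (1 - p) / n)
            assert abs(frac - p) <= half, group

    def test_iqr_calibration(self):
        # the log-scale sd solves the stated median/IQR relation
        s = lognormal_sigma(10.0, 8.0)
        q3 = 10.0 * np.exp(0.6744897501960817 * s)
        q1 = 10.0 * np.exp(-0.6744897501960817 * s)
        assert q3 - q1 == pytest.approx(8.0)

    def test_planted_share_model_preserves_ratio_shift(self):
        """The planted ratio's median shifts by ~planted_effect between the
        arms while its member medians stay near the configured bases."""
        planted = RatioSpec(numerator=("GM-CSF", "IL-17A", "IL-1β"),
                            denominator=("IL-4", "IL-7", "IL-21"))
        cfg = GroupEffectConfig.uniform(
            sizes={"no_bsi": 6000, "gram_negative": 3000,
                   "gram_positive": 3000},
            median=10.0, iqr=20.0,
            planted_ratio=planted, planted_effect=4.0, seed=17)
        cohort = generate_cohort(cfg)
        num = cohort[list(planted.numerator)].sum(axis=1)
        den = cohort[list(planted.denominator)].sum(axis=1)
        ratio = num / den
        fold = (ratio[cohort["bsi"] == "yes"].median()
                / ratio[cohort["bsi"] == "no"].median())
        assert fold == pytest.approx(4.0, rel=0.1)

    @pytest.mark.parametrize("bad", [
        dict(sizes={"no_bsi": 0, "gram_negative": 7, "gram_positive": 15}),
        dict(missingness={"no_bsi": 1.5, "gram_negative": 0.3,
                          "gram_positive": 0.05}),
        dict(planted_effect=-1.0),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            GroupEffectConfig(**bad)

    def test_nonpositive_median_rejected(self):
        med = GroupEffectConfig().medians
        med["no_bsi"]["IL-6"] = 0.0
        with pytest.raises(ConfigurationError):
            GroupEffectConfig(medians=med)


class TestFixtures:
    def test_table1_imv_counts(self):
        t1 = load_fixture("table1_counts")
        assert t1["imv"]["table"] == [[6, 17], [0, 22]]

    def test_table3_itac_medians(self):
        t3 = load_fixture("table3_bsi")
        assert t3.loc["ITAC", "median_bsi"] == 59.42
        assert t3.loc["ITAC", "median_no_bsi"] == 106.36

    def test_table4_il8_medians(self):
        t4 = load_fixture("table4_gram")
        assert t4.loc["IL-8", "median_gram_negative"] == 30.58
        assert t4.loc["IL-8", "median_gram_positive"] == 13.45

    def test_unknown_fixture(self):
        with pytest.raises(KeyError):
            load_fixture("table9")


class TestCsvRoundTrip:
    def test_missing_encoded_as_empty_fields(self, default_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort(default_cohort, path)
        text = path.read_text()
        assert ",," in text  # no-BSI lab markers are mostly missing
        back = read_cohort(path)
        pd.testing.assert_frame_equal(
            back, default_cohort, check_exact=False, rtol=1e-12)

    def test_read_rejects_empty_cohort(self, tmp_path):
        path = tmp_path / "empty.csv"
        cols = ["sample_id", "bsi", "gram", *DEFAULT_PANEL.names]
        path.write_text(",".join(cols) + "\n")
        with pytest.raises(ValueError):
            read_cohort(path)
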