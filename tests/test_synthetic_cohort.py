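import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mci_convert.stats import two_sample_t
from mci_convert.synthetic_cohort import (
    CONVERSION_MONTHS,
    DEFAULT_INFORMATIVE_MRI,
    CohortConfig,
    default_mri_feature_names,
    generate_cohort,
    read_cohort,
    write_cohort,
)

from .conftest import small_cohort_config


class TestGenerate:
    def test_default_group_sizes(self, default_cohort):
        counts = default_cohort.data["group"].value_counts().to_dict()
        assert counts == {"NC": 111, "AD": 96, "MCInc": 87, "MCIc": 56}
        assert len(default_cohort.mri_features) == 323
        assert len(default_cohort.csf_features) == 5
        assert len(default_cohort.nm_features) == 14

    def test_determinism(self):
        cfg = small_cohort_config(seed=7)
        assert generate_cohort(cfg) == generate_cohort(cfg)

    def test_conversion_months_only_for_converters(self, default_cohort):
        df = default_cohort.data
        mcic = df[df["group"] == "MCIc"]
        assert mcic["conversion_month"].notna().all()
        assert set(mcic["conversion_month"]) <= set(CONVERSION_MONTHS)
        assert df.loc[df["group"] != "MCIc", "conversion_month"].isna().all()

    def test_csf_ratios_are_exact_quotients(self, default_cohort):
        df = default_cohort.data
        assert np.allclose(df["ttau_abeta42"], df["ttau"] / df["abeta42"])
        assert np.allclose(df["ptau_abeta42"], df["ptau181"] / df["abeta42"])

    def test_no_missing_feature_values(self, default_cohort):
        assert not default_cohort.data[default_cohort.feature_names].isna().any().any()

    def test_ad_ttau_matches_truncated_normal_oracle(self):
        """At large n the sample mean must match the exact mean of the
        0-truncated Gaussian, which itself sits close to the configured
        122.9 pg/ml (truncation bias < 3%)."""
        cfg = CohortConfig(seed=5)
        cfg.group_sizes = {"NC": 2, "AD": 2000, "MCInc": 2, "MCIc": 2}
        cohort = generate_cohort(cfg)
        ttau = cohort.data.loc[cohort.data["group"] == "AD", "ttau"].to_numpy()
        mu, sd = 122.9, 58.0
        oracle = sps.truncnorm((0 - mu) / sd, np.inf, loc=mu, scale=sd)
        se = sd / np.sqrt(ttau.size)
        assert abs(ttau.mean() - oracle.mean()) < 3 * se
        assert abs(oracle.mean() - mu) / mu < 0.03
        assert (ttau >= 0).all()

    def test_severity_gradient_moves_early_converters_monotonically(self):
        """Raising the gradient pushes 6-month converters' planted features
        monotonically in the disease (atrophy) direction."""
        feature = "entorhinal_cortex_TA_L"
        means = []
        for g in (0.0, 0.5, 1.0, 1.5):
            cfg = CohortConfig(seed=3, severity_gradient=g)
            df = generate_cohort(cfg).data
            sel = (df["group"] == "MCIc") & (df["conversion_month"] == 6)
            means.append(df.loc[sel, feature].mean())
        assert all(a > b for a, b in zip(means, means[1:]))  # atrophy: decreasing

    def test_null_features_reject_at_nominal_rate(self, default_cohort):
        """NC-vs-AD t-tests on the null MRI features form a type-I
        calibration: the rejection rate at alpha = 0.05 stays within the
        3-sigma binomial band."""
        df = default_cohort.data
        nc = df[df["group"] == "NC"]
        ad = df[df["group"] == "AD"]
        nulls = [f for f in default_cohort.mri_features if f not in DEFAULT_INFORMATIVE_MRI]
        rejections = sum(
            two_sample_t(nc[f].to_numpy(), ad[f].to_numpy()).p_value < 0.05 for f in nulls
        )
        rate = rejections / len(nulls)
        band = 3 * np.sqrt(0.05 * 0.95 / len(nulls))
        assert abs(rate - 0.05) < band

    def test_group_means_converge_for_low_truncation_features(self):
        cfg = CohortConfig(seed=11)
        cfg.group_sizes = {"NC": 2000, "AD": 2, "MCInc": 2, "MCIc": 2}
        nc = generate_cohort(cfg).data.query("group == 'NC'")
        # abeta42 205.6 +/- 55.6 and AVLT trials 43.3 +/- 8.4: truncation
        # mass at 0 is negligible, so plain Gaussian moments apply
        for feat, mu, sd in [("abeta42", 205.6, 55.6), ("avlt_trials_1_5", 43.3, 8.4)]:
            x = nc[feat].to_numpy()
            assert abs(x.mean() - mu) < 3 * sd / np.sqrt(x.size)
            assert abs(x.std(ddof=1) - sd) < 0.05 * sd

    def test_equicorrelation_option(self):
        cfg = small_cohort_config(seed=13, equicorrelation=0.5)
        cfg.group_sizes = {"NC": 400, "AD": 2, "MCInc": 2, "MCIc": 2}
        cohort = generate_cohort(cfg)
        nulls = [f for f in cohort.mri_features if f not in cfg.informative_mri][:20]
        X = cohort.data.query("group == 'NC'")[nulls].to_numpy()
        corr = np.corrcoef(X, rowvar=False)
        off = corr[np.triu_indices_from(corr, k=1)]
        assert abs(off.mean() - 0.5) < 0.1

    def test_config_validation(self):
        with pytest.raises(ValueError):
            generate_cohort(CohortConfig(group_sizes={"NC": 0, "AD": 1, "MCInc": 1, "MCIc": 1}))
        with pytest.raises(ValueError):
            generate_cohort(CohortConfig(informative_mri={"no_such_region_TA_L": -1.0}))
        with pytest.raises(ValueError):
            generate_cohort(CohortConfig(conversion_month_probs={6: 0.5, 12: 0.2, 18: 0.2, 24: 0.2}))
        bad = CohortConfig()
        bad.csf_params["AD"]["ttau"] = (122.9, 0.0)
        with pytest.raises(ValueError):
            generate_cohort(bad)

    def test_feature_name_grid_contains_default_markers(self):
        names = default_mri_feature_names(323)
        assert len(names) == len(set(names)) == 323
        assert set(DEFAULT_INFORMATIVE_MRI) <= set(names)


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path):
        cohort = generate_cohort(small_cohort_config(seed=21))
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, path)
        assert read_cohort(path) == cohort

    def test_one_subject_per_group(self, tmp_path):
        cfg = small_cohort_config(seed=1)
        cfg.group_sizes = {g: 1 for g in ("NC", "AD", "MCInc", "MCIc")}
        path = tmp_path / "tiny.csv"
        write_cohort(generate_cohort(cfg), path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 5  # header + 4 subjects

    def test_missing_group_column_named_in_error(self, tmp_path):
        cohort = generate_cohort(small_cohort_config(seed=2))
        path = tmp_path / "broken.csv"
        cohort.data.drop(columns=["group"]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="group"):
            read_cohort(path)

    def test_duplicate_subject_id_rejected(self, tmp_path):
        cohort = generate_cohort(small_cohort_config(seed=2))
        df = cohort.data.copy()
        df.loc[1, "subject_id"] = df.loc[0, "subject_id"]
        path = tmp_path / "dup.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_cohort(path)

    def test_non_numeric_feature_cell_rejected(self, tmp_path):
        cohort = generate_cohort(small_cohort_config(seed=2))
        df = cohort.data.copy()
        df["ttau"] = df["ttau"].astype(object)
        df.loc[0, "ttau"] = "n/a"
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="ttau"):
            read_cohort(path)
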