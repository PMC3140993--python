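"""Synthetic four-group multimodal cohort generator.

Emulates the group structure of a baseline multicentre AD biomarker
study: cognitively normal controls (NC), Alzheimer's disease patients
(AD), and mild
cognitive impairment subjects who did (MCIc) or did not (MCInc) convert
to AD within 24 months. Each subject carries 342 features:

* 323 MRI ROI morphometry features (cortical thickness average TA,
  thickness SD TS, surface area SA, cortical volume CV, subcortical
  volume SV; named ``<roi>_<measure>_<L|R>``). Most are null (one
  global mean/SD shared by all groups); a configurable handful are
  "informative", shifted per group by standardized effect sizes graded
  NC < MCInc < MCIc < AD.
* 5 CSF measures: t-tau, Abeta1-42 and p-tau181p concentrations (pg/ml,
  truncated Gaussians per group) plus the two tau/Abeta ratios computed
  as exact quotients of the generated analytes.
* 14 neuropsychological and functional measures (NM), per-group
  truncated Gaussians.

MCIc subjects with earlier conversion months (6/12/18/24) are pulled
further toward the AD distribution by a severity gradient, so decision
values of a downstream classifier separate early from late converters.
Demographics (age, sex, education, ApoE e4) are generated for the group
statistics tables but never enter the classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "CSF_ANALYTES",
    "CSF_RATIOS",
    "CSF_FEATURES",
    "NM_FEATURES",
    "CONVERSION_MONTHS",
    "CohortConfig",
    "Cohort",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "default_mri_feature_names",
]

GROUPS = ("NC", "AD", "MCInc", "MCIc")
CONVERSION_MONTHS = (6, 12, 18, 24)

CSF_ANALYTES = ("ttau", "abeta42", "ptau181")
CSF_RATIOS = ("ttau_abeta42", "ptau_abeta42")
CSF_FEATURES = CSF_ANALYTES + CSF_RATIOS

NM_FEATURES = (
    "lm_delayed_recall",
    "lm_immediate_recall",
    "boston_naming",
    "avlt_trials_1_5",
    "avlt_delayed_recall",
    "avlt_recall_trial5_pct",
    "category_fluency_vegetable",
    "category_fluency_animal",
    "trail_making_a",
    "trail_making_b",
    "clock_drawing",
    "digit_forwards",
    "digit_backwards",
    "faq",
)

# Per-group (mean, SD) of the three CSF analytes, pg/ml.
DEFAULT_CSF_PARAMS = {
    "NC": {"ttau": (69.8, 30.6), "abeta42": (205.6, 55.6), "ptau181": (24.9, 14.6)},
    "AD": {"ttau": (122.9, 58.0), "abeta42": (142.8, 40.0), "ptau181": (42.2, 20.1)},
    "MCInc": {"ttau": (96.1, 53.2), "abeta42": (163.6, 58.5), "ptau181": (34.3, 17.1)},
    "MCIc": {"ttau": (110.5, 45.1), "abeta42": (142.2, 35.9), "ptau181": (39.5, 15.5)},
}

# Per-group (mean, SD) of the 14 NM features, in Table-3 row order.
_NM_TABLE = {
    "lm_delayed_recall": ((12.6, 3.6), (1.1, 1.8), (4.3, 2.7), (2.8, 2.3)),
    "lm_immediate_recall": ((13.5, 3.6), (3.9, 2.9), (7.5, 2.5), (6.0, 3.0)),
    "boston_naming": ((27.5, 2.4), (23.1, 6.1), (25.8, 4.1), (25.7, 3.7)),
    "avlt_trials_1_5": ((43.3, 8.4), (23.4, 7.1), (32.8, 8.9), (26.6, 6.7)),
    "avlt_delayed_recall": ((7.3, 3.5), (1.0, 2.0), (3.3, 3.4), (1.5, 1.9)),
    "avlt_recall_trial5_pct": ((66.5, 30.0), (14.2, 25.0), (35.2, 30.6), (21.1, 26.7)),
    "category_fluency_vegetable": ((14.4, 3.8), (8.1, 3.4), (11.1, 3.5), (10.1, 3.1)),
    "category_fluency_animal": ((19.3, 5.7), (12.8, 4.9), (16.3, 4.8), (15.6, 4.8)),
    "trail_making_a": ((36.7, 13.5), (68.4, 38.7), (42.6, 20.6), (49.6, 27.2)),
    "trail_making_b": ((88.5, 41.5), (204.3, 86.7), (118.2, 63.2), (144.6, 71.2)),
    "clock_drawing": ((4.6, 0.7), (3.3, 1.3), (4.3, 0.9), (3.8, 1.2)),
    "digit_forwards": ((8.7, 2.1), (7.8, 1.9), (8.1, 2.1), (8.5, 1.9)),
    "digit_backwards": ((7.0, 2.2), (4.9, 1.8), (6.3, 2.0), (6.2, 1.7)),
    "faq": ((0.2, 0.7), (12.7, 6.7), (2.8, 3.9), (5.2, 4.4)),
}
DEFAULT_NM_PARAMS = {
    g: {name: _NM_TABLE[name][i] for name in NM_FEATURES}
    for i, g in enumerate(GROUPS)
}

# age/education (mean, SD) in years, male and ApoE e4 carrier fractions.
DEFAULT_DEMO_PARAMS = {
    "NC": {"age": (75.4, 5.12), "education": (15.7, 2.81), "male_fraction": 0.505, "apoe4_fraction": 0.234},
    "AD": {"age": (74.8, 8.01), "education": (15.2, 3.35), "male_fraction": 0.583, "apoe4_fraction": 0.698},
    "MCInc": {"age": (74.3, 6.98), "education": (16.4, 2.74), "male_fraction": 0.632, "apoe4_fraction": 0.471},
    "MCIc": {"age": (75.02, 7.49), "education": (15.4, 3.11), "male_fraction": 0.679, "apoe4_fraction": 0.643},
}

_CORTICAL_ROIS = (
    "entorhinal_cortex",
    "middle_temporal_gyrus",
    "inferior_parietal_cortex",
    "retrosplenial_cortex",
    "superior_temporal_gyrus",
    "inferior_temporal_gyrus",
    "fusiform_gyrus",
    "parahippocampal_gyrus",
    "precuneus",
    "posterior_cingulate",
    "caudal_anterior_cingulate",
    "rostral_anterior_cingulate",
    "superior_parietal_cortex",
    "supramarginal_gyrus",
    "superior_frontal_gyrus",
    "middle_frontal_gyrus_rostral",
    "middle_frontal_gyrus_caudal",
    "inferior_frontal_pars_opercularis",
    "inferior_frontal_pars_triangularis",
    "inferior_frontal_pars_orbitalis",
    "lateral_orbitofrontal",
    "medial_orbitofrontal",
    "frontal_pole",
    "precentral_gyrus",
    "postcentral_gyrus",
    "paracentral_lobule",
    "lateral_occipital_cortex",
    "lingual_gyrus",
    "pericalcarine_cortex",
    "cuneus",
    "transverse_temporal_gyrus",
    "banks_superior_temporal_sulcus",
    "temporal_pole",
    "insula",
    "isthmus_cingulate",
)
_SUBCORTICAL = (
    "hippocampus",
    "amygdala",
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "accumbens_area",
    "ventral_diencephalon",
    "lateral_ventricle",
    "inferior_lateral_ventricle",
    "cerebellum_cortex",
    "cerebellum_white_matter",
    "choroid_plexus",
    "cerebral_white_matter",
    "brain_stem_hemi",
    "csf_space",
    "optic_chiasm",
    "vessel",
    "third_ventricle_hemi",
    "fourth_ventricle_hemi",
    "corpus_callosum_hemi",
    "operculum",
)
_CORTICAL_MEASURES = ("TA", "TS", "SA", "CV")


def default_mri_feature_names(n: int = 323) -> list:
    """Deterministic ROI-style MRI feature names (``<roi>_<measure>_<L|R>``)."""
    names = [
        f"{roi}_{m}_{h}"
        for roi in _CORTICAL_ROIS
        for m in _CORTICAL_MEASURES
        for h in ("L", "R")
    ]
    names += [f"{roi}_SV_{h}" for roi in _SUBCORTICAL for h in ("L", "R")]
    i = 0
    while len(names) < n:
        names += [f"extra_region_{i}_SV_{h}" for h in ("L", "R")]
        i += 1
    return names[:n]


# Default planted effects: standardized NC-vs-AD shifts for established
# atrophy markers (negative = loss relative to controls), at the low end
# of the effect sizes reported for temporal-lobe ROIs so that marker
# recovery is a non-trivial exercise. Group grading below maps these to
# NC < MCInc < MCIc < AD severity.
DEFAULT_INFORMATIVE_MRI = {
    "entorhinal_cortex_TA_L": -1.2,
    "middle_temporal_gyrus_CV_R": -1.2,
    "hippocampus_SV_R": -1.2,
    "hippocampus_SV_L": -1.2,
    "inferior_parietal_cortex_TA_R": -1.2,
    "retrosplenial_cortex_TA_L": -1.2,
    "middle_temporal_gyrus_TA_L": -1.2,
}
# Fraction of the full AD effect expressed by each group.
_GROUP_EFFECT_FRACTION = {"NC": 0.0, "MCInc": 0.3, "MCIc": 0.75, "AD": 1.0}


def _expand_effects(informative_mri) -> dict:
    """Normalise ``{name: effect}`` entries to ``{name: {group: effect}}``."""
    out = {}
    for name, eff in dict(informative_mri).items():
        if isinstance(eff, dict):
            missing = set(GROUPS) - set(eff)
            if missing:
                raise ValueError(f"informative feature {name!r} lacks groups {sorted(missing)}")
            out[name] = {g: float(eff[g]) for g in GROUPS}
        else:
            out[name] = {g: _GROUP_EFFECT_FRACTION[g] * float(eff) for g in GROUPS}
    return out


@dataclass
class CohortConfig:
    """All knobs of the generator; defaults reproduce the printed study
    group structure (group sizes and per-group CSF/NM moments)."""

    group_sizes: dict = field(
        default_factory=lambda: {"NC": 111, "AD": 96, "MCInc": 87, "MCIc": 56}
    )
    csf_params: dict = field(default_factory=lambda: {
        g: dict(DEFAULT_CSF_PARAMS[g]) for g in GROUPS
    })
    nm_params: dict = field(default_factory=lambda: {
        g: dict(DEFAULT_NM_PARAMS[g]) for g in GROUPS
    })
    n_mri_features: int = 323
    informative_mri: dict = field(default_factory=lambda: dict(DEFAULT_INFORMATIVE_MRI))
    mri_null_mean: float = 0.0
    mri_null_sd: float = 1.0
    conversion_month_probs: dict = field(
        default_factory=lambda: {m: 0.25 for m in CONVERSION_MONTHS}
    )
    severity_gradient: float = 1.0
    demo_params: dict = field(default_factory=lambda: {
        g: dict(DEFAULT_DEMO_PARAMS[g]) for g in GROUPS
    })
    equicorrelation: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for g in GROUPS:
            if g not in self.group_sizes or self.group_sizes[g] <= 0:
                raise ValueError(f"group size for {g!r} must be a positive integer")
        probs = [self.conversion_month_probs.get(m, 0.0) for m in CONVERSION_MONTHS]
        if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
            raise ValueError("conversion month probabilities must be >= 0 and sum to 1")
        for params in (self.csf_params, self.nm_params):
            for g, feats in params.items():
                for name, (_, sd) in feats.items():
                    if sd <= 0:
                        raise ValueError(f"SD for {name!r} in group {g!r} must be > 0")
        if self.mri_null_sd <= 0:
            raise ValueError("mri_null_sd must be > 0")
        if not 0.0 <= self.equicorrelation < 1.0:
            raise ValueError("equicorrelation must lie in [0, 1)")
        if self.severity_gradient < 0:
            raise ValueError("severity_gradient must be >= 0")
        mri_names = set(default_mri_feature_names(self.n_mri_features))
        unknown = set(self.informative_mri) - mri_names
        if unknown:
            raise ValueError(f"unknown MRI feature name(s) in informative_mri: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        cfg = cls()
        for key, value in d.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown cohort config field {key!r}")
            if key == "conversion_month_probs":
                value = {int(k): float(v) for k, v in value.items()}
            setattr(cfg, key, value)
        return cfg


@dataclass
class Cohort:
    """Per-subject records backed by a DataFrame.

    Columns: subject_id, group, age, sex, education, apoe4,
    conversion_month (nullable Int64, present only for MCIc), then the
    feature columns (MRI, CSF, NM in that order).
    """

    data: pd.DataFrame
    mri_features: list
    csf_features: list
    nm_features: list

    @property
    def feature_names(self) -> list:
        return list(self.mri_features) + list(self.csf_features) + list(self.nm_features)

    def subset(self, groups) -> "Cohort":
        groups = [groups] if isinstance(groups, str) else list(groups)
        mask = self.data["group"].isin(groups)
        return Cohort(
            self.data.loc[mask].reset_index(drop=True),
            list(self.mri_features),
            list(self.csf_features),
            list(self.nm_features),
        )

    def feature_matrix(self, columns=None, groups=None) -> pd.DataFrame:
        df = self.data if groups is None else self.subset(groups).data
        return df.loc[:, list(columns) if columns is not None else self.feature_names]

    def labels(self, groups=None) -> np.ndarray:
        df = self.data if groups is None else self.subset(groups).data
        return df["group"].to_numpy()

    def modality_features(self, modality: str) -> list:
        return {
            "MRI": list(self.mri_features),
            "CSF": list(self.csf_features),
            "NM": list(self.nm_features),
        }[modality.upper()]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.data.equals(other.data)
            and self.mri_features == other.mri_features
            and self.csf_features == other.csf_features
            and self.nm_features == other.nm_features
        )


def _truncated_normal(rng, means, sds, size, lower, shared=None, rho=0.0):
    """Gaussian draws with a lower bound enforced by resampling.

    ``shared`` is an optional per-subject latent factor inducing
    equicorrelation ``rho`` across features of one modality; only the
    idiosyncratic part is redrawn on truncation, so the realized
    correlation of truncated features is approximate.
    """
    means = np.broadcast_to(np.asarray(means, dtype=float), size).copy()
    sds = np.broadcast_to(np.asarray(sds, dtype=float), size)
    eps = rng.standard_normal(size)
    if shared is not None and rho > 0:
        z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps
    else:
        z = eps
    x = means + sds * z
    if lower is not None:
        scale = np.sqrt(1.0 - rho) if (shared is not None and rho > 0) else 1.0
        base = means + (sds * np.sqrt(rho) * shared if (shared is not None and rho > 0) else 0.0)
        for _ in range(1000):
            bad = x < lower
            if not bad.any():
                break
            x[bad] = base[bad] + sds[bad] * scale * rng.standard_normal(int(bad.sum()))
        else:  # pragma: no cover - pathological configs only
            x = np.maximum(x, lower)
    return x


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Draw a complete cohort according to ``config`` (deterministic in
    ``config.seed``)."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    mri_names = default_mri_feature_names(config.n_mri_features)
    effects = _expand_effects(config.informative_mri)
    rho = config.equicorrelation

    months_sorted = CONVERSION_MONTHS
    probs = np.asarray([config.conversion_month_probs.get(m, 0.0) for m in months_sorted])

    frames = []
    sid = 0
    for g in GROUPS:
        n = int(config.group_sizes[g])
        demo = config.demo_params[g]
        age = rng.normal(demo["age"][0], demo["age"][1], n)
        education = _truncated_normal(rng, demo["education"][0], demo["education"][1], n, 0.0)
        sex = np.where(rng.random(n) < demo["male_fraction"], "M", "F")
        apoe4 = (rng.random(n) < demo["apoe4_fraction"]).astype(np.int64)

        if g == "MCIc":
            months = rng.choice(months_sorted, size=n, p=probs).astype(np.int64)
            # extra shift in SD units toward the AD side of each feature:
            # severity_gradient at 6 months, 0 at 24 months. Deliberately
            # uncapped -- the earliest converters may overshoot the average
            # AD profile at baseline.
            w = config.severity_gradient * (24 - months) / 18.0
        else:
            months = None
            w = np.zeros(n)

        cols = {
            "subject_id": [f"S{sid + i:04d}" for i in range(n)],
            "group": [g] * n,
            "age": age,
            "sex": sex,
            "education": education,
            "apoe4": apoe4,
            "conversion_month": pd.array(
                months if months is not None else [pd.NA] * n, dtype="Int64"
            ),
        }
        sid += n

        # --- MRI block ---
        shared_mri = rng.standard_normal(n) if rho > 0 else None
        mri = np.empty((n, len(mri_names)))
        eps = rng.standard_normal((n, len(mri_names)))
        if shared_mri is not None:
            eps = np.sqrt(rho) * shared_mri[:, None] + np.sqrt(1.0 - rho) * eps
        mri[:] = config.mri_null_mean + config.mri_null_sd * eps
        for name, per_group in effects.items():
            j = mri_names.index(name)
            eff = per_group[g]
            if g == "MCIc":
                direction = np.sign(per_group["AD"] - per_group["NC"]) or 1.0
                eff = eff + w * direction
            mri[:, j] += config.mri_null_sd * eff
        for j, name in enumerate(mri_names):
            cols[name] = mri[:, j]

        # --- CSF block ---
        shared_csf = rng.standard_normal(n) if rho > 0 else None
        analytes = {}
        for a in CSF_ANALYTES:
            mean, sd = config.csf_params[g][a]
            if g == "MCIc":
                ad_mean = config.csf_params["AD"][a][0]
                nc_mean = config.csf_params["NC"][a][0]
                mean = mean + w * sd * (np.sign(ad_mean - nc_mean) or 1.0)
            analytes[a] = _truncated_normal(
                rng, mean, sd, n, 0.0, shared=shared_csf, rho=rho
            )
        cols["ttau"] = analytes["ttau"]
        cols["abeta42"] = analytes["abeta42"]
        cols["ptau181"] = analytes["ptau181"]
        cols["ttau_abeta42"] = analytes["ttau"] / analytes["abeta42"]
        cols["ptau_abeta42"] = analytes["ptau181"] / analytes["abeta42"]

        # --- NM block ---
        shared_nm = rng.standard_normal(n) if rho > 0 else None
        for name in NM_FEATURES:
            mean, sd = config.nm_params[g][name]
            if g == "MCIc":
                ad_mean = config.nm_params["AD"][name][0]
                nc_mean = config.nm_params["NC"][name][0]
                mean = mean + w * sd * (np.sign(ad_mean - nc_mean) or 1.0)
            cols[name] = _truncated_normal(rng, mean, sd, n, 0.0, shared=shared_nm, rho=rho)

        frames.append(pd.DataFrame(cols))

    data = pd.concat(frames, ignore_index=True)
    return Cohort(data, mri_names, list(CSF_FEATURES), list(NM_FEATURES))


_META_COLUMNS = ("subject_id", "group", "age", "sex", "education", "apoe4", "conversion_month")


def write_cohort(cohort: Cohort, path) -> None:
    """Serialize to CSV (header row, one subject per row, '.' decimals)."""
    cohort.data.to_csv(path, index=False)


def read_cohort(path) -> Cohort:
    """Read a cohort CSV written by :func:`write_cohort`.

    Feature columns are assigned to modalities by name: the fixed CSF and
    NM feature sets are recognised, every other feature column is MRI.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in _META_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"cohort file is missing required column {col!r}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject_id {dup!r}")
    df["conversion_month"] = df["conversion_month"].astype("Int64")
    df["apoe4"] = df["apoe4"].astype(np.int64)
    feature_cols = [c for c in df.columns if c not in _META_COLUMNS]
    for c in feature_cols:
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise ValueError(f"non-numeric value in feature column {c!r}")
        df[c] = df[c].astype(float)
        if df[c].isna().any():
            raise ValueError(f"missing value in feature column {c!r}")
    csf = [c for c in feature_cols if c in CSF_FEATURES]
    nm = [c for c in feature_cols if c in NM_FEATURES]
    mri = [c for c in feature_cols if c not in CSF_FEATURES and c not in NM_FEATURES]
    return Cohort(df, mri, csf, nm)
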