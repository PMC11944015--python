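"""Synthetic ICU cohort generator and in-study fixture tables.

The real serum-cytokine cohort behind this pipeline (45 ICU COVID-19
patients: 23 without bloodstream infection, 22 with confirmed BSI, of which
7 Gram-negative and 15 Gram-positive) is not publicly available.  This module
provides two substitutes:

* :func:`generate_cohort` draws synthetic cohorts with the statistical
  structure the analysis assumes — per-group log-normal cytokine
  concentrations parameterised by median and IQR width, demographics drawn
  from the published marginal frequencies, laboratory markers with per-group
  missingness — plus an optional *planted* ratio effect used for
  signal-recovery testing.
* :func:`load_fixture` returns the small published summary tables
  (demographic 2×2 counts, per-group cytokine medians and IQR widths) that
  several stages use as exact inputs.

Cytokine concentrations are modelled log-normally per cytokine per group:
positive, right-skewed, and parameterisable directly by the median
(``exp(mu)``) with the log-scale sd calibrated so that the interquartile
width matches the requested one.  The generator never emits concentrations
below 0.01 pg/mL, keeping ratio denominators finite.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import DEFAULT_PANEL, CytokinePanel

#: z-score of the 75th percentile of the standard normal.
_Z75 = 0.6744897501960817

#: Detection floor applied to every generated concentration, pg/mL.
CONCENTRATION_FLOOR = 0.01

#: Column layout of the tidy cohort CSV.
META_COLUMNS = ("sample_id", "bsi", "gram")
DEMOGRAPHIC_COLUMNS = ("age", "gender", "bmi", "ecmo", "imv", "comorbidities")
LAB_COLUMNS = ("crp", "pct", "lymphocytes", "ne_pct")

#: Generation groups.  BSI samples are generated per Gram type; the no-BSI
#: group has gram = "n/a".
GROUPS = ("no_bsi", "gram_negative", "gram_positive")


# ---------------------------------------------------------------------------
# Published fixture tables
# ---------------------------------------------------------------------------

# Demographic and clinical characteristics of the 45 ICU patients.
# 2x2 counts are [[no-BSI row], [BSI row]] with columns as labelled.
_TABLE1_COUNTS = {
    "gender": {"table": [[5, 18], [3, 19]], "columns": ("female", "male")},
    "ecmo": {"table": [[17, 6], [16, 6]], "columns": ("no", "yes")},
    "imv": {"table": [[6, 17], [0, 22]], "columns": ("no", "yes")},
    "comorbidities": {"table": [[2, 21], [1, 21]], "columns": ("no", "yes")},
    "age": {"no_bsi": (58.0, 12.0), "bsi": (62.0, 22.0)},  # median, IQR width
    "bmi": {"no_bsi": (29.0, 8.0), "bsi": (27.0, 6.0)},
    "rows": ("no_bsi", "bsi"),
}

# Cytokine medians (IQR widths) for BSI vs non-BSI patients, with the
# published absolute difference, percent difference and fold change columns.
_TABLE3_BSI = """\
cytokine,median_bsi,iqr_bsi,median_no_bsi,iqr_no_bsi,abs_diff,pct_diff,fold_change
ITAC,59.42,76.78,106.36,121.28,46.93,-78.98,0.56
GM-CSF,7.42,3.91,8.62,6.49,1.21,-13.99,0.86
Fractalkine,15.52,8.71,16.30,6.82,0.77,-4.75,0.95
IFN-γ,31.01,16.41,28.77,21.94,2.24,7.79,1.08
IL-10,24.92,59.17,32.99,18.45,8.06,-24.45,0.76
MIP-3α,14.34,10.69,13.19,8.04,1.15,8.72,1.09
IL-12p70,5.64,3.60,4.76,3.04,0.88,18.56,1.19
IL-13,2.44,1.50,3.05,3.17,0.61,-19.90,0.80
IL-17A,25.50,15.71,29.71,20.33,4.20,-14.15,0.86
IL-1β,1.22,0.52,1.08,0.67,0.14,12.64,1.13
IL-2,3.31,1.40,3.40,2.87,0.09,-2.64,0.97
IL-21,10.55,6.43,10.29,6.71,0.26,2.49,1.02
IL-4,8.31,7.53,12.75,7.90,4.44,-34.81,0.65
IL-23,232.51,125.91,211.53,134.44,20.98,9.92,1.10
IL-5,6.16,4.01,6.16,6.44,0.00,0.02,1.00
IL-6,21.50,192.18,2.78,10.84,18.71,672.65,7.73
IL-7,17.41,5.57,17.60,7.41,0.19,-1.10,0.99
IL-8,16.74,36.74,9.65,12.54,7.09,73.52,1.74
MIP-1α,19.00,11.97,15.09,11.92,3.91,25.91,1.26
MIP-1β,9.49,22.53,16.58,15.05,7.09,-42.75,0.57
TNF-α,9.19,11.55,9.03,4.26,0.16,1.83,1.02
"""

# Cytokine medians (IQR widths) for Gram-negative vs Gram-positive patients.
_TABLE4_GRAM = """\
cytokine,median_gram_negative,iqr_gram_negative,median_gram_positive,iqr_gram_positive,abs_diff,pct_diff,fold_change
ITAC,33.73,39.99,90.97,75.69,57.24,-169.72,0.37
GM-CSF,7.32,2.37,7.51,4.01,0.19,-2.58,0.97
Fractalkine,23.25,19.38,13.38,4.80,9.86,42.43,1.74
IFN-γ,28.98,22.68,33.03,15.15,4.05,-13.96,0.88
IL-10,21.88,245.68,25.87,53.37,3.99,-18.21,0.85
MIP-3α,9.60,34.20,14.84,9.90,5.24,-54.51,0.65
IL-12p70,4.74,2.86,5.85,3.25,1.11,-23.44,0.81
IL-13,2.29,1.11,3.33,1.57,1.05,-45.73,0.69
IL-17A,23.93,8.84,26.60,15.79,2.67,-11.16,0.90
IL-1β,1.05,0.51,1.27,0.49,0.21,-20.23,0.83
IL-2,3.48,1.66,3.22,1.25,0.25,7.28,1.08
IL-21,11.68,4.47,9.48,6.21,2.21,18.89,1.23
IL-4,11.60,8.22,6.35,7.46,5.25,45.24,1.83
IL-23,223.29,110.93,249.41,186.69,26.12,-11.70,0.90
IL-5,5.59,4.07,7.21,6.65,1.62,-28.91,0.78
IL-6,3.97,12207.22,21.55,157.65,17.58,-442.75,0.18
IL-7,14.47,4.08,18.26,6.09,3.79,-26.19,0.79
IL-8,30.58,642.58,13.45,27.51,17.12,56.00,2.27
MIP-1α,17.22,5.03,19.99,20.05,2.76,-16.05,0.86
MIP-1β,8.24,12.85,10.74,27.35,2.51,-30.45,0.77
TNF-α,13.60,16.65,8.72,10.74,4.89,35.92,1.56
"""


def load_fixture(name: str):
    """Return a transcribed published summary table.

    Parameters
    ----------
    name
        ``"table1_counts"`` — demographic/clinical 2×2 count tables and
        age/BMI medians; ``"table3_bsi"`` — cytokine medians and IQR widths
        for BSI vs non-BSI; ``"table4_gram"`` — the same for Gram-negative
        vs Gram-positive.

    Returns
    -------
    dict or pandas.DataFrame
        ``table1_counts`` returns a dict; the cytokine tables return a
        DataFrame indexed by cytokine name.
    """
    if name == "table1_counts":
        return {
            k: (dict(v) if isinstance(v, dict) else v)
            for k, v in _TABLE1_COUNTS.items()
        }
    if name == "table3_bsi":
        return pd.read_csv(io.StringIO(_TABLE3_BSI), index_col="cytokine")
    if name == "table4_gram":
        return pd.read_csv(io.StringIO(_TABLE4_GRAM), index_col="cytokine")
    raise KeyError(f"unknown fixture {name!r}; expected table1_counts, "
                   "table3_bsi or table4_gram")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


class ConfigurationError(ValueError):
    """Raised for invalid cohort-generation settings."""


def _default_group_medians() -> dict[str, dict[str, float]]:
    t3 = load_fixture("table3_bsi")
    t4 = load_fixture("table4_gram")
    return {
        "no_bsi": t3["median_no_bsi"].to_dict(),
        "gram_negative": t4["median_gram_negative"].to_dict(),
        "gram_positive": t4["median_gram_positive"].to_dict(),
    }


def _default_group_iqrs() -> dict[str, dict[str, float]]:
    t3 = load_fixture("table3_bsi")
    t4 = load_fixture("table4_gram")
    return {
        "no_bsi": t3["iqr_no_bsi"].to_dict(),
        "gram_negative": t4["iqr_gram_negative"].to_dict(),
        "gram_positive": t4["iqr_gram_positive"].to_dict(),
    }


# Laboratory-marker generation parameters: median (IQR width) per group.
# CRP and PCT Gram-group medians follow the published cohort values; the
# remaining entries are plausible ICU magnitudes (documented in the methods
# note) — lab markers are carried for missingness handling, not inference.
_DEFAULT_LAB_PARAMS = {
    "crp": {"no_bsi": (140.0, 120.0), "gram_negative": (118.40, 110.0),
            "gram_positive": (224.85, 150.0)},
    "pct": {"no_bsi": (0.70, 1.2), "gram_negative": (0.66, 1.0),
            "gram_positive": (0.35, 0.6)},
    "lymphocytes": {"no_bsi": (1.10, 0.8), "gram_negative": (1.00, 0.7),
                    "gram_positive": (0.80, 0.6)},
    "ne_pct": {"no_bsi": (85.0, 10.0), "gram_negative": (82.0, 9.0),
               "gram_positive": (84.0, 9.0)},
}

# Published per-group missingness of the traditional lab markers.  The
# BSI-wide 12.5% rate is consistent with the per-Gram rates below
# (7×0.286 + 15×0.05 ≈ 2.75 of 22).
_DEFAULT_MISSINGNESS = {
    "no_bsi": 0.826,
    "gram_negative": 0.286,
    "gram_positive": 0.05,
}


@dataclass
class GroupEffectConfig:
    """Distributional targets for one synthetic cohort.

    Parameters
    ----------
    sizes
        Samples per generation group: keys ``no_bsi``, ``gram_negative``,
        ``gram_positive`` (the BSI group is their union).
    medians, iqrs
        Per-group per-cytokine median and IQR width (pg/mL).  Defaults are
        the published cohort summary tables, i.e. the generator's default
        conditions are the real cohort's printed location/spread.
    missingness
        Per-group probability that a lab-marker block is missing.
    planted_ratio, planted_effect, planted_total_sigma, planted_share_sigma
        Optional planted signal emulating two co-regulated cytokine modules
        whose balance — not any single member — discriminates the groups.
        Each side of ``planted_ratio`` (a
        :class:`~cytoratio.ratio_engine.RatioSpec`) is generated as a
        tightly regulated module total (log-normal, log-sd
        ``planted_total_sigma``, median = sum of the members' configured
        medians) divided among its members by noisy compositional shares
        (member log-weight sd ``planted_share_sigma``).  The numerator
        cytokines' medians are multiplied by ``planted_effect`` in both BSI
        generation groups, so the planted ratio shifts by that factor while
        every individual member — and every partial sub-ratio — carries the
        extra share noise that the full ratio cancels.
    seed
        Seed for the generator; identical seeds give identical cohorts.
    """

    sizes: dict[str, int] = field(
        default_factory=lambda: {"no_bsi": 23, "gram_negative": 7,
                                 "gram_positive": 15})
    medians: dict[str, dict[str, float]] = field(
        default_factory=_default_group_medians)
    iqrs: dict[str, dict[str, float]] = field(
        default_factory=_default_group_iqrs)
    missingness: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MISSINGNESS))
    planted_ratio: object | None = None
    planted_effect: float = 1.0
    planted_total_sigma: float = 0.25
    planted_share_sigma: float = 0.8
    seed: int = 0
    panel: CytokinePanel = field(default=DEFAULT_PANEL)

    def __post_init__(self) -> None:
        for g in GROUPS:
            if g not in self.sizes:
                raise ConfigurationError(f"missing group size for {g!r}")
            if int(self.sizes[g]) < 1:
                raise ConfigurationError(f"group size for {g!r} must be >= 1")
            rate = self.missingness.get(g, 0.0)
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(
                    f"missingness rate for {g!r} must lie in [0, 1]")
            for c in self.panel.names:
                m = self.medians[g][c]
                if not m > 0:
                    raise ConfigurationError(
                        f"median for {c} in group {g!r} must be positive")
                if self.iqrs[g][c] < 0:
                    raise ConfigurationError(
                        f"IQR width for {c} in group {g!r} must be >= 0")
        if self.planted_effect <= 0:
            raise ConfigurationError("planted_effect must be positive")

    @classmethod
    def uniform(cls, sizes: dict[str, int], median: float = 10.0,
                iqr: float = 8.0, panel: CytokinePanel = DEFAULT_PANEL,
                **kwargs) -> "GroupEffectConfig":
        """A no-effect configuration: every cytokine shares one median/IQR
        in every group (useful for null-calibration experiments)."""
        med = {g: {c: median for c in panel.names} for g in GROUPS}
        iqrs = {g: {c: iqr for c in panel.names} for g in GROUPS}
        return cls(sizes=sizes, medians=med, iqrs=iqrs, panel=panel, **kwargs)

    def effective_medians(self) -> dict[str, dict[str, float]]:
        """Group medians with any planted ratio effect applied."""
        med = {g: dict(v) for g, v in self.medians.items()}
        if self.planted_ratio is not None and self.planted_effect != 1.0:
            for cyt in self.planted_ratio.numerator:
                for g in ("gram_negative", "gram_positive"):
                    med[g][cyt] *= self.planted_effect
        return med


def lognormal_sigma(median: float, iqr: float) -> float:
    """Log-scale sd of a log-normal with the given median and IQR width.

    For X ~ LogNormal(ln m, s), IQR = m·(e^{z·s} − e^{−z·s}) = 2m·sinh(z·s)
    with z the 75th-percentile normal score, hence s = asinh(IQR/2m)/z.
    """
    if median <= 0:
        raise ConfigurationError("median must be positive")
    return float(np.arcsinh(iqr / (2.0 * median)) / _Z75)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate_cohort(config: GroupEffectConfig) -> pd.DataFrame:
    """Draw one synthetic cohort.

    Returns a tidy per-sample DataFrame with columns
    ``sample_id, bsi, gram, <21 cytokines>, age, gender, bmi, ecmo, imv,
    comorbidities, crp, pct, lymphocytes, ne_pct``.  Cytokine concentrations
    are complete; lab markers are missing per the configured per-group rates.
    """
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    medians = config.effective_medians()
    t1 = load_fixture("table1_counts")

    blocks = []
    counter = 0
    for group in GROUPS:
        n = int(config.sizes[group])
        bsi = "no" if group == "no_bsi" else "yes"
        gram = {"no_bsi": "n/a", "gram_negative": "negative",
                "gram_positive": "positive"}[group]
        t1_key = "no_bsi" if group == "no_bsi" else "bsi"
        t1_row = 0 if group == "no_bsi" else 1

        block = pd.DataFrame({
            "sample_id": [f"S{counter + i:04d}" for i in range(n)],
            "bsi": bsi,
            "gram": gram,
        })
        counter += n

        planted_members: set[str] = set()
        if config.planted_ratio is not None:
            planted_members = set(config.planted_ratio.numerator) | set(
                config.planted_ratio.denominator)

        for cyt in panel.names:
            if cyt in planted_members:
                continue
            m = medians[group][cyt]
            s = lognormal_sigma(m, config.iqrs[group][cyt])
            vals = np.exp(rng.normal(np.log(m), s, size=n))
            block[cyt] = np.maximum(vals, CONCENTRATION_FLOOR)

        if config.planted_ratio is not None:
            # Regulated module totals with compositional member shares: the
            # planted ratio equals (numerator total)/(denominator total)
            # exactly, while each member carries extra share noise.
            for side in (config.planted_ratio.numerator,
                         config.planted_ratio.denominator):
                side = tuple(side)
                side_medians = np.array([medians[group][c] for c in side])
                total = np.exp(rng.normal(
                    np.log(side_medians.sum()),
                    config.planted_total_sigma, size=n))
                weights = side_medians * np.exp(rng.normal(
                    0.0, config.planted_share_sigma, size=(n, len(side))))
                shares = weights / weights.sum(axis=1, keepdims=True)
                for i, cyt in enumerate(side):
                    block[cyt] = np.maximum(total * shares[:, i],
                                            CONCENTRATION_FLOOR)

        # Demographics from the published marginal frequencies.
        age_m, age_iqr = t1["age"][t1_key]
        bmi_m, bmi_iqr = t1["bmi"][t1_key]
        block["age"] = np.round(
            rng.normal(age_m, age_iqr / (2 * _Z75), size=n)).astype(int)
        p_female = t1["gender"]["table"][t1_row][0] / sum(
            t1["gender"]["table"][t1_row])
        block["gender"] = np.where(
            rng.random(n) < p_female, "female", "male")
        block["bmi"] = np.round(
            rng.normal(bmi_m, bmi_iqr / (2 * _Z75), size=n), 1)
        for var in ("ecmo", "imv", "comorbidities"):
            row = t1[var]["table"][t1_row]
            p_yes = row[1] / sum(row)
            block[var] = np.where(rng.random(n) < p_yes, "yes", "no")

        # Lab markers, log-normal, with block-wise missingness.
        missing = rng.random(n) < config.missingness.get(group, 0.0)
        for lab in LAB_COLUMNS:
            m, iqr = _DEFAULT_LAB_PARAMS[lab][group]
            vals = np.exp(rng.normal(np.log(m), lognormal_sigma(m, iqr),
                                     size=n))
            vals = np.round(vals, 2)
            block[lab] = np.where(missing, np.nan, vals)

        blocks.append(block)

    cohort = pd.concat(blocks, ignore_index=True)
    ordered = list(META_COLUMNS) + list(panel.names) \
        + list(DEMOGRAPHIC_COLUMNS) + list(LAB_COLUMNS)
    return cohort[ordered]


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort as tidy CSV, missing values as empty fields."""
    cohort.to_csv(path, index=False, na_rep="")


def read_cohort(path, panel: CytokinePanel = DEFAULT_PANEL) -> pd.DataFrame:
    """Read a tidy cohort CSV and validate its invariants."""
    # only empty fields are missing; "n/a" is a literal gram label
    cohort = pd.read_csv(path, na_values=[""], keep_default_na=False)
    if len(cohort) == 0:
        raise ValueError(f"cohort file {path} contains no samples")
    missing_cols = [c for c in META_COLUMNS + panel.names
                    if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort file {path} lacks columns: {missing_cols}")
    cyt = cohort[list(panel.names)]
    if cyt.isna().any().any():
        raise ValueError("cytokine concentrations must be complete")
    if (cyt <= 0).any().any():
        raise ValueError("cytokine concentrations must be positive")
    bad_gram = ((cohort["bsi"] == "no") & (cohort["gram"] != "n/a")) | (
        (cohort["bsi"] == "yes") & (~cohort["gram"].isin(
            ["negative", "positive"])))
    if bad_gram.any():
        raise ValueError("gram label must be n/a exactly for non-BSI samples")
    return cohort


def config_from_dict(payload: dict) -> GroupEffectConfig:
    """Build a :class:`GroupEffectConfig` from a plain (YAML/JSON) mapping.

    Only keys present in the payload override the defaults.  A planted ratio
    may be given as ``{"numerator": [...], "denominator": [...]}``.
    """
    from .ratio_engine import RatioSpec

    kwargs = {}
    for key in ("sizes", "medians", "iqrs", "missingness", "seed",
                "planted_effect"):
        if key in payload:
            kwargs[key] = payload[key]
    if payload.get("planted_ratio"):
        pr = payload["planted_ratio"]
        kwargs["planted_ratio"] = RatioSpec(
            numerator=tuple(pr["numerator"]),
            denominator=tuple(pr["denominator"]))
    cfg = GroupEffectConfig(**kwargs)
    return cfg


def config_to_dict(config: GroupEffectConfig) -> dict:
    """Serialise a config to a plain mapping (YAML/JSON friendly)."""
    payload = dataclasses.asdict(config)
    payload.pop("panel")
    if config.planted_ratio is not None:
        payload["planted_ratio"] = {
            "numerator": list(config.planted_ratio.numerator),
            "denominator": list(config.planted_ratio.denominator),
        }
    return payload
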