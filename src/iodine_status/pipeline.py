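"""End-to-end orchestration: cohort CSV in, derived table and report out.

The pipeline mirrors how a surveillance analyst would process a cohort
with paired spot and 24-h urine samples:

1. screen 24-h collections for completeness (volume and sex-specific
   creatinine floors) and drop incomplete ones, counting every exclusion;
2. compute, per person, the predicted 24-h creatinine (PrCr) for each
   requested equation, the predicted and measured 24-h iodine excretion
   (PrUIE, mUIE), and estimated daily intakes (excretion / bioavailability,
   plus the IOM weight-based estimate);
3. classify intakes against the EAR, cross-tabulate predicted vs measured
   adequacy per equation (kappa, sensitivity, specificity), summarise the
   spot-UIC distribution (MUIC block), and compute log-scale Bland-Altman
   agreement and paired rank statistics.

Counts of every dropped row are kept in the report because sample sizes
legitimately differ between analyses (e.g. participants without the race
indicator leave only the Mage table).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import agreement, classify
from . import equations as eq
from .cohort import OBSERVABLE_COLUMNS

__all__ = [
    "RunConfig",
    "REQUIRED_COLUMNS",
    "read_cohort",
    "derive_records",
    "analyze",
    "run_pipeline",
    "MissingColumnsError",
    "EmptyResultError",
]

logger = logging.getLogger("iodine_status")

#: Columns the pipeline-facing CSV must provide (empty cells = missing).
REQUIRED_COLUMNS = OBSERVABLE_COLUMNS

ALL_EQUATIONS = ("tanaka", "kawasaki", "mage")


class MissingColumnsError(ValueError):
    """Input CSV lacks required columns (named in the message)."""


class EmptyResultError(ValueError):
    """Every row was excluded; there is nothing to analyse."""


@dataclass(frozen=True)
class RunConfig:
    """All tunable constants of a pipeline run.

    Defaults are the conventional surveillance values: EAR 95 µg/day,
    92% iodine bioavailability, MUIC deficiency cut-off 100 µg/L,
    completeness floors of 300 mL and 4/6 mmol creatinine per day
    (women/men), and 1.96-sd limits of agreement.
    """

    input: Optional[str] = None
    outdir: Optional[str] = None
    equations: Sequence[str] = ALL_EQUATIONS
    ear: float = classify.EAR_UG_DAY
    bioavailability: float = eq.IODINE_BIOAVAILABILITY
    muic_cutoff: float = classify.MUIC_DEFICIENCY_CUTOFF
    volume_threshold_ml: float = eq.INCOMPLETE_VOLUME_ML
    creatinine_threshold_female: float = 4.0
    creatinine_threshold_male: float = 6.0
    spot_cr_unit: str = "mg/dL"
    loa_z: float = 1.96
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.bioavailability <= 1.0:
            raise ValueError("bioavailability must be in (0, 1]")
        for name in ("ear", "muic_cutoff", "volume_threshold_ml",
                     "creatinine_threshold_female", "creatinine_threshold_male",
                     "loa_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.equations) - set(ALL_EQUATIONS)
        if unknown:
            raise ValueError(f"unknown equations: {sorted(unknown)}")


def read_cohort(path) -> pd.DataFrame:
    """Read the pipeline-facing CSV, checking the column dictionary."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnsError(
            f"input {path} is missing required column(s): {', '.join(missing)}"
        )
    return df


def _female_mask(df: pd.DataFrame) -> np.ndarray:
    sex = df["sex"].astype(str).str.strip().str.lower()
    bad = ~sex.isin(["male", "female"])
    if bad.any():
        raise eq.InputError(
            f"{int(bad.sum())} row(s) with missing/unrecognised sex"
        )
    return (sex == "female").to_numpy()


def derive_records(df: pd.DataFrame, cfg: RunConfig = RunConfig()) -> pd.DataFrame:
    """Add completeness flags and all derived quantities to a cohort table.

    Rows where an equation yields a non-positive PrCr are flagged: the
    prediction is set to missing and the count is logged, rather than
    carrying a non-physiological value into the iodine extrapolation.
    """
    out = df.copy()
    female = _female_mask(df)
    cr_floor = np.where(
        female, cfg.creatinine_threshold_female, cfg.creatinine_threshold_male
    )
    out["complete_collection"] = (
        (df["vol24_mL"].to_numpy(dtype=float) > cfg.volume_threshold_ml)
        & (df["ucr24_mmol"].to_numpy(dtype=float) > cr_floor)
    )

    age = df["age_y"].to_numpy(dtype=float)
    weight = df["weight_kg"].to_numpy(dtype=float)
    height = df["height_cm"].to_numpy(dtype=float)
    bmi = df["bmi"].to_numpy(dtype=float)
    bmi = np.where(np.isnan(bmi), weight / (height / 100.0) ** 2, bmi)
    black = df["ethnicity_black"].to_numpy(dtype=float)

    prcr = {}
    if "tanaka" in cfg.equations:
        prcr["tanaka"] = eq.tanaka_creatinine(age, weight, height)
    if "kawasaki" in cfg.equations:
        prcr["kawasaki"] = eq.kawasaki_creatinine(age, weight, height, female)
    if "mage" in cfg.equations:
        prcr["mage"] = eq.mage_creatinine(age, weight, height, bmi, black, female)

    uic = df["spot_uic_ugL"].to_numpy(dtype=float)
    ucr = df["spot_ucr_mgdL"].to_numpy(dtype=float)
    out["muie_ugday"] = (
        df["vol24_mL"].to_numpy(dtype=float) / 1000.0
        * df["iodine24_ugL"].to_numpy(dtype=float)
    )
    out["intake_muie_ugday"] = out["muie_ugday"] / cfg.bioavailability
    out["intake_iom_ugday"] = eq.iom_intake(
        uic, weight, bioavailability=cfg.bioavailability
    )

    for name, values in prcr.items():
        nonpositive = np.isfinite(values) & (values <= 0)
        if nonpositive.any():
            logger.warning(
                "%s equation: %d row(s) with non-positive PrCr set to missing",
                name, int(nonpositive.sum()),
            )
            values = np.where(nonpositive, np.nan, values)
        out[f"prcr_{name}_mgday"] = values
        pruie = eq.predicted_uie(uic, ucr, values, ucr_unit=cfg.spot_cr_unit)
        out[f"pruie_{name}_ugday"] = pruie
        out[f"intake_{name}_ugday"] = pruie / cfg.bioavailability
    return out


def _ba_summary(result: agreement.BlandAltmanResult) -> dict:
    return {
        "mean_ratio_pct": result.mean_ratio_pct,
        "loa_low_pct": result.loa_low_pct,
        "loa_high_pct": result.loa_high_pct,
        "mean_log_diff": result.mean_log_diff,
        "sd_log_diff": result.sd_log_diff,
        "z": result.z,
        "n": result.n,
        "n_excluded_nonpositive": result.n_excluded_nonpositive,
        "direction": result.direction,
    }


def analyze(derived: pd.DataFrame, cfg: RunConfig = RunConfig()) -> dict:
    """Build the classification/agreement report from a derived table."""
    n_input = len(derived)
    complete = derived[derived["complete_collection"]].reset_index(drop=True)
    n_excluded = n_input - len(complete)
    if len(complete) == 0:
        raise EmptyResultError("all rows excluded by the completeness screen")
    logger.info("completeness screen: %d of %d rows excluded", n_excluded, n_input)

    muic = classify.population_muic(complete["spot_uic_ugL"].dropna().to_numpy())
    meas_below = classify.below_ear(
        complete["intake_muie_ugday"].to_numpy(), ear=cfg.ear
    )
    iom_below = classify.below_ear(
        complete["intake_iom_ugday"].to_numpy(), ear=cfg.ear
    )

    report = {
        "n_input": int(n_input),
        "n_complete": int(len(complete)),
        "n_excluded_incomplete": int(n_excluded),
        "ear_ug_day": cfg.ear,
        "bioavailability": cfg.bioavailability,
        "muic": {
            "median_uic_ugL": muic.muic,
            "deficient": bool(muic.deficient),
            "pct_lt100": muic.pct_lt100,
            "pct_lt50": muic.pct_lt50,
            "n": muic.n,
        },
        "measured": {
            "n": int(np.sum(~np.isnan(meas_below))),
            "pct_below_ear": classify.pct_below_ear(meas_below),
        },
        "iom": {
            "n": int(np.sum(~np.isnan(iom_below))),
            "pct_below_ear": classify.pct_below_ear(iom_below),
        },
        "equations": {},
    }

    for name in cfg.equations:
        pred_intake = complete[f"intake_{name}_ugday"].to_numpy()
        pred_below = classify.below_ear(pred_intake, ear=cfg.ear)
        table = classify.cross_tabulate(pred_below, meas_below)
        sens_spec = classify.sensitivity_specificity(table)
        pair = np.isfinite(complete[f"pruie_{name}_ugday"].to_numpy()) & np.isfinite(
            complete["muie_ugday"].to_numpy()
        )
        ba = agreement.bland_altman_log(
            complete.loc[pair, f"pruie_{name}_ugday"],
            complete.loc[pair, "muie_ugday"],
            z=cfg.loa_z,
        )
        paired = agreement.paired_summary(
            complete.loc[pair, f"pruie_{name}_ugday"],
            complete.loc[pair, "muie_ugday"],
        )
        report["equations"][name] = {
            "n": int(table.n),
            "n_missing_prediction": int(np.sum(np.isnan(pred_below))),
            "table": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
            "kappa": classify.cohens_kappa(table),
            "sensitivity_pct": sens_spec["sens"],
            "specificity_pct": sens_spec["spec"],
            "pct_below_ear_pred": table.pred_below / table.n * 100.0,
            "pct_below_ear_meas": table.meas_below / table.n * 100.0,
            "bland_altman": _ba_summary(ba),
            "paired": dataclasses.asdict(paired),
        }
    return report


def run_pipeline(cfg: RunConfig) -> dict:
    """Read, screen, derive, analyse and write the full report bundle.

    Writes to ``cfg.outdir``: ``derived.csv`` (per-person derived table),
    ``report.json`` (classification + agreement report), one
    ``bland_altman_<equation>.csv`` per equation with the per-pair plot
    data, and ``run.log`` with the exclusion counts.
    """
    if cfg.input is None or cfg.outdir is None:
        raise ValueError("run_pipeline requires cfg.input and cfg.outdir")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        df = read_cohort(cfg.input)
        derived = derive_records(df, cfg)
        report = analyze(derived, cfg)
        derived.to_csv(outdir / "derived.csv", index=False)
        complete = derived[derived["complete_collection"]]
        for name in cfg.equations:
            pair = complete[
                np.isfinite(complete[f"pruie_{name}_ugday"])
                & np.isfinite(complete["muie_ugday"])
                & (complete[f"pruie_{name}_ugday"] > 0)
                & (complete["muie_ugday"] > 0)
            ]
            ba = agreement.bland_altman_log(
                pair[f"pruie_{name}_ugday"], pair["muie_ugday"], z=cfg.loa_z
            )
            agreement.bland_altman_frame(ba).to_csv(
                outdir / f"bland_altman_{name}.csv", index=False
            )
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        logger.info("report written to %s", outdir / "report.json")
    finally:
        logger.removeHandler(handler)
        handler.close()
    return report
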