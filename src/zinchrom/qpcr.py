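"""ChIP-qPCR quantification: standard curves, percent input, SNR, enrichment.

Each target's input dilution series (1, 1:10, 1:100, 1:1,000) defines a
standard curve Ct = intercept + slope * log10(relative quantity), from which
amplicon quantities in the immunoprecipitated (+Ab) and beads-only (-Ab)
samples are interpolated. Percent input scales each quantity to its total
eluate volume and then per unit of chromatin:

    %IP = 100 * (q_ip * V_chip_eluate / V_chromatin_for_chip)
              / (q_input * V_input_eluate / V_chromatin_as_input)

Signal-to-noise is %IP(+Ab) / %IP(-Ab); fold enrichment is a treatment's
+Ab %IP over the control condition's +Ab %IP for the same target. Outliers
among enrichment ratios are flagged by Tukey fences at 1.5 x IQR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Volumes",
    "StdCurve",
    "average_technical_replicates",
    "fit_standard_curve",
    "absolute_quantity",
    "percent_ip",
    "snr_and_enrichment",
    "iqr_outliers",
    "analyze_plate",
]

SAMPLE_CLASSES = ("ip_plus_ab", "ip_minus_ab", "input_dilution", "ntc")


@dataclass(frozen=True)
class Volumes:
    """Eluate and chromatin volumes (uL) used in the percent-input correction.

    Defaults mirror a protocol where 1/10 of 220 uL pre-cleared chromatin is
    reserved as input (22 uL), half of the remainder goes into each IP
    (99 uL), and both IP and input are eluted in 200 uL.
    """

    chip_eluate: float = 200.0
    input_eluate: float = 200.0
    chromatin_for_chip: float = 99.0
    chromatin_as_input: float = 22.0

    def __post_init__(self) -> None:
        if min(
            self.chip_eluate,
            self.input_eluate,
            self.chromatin_for_chip,
            self.chromatin_as_input,
        ) <= 0:
            raise ValueError("all volumes must be positive")


@dataclass(frozen=True)
class StdCurve:
    target: str
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError(
                f"{self.target}: standard curve slope must be negative "
                f"(got {self.slope:.3g}); plate flagged"
            )

    @property
    def efficiency(self) -> float:
        """Amplification efficiency; 1.0 means perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def average_technical_replicates(plate: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct over technical replicates per well group.

    Groups on every metadata column except well/tech-rep/ct. Undetermined
    Cts (NaN) are excluded from the mean; a group with no determined Ct
    keeps Ct = NaN and is flagged undetermined.
    """
    keys = [
        c
        for c in plate.columns
        if c not in ("well", "tech_rep", "ct")
    ]
    grouped = plate.groupby(keys, sort=False, dropna=False)["ct"]
    out = grouped.mean().reset_index()
    out["n_determined"] = grouped.count().to_numpy()
    out["undetermined"] = out["n_determined"] == 0
    return out


def fit_standard_curve(input_wells: pd.DataFrame, target: str = "") -> StdCurve:
    """Least-squares Ct vs log10(relative quantity = 1/dilution_factor).

    Needs >= 3 distinct dilution levels with determined Ct. A non-negative
    slope raises (flags the plate).
    """
    wells = input_wells.dropna(subset=["ct"])
    levels = wells["dilution_factor"].unique()
    if len(levels) < 3:
        raise ValueError(
            f"standard curve needs >=3 dilution levels, got {len(levels)}"
        )
    x = -np.log10(wells["dilution_factor"].to_numpy(dtype=float))
    y = wells["ct"].to_numpy(dtype=float)
    fit = stats.linregress(x, y)
    return StdCurve(
        target=target or str(wells.get("target", pd.Series(["?"])).iloc[0]),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def absolute_quantity(ct: float, curve: StdCurve) -> float:
    """Quantity relative to undiluted input: q = 10**((Ct - intercept)/slope)."""
    return float(10.0 ** ((ct - curve.intercept) / curve.slope))


def percent_ip(q_ip: float, q_input: float, volumes: Volumes) -> float:
    """Percent input with eluate-volume and chromatin-volume accounting."""
    if q_input <= 0:
        raise ValueError("q_input must be > 0")
    ip_total = q_ip * volumes.chip_eluate / volumes.chromatin_for_chip
    input_total = q_input * volumes.input_eluate / volumes.chromatin_as_input
    return 100.0 * ip_total / input_total


def iqr_outliers(values: np.ndarray | pd.Series) -> np.ndarray:
    """Tukey outlier flags: outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR].

    Quartiles use linear interpolation. Fewer than 4 values: nothing is
    flagged. Values are flagged, never dropped.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        return np.zeros(v.shape, dtype=bool)
    q1, q3 = np.percentile(v[~np.isnan(v)], [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    with np.errstate(invalid="ignore"):
        return (v < lo) | (v > hi)


def snr_and_enrichment(
    quants: pd.DataFrame,
    control_condition: str = "control",
    snr_reference: float = 1.5,
) -> pd.DataFrame:
    """Signal-to-noise and fold enrichment per target x condition.

    ``quants`` holds one row per (target, condition, replicate) with columns
    percent_ip_plus and percent_ip_minus. SNR = %IP(+Ab)/%IP(-Ab) (NaN when
    the -Ab signal is 0). Fold enrichment divides each condition's +Ab %IP
    by the control condition's +Ab %IP for the same target and replicate;
    the control condition is identically 1. Outliers are flagged among the
    fold-enrichment values of each target (across conditions/replicates).
    """
    df = quants.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        df["snr"] = np.where(
            df["percent_ip_minus"] > 0,
            df["percent_ip_plus"] / df["percent_ip_minus"],
            np.nan,
        )
    df["snr_above_reference"] = df["snr"] > snr_reference

    rep_cols = ["replicate"] if "replicate" in df.columns else []
    ctrl = (
        df[df["condition"] == control_condition]
        .set_index(["target"] + rep_cols)["percent_ip_plus"]
    )
    key = df.set_index(["target"] + rep_cols).index
    ctrl_vals = ctrl.reindex(key).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        df["fold_enrichment"] = np.where(
            ctrl_vals > 0, df["percent_ip_plus"] / ctrl_vals, np.nan
        )
    df["outlier"] = False
    for target, grp in df.groupby("target", sort=False):
        df.loc[grp.index, "outlier"] = iqr_outliers(grp["fold_enrichment"])
    return df


def analyze_plate(
    plate: pd.DataFrame,
    volumes: Volumes | None = None,
    control_condition: str = "control",
    snr_reference: float = 1.5,
) -> pd.DataFrame:
    """Full plate analysis: tech-rep averaging -> standard curves -> %IP -> SNR.

    ``plate`` columns: well, target, sample_class (ip_plus_ab / ip_minus_ab /
    input_dilution / ntc), condition, dilution_factor, tech_rep, ct, and
    optionally replicate (biological). A standard curve is fitted per
    (target, condition, replicate) from its input dilution series; +Ab and
    -Ab quantities are interpolated and converted to %IP with the volume
    correction. Returns one row per target x condition x replicate.
    """
    volumes = volumes or Volumes()
    rep_col = "replicate" if "replicate" in plate.columns else None
    work = plate.copy()
    if rep_col is None:
        work["replicate"] = 1
    avg = average_technical_replicates(
        work[
            ["target", "condition", "replicate", "sample_class",
             "dilution_factor", "well", "tech_rep", "ct"]
        ]
    )
    rows = []
    for (target, condition, replicate), grp in avg.groupby(
        ["target", "condition", "replicate"], sort=True
    ):
        inputs = grp[grp["sample_class"] == "input_dilution"]
        curve = fit_standard_curve(inputs, target=str(target))
        q_input = 1.0  # undiluted input defines the relative-quantity unit

        def _q(sample_class: str) -> float:
            sel = grp[grp["sample_class"] == sample_class]
            if len(sel) == 0 or sel["ct"].isna().all():
                return np.nan
            return absolute_quantity(float(sel["ct"].iloc[0]), curve)

        q_plus, q_minus = _q("ip_plus_ab"), _q("ip_minus_ab")
        rows.append(
            {
                "target": target,
                "condition": condition,
                "replicate": replicate,
                "slope": curve.slope,
                "efficiency": curve.efficiency,
                "r_squared": curve.r_squared,
                "percent_ip_plus": percent_ip(q_plus, q_input, volumes)
                if not np.isnan(q_plus)
                else np.nan,
                "percent_ip_minus": percent_ip(q_minus, q_input, volumes)
                if not np.isnan(q_minus)
                else np.nan,
            }
        )
    res = pd.DataFrame(rows)
    return snr_and_enrichment(
        res, control_condition=control_condition, snr_reference=snr_reference
    )
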