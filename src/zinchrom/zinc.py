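"""FRET-sensor quantification of labile nuclear Zn2+.

Per-cell intensity traces (donor/acceptor channels with backgrounds) are
converted to FRET ratios R = (acceptor - acceptor_bg) / (donor - donor_bg).
Each cell is calibrated in situ: a chelation phase gives the sensor minimum
ratio R_min, a saturation phase gives R_max, and the Hill-equation inverse

    [Zn2+] = K_d * ((R - R_min) / (R_max - R)) ** (1 / n)

converts a phase ratio into a concentration (K_d = 5.3 nM, Hill n = 0.29 for
the NLS-ZapCV2 sensor). Estimates outside the sensor's quantifiable range
are censored: below ~1 pM the occupancy ratio is indistinguishable from the
apo sensor (reported as below_range), and near saturation as above_range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationParams",
    "ZincEstimate",
    "fret_ratio",
    "extract_phase_ratios",
    "zn_concentration",
    "quantify_cells",
]

PHASES = ("rest", "treatment", "chelation", "saturation")


@dataclass(frozen=True)
class CalibrationParams:
    """Sensor constants and per-cell calibration ratios.

    kd_nM and hill_n are sensor properties; r_min and r_max are per-cell
    in-situ calibration values. zn_floor_nM / zn_ceiling_nM define the
    quantifiable range: the floor default of 0.001 nM (1 pM) is the minimum
    labile Zn2+ the sensor can resolve.
    """

    kd_nM: float = 5.3
    hill_n: float = 0.29
    r_min: float = 1.0
    r_max: float = 3.0
    zn_floor_nM: float = 1e-3
    zn_ceiling_nM: float = 5e3
    plateau_window: int = 10

    def __post_init__(self) -> None:
        if self.r_max <= self.r_min:
            raise ValueError("r_max must exceed r_min")
        if self.kd_nM <= 0:
            raise ValueError("kd_nM must be > 0")
        if not (0 < self.hill_n <= 1):
            raise ValueError("hill_n must be in (0, 1]")
        if not (0 < self.zn_floor_nM < self.zn_ceiling_nM):
            raise ValueError("need 0 < zn_floor_nM < zn_ceiling_nM")

    def occupancy_bounds(self) -> tuple[float, float]:
        """(u_floor, u_ceiling): censoring thresholds on u=(Zn/Kd)^n."""
        return (
            (self.zn_floor_nM / self.kd_nM) ** self.hill_n,
            (self.zn_ceiling_nM / self.kd_nM) ** self.hill_n,
        )


@dataclass(frozen=True)
class ZincEstimate:
    cell_id: str
    phase: str
    ratio: float
    zn_nM: float | None
    censor: str  # quantified | below_range | above_range

    def __post_init__(self) -> None:
        if self.censor not in ("quantified", "below_range", "above_range"):
            raise ValueError(f"bad censor flag {self.censor!r}")
        if self.censor == "quantified" and not (self.zn_nM and self.zn_nM > 0):
            raise ValueError("quantified estimate requires zn_nM > 0")


def fret_ratio(trace: pd.DataFrame) -> pd.Series:
    """Background-corrected acceptor/donor ratio per timepoint.

    Timepoints with non-positive corrected donor signal are invalid (NaN)
    and are excluded from plateau medians downstream.
    """
    donor = trace["donor"] - trace["donor_bg"]
    acceptor = trace["acceptor"] - trace["acceptor_bg"]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = acceptor / donor
    return r.where(donor > 0).rename("ratio")


def extract_phase_ratios(
    trace: pd.DataFrame, plateau_window: int = 10
) -> dict[str, float]:
    """Phase ratio = median of the last ``plateau_window`` valid frames.

    ``trace`` needs columns time_s, phase, donor, acceptor, donor_bg,
    acceptor_bg. Raises if a calibration phase (chelation/saturation) is
    absent or has no valid frames, or if the implied R_max <= R_min.
    """
    trace = trace.sort_values("time_s", kind="mergesort")
    ratios = fret_ratio(trace)
    out: dict[str, float] = {}
    for phase, grp in ratios.groupby(trace["phase"], sort=False):
        valid = grp.dropna()
        if len(valid) == 0:
            continue
        out[phase] = float(valid.tail(plateau_window).median())
    for needed in ("chelation", "saturation"):
        if needed not in out:
            raise ValueError(f"calibration phase {needed!r} missing or invalid")
    if out["saturation"] <= out["chelation"]:
        raise ValueError(
            "R_max (saturation) must exceed R_min (chelation); cell excluded"
        )
    return out


def zn_concentration(ratio: float, params: CalibrationParams) -> ZincEstimate | tuple:
    """Invert the Hill calibration for one ratio, censoring out-of-range values.

    Returns (zn_nM or None, censor flag). u = (R - R_min)/(R_max - R); u at
    or below the floor occupancy maps to below_range, u at or above the
    ceiling occupancy (or R >= R_max) to above_range, otherwise
    zn = K_d * u**(1/n).
    """
    u_floor, u_ceiling = params.occupancy_bounds()
    if ratio >= params.r_max:
        return None, "above_range"
    u = (ratio - params.r_min) / (params.r_max - ratio)
    if u <= u_floor:
        return None, "below_range"
    if u >= u_ceiling:
        return None, "above_range"
    return float(params.kd_nM * u ** (1.0 / params.hill_n)), "quantified"


def quantify_cells(
    traces: pd.DataFrame,
    sensor: CalibrationParams | None = None,
    phases: tuple[str, ...] = ("rest", "treatment"),
) -> pd.DataFrame:
    """Per-cell calibration and Zn2+ quantification from a trace table.

    ``traces`` holds all cells (columns cell_id, time_s, phase, donor,
    acceptor, donor_bg, acceptor_bg). Each cell's own chelation/saturation
    plateaus set R_min/R_max; ``sensor`` supplies K_d, Hill n, censoring
    range, and plateau window. Cells failing calibration are reported with
    censor="excluded". Returns a tidy frame (cell_id, phase, ratio, zn_nM,
    censor).
    """
    sensor = sensor or CalibrationParams()
    rows = []
    for cell_id, trace in traces.groupby("cell_id", sort=True):
        try:
            phase_r = extract_phase_ratios(trace, sensor.plateau_window)
        except ValueError:
            for phase in phases:
                rows.append((cell_id, phase, np.nan, np.nan, "excluded"))
            continue
        params = CalibrationParams(
            kd_nM=sensor.kd_nM,
            hill_n=sensor.hill_n,
            r_min=phase_r["chelation"],
            r_max=phase_r["saturation"],
            zn_floor_nM=sensor.zn_floor_nM,
            zn_ceiling_nM=sensor.zn_ceiling_nM,
            plateau_window=sensor.plateau_window,
        )
        for phase in phases:
            if phase not in phase_r:
                rows.append((cell_id, phase, np.nan, np.nan, "excluded"))
                continue
            zn, censor = zn_concentration(phase_r[phase], params)
            rows.append(
                (cell_id, phase, phase_r[phase], np.nan if zn is None else zn, censor)
            )
    return pd.DataFrame(
        rows, columns=["cell_id", "phase", "ratio", "zn_nM", "censor"]
    )
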