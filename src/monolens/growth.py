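"""Doubling-rate estimation from microplate OD curves.

The fitness proxy throughout the package is the *relative doubling rate*
(rDR): a strain's doubling rate (DR, doublings per hour, estimated from the
exponential phase of its OD600 curve) divided by the mean DR of control
strains carried on the same plate. Deviations ``d = rDR - 1`` are the
per-strain fitness costs that feed the epistasis module.

DR is estimated as the maximal least-squares slope of ``log2(OD)`` versus
time over sliding windows of consecutive readings whose blank-corrected OD
lies inside a configurable range (default 0.05-1.4; reading noise is
amplified by blank subtraction at low OD, so the default window is long
and starts above the blank level). On a noiseless
exponential ``OD = A * 2**(DR * t)`` this recovers DR exactly; on noisy
curves the window maximum tracks the steepest sustained exponential phase.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GrowthCurve",
    "DoublingRateEstimate",
    "StrainFitness",
    "blank_correct",
    "estimate_dr",
    "relative_dr",
    "aggregate_replicates",
    "fit_plate",
]

WELL_CLASSES = ("blank", "control", "test", "monosomic")


@dataclass
class GrowthCurve:
    """One well's OD600 time series with plate/well metadata.

    ``times`` are hours (strictly increasing, nominally 0.5-h steps) and
    ``od`` the raw or blank-corrected optical densities. ``flags`` records
    processing events such as floored blank-corrected values.
    """

    plate_id: str
    well: str
    strain_id: str | None
    well_class: str
    times: np.ndarray
    od: np.ndarray
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.well_class not in WELL_CLASSES:
            raise ValueError(
                f"well_class {self.well_class!r} not in {WELL_CLASSES}"
            )
        if self.times.shape != self.od.shape:
            raise ValueError("times and od must have equal length")
        if self.times.size < 4:
            raise ValueError(
                f"need >= 4 readings, got {self.times.size} "
                f"(well {self.well} on plate {self.plate_id})"
            )
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class DoublingRateEstimate:
    """DR for one well: winning log2-linear window, its slope and fit."""

    strain_id: str | None
    plate_id: str
    replicate: int
    dr: float
    window: tuple[float, float]
    fit_r2: float
    well_class: str = "test"
    flags: tuple[str, ...] = ()


@dataclass
class StrainFitness:
    """Replicate-aggregated relative doubling rate for one strain.

    ``d = rdr - 1`` is maintained exactly; ``se`` is the standard error of
    the replicate mean (0 and flagged for a single replicate).
    """

    strain_id: str
    rdr: float
    d: float
    n_replicates: int
    se: float
    flags: tuple[str, ...] = ()


def blank_correct(
    curve: GrowthCurve,
    blank_curves: Sequence[GrowthCurve],
    floor: float = 1e-4,
) -> GrowthCurve:
    """Subtract the per-time-point mean of same-plate blank wells.

    Corrected values that fall to or below zero are replaced by ``floor``
    and the curve is flagged ``"floored"``.
    """
    if not blank_curves:
        raise ValueError(f"no blank wells supplied for plate {curve.plate_id}")
    for b in blank_curves:
        if b.plate_id != curve.plate_id:
            raise ValueError(
                f"blank well {b.well} is from plate {b.plate_id}, "
                f"curve from {curve.plate_id}"
            )
        if not np.array_equal(b.times, curve.times):
            raise ValueError("blank and sample time grids differ")
    blank_mean = np.mean([b.od for b in blank_curves], axis=0)
    corrected = curve.od - blank_mean
    flags = curve.flags
    if np.any(corrected <= 0):
        corrected = np.where(corrected <= 0, floor, corrected)
        flags = flags + ("floored",)
    return replace(curve, od=corrected, flags=flags)


def _window_fit(t: np.ndarray, log2_od: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of log2(OD) vs t and its R^2."""
    slope, intercept = np.polyfit(t, log2_od, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((log2_od - pred) ** 2))
    ss_tot = float(np.sum((log2_od - log2_od.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(slope), r2


def estimate_dr(
    curve: GrowthCurve,
    window_points: int = 9,
    od_min: float = 0.05,
    od_max: float = 1.4,
    replicate: int = 0,
) -> DoublingRateEstimate:
    """Maximal sliding-window log2-linear slope of the OD curve.

    Windows are runs of ``window_points`` consecutive readings whose OD is
    inside ``[od_min, od_max]``. The window with the largest slope wins;
    a non-positive winning slope is clamped to 0 and flagged, matching the
    convention that measured doubling rates are non-negative.
    """
    if window_points < 2:
        raise ValueError("window_points must be >= 2")
    in_range = (curve.od >= od_min) & (curve.od <= od_max)
    n_in = int(in_range.sum())
    best: tuple[float, float, tuple[float, float]] | None = None
    # consecutive runs of in-range readings
    idx = np.flatnonzero(in_range)
    if idx.size:
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in splits:
            if run.size < window_points:
                continue
            t = curve.times[run]
            y = np.log2(curve.od[run])
            for start in range(run.size - window_points + 1):
                sl = slice(start, start + window_points)
                slope, r2 = _window_fit(t[sl], y[sl])
                if best is None or slope > best[0]:
                    best = (slope, r2, (float(t[sl][0]), float(t[sl][-1])))
    if best is None:
        raise ValueError(
            f"insufficient in-range points for well {curve.well} on plate "
            f"{curve.plate_id}: {n_in} readings in [{od_min}, {od_max}], "
            f"no run of {window_points} consecutive ones"
        )
    slope, r2, window = best
    flags: tuple[str, ...] = ()
    dr = slope
    if slope <= 1e-12:  # tolerance: polyfit on a flat curve is not exactly 0
        dr = 0.0
        flags = ("nonpositive_slope",)
    return DoublingRateEstimate(
        strain_id=curve.strain_id,
        plate_id=curve.plate_id,
        replicate=replicate,
        dr=dr,
        window=window,
        fit_r2=r2,
        well_class=curve.well_class,
        flags=flags,
    )


def relative_dr(
    dr: DoublingRateEstimate,
    controls: Sequence[DoublingRateEstimate],
    average: str = "mean",
) -> float:
    """Divide a DR estimate by the average control DR of the same plate."""
    if not controls:
        raise ValueError("control set is empty")
    for c in controls:
        if c.plate_id != dr.plate_id:
            raise ValueError(
                f"control from plate {c.plate_id} used for strain on "
                f"plate {dr.plate_id}; controls must be plate-matched"
            )
    values = np.array([c.dr for c in controls], dtype=float)
    if average == "mean":
        ref = float(values.mean())
    elif average == "median":
        ref = float(np.median(values))
    else:
        raise ValueError(f"unknown average {average!r}")
    if ref <= 0:
        raise ValueError(f"control average DR is {ref}; cannot normalize")
    return dr.dr / ref


def aggregate_replicates(
    rdrs: Sequence[float], strain_id: str = ""
) -> StrainFitness:
    """Replicate mean rDR with its standard error; ``d = rdr - 1``."""
    if len(rdrs) == 0:
        raise ValueError("no replicate rDR values supplied")
    values = np.asarray(rdrs, dtype=float)
    rdr = float(values.mean())
    flags: tuple[str, ...] = ()
    if values.size == 1:
        se = 0.0
        flags = ("single_replicate",)
    else:
        se = float(values.std(ddof=1) / np.sqrt(values.size))
    return StrainFitness(
        strain_id=strain_id,
        rdr=rdr,
        d=rdr - 1.0,
        n_replicates=int(values.size),
        se=se,
        flags=flags,
    )


def fit_plate(
    curves: Iterable[GrowthCurve],
    window_points: int = 9,
    od_min: float = 0.05,
    od_max: float = 1.4,
    blank_floor: float = 1e-4,
    replicate: int = 0,
    control_class: str = "control",
) -> dict[str, float]:
    """Blank-correct and fit every non-blank well of one plate.

    Returns ``{strain_id: rdr}`` with each test (or monosomic) well
    normalized by the mean DR of the plate's ``control_class`` wells.
    Control wells are themselves reported, normalized against the full
    control set, so their rDR hovers around 1.
    """
    curves = list(curves)
    plates = {c.plate_id for c in curves}
    if len(plates) != 1:
        raise ValueError(f"fit_plate expects a single plate, got {plates}")
    blanks = [c for c in curves if c.well_class == "blank"]
    estimates: list[DoublingRateEstimate] = []
    for c in curves:
        if c.well_class == "blank":
            continue
        corrected = blank_correct(c, blanks, floor=blank_floor)
        estimates.append(
            estimate_dr(
                corrected,
                window_points=window_points,
                od_min=od_min,
                od_max=od_max,
                replicate=replicate,
            )
        )
    controls = [e for e in estimates if e.well_class == control_class]
    if not controls:
        raise ValueError(f"no {control_class!r} wells on plate {plates.pop()}")
    out: dict[str, float] = {}
    for e in estimates:
        assert e.strain_id is not None
        out[e.strain_id] = relative_dr(e, controls)
    return out
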