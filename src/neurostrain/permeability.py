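"""Membrane-permeability trace analysis.

Mechanoporation is probed with a cell-impermeant dye (Alexa Fluor 568
hydrazide, "AFH"): a rise in mean in-cell AFH intensity marks membrane
compromise, and the influx time is the time at which the smoothed intensity
peaks.  Cell death is read from the live-cell dye calcein AM, whose
intensity drops when the membrane loses integrity; the death time is the
first time the smoothed calcein trace falls below a fraction of its
baseline.  Detections landing on the final sample (AFH) or never occurring
(calcein) are censored: reported but excluded from group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .injury import welch_ttest

__all__ = [
    "IntensityTrace",
    "PermeabilityResult",
    "mean_intensity_in_mask",
    "influx_time",
    "death_time_from_calcein",
    "analyze_trace_pair",
    "compare_influx_death",
]


@dataclass(frozen=True)
class IntensityTrace:
    """Mean in-cell fluorescence intensity over time for one channel."""

    times_hr: np.ndarray
    values: np.ndarray
    channel: str  # "AFH" | "calcein"
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        t = np.asarray(self.times_hr, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1 or len(t) < 3:
            raise ValueError("trace needs matching 1D time/value arrays, >=3 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("fluorescence values must be non-negative")
        object.__setattr__(self, "times_hr", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class PermeabilityResult:
    """Detected influx and death times for one cell."""

    cell_id: str
    rate_group: str
    influx_time_hr: float | None = None
    influx_censored: bool = False
    death_time_hr: float | None = None
    death_censored: bool = False


def mean_intensity_in_mask(volumes: np.ndarray, mask: np.ndarray,
                           times_hr: np.ndarray, channel: str = "AFH",
                           cell_id: str = "cell") -> IntensityTrace:
    """Mean voxel intensity inside a cell mask, per time point.

    ``volumes`` is a (t, z, y, x) stack (or any (t, ...) array) and
    ``mask`` a boolean array matching the spatial shape.
    """
    volumes = np.asarray(volumes, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volumes.shape[1:]:
        raise ValueError("mask shape must match the per-timepoint volume shape")
    if not mask.any():
        raise ValueError("mask is empty")
    values = volumes[:, mask].mean(axis=1)
    return IntensityTrace(times_hr=times_hr, values=values,
                          channel=channel, cell_id=cell_id)


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge truncation (window in samples)."""
    if window <= 1:
        return values
    kernel = np.ones(window)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def influx_time(trace: IntensityTrace, window: int = 3) -> tuple[float, bool]:
    """Dye influx time: argmax of the smoothed AFH trace.

    Returns (time in hours, censored).  Censored when the maximum sits on
    the final sample, i.e. the peak may lie beyond the observation window.
    """
    if trace.channel != "AFH":
        raise ValueError("influx detection expects an AFH-channel trace")
    if window < 0:
        raise ValueError("window must be >= 0")
    smoothed = _smooth(trace.values, window)
    idx = int(np.argmax(smoothed))
    censored = idx == len(smoothed) - 1
    return float(trace.times_hr[idx]), censored


def death_time_from_calcein(
    trace: IntensityTrace, drop_fraction: float = 0.5, window: int = 3
) -> tuple[float | None, bool]:
    """Death time: first drop of smoothed calcein below a baseline fraction.

    Baseline is the mean of the first three samples.  Returns
    (time or None, censored); censored (None) when the trace never crosses.
    """
    if trace.channel != "calcein":
        raise ValueError("death detection expects a calcein-channel trace")
    if not 0 < drop_fraction < 1:
        raise ValueError("drop_fraction must be in (0, 1)")
    baseline = float(np.mean(trace.values[:3]))
    if baseline <= 0:
        raise ValueError("calcein baseline is non-positive")
    smoothed = _smooth(trace.values, window)
    below = smoothed < drop_fraction * baseline
    if not below.any():
        return None, True
    return float(trace.times_hr[int(np.argmax(below))]), False


def analyze_trace_pair(
    afh: IntensityTrace | None,
    calcein: IntensityTrace | None,
    rate_group: str,
    window: int = 3,
    drop_fraction: float = 0.5,
) -> PermeabilityResult:
    """Run both detections for one cell's channel pair."""
    if afh is None and calcein is None:
        raise ValueError("at least one channel trace is required")
    cell_id = (afh or calcein).cell_id
    influx = influx_time(afh, window=window) if afh is not None else (None, True)
    death = (
        death_time_from_calcein(calcein, drop_fraction, window)
        if calcein is not None
        else (None, True)
    )
    return PermeabilityResult(
        cell_id=cell_id,
        rate_group=rate_group,
        influx_time_hr=influx[0] if afh is not None else None,
        influx_censored=influx[1] if afh is not None else True,
        death_time_hr=death[0],
        death_censored=death[1],
    )


def compare_influx_death(results: list[PermeabilityResult]) -> pd.DataFrame:
    """Group means ± SD of influx and death times with Welch t-tests.

    Censored detections are excluded from means (their counts are
    reported).  Tests: influx vs death within each group, and pairwise
    across groups per quantity.  Raises when any group has fewer than two
    uncensored values for either quantity.
    """
    groups: dict[str, list[PermeabilityResult]] = {}
    for r in results:
        groups.setdefault(r.rate_group, []).append(r)

    data: dict[str, dict[str, np.ndarray]] = {}
    rows = []
    for g, recs in groups.items():
        influx = np.array(
            [r.influx_time_hr for r in recs
             if r.influx_time_hr is not None and not r.influx_censored]
        )
        death = np.array(
            [r.death_time_hr for r in recs
             if r.death_time_hr is not None and not r.death_censored]
        )
        if len(influx) < 2 or len(death) < 2:
            raise ValueError(
                f"group {g!r} has insufficient uncensored detections"
            )
        data[g] = {"influx": influx, "death": death}
        _, p_within = welch_ttest(influx, death)
        rows.append(
            {
                "rate_group": g,
                "n_influx": len(influx),
                "n_influx_censored": sum(r.influx_censored for r in recs),
                "mean_influx_hr": influx.mean(),
                "sd_influx_hr": influx.std(ddof=1),
                "n_death": len(death),
                "n_death_censored": sum(r.death_censored for r in recs),
                "mean_death_hr": death.mean(),
                "sd_death_hr": death.std(ddof=1),
                "p_influx_vs_death": p_within,
            }
        )
    table = pd.DataFrame(rows).set_index("rate_group")

    names = list(data)
    for qty in ("influx", "death"):
        for i, gi in enumerate(names):
            for gj in names[i + 1:]:
                _, p = welch_ttest(data[gi][qty], data[gj][qty])
                table.loc[gi, f"p_{qty}_vs_{gj}"] = p
    return table
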