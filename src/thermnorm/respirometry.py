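"""Intermittent-closed respirometry trace processing.

Converts raw oxygen-concentration time series (alternating closed and flush
phases) into per-cycle oxygen uptake rates (MO2, mg/h), applies background
(microbial) respiration correction using a blank chamber and post-trial
recordings, and extracts standard metabolic rate (SMR), maximum metabolic
rate (MMR) and aerobic scope (AS = MMR - SMR) per trial.

Conventions
-----------
* Cycle 0 is the manually started closed phase immediately after the
  exhaustive chase; its corrected MO2 is the MMR estimate.
* SMR is the mean of the lowest 10% of corrected MO2 values over the
  remaining overnight cycles, after excluding low-R2 outliers (R2 more than
  two standard deviations below the fish's trial-wide mean R2).
* Background correction rescales the blank-chamber curve multiplicatively so
  that its final value meets the mean of the post-trial background
  recordings of the fish's own chamber.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

PHASE_CLOSED = "closed"
PHASE_FLUSH = "flush"

#: Acceptable chamber volume range (L); outside this the trace is suspect.
CHAMBER_VOLUME_BOUNDS_L = (0.124, 0.129)


class RespirometryError(ValueError):
    """Raised for unusable traces or inconsistent processing inputs."""


@dataclass
class RespirometryTrace:
    """A single trial's oxygen record with phase labels.

    Parameters
    ----------
    trial_id, chamber_id : str
        Identifiers; blank (fishless) traces carry ``fish_mass_g=None``.
    chamber_volume_l : float
        Total chamber + recirculation loop volume in litres.
    fish_mass_g : float or None
        Fish wet mass; ``None`` for blank chambers (fish volume 0).
    time_s, o2_mg_per_l : ndarray
        Sample times (strictly increasing) and oxygen concentrations.
    phase : ndarray of str
        Phase label per sample, ``"closed"`` or ``"flush"``.
    """

    trial_id: str
    chamber_id: str
    chamber_volume_l: float
    fish_mass_g: Optional[float]
    time_s: np.ndarray
    o2_mg_per_l: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.o2_mg_per_l = np.asarray(self.o2_mg_per_l, dtype=float)
        self.phase = np.asarray(self.phase)
        if self.time_s.ndim != 1 or len(self.time_s) != len(self.o2_mg_per_l):
            raise RespirometryError(
                f"trial {self.trial_id}: time and O2 arrays must align"
            )
        if len(self.time_s) > 1 and np.any(np.diff(self.time_s) <= 0):
            raise RespirometryError(
                f"trial {self.trial_id}: sample times must be strictly increasing"
            )

    @property
    def is_blank(self) -> bool:
        return self.fish_mass_g is None

    def closed_segments(self) -> list[np.ndarray]:
        """Indices of each maximal run of closed-phase samples, in order."""
        closed = self.phase == PHASE_CLOSED
        if not closed.any():
            return []
        # boundaries where the closed mask switches value
        change = np.flatnonzero(np.diff(closed.astype(np.int8)))
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change + 1, [len(closed)]))
        return [
            np.arange(s, e) for s, e in zip(starts, ends) if closed[s]
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_id": self.trial_id,
                "chamber_id": self.chamber_id,
                "time_s": self.time_s,
                "o2_mg_per_L": self.o2_mg_per_l,
                "phase": self.phase,
            }
        )


def read_trace_csv(
    path: str | Path,
    chamber_volume_l: float,
    fish_mass_g: Optional[float],
) -> RespirometryTrace:
    """Read a trace CSV (columns trial_id, chamber_id, time_s, o2_mg_per_L, phase)."""
    df = pd.read_csv(path, comment="#")
    required = {"trial_id", "chamber_id", "time_s", "o2_mg_per_L", "phase"}
    missing = required - set(df.columns)
    if missing:
        raise RespirometryError(f"{path}: missing columns {sorted(missing)}")
    return RespirometryTrace(
        trial_id=str(df["trial_id"].iloc[0]),
        chamber_id=str(df["chamber_id"].iloc[0]),
        chamber_volume_l=chamber_volume_l,
        fish_mass_g=fish_mass_g,
        time_s=df["time_s"].to_numpy(float),
        o2_mg_per_l=df["o2_mg_per_L"].to_numpy(float),
        phase=df["phase"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# Cycle slopes and MO2
# ---------------------------------------------------------------------------

@dataclass
class CycleSlope:
    """OLS slope of O2 concentration against time within one closed phase."""

    cycle_index: int
    start_time_s: float
    slope_mg_per_l_h: float
    r_squared: float
    n_points: int
    usable: bool = True


def fit_cycle_slope(
    time_s: np.ndarray,
    o2_mg_per_l: np.ndarray,
    cycle_index: int = 0,
    trim_leading_s: float = 0.0,
) -> CycleSlope:
    """Ordinary least-squares slope of O2 vs time for one closed phase.

    The slope is reported in mg/L/h (signed; negative while the fish consumes
    oxygen).  R2 is defined as 0 when the response has zero variance so the
    downstream outlier rule never divides by zero.  ``trim_leading_s``
    optionally discards an initial mixing window (default 0).
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(o2_mg_per_l, dtype=float)
    if trim_leading_s > 0 and len(t):
        keep = t - t[0] >= trim_leading_s
        t, y = t[keep], y[keep]
    n = len(t)
    start = float(t[0]) if n else math.nan
    if n < 3:
        return CycleSlope(cycle_index, start, math.nan, math.nan, n, usable=False)
    tc = t - t.mean()
    yc = y - y.mean()
    sxx = float(tc @ tc)
    syy = float(yc @ yc)
    if sxx == 0.0:
        return CycleSlope(cycle_index, start, math.nan, math.nan, n, usable=False)
    beta = float(tc @ yc) / sxx  # mg/L/s
    if syy == 0.0:
        r2 = 0.0
    else:
        ss_res = syy - beta * float(tc @ yc)
        r2 = max(0.0, min(1.0, 1.0 - ss_res / syy))
    return CycleSlope(cycle_index, start, beta * 3600.0, r2, n)


def compute_mo2(
    slope_mg_per_l_h: float,
    chamber_volume_l: float,
    fish_mass_g: Optional[float],
) -> float:
    """Oxygen uptake rate (mg/h) from a closed-phase slope.

    MO2 = -slope x (chamber volume - fish volume), with fish volume taken as
    mass/1000 L (density 1 kg/L).  Blank chambers pass ``fish_mass_g=None``
    (fish volume 0).  Positive when oxygen declines.
    """
    fish_volume_l = 0.0 if fish_mass_g is None else fish_mass_g / 1000.0
    if fish_volume_l >= chamber_volume_l:
        raise RespirometryError(
            f"fish volume {fish_volume_l:.4f} L >= chamber volume "
            f"{chamber_volume_l:.4f} L"
        )
    return -slope_mg_per_l_h * (chamber_volume_l - fish_volume_l)


def trace_mo2_series(
    trace: RespirometryTrace, trim_leading_s: float = 0.0
) -> pd.DataFrame:
    """Per-cycle MO2 for a trace: columns cycle, start_time_s, mo2_mg_h, r_squared, usable."""
    rows = []
    for i, idx in enumerate(trace.closed_segments()):
        cs = fit_cycle_slope(
            trace.time_s[idx], trace.o2_mg_per_l[idx], i, trim_leading_s
        )
        mo2 = (
            compute_mo2(cs.slope_mg_per_l_h, trace.chamber_volume_l, trace.fish_mass_g)
            if cs.usable
            else math.nan
        )
        rows.append(
            {
                "cycle": i,
                "start_time_s": cs.start_time_s,
                "mo2_mg_h": mo2,
                "r_squared": cs.r_squared,
                "usable": cs.usable,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Background correction
# ---------------------------------------------------------------------------

def estimate_background_onset(
    blank_mo2: Sequence[float], k: int = 3, m: int = 2
) -> Optional[int]:
    """First blank cycle where background respiration departs from zero.

    Operationalised as the first cycle (at or after index ``k``) whose MO2
    exceeds mean + 2 sd of the first ``k`` blank cycles and stays above that
    threshold for ``m`` consecutive cycles.  Returns ``None`` if background
    never rises.  The opening cycles are background-free by protocol (the
    system is bleached between trials), so they define the baseline.
    """
    x = np.asarray(blank_mo2, dtype=float)
    if len(x) < k:
        raise RespirometryError(
            f"blank series has {len(x)} cycles; need at least k={k}"
        )
    baseline = x[:k]
    thresh = baseline.mean() + 2.0 * baseline.std(ddof=1)
    above = x > thresh
    for i in range(k, len(x) - m + 1):
        if above[i : i + m].all():
            return i
    return None


def build_background_series(
    blank_mo2: Sequence[float],
    onset: Optional[int],
    post_fish_mean: float,
    n_cycles: int,
) -> np.ndarray:
    """Background MO2 per fish-chamber cycle, anchored at the post-trial mean.

    The blank chamber gives the *shape* of background growth; each fish
    chamber's curve is the blank curve progressively adjusted (rescaled
    multiplicatively) so its final value equals ``post_fish_mean``, the mean
    of the three post-trial background recordings for that chamber.  Zero
    before onset; clipped at zero.  If the blank and fish trials differ in
    cycle count the blank curve is interpolated on relative cycle index.

    Falls back to a linear ramp from zero at onset to ``post_fish_mean`` at
    the final cycle when the blank curve ends at or below zero.
    """
    if post_fish_mean < 0:
        raise RespirometryError("post-fish background mean must be >= 0")
    blank = np.asarray(blank_mo2, dtype=float)
    if len(blank) != n_cycles:
        rel = np.linspace(0.0, 1.0, n_cycles)
        blank = np.interp(rel, np.linspace(0.0, 1.0, len(blank)), blank)
        if onset is not None:
            onset = min(n_cycles - 1, int(round(onset * (n_cycles - 1) / max(1, len(blank_mo2) - 1))))
    bg = np.zeros(n_cycles)
    if onset is None or post_fish_mean == 0.0:
        return bg
    final = blank[-1]
    if final <= 0.0:
        warnings.warn(
            "blank background curve ends at or below zero; "
            "falling back to a linear ramp to the post-trial mean",
            RuntimeWarning,
            stacklevel=2,
        )
        span = max(1, n_cycles - 1 - onset)
        ramp = (np.arange(n_cycles) - onset) / span
        bg = np.clip(ramp, 0.0, None) * post_fish_mean
        return bg
    scale = post_fish_mean / final
    bg[onset:] = np.clip(blank[onset:] * scale, 0.0, None)
    return bg


def correct_and_extract(
    mo2_series: pd.DataFrame, background: np.ndarray
) -> tuple[float, pd.DataFrame]:
    """Subtract background and split out MMR (cycle 0) from the SMR pool.

    Returns ``(mmr, pool)`` where ``pool`` holds the corrected overnight
    cycles (everything after the post-chase cycle) with their R2 values.
    """
    if len(mo2_series) != len(background):
        raise RespirometryError(
            f"MO2 series ({len(mo2_series)}) and background ({len(background)}) "
            "are misaligned"
        )
    corrected = mo2_series["mo2_mg_h"].to_numpy(float) - np.asarray(background, float)
    out = mo2_series.copy()
    out["background_mg_h"] = background
    out["corrected_mg_h"] = corrected
    usable = out[out["usable"]].reset_index(drop=True)
    if usable.empty:
        raise RespirometryError("no usable cycles in trial")
    mmr = float(usable["corrected_mg_h"].iloc[0])
    pool = usable.iloc[1:].reset_index(drop=True)
    return mmr, pool


def estimate_smr(
    pool_mo2: Sequence[float],
    pool_r2: Sequence[float],
    all_r2: Sequence[float],
) -> tuple[float, int, int]:
    """SMR as the outlier-screened mean of the lowest 10% of overnight MO2.

    Selects the ``ceil(0.1 N)`` lowest corrected MO2 values (minimum 1),
    drops any whose cycle R2 falls below (mean - 2 sd) of the R2 of *all*
    cycles in the fish's trial, and returns the mean of the survivors.  If
    every selected value is dropped, the single highest-R2 member is kept
    with a warning.

    Returns ``(smr, n_lowest_used, n_outliers_removed)``.
    """
    mo2 = np.asarray(pool_mo2, dtype=float)
    r2 = np.asarray(pool_r2, dtype=float)
    if len(mo2) < 2:
        raise RespirometryError(
            f"SMR pool has {len(mo2)} cycles; need at least 2"
        )
    n_low = max(1, math.ceil(0.1 * len(mo2)))
    order = np.argsort(mo2, kind="stable")[:n_low]
    all_r2 = np.asarray(all_r2, dtype=float)
    thresh = all_r2.mean() - 2.0 * all_r2.std(ddof=1)
    keep = r2[order] >= thresh
    n_out = int((~keep).sum())
    if keep.any():
        survivors = mo2[order][keep]
    else:
        warnings.warn(
            "all lowest-10% cycles flagged as outliers; keeping the single "
            "highest-R2 member",
            RuntimeWarning,
            stacklevel=2,
        )
        best = order[np.argmax(r2[order])]
        survivors = mo2[[best]]
        n_out = n_low - 1
    return float(survivors.mean()), int(len(survivors)), n_out


def count_cycles(
    closed_minutes: float, flush_minutes: float, trial_minutes: float
) -> int:
    """Number of completed closed-phase recordings in a trial window.

    Counts the manually started phase at time zero: the largest ``k + 1``
    such that ``k (closed + flush) + closed <= trial_minutes``; zero when not
    even one closed phase fits.
    """
    if closed_minutes <= 0 or flush_minutes <= 0:
        raise RespirometryError("closed and flush durations must be positive")
    if closed_minutes > trial_minutes:
        return 0
    k = math.floor((trial_minutes - closed_minutes) / (closed_minutes + flush_minutes))
    return k + 1


# ---------------------------------------------------------------------------
# Per-trial driver
# ---------------------------------------------------------------------------

@dataclass
class MetabolicEstimates:
    """Per fish-by-temperature metabolic summary with QC bookkeeping."""

    fish_id: str
    temperature_c: float
    smr_mg_h: float
    mmr_mg_h: float
    as_mg_h: float = field(init=False)
    n_cycles: int = 0
    n_lowest_used: int = 0
    n_outliers_removed: int = 0
    background_onset_cycle: Optional[int] = None

    def __post_init__(self) -> None:
        self.as_mg_h = self.mmr_mg_h - self.smr_mg_h
        if self.as_mg_h < 0:
            warnings.warn(
                f"fish {self.fish_id} at {self.temperature_c} degC: "
                f"negative aerobic scope ({self.as_mg_h:.4f} mg/h)",
                RuntimeWarning,
                stacklevel=2,
            )


def process_trial(
    trace: RespirometryTrace,
    blank_mo2: Sequence[float],
    post_fish_mean: float,
    fish_id: str,
    temperature_c: float,
    onset_k: int = 3,
    onset_m: int = 2,
    trim_leading_s: float = 0.0,
) -> MetabolicEstimates:
    """Full single-trial pipeline: slopes -> MO2 -> background -> SMR/MMR/AS."""
    series = trace_mo2_series(trace, trim_leading_s)
    onset = estimate_background_onset(blank_mo2, k=onset_k, m=onset_m)
    bg = build_background_series(blank_mo2, onset, post_fish_mean, len(series))
    mmr, pool = correct_and_extract(series, bg)
    all_r2 = series.loc[series["usable"], "r_squared"].to_numpy(float)
    smr, n_used, n_out = estimate_smr(
        pool["corrected_mg_h"], pool["r_squared"], all_r2
    )
    return MetabolicEstimates(
        fish_id=fish_id,
        temperature_c=temperature_c,
        smr_mg_h=smr,
        mmr_mg_h=mmr,
        n_cycles=len(series),
        n_lowest_used=n_used,
        n_outliers_removed=n_out,
        background_onset_cycle=onset,
    )


def process_study(
    traces: dict[str, RespirometryTrace],
    manifest: pd.DataFrame,
    blank_series: dict[str, Sequence[float]],
    trim_leading_s: float = 0.0,
) -> pd.DataFrame:
    """Process every fish trial listed in a manifest.

    ``manifest`` columns: trial_id, fish_id, temperature_c, chamber_id,
    fish_mass_g, post_fish_background_mean_mg_h, blank_trial_id.
    ``blank_series`` maps blank trial ids to their per-cycle blank MO2.
    """
    rows = []
    for rec in manifest.itertuples(index=False):
        trace = traces.get(str(rec.trial_id))
        if trace is None:
            raise RespirometryError(f"trace for trial {rec.trial_id} not supplied")
        blank = blank_series.get(str(rec.blank_trial_id))
        if blank is None:
            raise RespirometryError(
                f"blank series {rec.blank_trial_id} (trial {rec.trial_id}) missing"
            )
        est = process_trial(
            trace,
            blank,
            float(rec.post_fish_background_mean_mg_h),
            fish_id=str(rec.fish_id),
            temperature_c=float(rec.temperature_c),
            trim_leading_s=trim_leading_s,
        )
        rows.append(
            {
                "fish_id": est.fish_id,
                "temperature_c": est.temperature_c,
                "smr_mg_h": est.smr_mg_h,
                "mmr_mg_h": est.mmr_mg_h,
                "as_mg_h": est.as_mg_h,
                "n_cycles": est.n_cycles,
                "n_lowest_used": est.n_lowest_used,
                "n_outliers_removed": est.n_outliers_removed,
                "background_onset_cycle": est.background_onset_cycle,
            }
        )
    return pd.DataFrame(rows)
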