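"""Analysis-ready trait table construction.

Turns raw measurements into the long-format table the mixed models consume:
specific growth rate (SGR) from consecutive masses, swimming speed and
movement indicators from tracked distances, binary food intake from pellet
counts, metabolic estimates from respirometry, with exclusion filters,
temperature centring and body-mass z-scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

TRAIT_COLUMNS = [
    "fish_id",
    "aquarium_id",
    "unit_id",
    "trait",
    "temperature_c",
    "centred_temperature",
    "body_mass_g",
    "scaled_mass",
    "value",
]


class TraitError(ValueError):
    pass


def compute_sgr(bm_initial_g: float, bm_final_g: float, days: float) -> float:
    """Specific growth rate, %/day: 100 (ln BM_final - ln BM_initial)/days."""
    if bm_initial_g <= 0 or bm_final_g <= 0:
        raise TraitError("body masses must be positive")
    if days <= 0:
        raise TraitError("growth interval must be positive")
    return (math.log(bm_final_g) - math.log(bm_initial_g)) / days * 100.0


def align_sgr_midpoints(
    temperature_pairs: Sequence[tuple[float, float]],
    ladder: Sequence[float] = (14.0, 11.0, 8.0, 5.0, 2.0),
) -> list[float]:
    """Midpoint temperature of each growth interval.

    Growth is measured between consecutive temperatures on the cooling
    ladder, so each SGR is aligned with the middle of its interval (12.5,
    9.5, 6.5 and 3.5 degC on the default ladder).  Non-adjacent or
    degenerate pairs are rejected.
    """
    adjacent = set(zip(ladder, ladder[1:]))
    mids = []
    for pair in temperature_pairs:
        hi, lo = pair
        if (hi, lo) not in adjacent:
            raise TraitError(
                f"({hi}, {lo}) is not a consecutive pair on the cooling ladder"
            )
        mids.append((hi + lo) / 2.0)
    return mids


def compute_activity(distance_mm: float, duration_s: float) -> tuple[float, int]:
    """Mean swimming speed (mm/s) and movement indicator from a trial."""
    if duration_s <= 0:
        raise TraitError("trial duration must be positive")
    if distance_mm < 0:
        raise TraitError("distance cannot be negative")
    return distance_mm / duration_s, int(distance_mm > 0)


def binarize_feeding(pellets: int, ration: int = 10) -> int:
    """1 if the fish ate anything, 0 if it ate nothing."""
    if not 0 <= pellets <= ration:
        raise TraitError(f"pellet count {pellets} outside [0, {ration}]")
    return int(pellets > 0)


@dataclass
class Exclusions:
    """Per-fish and per-observation exclusion lists.

    ``fish`` removes an individual entirely; ``observations`` removes
    (fish_id, trait, temperature_c) triples (e.g. one fish's metabolic data
    at a single temperature after a chamber leak).
    """

    fish: list[str] = field(default_factory=list)
    observations: list[tuple[str, str, float]] = field(default_factory=list)


def growth_records(
    masses: pd.DataFrame,
    ladder: Sequence[float] = (14.0, 11.0, 8.0, 5.0, 2.0),
    interval_days: float = 25.0,
) -> pd.DataFrame:
    """Per-fish SGR between consecutive measurement temperatures.

    ``masses`` columns: fish_id, temperature_c, mass_g.  Output columns:
    fish_id, interval_start_c, interval_end_c, midpoint_c, bm_initial_g,
    bm_final_g, interval_days, sgr_pct_day.
    """
    wide = masses.pivot(index="fish_id", columns="temperature_c", values="mass_g")
    rows = []
    for hi, lo in zip(ladder, ladder[1:]):
        if hi not in wide.columns or lo not in wide.columns:
            continue
        mid = align_sgr_midpoints([(hi, lo)], ladder)[0]
        for fish, bm0, bm1 in zip(wide.index, wide[hi], wide[lo]):
            if pd.isna(bm0) or pd.isna(bm1):
                continue
            rows.append(
                {
                    "fish_id": fish,
                    "interval_start_c": hi,
                    "interval_end_c": lo,
                    "midpoint_c": mid,
                    "bm_initial_g": bm0,
                    "bm_final_g": bm1,
                    "interval_days": interval_days,
                    "sgr_pct_day": compute_sgr(bm0, bm1, interval_days),
                }
            )
    return pd.DataFrame(rows)


def _apply_exclusions(
    table: pd.DataFrame, exclusions: Optional[Exclusions]
) -> pd.DataFrame:
    if exclusions is None:
        return table
    known = set(table["fish_id"])
    for fid in exclusions.fish:
        if fid not in known:
            raise TraitError(f"exclusion list names unknown fish id {fid!r}")
    table = table[~table["fish_id"].isin(exclusions.fish)]
    for fid, trait, temp in exclusions.observations:
        if fid not in known:
            raise TraitError(f"exclusion list names unknown fish id {fid!r}")
        table = table[
            ~(
                (table["fish_id"] == fid)
                & (table["trait"] == trait)
                & (table["temperature_c"] == temp)
            )
        ]
    return table


def assemble_trait_table(
    metabolic_estimates: Optional[pd.DataFrame] = None,
    growth: Optional[pd.DataFrame] = None,
    activity: Optional[pd.DataFrame] = None,
    feeding: Optional[pd.DataFrame] = None,
    fish_info: Optional[pd.DataFrame] = None,
    masses: Optional[pd.DataFrame] = None,
    exclusions: Optional[Exclusions] = None,
    centre_temperature: float = 8.0,
    feeding_ration: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the long-format analysis table and a retention report.

    Sources (any subset may be supplied):

    * ``metabolic_estimates`` — respirometry output (fish_id, temperature_c,
      smr_mg_h, mmr_mg_h, as_mg_h [, chamber_id]); becomes traits
      ``smr``/``mmr``/``as`` with the respirometry chamber as unit.
    * ``growth`` — :func:`growth_records` output; trait ``sgr`` aligned at
      interval midpoints, with the interval-start mass as covariate.
    * ``activity`` — fish_id, arena_id, temperature_c, period, distance_mm,
      duration_s; traits ``activity_day``/``activity_night`` (binary moved).
    * ``feeding`` — fish_id, arena_id, temperature_c, pellets; trait
      ``feeding`` (binary ate-anything).
    * ``fish_info`` — fish_id, aquarium_id mapping.
    * ``masses`` — fish_id, temperature_c, mass_g, used as the body-mass
      covariate for rows whose source does not carry a mass.

    Temperature is centred at ``centre_temperature`` (the model intercept
    temperature); body mass is z-scaled per trait over retained rows.
    Returns ``(table, retention)`` where retention counts rows per trait per
    temperature after exclusions.
    """
    aq_map = {}
    if fish_info is not None:
        aq_map = dict(zip(fish_info["fish_id"], fish_info["aquarium_id"]))
    mass_map = {}
    if masses is not None:
        mass_map = {
            (r.fish_id, r.temperature_c): r.mass_g
            for r in masses.itertuples(index=False)
        }

    def lookup_mass(fish: str, temp: float) -> float:
        return mass_map.get((fish, temp), np.nan)

    pieces: list[pd.DataFrame] = []

    if metabolic_estimates is not None:
        me = metabolic_estimates
        unit = me["chamber_id"] if "chamber_id" in me.columns else pd.NA
        for trait, col in (("smr", "smr_mg_h"), ("mmr", "mmr_mg_h"), ("as", "as_mg_h")):
            pieces.append(
                pd.DataFrame(
                    {
                        "fish_id": me["fish_id"],
                        "unit_id": unit,
                        "trait": trait,
                        "temperature_c": me["temperature_c"],
                        "body_mass_g": [
                            lookup_mass(f, t)
                            for f, t in zip(me["fish_id"], me["temperature_c"])
                        ]
                        if "mass_g" not in me.columns
                        else me["mass_g"],
                        "value": me[col],
                    }
                )
            )

    if growth is not None and len(growth):
        pieces.append(
            pd.DataFrame(
                {
                    "fish_id": growth["fish_id"],
                    "unit_id": pd.NA,
                    "trait": "sgr",
                    "temperature_c": growth["midpoint_c"],
                    "body_mass_g": growth["bm_initial_g"],
                    "value": growth["sgr_pct_day"],
                }
            )
        )

    if activity is not None and len(activity):
        speed_moved = [
            compute_activity(d, s)
            for d, s in zip(activity["distance_mm"], activity["duration_s"])
        ]
        moved = [m for _, m in speed_moved]
        pieces.append(
            pd.DataFrame(
                {
                    "fish_id": activity["fish_id"],
                    "unit_id": activity["arena_id"],
                    "trait": "activity_" + activity["period"].astype(str),
                    "temperature_c": activity["temperature_c"],
                    "body_mass_g": [
                        lookup_mass(f, t)
                        for f, t in zip(activity["fish_id"], activity["temperature_c"])
                    ],
                    "value": moved,
                }
            )
        )

    if feeding is not None and len(feeding):
        pieces.append(
            pd.DataFrame(
                {
                    "fish_id": feeding["fish_id"],
                    "unit_id": feeding["arena_id"],
                    "trait": "feeding",
                    "temperature_c": feeding["temperature_c"],
                    "body_mass_g": [
                        lookup_mass(f, t)
                        for f, t in zip(feeding["fish_id"], feeding["temperature_c"])
                    ],
                    "value": [
                        binarize_feeding(int(p), feeding_ration)
                        for p in feeding["pellets"]
                    ],
                }
            )
        )

    if not pieces:
        raise TraitError("no data sources supplied")
    table = pd.concat(pieces, ignore_index=True)
    table["aquarium_id"] = table["fish_id"].map(aq_map).fillna(pd.NA)

    dup = table.duplicated(subset=["fish_id", "trait", "temperature_c"])
    if dup.any():
        first = table[dup].iloc[0]
        raise TraitError(
            "duplicate observation key "
            f"({first['fish_id']}, {first['trait']}, {first['temperature_c']})"
        )

    table = _apply_exclusions(table, exclusions)
    table = table.reset_index(drop=True)
    table["centred_temperature"] = table["temperature_c"] - centre_temperature

    # z-scale body mass once per trait over retained rows
    table["scaled_mass"] = np.nan
    for trait, grp in table.groupby("trait"):
        m = grp["body_mass_g"].astype(float)
        if m.notna().sum() >= 2 and m.std(ddof=0) > 0:
            scaled = (m - m.mean()) / m.std(ddof=0)
            table.loc[grp.index, "scaled_mass"] = scaled.fillna(0.0)
        else:
            table.loc[grp.index, "scaled_mass"] = 0.0

    retention = (
        table.groupby(["trait", "temperature_c"])
        .size()
        .rename("n_observations")
        .reset_index()
    )
    return table[TRAIT_COLUMNS], retention


def retained_fish_count(
    n_start: int, excluded: Iterable[tuple[str, int]]
) -> int:
    """Bookkeeping for sample attrition: start count minus each exclusion.

    ``excluded`` pairs a reason with a count, e.g. [("euthanized", 1),
    ("died", 2), ("untrackable", 3)].
    """
    total = n_start - sum(n for _, n in excluded)
    if total < 0:
        raise TraitError("exclusions exceed the starting sample")
    return total
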