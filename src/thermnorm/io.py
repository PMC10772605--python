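"""File-format contracts: headered CSV interchange and validation.

Every output file begins with ``#``-prefixed comment lines recording the
package version, the run seed and a hash of the configuration, so any number
in a report can be traced to the run that produced it.  All tables are plain
CSV; floats round-trip at full precision (repr format).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd

from .traits import TRAIT_COLUMNS

PACKAGE_VERSION = "0.1.0"


class IOError_(ValueError):
    pass


def config_fingerprint(config_dict: dict) -> str:
    """Stable short hash of a configuration dictionary."""
    blob = json.dumps(config_dict, sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _header_lines(seed: Optional[int], fingerprint: Optional[str]) -> list[str]:
    lines = [f"# thermnorm {PACKAGE_VERSION}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if fingerprint is not None:
        lines.append(f"# config: {fingerprint}")
    return lines


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: Optional[int] = None,
    fingerprint: Optional[str] = None,
) -> None:
    """Write a CSV with a traceability comment header, full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        for line in _header_lines(seed, fingerprint):
            fh.write(line + "\n")
        # repr gives the shortest digit string that round-trips exactly
        df.to_csv(fh, index=False, float_format=lambda x: repr(float(x)))


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a headered CSV (tolerates CRLF line endings)."""
    try:
        return pd.read_csv(path, comment="#", float_precision="round_trip")
    except UnicodeDecodeError as exc:
        raise IOError_(f"{path}: not valid UTF-8 text") from exc


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format trait table.

    Checks the full column contract and rejects duplicated
    (fish, trait, temperature) observation keys, naming the offender.
    """
    df = read_table(path)
    missing = set(TRAIT_COLUMNS) - set(df.columns)
    if missing:
        raise IOError_(f"{path}: missing trait-table columns {sorted(missing)}")
    dup = df.duplicated(subset=["fish_id", "trait", "temperature_c"])
    if dup.any():
        first = df[dup].iloc[0]
        raise IOError_(
            f"{path}: duplicate observation key "
            f"({first['fish_id']}, {first['trait']}, {first['temperature_c']})"
        )
    return df


def write_trait_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: Optional[int] = None,
    fingerprint: Optional[str] = None,
) -> None:
    write_table(df[TRAIT_COLUMNS], path, seed, fingerprint)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    required = {
        "trial_id",
        "fish_id",
        "temperature_c",
        "chamber_id",
        "fish_mass_g",
        "post_fish_background_mean_mg_h",
        "blank_trial_id",
    }
    missing = required - set(df.columns)
    if missing:
        raise IOError_(f"{path}: manifest missing columns {sorted(missing)}")
    return df
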