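"""Input/output layer: tabular schemas, run configuration and result writing.

All tag data are exchanged as plain CSV tables keyed by ``tag_id``:

``fixes.csv``
    tag_id, t_s, x_km, y_km, source{land,boat}
``depth.csv``
    tag_id, t_s, depth_m  (depth positive down, metres)
``calls.csv``
    tag_id, t_s, age_class{adult_female,calf}, received_level_db,
    peak_frequency_hz, caller_depth_m (optional)
``noise.csv``
    tag_id, t_s, then either ``broadband_db`` or one column per
    third-octave band, ``tob_<center_hz>_db``
``esb.csv``
    tag_id, t_s, count  (energetic surface behaviors)
``follows.csv``
    tag_id, follow_start_s, follow_end_s
``tl_bands.csv``
    center_hz, a_db, b_near, b_far, crossover_m

Timestamps are seconds since an arbitrary epoch; positions are local planar
easting/northing in kilometres with y increasing northward.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("pairspace")

__all__ = [
    "SchemaError",
    "ValidationError",
    "RunConfig",
    "TagDataset",
    "load_tag_dataset",
    "load_tag_datasets",
    "load_tl_bands",
    "write_results",
]


class SchemaError(ValueError):
    """A required column is missing or a file cannot be interpreted."""


class ValidationError(ValueError):
    """Rows violate an invariant (order, sign, range)."""


@dataclass
class RunConfig:
    """Analysis configuration with the study's default thresholds.

    Parameters
    ----------
    bin_length_s : float
        Length of the behavioral time bin, seconds (default 600 = 10 min).
    deep_dive_depth_m : float
        Depth a dive must strictly exceed to count as a deep dive (m).
    deep_dive_duration_s : float
        Duration a dive must strictly exceed to count as a deep dive (s).
    snr_threshold_db : float
        Signal-to-noise ratio at which a call is deemed no longer audible.
    band_low_hz, band_high_hz : float
        Third-octave bands inside this range enter the broadband noise sum.
    noise_window_s : float
        Maximum age of a noise sample matched to a call (s).
    distance_floor_m : float
        Smallest reportable detection distance (the transmission-loss
        reference distance); estimates at the floor are flagged.
    seed : int
        Seed for every stochastic step (k-means restarts, simulations).
    """

    bin_length_s: float = 600.0
    deep_dive_depth_m: float = 10.0
    deep_dive_duration_s: float = 75.0
    snr_threshold_db: float = 0.0
    band_low_hz: float = 40.0
    band_high_hz: float = 2500.0
    noise_window_s: float = 600.0
    distance_floor_m: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "bin_length_s",
            "deep_dive_depth_m",
            "deep_dive_duration_s",
            "band_low_hz",
            "band_high_hz",
            "noise_window_s",
            "distance_floor_m",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.bin_length_s != round(self.bin_length_s):
            raise ValidationError("bin_length_s must be a whole number of seconds")
        if self.band_high_hz <= self.band_low_hz:
            raise ValidationError("band_high_hz must exceed band_low_hz")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def hash(self) -> str:
        """Stable sha256 of the configuration (for run manifests)."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class TagDataset:
    """All series recorded for one tagged female-calf pair focal follow."""

    tag_id: str
    depth: pd.DataFrame
    fixes: pd.DataFrame
    calls: pd.DataFrame
    noise: pd.DataFrame
    esb: pd.DataFrame
    follow_start: float
    follow_end: float
    n_dropped_outside_follow: int = 0


_REQUIRED = {
    "fixes": ["tag_id", "t_s", "x_km", "y_km"],
    "depth": ["tag_id", "t_s", "depth_m"],
    "calls": ["tag_id", "t_s", "age_class", "received_level_db", "peak_frequency_hz"],
    "esb": ["tag_id", "t_s", "count"],
    "follows": ["tag_id", "follow_start_s", "follow_end_s"],
}

_TOB_RE = re.compile(r"^tob_(\d+(?:_\d+)?)_db$")

# observed span of received levels in this population; values outside it are
# legal but flagged, values outside [100, 200] are rejected
RL_HARD_RANGE = (100.0, 200.0)
RL_OBSERVED_RANGE = (124.0, 173.0)


def _check_columns(df: pd.DataFrame, name: str, required: list[str]) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing mandatory column(s) {missing}")


def _check_monotone(df: pd.DataFrame, name: str) -> None:
    t = df["t_s"].to_numpy(float)
    if len(t) > 1:
        bad = np.where(np.diff(t) <= 0)[0]
        if bad.size:
            raise ValidationError(
                f"{name}: timestamps not strictly increasing at row {int(bad[0]) + 1} "
                f"(t={t[bad[0] + 1]!r} after t={t[bad[0]]!r})"
            )


def tob_band_columns(df: pd.DataFrame) -> dict[float, str]:
    """Map third-octave center frequency (Hz) -> column name, from headers
    like ``tob_125_db`` or ``tob_31_5_db``."""
    out = {}
    for col in df.columns:
        m = _TOB_RE.match(col)
        if m:
            out[float(m.group(1).replace("_", "."))] = col
    return dict(sorted(out.items()))


def _validate_calls(calls: pd.DataFrame, tag_id: str) -> None:
    rl = calls["received_level_db"].to_numpy(float)
    lo, hi = RL_HARD_RANGE
    bad = np.where((rl < lo) | (rl > hi))[0]
    if bad.size:
        raise ValidationError(
            f"calls[{tag_id}]: received_level_db {rl[bad[0]]} outside plausible "
            f"range [{lo}, {hi}] at row {int(bad[0])}"
        )
    olo, ohi = RL_OBSERVED_RANGE
    n_flag = int(np.sum((rl < olo) | (rl > ohi)))
    if n_flag:
        logger.warning(
            "calls[%s]: %d received levels outside observed span [%s, %s] dB",
            tag_id, n_flag, olo, ohi,
        )
    if (calls["peak_frequency_hz"].to_numpy(float) <= 0).any():
        raise ValidationError(f"calls[{tag_id}]: peak_frequency_hz must be > 0")
    bad_class = set(calls["age_class"]) - {"adult_female", "calf"}
    if bad_class:
        raise ValidationError(f"calls[{tag_id}]: unknown age_class {sorted(bad_class)}")


def load_tag_datasets(
    directory: str | Path, config: RunConfig | None = None
) -> dict[str, TagDataset]:
    """Load and validate every tag in a directory of schema CSVs.

    Rows outside each tag's [follow_start, follow_end] window are dropped,
    with the count logged and recorded on the dataset. Any invariant
    violation raises :class:`ValidationError`; a missing mandatory column
    raises :class:`SchemaError`.
    """
    config = config or RunConfig()
    directory = Path(directory)
    frames: dict[str, pd.DataFrame] = {}
    for name in ("fixes", "depth", "calls", "noise", "esb", "follows"):
        path = directory / f"{name}.csv"
        if not path.exists():
            raise SchemaError(f"missing input file {path}")
        df = pd.read_csv(path)
        if name == "noise":
            _check_columns(df, name, ["tag_id", "t_s"])
            if "broadband_db" not in df.columns and not tob_band_columns(df):
                raise SchemaError(
                    "noise: need either broadband_db or tob_<center_hz>_db columns"
                )
        else:
            _check_columns(df, name, _REQUIRED[name])
        frames[name] = df

    out: dict[str, TagDataset] = {}
    for _, row in frames["follows"].iterrows():
        tag_id = str(row["tag_id"])
        out[tag_id] = _assemble(tag_id, frames, float(row["follow_start_s"]),
                                float(row["follow_end_s"]))
    return out


def load_tag_dataset(
    directory: str | Path, tag_id: str, config: RunConfig | None = None
) -> TagDataset:
    """Load a single tag's validated dataset from a schema directory."""
    datasets = load_tag_datasets(directory, config)
    if tag_id not in datasets:
        raise ValidationError(f"tag_id {tag_id!r} not present in follows.csv")
    return datasets[tag_id]


def _assemble(
    tag_id: str, frames: Mapping[str, pd.DataFrame], t0: float, t1: float
) -> TagDataset:
    if not t0 < t1:
        raise ValidationError(f"follows[{tag_id}]: follow_start must precede follow_end")
    parts: dict[str, pd.DataFrame] = {}
    n_dropped = 0
    for name in ("fixes", "depth", "calls", "noise", "esb"):
        df = frames[name]
        sub = df[df["tag_id"].astype(str) == tag_id].reset_index(drop=True)
        _check_monotone(sub, f"{name}[{tag_id}]")
        # position fixes may legitimately bracket the follow window (they are
        # interpolation support); everything else is clipped to the window
        if name == "fixes":
            keep = sub
        else:
            inside = (sub["t_s"] >= t0) & (sub["t_s"] <= t1)
            n_out = int((~inside).sum())
            if n_out:
                logger.info("%s[%s]: dropped %d rows outside follow window",
                            name, tag_id, n_out)
                n_dropped += n_out
            keep = sub[inside].reset_index(drop=True)
        parts[name] = keep

    depth = parts["depth"]
    if len(depth):
        d = depth["depth_m"].to_numpy(float)
        bad = np.where(d < 0)[0]
        if bad.size:
            raise ValidationError(
                f"depth[{tag_id}]: negative depth {d[bad[0]]} at row {int(bad[0])}"
            )
    fixes = parts["fixes"]
    if len(fixes) and not np.isfinite(fixes[["x_km", "y_km"]].to_numpy(float)).all():
        raise ValidationError(f"fixes[{tag_id}]: non-finite coordinates")
    if len(parts["calls"]):
        _validate_calls(parts["calls"], tag_id)
    if len(parts["esb"]) and (parts["esb"]["count"].to_numpy(float) < 0).any():
        raise ValidationError(f"esb[{tag_id}]: counts must be >= 0")

    return TagDataset(
        tag_id=tag_id,
        depth=parts["depth"],
        fixes=parts["fixes"],
        calls=parts["calls"],
        noise=parts["noise"],
        esb=parts["esb"],
        follow_start=t0,
        follow_end=t1,
        n_dropped_outside_follow=n_dropped,
    )


def load_tl_bands(path: str | Path) -> pd.DataFrame:
    """Load the per-octave-band transmission-loss coefficient table."""
    df = pd.read_csv(path)
    _check_columns(df, "tl_bands", ["center_hz", "a_db", "b_near", "b_far", "crossover_m"])
    if (df["b_near"] <= 0).any() or (df["b_far"] <= 0).any():
        raise ValidationError("tl_bands: slopes must be > 0")
    if (df["crossover_m"] < 1).any():
        raise ValidationError("tl_bands: crossover_m must be >= 1 m")
    return df.sort_values("center_hz").reset_index(drop=True)


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Write one CSV per result table plus ``manifest.json``.

    The manifest records file names, row counts, the configuration hash and
    the seed, so that two runs with identical config/seed are comparable at
    a glance.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, df in tables.items():
        fname = f"{name}.csv"
        df.to_csv(out_dir / fname, index=False)
        entries.append({"table": name, "file": fname, "rows": int(len(df))})
    manifest = {
        "tables": entries,
        "config_hash": (config or RunConfig()).hash(),
        "seed": seed,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
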