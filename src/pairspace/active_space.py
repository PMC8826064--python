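"""Acoustic active space: noise levels, piecewise transmission loss and the
detection distance of each call.

A call recorded at level RL (dB re 1 µPa) in broadband wind noise N is
assumed audible wherever its received level after propagation stays above
the noise, i.e. out to the distance d at which SNR(d) = RL - TL(d) - N
reaches 0. Transmission loss follows the site-measured piecewise
log-distance regression TL = a + b * log10(x) with one slope inside and one
beyond a per-band crossover distance, continuous at the crossover; the band
is the octave whose interval contains the call's peak frequency. Broadband
noise is the power sum of third-octave band levels between 40 Hz and
2.5 kHz. Depth-dependent propagation (e.g. the Lloyd-mirror penalty for
near-surface callers) is not modelled; calls produced above 10 m are merely
flagged ``near_surface`` because their detection distances are likely
overestimated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import Gamma, MixedGLM, lsmeans, pairwise_contrasts
from .io import RunConfig, tob_band_columns
from .states import RESTING_MILLING, TRAVELLING

__all__ = [
    "TransmissionLossBand",
    "DetectionEstimate",
    "broadband_noise_level",
    "broadband_noise_table",
    "match_noise_to_call",
    "select_tl_band",
    "transmission_loss",
    "detection_distance",
    "estimate_detection_distances",
    "fit_detection_distance_model",
    "distance_surface_summary",
]

NEAR_SURFACE_DEPTH_M = 10.0


@dataclass(frozen=True)
class TransmissionLossBand:
    """Piecewise log-distance TL coefficients for one octave band.

    TL(x) = a + b_near * log10(x) for x <= crossover, continuing beyond the
    crossover with slope b_far (dB per decade of distance). ``crossover``
    may be ``inf`` for a single-slope band.
    """

    center_hz: float
    a_db: float
    b_near: float
    b_far: float
    crossover_m: float

    def __post_init__(self):
        if self.b_near <= 0 or self.b_far <= 0:
            raise ValueError("TL slopes must be > 0")
        if self.crossover_m < 1.0:
            raise ValueError("crossover must be >= 1 m")

    @property
    def octave_low_hz(self) -> float:
        return self.center_hz / math.sqrt(2.0)

    @property
    def octave_high_hz(self) -> float:
        return self.center_hz * math.sqrt(2.0)


@dataclass
class DetectionEstimate:
    """Per-call SNR at the tag and distance to SNR = 0."""

    call_t: float
    age_class: str
    received_level_db: float
    noise_level_db: float
    snr_at_tag_db: float
    band_center_hz: float
    detection_distance_m: float
    floored: bool
    near_surface: bool | None


def broadband_noise_level(
    band_levels: dict[float, float] | pd.Series,
    band_low_hz: float = 40.0,
    band_high_hz: float = 2500.0,
) -> float:
    """Power sum of third-octave band levels within [band_low, band_high] Hz.

    10 * log10(sum 10^(L_i/10)) over in-range bands; out-of-range bands are
    ignored. Raises if no band falls in range.
    """
    if isinstance(band_levels, pd.Series):
        band_levels = band_levels.to_dict()
    levels = [
        lv
        for fc, lv in band_levels.items()
        if band_low_hz <= float(fc) <= band_high_hz and np.isfinite(lv)
    ]
    if not levels:
        raise ValueError(
            f"no third-octave bands within [{band_low_hz}, {band_high_hz}] Hz"
        )
    arr = np.asarray(levels, float)
    return float(10.0 * np.log10(np.sum(10.0 ** (arr / 10.0))))


def broadband_noise_table(noise: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """Per-sample broadband level: pass through ``broadband_db`` or power-sum
    the third-octave columns."""
    config = config or RunConfig()
    out = noise[["t_s"]].copy()
    bands = tob_band_columns(noise)
    if bands:
        cols = [c for fc, c in bands.items() if config.band_low_hz <= fc <= config.band_high_hz]
        if not cols:
            raise ValueError("no third-octave columns inside the analysis band")
        arr = noise[cols].to_numpy(float)
        out["broadband_db"] = 10.0 * np.log10(np.sum(10.0 ** (arr / 10.0), axis=1))
    elif "broadband_db" in noise.columns:
        out["broadband_db"] = noise["broadband_db"].to_numpy(float)
    else:
        raise ValueError("noise table has neither band columns nor broadband_db")
    return out


def match_noise_to_call(
    call_t: float, noise: pd.DataFrame, window_s: float = 600.0
) -> pd.Series | None:
    """Most recent noise sample at or before the call within ``window_s``.

    Returns ``None`` when no sample qualifies — the call is then excluded
    from the active-space analysis (a valid outcome, not an error).
    """
    t = noise["t_s"].to_numpy(float)
    idx = np.searchsorted(t, call_t, side="right") - 1
    if idx < 0 or call_t - t[idx] > window_s:
        return None
    return noise.iloc[idx]


def tl_bands_from_table(table: pd.DataFrame) -> list[TransmissionLossBand]:
    return [
        TransmissionLossBand(
            center_hz=float(r["center_hz"]),
            a_db=float(r["a_db"]),
            b_near=float(r["b_near"]),
            b_far=float(r["b_far"]),
            crossover_m=float(r["crossover_m"]),
        )
        for _, r in table.iterrows()
    ]


def select_tl_band(
    peak_frequency_hz: float, bands: list[TransmissionLossBand] | pd.DataFrame
) -> TransmissionLossBand:
    """Band whose octave interval [fc/sqrt2, fc*sqrt2) contains the peak."""
    if isinstance(bands, pd.DataFrame):
        bands = tl_bands_from_table(bands)
    for band in bands:
        if band.octave_low_hz <= peak_frequency_hz < band.octave_high_hz:
            return band
    coverage = ", ".join(
        f"[{b.octave_low_hz:.0f}, {b.octave_high_hz:.0f})" for b in bands
    )
    raise ValueError(
        f"peak frequency {peak_frequency_hz} Hz outside covered octave bands: {coverage}"
    )


def transmission_loss(band: TransmissionLossBand, distance_m) -> np.ndarray | float:
    """Piecewise TL at a distance (m); distances < 1 m are clamped to 1 m.

    Continuous at the crossover: beyond it,
    TL = a + b_near*log10(crossover) + b_far*log10(x/crossover).
    """
    x = np.clip(np.asarray(distance_m, float), 1.0, None)
    near = band.a_db + band.b_near * np.log10(x)
    if not np.isfinite(band.crossover_m):
        out = near
    else:
        tl_cross = band.a_db + band.b_near * np.log10(band.crossover_m)
        far = tl_cross + band.b_far * np.log10(x / band.crossover_m)
        out = np.where(x <= band.crossover_m, near, far)
    return float(out) if np.isscalar(distance_m) else out


def detection_distance(
    received_level_db: float,
    noise_level_db: float,
    band: TransmissionLossBand,
    config: RunConfig | None = None,
) -> tuple[float, bool]:
    """Distance at which the call's SNR reaches the audibility threshold.

    Solves RL - TL(d) - N = snr_threshold in closed form on whichever piece
    of the TL curve contains the solution. When the available SNR cannot
    exceed the TL even at the floor distance, the floor is returned with
    ``floored=True``.
    """
    config = config or RunConfig()
    floor = config.distance_floor_m
    budget = received_level_db - noise_level_db - config.snr_threshold_db
    if budget <= transmission_loss(band, floor):
        return floor, True
    d_near = 10.0 ** ((budget - band.a_db) / band.b_near)
    if not np.isfinite(band.crossover_m) or d_near <= band.crossover_m:
        d = d_near
    else:
        tl_cross = band.a_db + band.b_near * np.log10(band.crossover_m)
        d = band.crossover_m * 10.0 ** ((budget - tl_cross) / band.b_far)
    return float(max(d, floor)), False


def estimate_detection_distances(
    calls: pd.DataFrame,
    noise: pd.DataFrame,
    tl_table: pd.DataFrame,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Detection-distance table for every call with matchable noise.

    Calls without a noise sample within the matching window, or with a peak
    frequency outside the TL band coverage, are excluded with a reason in
    the ``excluded_reason`` column (their distance columns are NaN).
    """
    config = config or RunConfig()
    bands = tl_bands_from_table(tl_table)
    bb = broadband_noise_table(noise, config)
    rows = []
    for _, call in calls.iterrows():
        row = {
            "tag_id": call.get("tag_id", ""),
            "t_s": float(call["t_s"]),
            "age_class": call["age_class"],
            "received_level_db": float(call["received_level_db"]),
            "peak_frequency_hz": float(call["peak_frequency_hz"]),
        }
        depth = call.get("caller_depth_m", np.nan)
        row["near_surface"] = (
            bool(depth < NEAR_SURFACE_DEPTH_M) if np.isfinite(depth) else None
        )
        sample = match_noise_to_call(row["t_s"], bb, config.noise_window_s)
        if sample is None:
            row.update(noise_db=np.nan, snr_db=np.nan, band_hz=np.nan,
                       distance_m=np.nan, floored=False,
                       excluded_reason="no noise sample within window")
            rows.append(row)
            continue
        try:
            band = select_tl_band(row["peak_frequency_hz"], bands)
        except ValueError:
            row.update(noise_db=float(sample["broadband_db"]), snr_db=np.nan,
                       band_hz=np.nan, distance_m=np.nan, floored=False,
                       excluded_reason="peak frequency outside TL bands")
            rows.append(row)
            continue
        n_db = float(sample["broadband_db"])
        d, floored = detection_distance(row["received_level_db"], n_db, band, config)
        row.update(
            noise_db=n_db,
            snr_db=row["received_level_db"] - n_db,
            band_hz=band.center_hz,
            distance_m=d,
            floored=floored,
            excluded_reason=None,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def fit_detection_distance_model(
    detections: pd.DataFrame,
    include_floored: bool = False,
    n_quad: int = 32,
):
    """Gamma log-link mixed model of detection distance vs behavioral state.

    Random intercept per tag; least-squares state means back-transformed to
    metres and the travelling-minus-resting contrast on the log scale with
    a t reference on ``n_groups - 1`` degrees of freedom. Floored estimates
    are excluded by default (their distance is a reporting floor, not a
    propagation solution).
    """
    df = detections.dropna(subset=["distance_m", "state"]).copy()
    if not include_floored:
        df = df[~df["floored"].astype(bool)]
    flags = []
    for st in (RESTING_MILLING, TRAVELLING):
        if (df["state"] == st).sum() < 2:
            flags.append(f"state {st} has <2 estimates: contrast unreliable")
    if df["distance_m"].nunique() <= 1:
        flags.append("degenerate dispersion: all distances equal")
    y = df["distance_m"].to_numpy(float)
    travel = (df["state"] == TRAVELLING).to_numpy(float)
    X = np.column_stack([np.ones(len(df)), travel])
    groups = df["tag_id"].to_numpy()
    fit = MixedGLM(
        y, X, groups, Gamma(), exog_names=["intercept", "state_travelling"]
    ).fit(n_quad=n_quad)
    flags += fit.flags
    n_groups = len(np.unique(groups))
    design = np.array([[1.0, 0.0], [1.0, 1.0]])
    fe_cov = fit.cov_params[:2, :2]
    lsm = lsmeans(fit.fe_params, fe_cov, design,
                  [RESTING_MILLING, TRAVELLING], backtransform=True)
    lsm = lsm.rename(columns={"response": "distance_m", "response_se": "distance_se"})
    con = pairwise_contrasts(fit.fe_params, fe_cov, design,
                             [RESTING_MILLING, TRAVELLING],
                             df=float(n_groups - 1))
    return {"lsmeans": lsm, "contrast": con, "flags": flags, "results": fit}


def distance_surface_summary(
    detections: pd.DataFrame,
    rl_bin_db: float = 2.0,
    noise_bin_db: float = 1.0,
) -> pd.DataFrame:
    """Median detection distance on a (received level, noise) grid.

    A descriptive binned surface for plotting the joint dependence of
    detection distance on signal and noise level (no spatial smoothing is
    applied). Cells are labelled by their lower edges.
    """
    df = detections.dropna(subset=["distance_m"]).copy()
    if not len(df):
        return pd.DataFrame(columns=["rl_bin_db", "noise_bin_db", "median_distance_m", "n"])
    df["rl_cell"] = np.floor(df["received_level_db"] / rl_bin_db) * rl_bin_db
    df["noise_cell"] = np.floor(df["noise_db"] / noise_bin_db) * noise_bin_db
    out = (
        df.groupby(["rl_cell", "noise_cell"])["distance_m"]
        .agg(median_distance_m="median", n="count")
        .reset_index()
        .rename(columns={"rl_cell": "rl_bin_db", "noise_cell": "noise_bin_db"})
    )
    return out
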