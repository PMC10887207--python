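"""Per-beat pulse transit time and pulse wave velocity estimation.

Turns a (possibly reconstructed) two-channel pulse recording into matched
proximal/distal peak pairs, per-beat transit times and velocities, applies
the physiological validity filter (keep 0 < PWV <= 20 m/s) and summarizes a
trial.  The beat fiducial is the waveform's local maximum on the sample
grid — deliberately without sub-sample interpolation, so that timing
resolution is exactly the sample period and can be compared across rates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .dspcore import TimeSeries, lowpass10, resample_bandlimited
from .errors import (
    EmptyResultError,
    InvalidArgumentError,
    UndefinedRateError,
)

__all__ = [
    "PulseRecording",
    "BeatPair",
    "PwvResult",
    "detect_peaks",
    "peak_times",
    "pair_beats",
    "compute_pwv",
    "filter_valid",
    "heart_rate",
    "summarize",
    "analyze_recording",
]

logger = logging.getLogger(__name__)

#: Upper physiological bound for a valid velocity, m/s.
PWV_MAX = 20.0


@dataclass
class PulseRecording:
    """A synchronized proximal/distal channel pair with electrode distance."""

    prox: TimeSeries
    dist: TimeSeries
    distance: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.prox.fs - self.dist.fs) > 1e-9 * max(self.prox.fs, self.dist.fs):
            raise InvalidArgumentError(
                f"channel rate mismatch: {self.prox.fs} vs {self.dist.fs}"
            )
        if self.prox.n != self.dist.n:
            raise InvalidArgumentError(
                f"channel length mismatch: {self.prox.n} vs {self.dist.n}"
            )
        if not self.distance > 0:
            raise InvalidArgumentError("distance must be positive")

    @property
    def fs(self) -> float:
        return self.prox.fs


@dataclass
class BeatPair:
    """One matched proximal/distal peak pair and its transit quantities."""

    prox_peak_index: int
    dist_peak_index: int
    prox_peak_time: float
    dist_peak_time: float
    ptt: float
    pwv: float = math.nan
    valid: bool = False


@dataclass
class PwvResult:
    """Per-beat velocities plus trial-level summary statistics."""

    beat_pairs: list[BeatPair]
    mean_pwv: float
    max_deviation: float
    n_total: int
    n_valid: int
    omitted_fraction: float
    heart_rate_bpm: float
    stages: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mean_pwv": self.mean_pwv,
            "max_deviation": self.max_deviation,
            "n_total": self.n_total,
            "n_valid": self.n_valid,
            "omitted_fraction": self.omitted_fraction,
            "heart_rate_bpm": self.heart_rate_bpm,
            "stages": dict(self.stages),
        }


def detect_peaks(
    ts: TimeSeries,
    min_interval: float = 0.333,
    prominence_frac: float = 0.5,
) -> np.ndarray:
    """Indices of beat peaks: grid local maxima, no sub-sample refinement.

    Candidates are strict local maxima separated by at least
    ``min_interval`` seconds; of these, peaks whose prominence reaches
    ``prominence_frac`` times the median candidate prominence are kept.
    An equal-valued plateau yields its first index.  The caller is expected
    to low-pass the signal first.
    """
    if ts.duration < 2 * min_interval:
        raise InvalidArgumentError(
            f"signal of {ts.duration:.3g} s is shorter than 2 * min_interval"
        )
    spacing = max(1, int(round(min_interval * ts.fs)))
    idx, props = sps.find_peaks(ts.samples, distance=spacing, plateau_size=1)
    if idx.size == 0:
        return np.zeros(0, dtype=int)
    positions = props["left_edges"]
    prominences = sps.peak_prominences(ts.samples, idx)[0]
    threshold = prominence_frac * float(np.median(prominences))
    return positions[prominences >= threshold].astype(int)


def peak_times(ts: TimeSeries, indices: np.ndarray) -> np.ndarray:
    """Absolute times of grid peak indices."""
    return ts.start_time + np.asarray(indices, dtype=float) / ts.fs


def pair_beats(prox_peaks, dist_peaks, max_delay: float = 0.1) -> list[tuple[float, float]]:
    """Match each proximal peak to the earliest later distal peak.

    A pair requires a strictly positive delay of at most ``max_delay``
    seconds; each distal peak is used at most once; unmatched peaks on
    either side are dropped.  Inputs must be sorted ascending.
    """
    prox_peaks = np.asarray(prox_peaks, dtype=float)
    dist_peaks = np.asarray(dist_peaks, dtype=float)
    pairs: list[tuple[float, float]] = []
    j = 0
    for tp in prox_peaks:
        while j < dist_peaks.size and dist_peaks[j] <= tp:
            j += 1
        if j < dist_peaks.size and dist_peaks[j] - tp <= max_delay:
            pairs.append((float(tp), float(dist_peaks[j])))
            j += 1
    return pairs


def compute_pwv(ptt: float, distance: float) -> float:
    """Velocity ``distance / ptt`` in m/s; NaN for non-positive transit time.

    A non-positive PTT has no physical velocity and propagates as NaN, which
    downstream validity filtering removes.
    """
    if not distance > 0:
        raise InvalidArgumentError("distance must be positive")
    if not ptt > 0:
        return math.nan
    return distance / ptt


def filter_valid(pwv_values) -> tuple[np.ndarray, float]:
    """Keep velocities in ``(0, 20]`` m/s; report the omitted fraction.

    Exactly 20 m/s is retained (only values *exceeding* 20 are excluded);
    non-positive and NaN values are removed.
    """
    values = np.asarray(pwv_values, dtype=float)
    n = values.size
    if n == 0:
        return values, 0.0
    mask = (values > 0.0) & (values <= PWV_MAX)
    kept = values[mask]
    return kept, (n - kept.size) / n


def heart_rate(peaks) -> float:
    """Beats per minute from peak times: ``60 / mean(inter-peak interval)``."""
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size < 2:
        raise UndefinedRateError("heart rate needs at least two peaks")
    return 60.0 / float(np.mean(np.diff(peaks)))


def summarize(beat_pairs: list[BeatPair], distance: float) -> PwvResult:
    """Fill per-pair velocities, apply the validity filter, and aggregate.

    Mean and maximum absolute deviation are computed over valid pairs only.
    Raises :class:`EmptyResultError` (with ``n_total`` preserved) when no
    pair survives.
    """
    n_total = len(beat_pairs)
    if n_total == 0:
        raise EmptyResultError("no beat pairs to summarize", n_total=0)
    for bp in beat_pairs:
        bp.pwv = compute_pwv(bp.ptt, distance)
        bp.valid = bool(0.0 < bp.pwv <= PWV_MAX) if not math.isnan(bp.pwv) else False
    valid_vals = np.array([bp.pwv for bp in beat_pairs if bp.valid])
    n_valid = valid_vals.size
    if n_valid == 0:
        raise EmptyResultError(
            f"all {n_total} beat pairs were filtered out", n_total=n_total
        )
    mean_pwv = float(valid_vals.mean())
    max_dev = float(np.max(np.abs(valid_vals - mean_pwv)))
    prox_times = [bp.prox_peak_time for bp in beat_pairs]
    hr = heart_rate(prox_times) if len(prox_times) >= 2 else math.nan
    return PwvResult(
        beat_pairs=beat_pairs,
        mean_pwv=mean_pwv,
        max_deviation=max_dev,
        n_total=n_total,
        n_valid=int(n_valid),
        omitted_fraction=(n_total - n_valid) / n_total,
        heart_rate_bpm=hr,
    )


def analyze_recording(
    rec: PulseRecording,
    reconstruct_to: float | None = None,
    *,
    cutoff: float = 10.0,
    min_interval: float = 0.333,
    prominence_frac: float = 0.5,
    max_delay: float = 0.1,
    edge_guard: float = 0.6,
) -> PwvResult:
    """End-to-end per-trial analysis.

    Pipeline: optional bandlimited reconstruction of both channels to
    ``reconstruct_to`` -> 10 Hz low-pass -> grid peak detection per channel
    -> beat pairing -> validity filter and summary.  Peaks closer than
    ``edge_guard`` seconds to either boundary are discarded, since the
    zero-phase filters are unreliable inside their edge transients.
    """
    prox, dist = rec.prox, rec.dist
    if reconstruct_to is not None:
        prox = resample_bandlimited(prox, reconstruct_to)
        dist = resample_bandlimited(dist, reconstruct_to)
    prox_f = lowpass10(prox, cutoff)
    dist_f = lowpass10(dist, cutoff)

    stages: dict = {"fs": prox_f.fs, "n_samples": prox_f.n}
    pairs_t: list[tuple[float, float]] = []
    index_of: dict[float, int] = {}
    for name, ch in (("prox", prox_f), ("dist", dist_f)):
        idx = detect_peaks(ch, min_interval=min_interval, prominence_frac=prominence_frac)
        t = peak_times(ch, idx)
        lo = ch.start_time + edge_guard
        hi = ch.start_time + ch.duration - edge_guard
        keep = (t >= lo) & (t <= hi)
        stages[f"n_{name}_peaks"] = int(idx.size)
        stages[f"n_{name}_peaks_kept"] = int(keep.sum())
        if name == "prox":
            prox_t, prox_idx = t[keep], idx[keep]
        else:
            dist_t, dist_idx = t[keep], idx[keep]
        index_of.update(zip(t[keep].tolist(), idx[keep].tolist()))

    pairs_t = pair_beats(prox_t, dist_t, max_delay=max_delay)
    stages["n_pairs"] = len(pairs_t)
    logger.info("analyze_recording stages: %s", stages)
    if not pairs_t:
        raise EmptyResultError("no matched beat pairs in recording", n_total=0)

    beat_pairs = [
        BeatPair(
            prox_peak_index=index_of[tp],
            dist_peak_index=index_of[td],
            prox_peak_time=tp,
            dist_peak_time=td,
            ptt=td - tp,
        )
        for tp, td in pairs_t
    ]
    result = summarize(beat_pairs, rec.distance)
    result.stages = stages
    return result
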