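"""Sleep architecture and cumulative spectral-energy metrics.

Works from three time-aligned inputs: a hypnogram scored in 30-s epochs
(stages W, N1, N2, N3, REM), a set of arousal/artifact annotation
intervals, and a single frontal EEG channel sampled at (typically) 200 Hz.

Architecture metrics (total sleep time, sleep onset latency, efficiency,
REM percentage, REM latency/arousals/episodes) come from the hypnogram
alone.  The spectral-energy metrics — slow wave energy (SWE, cumulated
0.5-4 Hz power during slow wave sleep) and cumulated REM theta power
(4-8 Hz) — are built from Welch band power on 4-s segments with 2-s
overlap, restricted to segments free of any annotated arousal/artifact,
averaged per 30-min bin with a stage-time weight that adjusts for the
proportion of rejected data, and summed over bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import welch
from scipy.signal.windows import hann

__all__ = [
    "STAGES",
    "BANDS",
    "Hypnogram",
    "AnnotationSet",
    "SleepMetrics",
    "stage_metrics",
    "rem_metrics",
    "welch_band_power",
    "cumulative_band_energy",
    "compute_sleep_metrics",
    "read_hypnogram_csv",
    "write_hypnogram_csv",
    "read_annotations_csv",
    "write_annotations_csv",
    "read_eeg",
    "write_eeg_csv",
]

STAGES = ("W", "N1", "N2", "N3", "REM")

#: Canonical EEG frequency bands (Hz), half-open [lo, hi).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 16.0),
    "beta": (16.0, 30.0),
}

EPOCH_SECONDS = 30.0
SEGMENT_SECONDS = 4.0
SEGMENT_STEP_SECONDS = 2.0
BIN_MINUTES = 30.0


@dataclass(frozen=True)
class Hypnogram:
    """Sleep stages scored in fixed-length epochs.

    ``lights_off`` / ``lights_on`` are seconds from record start and bound
    the time-in-bed window; epochs only partially inside it are excluded
    from every metric.
    """

    stages: tuple[str, ...]
    epoch_length: float = EPOCH_SECONDS
    lights_off: float = 0.0
    lights_on: float | None = None

    def __post_init__(self) -> None:
        if len(self.stages) == 0:
            raise ValueError("hypnogram has no epochs")
        bad = sorted({s for s in self.stages} - set(STAGES))
        if bad:
            raise ValueError(f"unknown stage labels: {bad}")
        end = len(self.stages) * self.epoch_length
        lights_on = self.lights_on if self.lights_on is not None else end
        if not (0 <= self.lights_off < lights_on <= end):
            raise ValueError(
                f"need 0 <= lights_off < lights_on <= record end ({end} s); "
                f"got lights_off={self.lights_off}, lights_on={lights_on}"
            )
        object.__setattr__(self, "stages", tuple(self.stages))
        object.__setattr__(self, "lights_on", float(lights_on))

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration_seconds(self) -> float:
        return self.n_epochs * self.epoch_length

    @property
    def time_in_bed_minutes(self) -> float:
        return (self.lights_on - self.lights_off) / 60.0

    def in_bed_epochs(self) -> np.ndarray:
        """Indices of epochs fully inside [lights_off, lights_on]."""
        starts = np.arange(self.n_epochs) * self.epoch_length
        ends = starts + self.epoch_length
        return np.nonzero((starts >= self.lights_off) & (ends <= self.lights_on))[0]


@dataclass(frozen=True)
class AnnotationSet:
    """Arousal and artifact intervals, in seconds from record start."""

    intervals: tuple[tuple[float, float, str], ...] = ()

    def __post_init__(self) -> None:
        for start, end, kind in self.intervals:
            if not start < end:
                raise ValueError(f"annotation interval with start >= end: {(start, end)}")
            if kind not in ("arousal", "artifact"):
                raise ValueError(f"unknown annotation kind {kind!r}")
        object.__setattr__(
            self,
            "intervals",
            tuple((float(s), float(e), str(k)) for s, e, k in self.intervals),
        )

    def of_kind(self, *kinds: str) -> list[tuple[float, float]]:
        return [(s, e) for s, e, k in self.intervals if k in kinds]

    def overlaps(self, start: float, end: float, kinds: Iterable[str] | None = None) -> bool:
        for s, e, k in self.intervals:
            if kinds is not None and k not in kinds:
                continue
            if s < end and e > start:
                return True
        return False


@dataclass
class SleepMetrics:
    """Per-night derived metrics.

    Durations are minutes, efficiency and REM% are percentages, energies
    are cumulated band power in µV² (summed stage-time-weighted bin means,
    dimensionless bin weight).  Undefined quantities (no sleep, no REM,
    no target-stage epochs) are ``None`` rather than silently zero.
    """

    tst_minutes: float
    sleep_onset_latency_minutes: float | None
    sleep_efficiency_percent: float
    rem_percentage: float | None
    rem_latency_minutes: float | None = None
    rem_arousal_count: int = 0
    rem_episode_durations_minutes: list[float] = field(default_factory=list)
    swe: float | None = None
    rem_theta_energy: float | None = None

    def to_dict(self) -> dict:
        return {
            "tst_minutes": self.tst_minutes,
            "sleep_onset_latency_minutes": self.sleep_onset_latency_minutes,
            "sleep_efficiency_percent": self.sleep_efficiency_percent,
            "rem_percentage": self.rem_percentage,
            "rem_latency_minutes": self.rem_latency_minutes,
            "rem_arousal_count": self.rem_arousal_count,
            "rem_episode_durations_minutes": list(self.rem_episode_durations_minutes),
            "swe": self.swe,
            "rem_theta_energy": self.rem_theta_energy,
        }


# ---------------------------------------------------------------------------
# Architecture metrics


def stage_metrics(hypnogram: Hypnogram) -> SleepMetrics:
    """TST, sleep onset latency, efficiency and REM percentage.

    TST counts non-wake epochs inside the time-in-bed window; sleep onset
    is the first non-wake epoch after lights off (any stage); efficiency
    is 100 x TST / time in bed; REM% is 100 x REM minutes / TST.
    """
    idx = hypnogram.in_bed_epochs()
    if idx.size == 0:
        raise ValueError("no epochs fall inside the lights_off..lights_on window")
    stages = np.asarray(hypnogram.stages, dtype=object)[idx]
    epoch_min = hypnogram.epoch_length / 60.0

    asleep = stages != "W"
    tst = float(asleep.sum() * epoch_min)
    tib = hypnogram.time_in_bed_minutes
    efficiency = 100.0 * tst / tib

    if not asleep.any():
        sol = None
        rem_pct = None
    else:
        first_sleep = int(np.argmax(asleep))
        first_sleep_start = idx[first_sleep] * hypnogram.epoch_length
        sol = (first_sleep_start - hypnogram.lights_off) / 60.0
        rem_minutes = float((stages == "REM").sum() * epoch_min)
        rem_pct = 100.0 * rem_minutes / tst

    return SleepMetrics(
        tst_minutes=tst,
        sleep_onset_latency_minutes=sol,
        sleep_efficiency_percent=efficiency,
        rem_percentage=rem_pct,
    )


def rem_metrics(
    hypnogram: Hypnogram,
    annotations: AnnotationSet,
    merge_gap_epochs: int = 0,
) -> tuple[float | None, int, list[float]]:
    """REM onset latency, arousal-event count during REM, episode durations.

    Latency runs from the first sleep epoch to the first REM epoch
    (minutes).  Arousals are counted as *events* whose interval overlaps
    at least one REM epoch.  Episodes are maximal runs of REM epochs;
    non-REM gaps of at most ``merge_gap_epochs`` epochs are bridged
    (default 0: strict runs).  With no REM the latency is ``None``, the
    count 0 and the episode list empty.
    """
    idx = hypnogram.in_bed_epochs()
    stages = np.asarray(hypnogram.stages, dtype=object)[idx]
    epoch_min = hypnogram.epoch_length / 60.0

    asleep = stages != "W"
    is_rem = stages == "REM"
    if not is_rem.any():
        return None, 0, []
    if not asleep.any():  # unreachable when REM exists, kept for clarity
        return None, 0, []

    first_sleep = int(np.argmax(asleep))
    first_rem = int(np.argmax(is_rem))
    latency = (first_rem - first_sleep) * epoch_min

    # arousal events overlapping any REM epoch
    count = 0
    rem_epoch_global = idx[is_rem]
    rem_starts = rem_epoch_global * hypnogram.epoch_length
    for start, end in annotations.of_kind("arousal"):
        if np.any((rem_starts < end) & (rem_starts + hypnogram.epoch_length > start)):
            count += 1

    # episodes: runs of REM tolerating short gaps
    episodes: list[float] = []
    run = 0
    gap = None
    for flag in is_rem:
        if flag:
            if run > 0 and gap is not None and gap <= merge_gap_epochs:
                pass  # bridge the gap, run continues
            elif gap is not None:  # gap too long: close previous run
                episodes.append(run * epoch_min)
                run = 0
            run += 1
            gap = None
        elif run > 0:
            gap = 1 if gap is None else gap + 1
    if run > 0:
        episodes.append(run * epoch_min)
    return latency, count, episodes


# ---------------------------------------------------------------------------
# Spectral power


def welch_band_power(
    signal: np.ndarray,
    sampling_rate: float,
    band: tuple[float, float],
) -> float:
    """Band power (µV²) via Welch's method, 4-s segments, 2-s overlap.

    The PSD (Hann window, density scaling) is summed over frequency bins
    with ``lo <= f < hi`` and multiplied by the bin width, so a
    unit-amplitude sinusoid inside the band yields ~0.5 µV².
    """
    x = np.asarray(signal, dtype=float)
    nperseg = int(round(SEGMENT_SECONDS * sampling_rate))
    if x.size < nperseg:
        raise ValueError(
            f"signal shorter than one {SEGMENT_SECONDS:.0f}-s segment "
            f"({x.size} < {nperseg} samples)"
        )
    lo, hi = band
    nyquist = sampling_rate / 2.0
    if not (0 <= lo < hi <= nyquist):
        raise ValueError(f"band {band} outside [0, Nyquist={nyquist}] or inverted")
    freqs, psd = welch(
        x,
        fs=sampling_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(SEGMENT_STEP_SECONDS * sampling_rate)),
        detrend="constant",
        scaling="density",
    )
    df = freqs[1] - freqs[0]
    mask = (freqs >= lo) & (freqs < hi)
    return float(psd[mask].sum() * df)


def _segment_band_powers(
    x: np.ndarray,
    starts: np.ndarray,
    nseg: int,
    sampling_rate: float,
    band: tuple[float, float],
) -> np.ndarray:
    """Hann-windowed periodogram band power of many equal-length windows."""
    win = hann(nseg, sym=False)
    scale = 1.0 / (sampling_rate * (win * win).sum())
    segs = x[starts[:, None] + np.arange(nseg)[None, :]]
    segs = segs - segs.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(segs * win, axis=1)
    psd = (np.abs(spec) ** 2) * scale
    psd[:, 1:-1] *= 2.0
    freqs = np.fft.rfftfreq(nseg, d=1.0 / sampling_rate)
    df = freqs[1] - freqs[0]
    lo, hi = band
    mask = (freqs >= lo) & (freqs < hi)
    return psd[:, mask].sum(axis=1) * df


def cumulative_band_energy(
    signal: np.ndarray,
    sampling_rate: float,
    hypnogram: Hypnogram,
    annotations: AnnotationSet,
    stage_set: Sequence[str],
    band: tuple[float, float],
    bin_minutes: float = BIN_MINUTES,
    adjust_for_rejection: bool = True,
) -> tuple[float, pd.DataFrame]:
    """Cumulated overnight band power during a set of stages.

    For each 30-min bin (anchored at lights off) the band power of every
    clean 4-s segment (2-s step, aligned to epoch boundaries, overlapping
    no annotation) inside target-stage epochs is averaged; that
    clean-segment mean is then weighted by the fraction of the bin's
    epochs spent in the target stages — the adjustment for rejected data,
    which makes the cumulated sum insensitive to how many segments were
    discarded.  Energy is the sum of weighted bin means.  With
    ``adjust_for_rejection=False`` the unweighted clean-mean sum is
    returned instead.

    Bins that contain target-stage epochs but no clean segment are flagged
    (``flagged`` column) and excluded from the sum with a warning.

    Returns ``(energy, bins)`` where ``bins`` has one row per 30-min bin:
    ``bin_index, mean_power, n_clean_segments, n_stage_epochs,
    n_bin_epochs, rejected_fraction, flagged``.

    Raises
    ------
    ValueError
        If the record contains no epoch of the target stages at all
        (the energy is then undefined, not zero).
    """
    x = np.asarray(signal, dtype=float)
    lo, hi = band
    if not (0 <= lo < hi <= sampling_rate / 2.0):
        raise ValueError(f"band {band} outside [0, Nyquist]")
    stage_set = tuple(stage_set)
    bad = sorted(set(stage_set) - set(STAGES))
    if bad:
        raise ValueError(f"unknown stages in stage_set: {bad}")

    epoch_len = hypnogram.epoch_length
    nseg = int(round(SEGMENT_SECONDS * sampling_rate))
    step = int(round(SEGMENT_STEP_SECONDS * sampling_rate))
    expected = int(round(hypnogram.duration_seconds * sampling_rate))
    if x.size < expected:
        raise ValueError(
            f"EEG signal ({x.size} samples) shorter than the hypnogram span "
            f"({expected} samples at {sampling_rate} Hz)"
        )

    in_bed = set(hypnogram.in_bed_epochs().tolist())
    stages = hypnogram.stages
    epochs_per_bin = bin_minutes * 60.0 / epoch_len

    # dirty-sample indicator + cumulative sum: a segment [s0, s1) is clean
    # iff it contains no annotated sample (half-open interval semantics)
    dirty = np.zeros(expected, dtype=np.int8)
    for a0, a1, _kind in annotations.intervals:
        i0 = max(0, int(round(a0 * sampling_rate)))
        i1 = min(expected, int(round(a1 * sampling_rate)))
        if i1 > i0:
            dirty[i0:i1] = 1
    dirty_csum = np.concatenate([[0], np.cumsum(dirty, dtype=np.int64)])

    rows = []
    any_stage_epoch = False
    n_bins = int(np.ceil((hypnogram.lights_on - hypnogram.lights_off) / (bin_minutes * 60.0)))
    for b in range(n_bins):
        t0 = hypnogram.lights_off + b * bin_minutes * 60.0
        t1 = min(t0 + bin_minutes * 60.0, hypnogram.lights_on)
        ep_lo = int(np.ceil(t0 / epoch_len - 1e-9))
        ep_hi = int(np.floor(t1 / epoch_len + 1e-9))
        bin_epochs = [e for e in range(ep_lo, ep_hi) if e in in_bed]
        stage_epochs = [e for e in bin_epochs if stages[e] in stage_set]
        n_stage = len(stage_epochs)
        if n_stage:
            any_stage_epoch = True

        offs = np.arange(
            0.0, epoch_len - SEGMENT_SECONDS + 1e-9, SEGMENT_STEP_SECONDS
        )
        if stage_epochs:
            seg_t0 = (
                np.asarray(stage_epochs, dtype=float)[:, None] * epoch_len
                + offs[None, :]
            ).ravel()
            start_idx = np.round(seg_t0 * sampling_rate).astype(np.int64)
            n_total_segments = start_idx.size
            clean = (
                dirty_csum[start_idx + nseg] - dirty_csum[start_idx]
            ) == 0
            starts = start_idx[clean]
        else:
            n_total_segments = 0
            starts = np.empty(0, dtype=np.int64)
        n_clean = int(starts.size)
        rejected = 0.0 if n_total_segments == 0 else 1.0 - n_clean / n_total_segments

        if n_clean:
            powers = _segment_band_powers(
                x, np.asarray(starts), nseg, sampling_rate, band
            )
            mean_power = float(powers.mean())
        else:
            mean_power = np.nan
        flagged = bool(n_stage > 0 and n_clean == 0)
        rows.append(
            {
                "bin_index": b,
                "mean_power": mean_power,
                "n_clean_segments": n_clean,
                "n_stage_epochs": n_stage,
                "n_bin_epochs": len(bin_epochs),
                "rejected_fraction": rejected,
                "flagged": flagged,
            }
        )

    if not any_stage_epoch:
        raise ValueError(
            f"no epochs of stages {stage_set} in the record: energy undefined"
        )

    bins = pd.DataFrame(rows)
    if bins["flagged"].any():
        warnings.warn(
            f"{int(bins['flagged'].sum())} bin(s) had target-stage epochs but no "
            "clean segments; they are excluded from the cumulated energy",
            stacklevel=2,
        )
    usable = bins[(bins["n_clean_segments"] > 0) & ~bins["flagged"]]
    if adjust_for_rejection:
        weights = usable["n_stage_epochs"] / epochs_per_bin
        energy = float((usable["mean_power"] * weights).sum())
    else:
        energy = float(usable["mean_power"].sum())
    return energy, bins


def compute_sleep_metrics(
    hypnogram: Hypnogram,
    annotations: AnnotationSet,
    signal: np.ndarray | None = None,
    sampling_rate: float | None = None,
    swe_stages: Sequence[str] = ("N3",),
    merge_gap_epochs: int = 0,
) -> tuple[SleepMetrics, dict[str, pd.DataFrame]]:
    """Full per-night metrics record (architecture + SWE + REM theta).

    ``swe_stages`` selects the slow-wave-sleep definition for SWE: N3 only
    by default, ``("N2", "N3")`` for a broader NREM cumulation.  Spectral
    energies are left ``None`` when no EEG signal is given or when the
    record lacks the target stage.
    """
    metrics = stage_metrics(hypnogram)
    latency, arousals, episodes = rem_metrics(hypnogram, annotations, merge_gap_epochs)
    metrics.rem_latency_minutes = latency
    metrics.rem_arousal_count = arousals
    metrics.rem_episode_durations_minutes = episodes

    bin_series: dict[str, pd.DataFrame] = {}
    if signal is not None:
        if sampling_rate is None:
            raise ValueError("sampling_rate is required with an EEG signal")
        try:
            swe, swe_bins = cumulative_band_energy(
                signal, sampling_rate, hypnogram, annotations,
                swe_stages, BANDS["delta"],
            )
            metrics.swe = swe
            bin_series["swe"] = swe_bins
        except ValueError:
            metrics.swe = None
        try:
            theta, theta_bins = cumulative_band_energy(
                signal, sampling_rate, hypnogram, annotations,
                ("REM",), BANDS["theta"],
            )
            metrics.rem_theta_energy = theta
            bin_series["rem_theta"] = theta_bins
        except ValueError:
            metrics.rem_theta_energy = None
    return metrics, bin_series


# ---------------------------------------------------------------------------
# CSV / EDF I/O (the plain-text dialect shared with the synthetic generators)


def write_hypnogram_csv(hypnogram: Hypnogram, path) -> None:
    df = pd.DataFrame(
        {"epoch": np.arange(hypnogram.n_epochs), "stage": list(hypnogram.stages)}
    )
    with open(path, "w") as fh:
        fh.write(
            f"# epoch_length_s={hypnogram.epoch_length} "
            f"lights_off_s={hypnogram.lights_off} lights_on_s={hypnogram.lights_on}\n"
        )
        df.to_csv(fh, index=False)


def read_hypnogram_csv(path) -> Hypnogram:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(
            item.split("=") for item in header.lstrip("# ").split() if "=" in item
        )
        df = pd.read_csv(fh)
    return Hypnogram(
        stages=tuple(df["stage"].astype(str)),
        epoch_length=float(meta.get("epoch_length_s", EPOCH_SECONDS)),
        lights_off=float(meta.get("lights_off_s", 0.0)),
        lights_on=float(meta["lights_on_s"]) if "lights_on_s" in meta else None,
    )


def write_annotations_csv(annotations: AnnotationSet, path) -> None:
    df = pd.DataFrame(
        annotations.intervals, columns=["start_s", "end_s", "kind"]
    )
    df.to_csv(path, index=False)


def read_annotations_csv(path) -> AnnotationSet:
    df = pd.read_csv(path)
    if df.empty:
        return AnnotationSet()
    return AnnotationSet(
        intervals=tuple(
            (float(r.start_s), float(r.end_s), str(r.kind)) for r in df.itertuples()
        )
    )


def write_eeg_csv(signal: np.ndarray, sampling_rate: float, path) -> None:
    """Single-column CSV; the header comment states the sampling rate."""
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={sampling_rate}\n")
        fh.write("eeg_uv\n")
        np.savetxt(fh, np.asarray(signal, dtype=float), fmt="%.6f")


def read_eeg(path, channel: str | None = None) -> tuple[np.ndarray, float]:
    """Read an EEG channel from CSV (our dialect) or EDF (via mne).

    Returns ``(signal_in_µV, sampling_rate_Hz)``.  For EDF, ``channel``
    names the channel label; mne's volt-scaled output is converted to µV.
    """
    path = str(path)
    if path.lower().endswith(".edf"):
        import mne  # optional dependency, only needed for EDF input

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        if channel is not None:
            raw.pick([channel])
        data = raw.get_data()[0] * 1e6
        return np.asarray(data, dtype=float), float(raw.info["sfreq"])
    with open(path) as fh:
        header = fh.readline()
        meta = dict(
            item.split("=") for item in header.lstrip("# ").split() if "=" in item
        )
        if "sampling_rate_hz" not in meta:
            raise ValueError(f"{path}: missing '# sampling_rate_hz=' header")
        df = pd.read_csv(fh)
    return df.iloc[:, 0].to_numpy(dtype=float), float(meta["sampling_rate_hz"])
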