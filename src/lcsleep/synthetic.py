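"""Synthetic ground-truth generators for every pipeline stage.

Each generator is a pure function of a spec dataclass and an integer
seed, and returns both the simulated data and a ground-truth record from
which the expected output of the downstream stage can be computed without
rerunning the generator:

- :func:`generate_lc_volume` — a pontine phantom with tubular hyperintense
  LC paths, a known contrast per side, and masks dilated around the
  centerline;
- :func:`generate_hypnogram` — a staged night with planted sleep onset,
  REM bouts, arousal events and artifact segments;
- :func:`generate_sleep_eeg` — band-limited Gaussian EEG whose per-stage
  band powers equal spec targets (filtered-white-noise synthesis gives
  analytically known powers), with x10-amplitude bursts on artifact spans;
- :func:`generate_cohort` — a two-group cohort with planted group-specific
  LC-activity slopes on the outcomes and a planted linear mediation
  structure (exposure -> sqrt-scale mediator -> outcome, optional
  exposure x mediator interaction); the mediator is stored squared so the
  square-root transform used in the mediation stage is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contrast import Volume3D
from .sleep import BANDS, STAGES, AnnotationSet, Hypnogram

__all__ = [
    "LCVolumeSpec",
    "HypnogramSpec",
    "StageSpectrumSpec",
    "CohortSpec",
    "generate_lc_volume",
    "generate_hypnogram",
    "generate_sleep_eeg",
    "generate_cohort",
]


# ---------------------------------------------------------------------------
# LC volume phantom


def _default_lc_paths(grid_shape: tuple[int, int, int]) -> dict[str, list]:
    """Two near-vertical centerlines in the dorsal half of the grid."""
    nz, ny, nx = grid_shape
    k0, k1 = nz // 4, 3 * nz // 4
    left, right = [], []
    for k in range(k0, k1):
        wobble = int(round(np.sin(k / 3.0)))
        left.append((k, ny // 3 + wobble, nx // 2 - nx // 8))
        right.append((k, ny // 3 + wobble, nx // 2 + nx // 8))
    return {"left": left, "right": right}


@dataclass(frozen=True)
class LCVolumeSpec:
    """Geometry and intensities of the LC phantom.

    ``lc_paths`` maps side -> ordered (slice, row, col) centerline voxels,
    at most one per axial slice per side; ``ref_center_per_slice`` places
    the in-plane reference-square center on each slice that has a
    centerline voxel.  Intensities are arbitrary units; the analytic
    contrast of the phantom is (lc_intensity - background) / background.
    """

    grid_shape: tuple[int, int, int] = (24, 48, 48)
    voxel_size: tuple[float, float, float] = (0.5, 0.4, 0.4)
    lc_paths: Mapping[str, Sequence[tuple[int, int, int]]] | None = None
    lc_intensity: float = 120.0
    background_intensity: float = 100.0
    noise_sd: float = 0.0
    mask_radius: int = 1
    ref_size: int = 15
    ref_center_per_slice: Mapping[int, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (np.isfinite(self.lc_intensity) and np.isfinite(self.background_intensity)):
            raise ValueError("intensities must be finite")
        paths = self.lc_paths
        if paths is None:
            paths = _default_lc_paths(self.grid_shape)
        paths = {s: [tuple(int(v) for v in p) for p in pts] for s, pts in paths.items()}
        for side, pts in paths.items():
            slices = [p[0] for p in pts]
            if len(slices) != len(set(slices)):
                raise ValueError(f"{side} path has more than one voxel on some slice")
            for k, r, c in pts:
                nz, ny, nx = self.grid_shape
                if not (0 <= k < nz and 0 <= r < ny and 0 <= c < nx):
                    raise ValueError(f"{side} path voxel {(k, r, c)} outside the grid")
        object.__setattr__(self, "lc_paths", paths)

        centers = self.ref_center_per_slice
        if centers is None:
            nz, ny, nx = self.grid_shape
            slices = sorted({p[0] for pts in paths.values() for p in pts})
            centers = {k: (2 * ny // 3, nx // 2) for k in slices}
        centers = {int(k): (int(v[0]), int(v[1])) for k, v in centers.items()}
        half = self.ref_size // 2
        _, ny, nx = self.grid_shape
        for k, (r, c) in centers.items():
            if r - half < 0 or c - half < 0 or r + half >= ny or c + half >= nx:
                raise ValueError(
                    f"reference square (edge {self.ref_size}) centered at "
                    f"({r}, {c}) exceeds the grid on slice {k}"
                )
        object.__setattr__(self, "ref_center_per_slice", centers)

    @property
    def analytic_contrast(self) -> float:
        return (self.lc_intensity - self.background_intensity) / self.background_intensity


def generate_lc_volume(
    spec: LCVolumeSpec, seed: int
) -> tuple[Volume3D, dict[str, np.ndarray], dict[str, float]]:
    """Build the phantom volume, per-side masks, and ground-truth contrasts.

    The masks are in-plane dilations (Chebyshev radius ``mask_radius``)
    of the centerline paths, so with small noise the centerline voxel is
    the in-mask maximum of its slice.  With ``noise_sd = 0`` the contrast
    computed downstream equals ``spec.analytic_contrast`` exactly on every
    slice and overall.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = spec.grid_shape
    vol = np.full(spec.grid_shape, spec.background_intensity, dtype=float)
    if spec.noise_sd > 0:
        vol += rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)

    masks: dict[str, np.ndarray] = {}
    truth: dict[str, float] = {}
    r = spec.mask_radius
    for side, pts in spec.lc_paths.items():
        mask = np.zeros(spec.grid_shape, dtype=bool)
        for k, row, col in pts:
            vol[k, row, col] = spec.lc_intensity
            if spec.noise_sd > 0:
                vol[k, row, col] += rng.normal(0.0, spec.noise_sd)
            mask[
                k,
                max(0, row - r): min(ny, row + r + 1),
                max(0, col - r): min(nx, col + r + 1),
            ] = True
        masks[side] = mask
        truth[side] = spec.analytic_contrast
    truth["bilateral"] = spec.analytic_contrast
    return Volume3D(data=vol, voxel_size=spec.voxel_size, axial_axis=0), masks, truth


# ---------------------------------------------------------------------------
# Hypnogram


@dataclass(frozen=True)
class HypnogramSpec:
    """Design of a synthetic night.

    ``stage_proportions`` must sum to 1; the wake fraction is spent
    partly as the sleep-onset prefix.  ``rem_bout_plan`` (epoch start,
    length) places REM explicitly; when ``None``, bouts are derived from
    the REM fraction as evenly spaced episodes in the post-onset night.
    ``arousal_rate`` is events per hour of time in bed and
    ``artifact_fraction`` the fraction of 4-s signal segments carrying an
    artifact.
    """

    time_in_bed_minutes: float = 480.0
    epoch_length: float = 30.0
    stage_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"W": 0.08, "N1": 0.07, "N2": 0.45, "N3": 0.20, "REM": 0.20}
    )
    sleep_onset_epoch: int = 20
    rem_bout_plan: Sequence[tuple[int, int]] | None = None
    arousal_rate_per_hour: float = 5.0
    artifact_fraction: float = 0.02

    def __post_init__(self) -> None:
        total = float(sum(self.stage_proportions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stage proportions sum to {total}, expected 1")
        bad = sorted(set(self.stage_proportions) - set(STAGES))
        if bad:
            raise ValueError(f"unknown stages in proportions: {bad}")
        n_sec = self.time_in_bed_minutes * 60.0
        if abs(n_sec / self.epoch_length - round(n_sec / self.epoch_length)) > 1e-9:
            raise ValueError(
                f"epoch_length {self.epoch_length}s does not divide time in bed "
                f"({self.time_in_bed_minutes} min)"
            )
        if self.sleep_onset_epoch >= self.n_epochs:
            raise ValueError("sleep_onset_epoch beyond the record")
        if self.rem_bout_plan is not None:
            bouts = sorted((int(s), int(l)) for s, l in self.rem_bout_plan)
            for (s0, l0), (s1, _l1) in zip(bouts, bouts[1:]):
                if s0 + l0 > s1:
                    raise ValueError("REM bouts overlap")
            object.__setattr__(self, "rem_bout_plan", tuple(bouts))

    @property
    def n_epochs(self) -> int:
        return int(round(self.time_in_bed_minutes * 60.0 / self.epoch_length))


def _plan_rem_bouts(spec: HypnogramSpec) -> list[tuple[int, int]]:
    n_rem = int(round(spec.stage_proportions.get("REM", 0.0) * spec.n_epochs))
    if n_rem == 0:
        return []
    n_bouts = max(1, min(4, n_rem // 10))
    base = n_rem // n_bouts
    lengths = [base + (1 if i < n_rem - base * n_bouts else 0) for i in range(n_bouts)]
    # place bouts evenly through the post-onset night, later-night weighted
    span = spec.n_epochs - spec.sleep_onset_epoch
    bouts = []
    for i, ln in enumerate(lengths):
        start = spec.sleep_onset_epoch + int(span * (0.25 + 0.7 * i / max(1, n_bouts)))
        start = min(start, spec.n_epochs - ln)
        bouts.append((start, ln))
    # resolve any overlap from clamping
    merged: list[tuple[int, int]] = []
    for s, ln in sorted(bouts):
        if merged and s < merged[-1][0] + merged[-1][1]:
            s = merged[-1][0] + merged[-1][1]
        merged.append((min(s, spec.n_epochs - ln), ln))
    return merged


def generate_hypnogram(
    spec: HypnogramSpec, seed: int
) -> tuple[Hypnogram, AnnotationSet]:
    """Simulate a staged night plus arousal/artifact annotations.

    Stage counts follow the spec proportions (largest-remainder
    rounding); the first ``sleep_onset_epoch`` epochs are wake, REM goes
    where the bout plan says, and the remaining stages fill the rest in
    shuffled runs, so realized proportions sit within ~2 percentage
    points of the spec.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_epochs
    props = {s: spec.stage_proportions.get(s, 0.0) for s in STAGES}
    raw = {s: props[s] * n for s in STAGES}
    counts = {s: int(np.floor(raw[s])) for s in STAGES}
    short = n - sum(counts.values())
    for s in sorted(STAGES, key=lambda s: raw[s] - counts[s], reverse=True)[:short]:
        counts[s] += 1

    stages = np.empty(n, dtype=object)
    stages[:] = None

    onset = min(spec.sleep_onset_epoch, counts["W"])
    stages[:onset] = "W"
    counts["W"] -= onset

    bouts = spec.rem_bout_plan
    if bouts is None:
        bouts = _plan_rem_bouts(spec)
    rem_left = counts["REM"]
    for start, length in bouts:
        take = min(length, rem_left)
        for e in range(start, min(start + take, n)):
            if stages[e] is None:
                stages[e] = "REM"
                rem_left -= 1
    counts["REM"] = 0

    # fill remaining slots with runs of the leftover stages, shuffled
    pool: list[tuple[str, int]] = []
    run_len = {"W": 2, "N1": 2, "N2": 8, "N3": 6, "REM": 6}
    for s in ("W", "N1", "N2", "N3", "REM"):
        c = counts[s] + (rem_left if s == "REM" else 0)
        while c > 0:
            take = min(run_len[s], c)
            pool.append((s, take))
            c -= take
    rng.shuffle(pool)
    free = [i for i in range(n) if stages[i] is None]
    pos = 0
    for s, take in pool:
        for _ in range(take):
            if pos >= len(free):
                break
            stages[free[pos]] = s
            pos += 1
    assert all(st is not None for st in stages)

    hyp = Hypnogram(
        stages=tuple(stages),
        epoch_length=spec.epoch_length,
        lights_off=0.0,
        lights_on=n * spec.epoch_length,
    )

    intervals: list[tuple[float, float, str]] = []
    hours = spec.time_in_bed_minutes / 60.0
    n_arousals = rng.poisson(spec.arousal_rate_per_hour * hours)
    record_end = n * spec.epoch_length
    for _ in range(n_arousals):
        start = rng.uniform(onset * spec.epoch_length, record_end - 15.0)
        intervals.append((float(start), float(start + rng.uniform(3.0, 15.0)), "arousal"))

    if spec.artifact_fraction > 0:
        n_slots = int(record_end // 4.0)
        n_bad = int(round(spec.artifact_fraction * n_slots))
        slots = rng.choice(n_slots, size=n_bad, replace=False)
        for sl in sorted(slots):
            intervals.append((float(sl * 4.0), float(sl * 4.0 + 4.0), "artifact"))

    intervals.sort()
    return hyp, AnnotationSet(intervals=tuple(intervals))


# ---------------------------------------------------------------------------
# Sleep EEG


@dataclass(frozen=True)
class StageSpectrumSpec:
    """Target band powers (µV²) per sleep stage.

    ``band_powers`` maps stage -> {band name -> power}; band edges come
    from :data:`lcsleep.sleep.BANDS`.  ``noise_sd`` adds broadband
    Gaussian noise on top of the shaped components.  Defaults give a
    delta-dominated N3, theta-visible REM, and quiet wake — placeholder
    levels in plausible µV² ranges, not calibrated to any cohort.
    """

    band_powers: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "W": {"delta": 10.0, "theta": 5.0, "alpha": 10.0},
            "N1": {"delta": 20.0, "theta": 10.0, "alpha": 5.0},
            "N2": {"delta": 60.0, "theta": 15.0, "sigma": 10.0},
            "N3": {"delta": 160.0, "theta": 20.0},
            "REM": {"delta": 15.0, "theta": 20.0},
        }
    )
    noise_sd: float = 1.0
    sampling_rate: float = 200.0
    artifact_gain: float = 10.0

    def __post_init__(self) -> None:
        for stage, bands in self.band_powers.items():
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            for band, p in bands.items():
                if band not in BANDS:
                    raise ValueError(f"unknown band {band!r}")
                if p < 0:
                    raise ValueError(f"negative power for ({stage}, {band})")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


def _shaped_stage_noise(
    rng: np.random.Generator,
    n_samples: int,
    band_powers: Mapping[str, float],
    sampling_rate: float,
) -> np.ndarray:
    """Gaussian noise whose variance inside each band equals the target.

    White noise is FFT-masked to each band and rescaled to the exact
    target variance, so Welch estimates recover the planted band powers
    up to estimator variance.
    """
    out = np.zeros(n_samples)
    if n_samples == 0:
        return out
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    for band, power in band_powers.items():
        if power <= 0:
            continue
        lo, hi = BANDS[band]
        mask = (freqs >= lo) & (freqs < hi)
        if not mask.any():
            continue
        spec = np.fft.rfft(rng.standard_normal(n_samples))
        spec[~mask] = 0.0
        comp = np.fft.irfft(spec, n=n_samples)
        sd = comp.std()
        if sd > 0:
            out += comp * (np.sqrt(power) / sd)
    return out


def generate_sleep_eeg(
    hypnogram: Hypnogram,
    spec: StageSpectrumSpec,
    seed: int,
    annotations: AnnotationSet | None = None,
) -> tuple[np.ndarray, dict[str, dict[str, float]]]:
    """Synthesize a single-channel EEG matching the hypnogram staging.

    Per stage, one long shaped-noise signal with the spec's exact band
    variances is generated and dealt into that stage's epochs, so the
    signal is stationary within stage.  Broadband noise (``noise_sd``) is
    added everywhere.  Samples inside artifact annotations are multiplied
    by ``artifact_gain`` (a x10 burst by default) — an unambiguous
    signature whose content is irrelevant because artifacts are excluded
    by annotation downstream.

    Returns ``(signal µV, ground-truth band powers per stage)``.
    """
    present = sorted(set(hypnogram.stages))
    missing = [s for s in present if s not in spec.band_powers]
    if missing:
        raise ValueError(f"stages present in hypnogram but absent from spec: {missing}")

    fs = spec.sampling_rate
    spe = int(round(hypnogram.epoch_length * fs))
    n_total = hypnogram.n_epochs * spe
    signal = np.zeros(n_total)
    rng = np.random.default_rng(seed)

    stage_arr = np.asarray(hypnogram.stages, dtype=object)
    for stage in present:
        idx = np.nonzero(stage_arr == stage)[0]
        shaped = _shaped_stage_noise(rng, idx.size * spe, spec.band_powers[stage], fs)
        for j, e in enumerate(idx):
            signal[e * spe:(e + 1) * spe] = shaped[j * spe:(j + 1) * spe]

    if spec.noise_sd > 0:
        signal += rng.normal(0.0, spec.noise_sd, size=n_total)

    if annotations is not None:
        for a0, a1, kind in annotations.intervals:
            if kind != "artifact":
                continue
            i0 = max(0, int(round(a0 * fs)))
            i1 = min(n_total, int(round(a1 * fs)))
            signal[i0:i1] *= spec.artifact_gain

    truth = {s: dict(spec.band_powers[s]) for s in present}
    return signal, truth


# ---------------------------------------------------------------------------
# Cohort


@dataclass(frozen=True)
class CohortSpec:
    """Generating model of the two-group cohort.

    Group sizes default to the study design this package emulates
    (33 younger, 19 older participants).  ``slope_young``/``slope_old``
    are the group-specific direct slopes of the subjective-sleep outcome
    (and, additively with ``a``, of the sqrt-scale mediator) on LC
    activity.  ``a``, ``b``, ``c_prime`` and ``gamma`` plant a linear
    mediation: mediator_sqrt = m0 + (a + slope_g)·X, outcome =
    p0 + (c_prime + slope_g)·X + b·Mc + gamma·X·Mc + covariates + noise,
    with Mc the centered sqrt-scale mediator.  The mediator column
    ``rem_theta_energy`` is stored on the squared scale so downstream
    square-root transforms are exercised.
    """

    n_young: int = 33
    n_old: int = 19
    slope_young: float = 0.0
    slope_old: float = 0.0
    beta_sex: float = 0.5
    beta_bmi: float = 0.1
    beta_tst: float = 0.01
    noise_sd: float = 1.0
    a: float = 0.0
    b: float = 0.0
    c_prime: float = 0.0
    gamma: float = 0.0
    mediator_intercept: float = 20.0
    mediator_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_young <= 0 or self.n_old <= 0:
            raise ValueError("group sizes must be positive")
        if self.noise_sd <= 0 or self.mediator_noise_sd <= 0:
            raise ValueError("noise standard deviations must be positive")


def generate_cohort(spec: CohortSpec, seed: int) -> tuple[pd.DataFrame, dict]:
    """Simulate the per-participant table plus its generating record.

    Columns: participant id, age_group (young/old), sex (F/M), bmi, tst,
    lc_activity, lc_contrast, psqi, and the night metrics (sol,
    sleep_efficiency, rem_percentage, swe, rem_theta_energy, rem_latency,
    rem_arousals, rem_episode_mean).  Outcomes without planted effects are
    covariate-plus-noise nulls.  The ground-truth record stores every
    generating coefficient.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_young + spec.n_old
    old = np.r_[np.zeros(spec.n_young), np.ones(spec.n_old)].astype(int)

    lc_activity = rng.normal(0.0, 1.0, n)
    sex_f = rng.random(n) < 0.75  # cohort is ~3/4 female
    bmi = rng.normal(23.0, 2.5, n)
    tst = rng.normal(420.0, 35.0, n) - 20.0 * old
    lc_contrast = rng.normal(0.18, 0.04, n) + 0.02 * old

    bmi_c = bmi - bmi.mean()
    tst_c = tst - tst.mean()
    slope = np.where(old == 1, spec.slope_old, spec.slope_young)

    # sqrt-scale mediator (REM theta energy), stored squared
    m_sqrt = (
        spec.mediator_intercept
        + (spec.a + slope) * lc_activity
        - 1.0 * old
        + spec.beta_tst * tst_c
        + rng.normal(0.0, spec.mediator_noise_sd, n)
    )
    m_c = m_sqrt - m_sqrt.mean()

    psqi = (
        5.0
        + (spec.c_prime + slope) * lc_activity
        + spec.b * m_c
        + spec.gamma * lc_activity * m_c
        + 0.8 * old
        + spec.beta_sex * sex_f
        + spec.beta_bmi * bmi_c
        + rng.normal(0.0, spec.noise_sd, n)
    )

    def null_outcome(loc: float, scale: float, old_shift: float = 0.0) -> np.ndarray:
        return (
            loc
            + old_shift * old
            + spec.beta_sex * scale * 0.1 * sex_f
            + rng.normal(0.0, scale, n)
        )

    df = pd.DataFrame(
        {
            "participant": [f"p{i:03d}" for i in range(n)],
            "age_group": np.where(old == 1, "old", "young"),
            "sex": np.where(sex_f, "F", "M"),
            "bmi": bmi,
            "tst": tst,
            "lc_activity": lc_activity,
            "lc_contrast": lc_contrast,
            "psqi": psqi,
            "sol": null_outcome(18.0, 6.0, old_shift=4.0),
            "sleep_efficiency": null_outcome(88.0, 4.0, old_shift=-4.0),
            "rem_percentage": null_outcome(20.0, 3.0, old_shift=-2.0),
            "swe": null_outcome(4000.0, 600.0, old_shift=-800.0),
            "rem_theta_energy": m_sqrt**2,
            "rem_latency": null_outcome(80.0, 20.0, old_shift=10.0),
            "rem_arousals": rng.poisson(6.0 + 2.0 * old).astype(float),
            "rem_episode_mean": null_outcome(18.0, 4.0),
        }
    )

    truth = {
        "n_young": spec.n_young,
        "n_old": spec.n_old,
        "slope_young": spec.slope_young,
        "slope_old": spec.slope_old,
        "interaction": spec.slope_old - spec.slope_young,
        "beta_sex": spec.beta_sex,
        "beta_bmi": spec.beta_bmi,
        "beta_tst": spec.beta_tst,
        "noise_sd": spec.noise_sd,
        "a": spec.a,
        "b": spec.b,
        "c_prime": spec.c_prime,
        "gamma": spec.gamma,
        "mediator_intercept": spec.mediator_intercept,
        "mediator_noise_sd": spec.mediator_noise_sd,
        "seed": seed,
    }
    return df, truth
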