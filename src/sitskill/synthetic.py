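"""Synthetic skill-stratified trajectories, videos and labelled datasets.

The generator emulates the structure of a suturing-skill cohort: three
self-proclaimed skill classes (novice / intermediate / expert), several
subjects per class, five trials per subject, sampled at 30 Hz. Class
differences enter through trial duration (novice 172.5 +/- 58.3 s,
intermediate 90.8 +/- 15.1 s, expert 83 +/- 13.3 s), path complexity
(via-point rate) and smoothness (tremor amplitude x jerk scale): novice
paths are the longest and most convoluted, expert paths the smoothest.

Each trajectory is a chain of minimum-jerk segments — the quintic
polynomial reach that minimizes integrated squared jerk, the standard model
of smooth point-to-point movement — between uniformly placed via-points,
plus band-limited Gaussian tremor. Rendered videos place a bright
anti-aliased disc on a static textured background with per-frame
photometric noise, giving pixel-exact ground truth for the tracker.

These profiles are synthetic stand-ins calibrated to the cohort's duration
statistics and qualitative smoothness ordering; they are not replicas of
any recorded surgical data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import signal

from .classifier import MTSSample
from .features import Trajectory, build_motion_series

__all__ = [
    "SkillProfile",
    "SceneSpec",
    "GroundTruth",
    "default_profiles",
    "overlapping_profiles",
    "minimum_jerk_position",
    "minimum_jerk_jerk",
    "sample_trajectory",
    "render_video",
    "write_frames",
    "generate_mts_dataset",
]

MIN_DURATION_S = 5.0


@dataclass(frozen=True)
class SkillProfile:
    """Generative parameters of one skill class."""

    label: int                  # 0 novice, 1 intermediate, 2 expert
    duration_mean: float        # s
    duration_sd: float          # s
    via_point_rate: float       # via-points per second (path complexity)
    tremor_amplitude: float     # px (sd of the band-limited tremor)
    tremor_bandwidth: float     # Hz (low-pass corner of the tremor)
    jerk_scale: float = 1.0     # dimensionless multiplier on the tremor
    subject_sd: float = 0.1     # sd of the multiplicative subject effect

    def __post_init__(self):
        if min(self.duration_mean, self.duration_sd, self.via_point_rate,
               self.tremor_bandwidth) <= 0 or self.tremor_amplitude < 0:
            raise ValueError("profile scales must be positive")


def default_profiles() -> dict[int, SkillProfile]:
    """Well-separated class profiles following the cohort durations."""
    return {
        0: SkillProfile(label=0, duration_mean=172.5, duration_sd=58.3,
                        via_point_rate=1.0, tremor_amplitude=3.0,
                        tremor_bandwidth=8.0, jerk_scale=2.0),
        1: SkillProfile(label=1, duration_mean=90.8, duration_sd=15.1,
                        via_point_rate=0.7, tremor_amplitude=1.5,
                        tremor_bandwidth=8.0, jerk_scale=1.4),
        2: SkillProfile(label=2, duration_mean=83.0, duration_sd=13.3,
                        via_point_rate=0.5, tremor_amplitude=0.8,
                        tremor_bandwidth=8.0, jerk_scale=1.0),
    }


def overlapping_profiles() -> dict[int, SkillProfile]:
    """Profiles with an ambiguous intermediate class.

    The intermediate smoothness parameters sit between — and, with the
    enlarged subject effect, overlap — the expert's, reproducing the
    intermediate/expert confusability that makes three-class separation
    harder than two-class (novice vs expert).
    """
    p = default_profiles()
    p[1] = replace(p[1], tremor_amplitude=0.95, jerk_scale=1.05,
                   subject_sd=0.3)
    p[2] = replace(p[2], subject_sd=0.3)
    return p


@dataclass(frozen=True)
class SceneSpec:
    """Rendering parameters for synthetic endoscope-like frames."""

    frame_size: tuple[int, int] = (120, 160)  # (height, width) px
    background_noise: float = 0.05            # sd of the static texture
    target_radius: float = 6.0                # px
    target_intensity: float = 0.9             # in [0, 1]
    photometric_noise: float = 0.02           # per-frame additive sd

    def __post_init__(self):
        h, w = self.frame_size
        if 2 * self.target_radius + 4 > min(h, w):
            raise ValueError("target larger than frame")


@dataclass
class GroundTruth:
    """Per-frame true target centers with generation provenance."""

    x: np.ndarray
    y: np.ndarray
    label: Optional[int]
    seed: int
    profile: Optional[SkillProfile] = None

    def __len__(self) -> int:
        return len(self.x)


def minimum_jerk_position(p0: np.ndarray, p1: np.ndarray, T: float,
                          t: np.ndarray) -> np.ndarray:
    """Quintic minimum-jerk reach from p0 to p1 over duration T.

    p(t) = p0 + (p1 - p0)(10 tau^3 - 15 tau^4 + 6 tau^5), tau = t/T; start
    and end have zero velocity and acceleration.
    """
    tau = np.clip(t / T, 0.0, 1.0)[:, None]
    s = 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5
    return p0 + (p1 - p0) * s


def minimum_jerk_jerk(p0: np.ndarray, p1: np.ndarray, T: float,
                      t: np.ndarray) -> np.ndarray:
    """Analytic third derivative of the minimum-jerk reach (closed form)."""
    tau = np.clip(t / T, 0.0, 1.0)[:, None]
    return (p1 - p0) * (60 - 360 * tau + 360 * tau ** 2) / T ** 3


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v >= lower:
            return float(v)
    return lower


def _band_limited_noise(rng: np.random.Generator, n: int, fps: float,
                        bandwidth: float) -> np.ndarray:
    """Unit-variance Gaussian noise low-passed to ``bandwidth`` Hz, (n, 2)."""
    white = rng.normal(size=(n, 2))
    wn = min(bandwidth / (fps / 2.0), 0.99)
    b, a = signal.butter(4, wn)
    filt = signal.filtfilt(b, a, white, axis=0)
    sd = filt.std(axis=0)
    return filt / np.where(sd < 1e-12, 1.0, sd)


def sample_trajectory(profile: SkillProfile, fps: float = 30.0,
                      seed: int = 0,
                      frame_size: tuple[int, int] = (480, 640),
                      margin: float = 40.0,
                      ) -> tuple[Trajectory, GroundTruth]:
    """Draw one trial trajectory for a skill profile.

    Duration is a truncated normal (>= 5 s); via-points are uniform inside
    the frame (with a margin) at ``via_point_rate`` per second; consecutive
    via-points are joined by minimum-jerk segments; band-limited tremor with
    sd ``tremor_amplitude * jerk_scale`` is added. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    h, w = frame_size
    duration = _truncated_normal(rng, profile.duration_mean,
                                 profile.duration_sd, MIN_DURATION_S)
    n = int(round(duration * fps)) + 1
    t = np.arange(n) / fps
    total_t = t[-1]

    n_via = max(1, int(rng.poisson(profile.via_point_rate * duration)))
    pts = np.column_stack([rng.uniform(margin, w - margin, n_via + 2),
                           rng.uniform(margin, h - margin, n_via + 2)])
    knots = np.linspace(0.0, total_t, n_via + 2)
    pos = np.empty((n, 2))
    for i in range(n_via + 1):
        lo, hi = knots[i], knots[i + 1]
        mask = (t >= lo) & (t <= hi) if i == n_via else (t >= lo) & (t < hi)
        pos[mask] = minimum_jerk_position(pts[i], pts[i + 1],
                                          hi - lo, t[mask] - lo)

    amp = profile.tremor_amplitude * profile.jerk_scale
    if amp > 0:
        pos = pos + amp * _band_limited_noise(rng, n, fps,
                                              profile.tremor_bandwidth)
    pos[:, 0] = np.clip(pos[:, 0], 0, w - 1)
    pos[:, 1] = np.clip(pos[:, 1], 0, h - 1)
    traj = Trajectory(t=t, x=pos[:, 0], y=pos[:, 1], fps=fps)
    gt = GroundTruth(x=pos[:, 0].copy(), y=pos[:, 1].copy(),
                     label=profile.label, seed=seed, profile=profile)
    return traj, gt


def render_video(traj: Trajectory, scene: SceneSpec = SceneSpec(),
                 seed: int = 0) -> tuple[np.ndarray, GroundTruth]:
    """Render a trajectory as grayscale frames with pixel ground truth.

    Frames are uint8 (n, height, width): a static seeded background texture,
    an anti-aliased bright disc at each true center, and per-frame Gaussian
    photometric noise. Centers outside the frame are clamped (and the
    clamping is visible in the returned ground truth).
    """
    rng = np.random.default_rng(seed)
    h, w = scene.frame_size
    r = scene.target_radius
    x = np.clip(traj.x, r, w - 1 - r)
    y = np.clip(traj.y, r, h - 1 - r)
    background = 0.25 + scene.background_noise * rng.normal(size=(h, w))
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    frames = np.empty((len(traj), h, w), dtype=np.uint8)
    for i in range(len(traj)):
        dist = np.hypot(rows - y[i], cols - x[i])
        disc = np.clip(r + 0.5 - dist, 0.0, 1.0)  # anti-aliased edge
        img = background + scene.target_intensity * disc
        if scene.photometric_noise > 0:
            img = img + scene.photometric_noise * rng.normal(size=(h, w))
        frames[i] = (np.clip(img, 0, 1) * 255).astype(np.uint8)
    gt = GroundTruth(x=x, y=y, label=getattr(traj, "label", None), seed=seed)
    return frames, gt


def write_frames(frames: np.ndarray, out_dir: str | Path) -> list[Path]:
    """Write frames as zero-padded PNGs (lossless, bit-exact round trip)."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, f in enumerate(frames):
        p = out / f"frame_{i:06d}.png"
        iio.imwrite(p, f)
        paths.append(p)
    return paths


def generate_mts_dataset(n_subjects_per_class: int = 2,
                         trials_per_subject: int = 5,
                         profiles: Optional[dict[int, SkillProfile]] = None,
                         fps: float = 30.0, seed: int = 0,
                         ) -> tuple[list[MTSSample], list[dict]]:
    """Generate a balanced labelled motion-series dataset plus its manifest.

    Every subject carries a lognormal multiplicative random effect on
    duration, path complexity and smoothness, so trials within a subject are
    correlated the way repeated performances are. The manifest lists
    subject, trial index (1..trials_per_subject), label and the trial seed,
    and is LOSO-ready.
    """
    if n_subjects_per_class < 1:
        raise ValueError("need at least one subject per class")
    profiles = profiles or default_profiles()
    master = np.random.SeedSequence(seed)
    samples: list[MTSSample] = []
    manifest: list[dict] = []
    subj_counter = 0
    for label in sorted(profiles):
        prof = profiles[label]
        for _ in range(n_subjects_per_class):
            subj_counter += 1
            subject_id = f"S{subj_counter:02d}"
            ss = master.spawn(1)[0]
            subj_rng = np.random.default_rng(ss)
            effect = np.exp(subj_rng.normal(0.0, prof.subject_sd, size=3))
            subj_prof = replace(
                prof,
                duration_mean=prof.duration_mean * effect[0],
                via_point_rate=prof.via_point_rate * effect[1],
                tremor_amplitude=prof.tremor_amplitude * effect[2])
            for trial in range(1, trials_per_subject + 1):
                trial_seed = int(subj_rng.integers(2 ** 31))
                traj, _ = sample_trajectory(subj_prof, fps=fps,
                                            seed=trial_seed)
                series = build_motion_series(traj, label=label)
                samples.append(MTSSample(series=series, label=label,
                                         subject_id=subject_id,
                                         trial_index=trial))
                manifest.append({"subject": subject_id, "trial": trial,
                                 "label": label, "seed": trial_seed,
                                 "n_samples": len(series),
                                 "duration_s": float(traj.t[-1])})
    return samples, manifest
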