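"""In vitro motility simulation and analysis.

Synthetic filament tracks emulate 10 frames/s, 30 s videos of fluorescent
native thin filaments: moving filaments advance along a persistent random
direction at a per-filament speed, stalled filaments only jitter, and every
centroid carries isotropic Gaussian localization noise. Analysis recovers
per-filament velocities, the moving fraction, the motility index (mean moving
velocity x fraction moving) and, across calcium levels, the Hill parameters
of the velocity-pCa relation

    V(pCa) = Vmax / (1 + 10^(n * (pCa - pCa50)))

with n > 0 so velocity falls as calcium is withdrawn (pCa rises). pCa50 is the
calcium sensitivity; n the cooperativity of thin-filament activation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FilamentTrack",
    "FilamentTrackSet",
    "MotilitySummary",
    "HillFitResult",
    "TrackSimParams",
    "simulate_tracks",
    "track_velocity",
    "classify_moving",
    "summarize",
    "hill_velocity",
    "fit_hill",
    "kruskal_wallis",
    "anova_tukey",
    "stationary_velocity_floor",
    "write_tracks",
    "read_tracks",
]

#: Default moving-filament criteria (velocity in um/s, straightness in [0, 1]).
VELOCITY_THRESHOLD = 0.25
STRAIGHTNESS_THRESHOLD = 0.5


@dataclass
class FilamentTrack:
    """Centroid time series of one filament (x, y in um per frame)."""

    filament_id: int
    frame_interval: float
    xy: np.ndarray  # shape (n_frames, 2)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2 or self.xy.shape[0] < 2:
            raise ValueError("track needs >= 2 frames of (x, y) centroids")
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")


@dataclass
class FilamentTrackSet:
    """All tracks at one condition x pCa, with generation metadata if synthetic."""

    condition: str
    pca: float
    tracks: list
    seed: int | None = None
    true_moving: np.ndarray | None = None  # ground-truth labels when synthetic

    def __post_init__(self) -> None:
        if not self.tracks:
            raise ValueError("track set must be non-empty")
        if not 3.0 <= self.pca <= 9.0:
            raise ValueError(f"pCa {self.pca} outside the physiological range [3, 9]")


@dataclass
class MotilitySummary:
    """Per-condition summary: velocity of movers, moving fraction, their product."""

    mean_velocity: float | None
    sem_velocity: float | None
    fraction_moving: float
    motility_index: float
    n_tracks: int
    n_moving: int


@dataclass
class HillFitResult:
    """Hill velocity-pCa fit: Vmax (um/s), pCa50, n, with standard errors."""

    vmax: float
    pca50: float
    n: float
    se_vmax: float
    se_pca50: float
    se_n: float
    rss: float
    converged: bool


@dataclass
class TrackSimParams:
    """Generator settings for one condition x pCa.

    Defaults mirror the acquisition design: 10 frames/s for 30 s. ``mean_speed``
    is the moving-filament speed in um/s, ``speed_cv`` the per-filament
    lognormal speed spread, ``noise_sd`` the per-coordinate localization noise
    in um per frame.
    """

    n_filaments: int = 50
    fraction_moving: float = 0.8
    mean_speed: float = 4.0
    speed_cv: float = 0.10
    noise_sd: float = 0.05
    n_frames: int = 300
    frame_interval: float = 0.1

    def validate(self) -> list[str]:
        v = []
        if self.n_filaments < 1:
            v.append("n_filaments must be >= 1")
        if not 0.0 <= self.fraction_moving <= 1.0:
            v.append("fraction_moving outside [0, 1]")
        if self.mean_speed < 0:
            v.append("mean_speed must be >= 0")
        if self.speed_cv < 0:
            v.append("speed_cv must be >= 0")
        if self.noise_sd < 0:
            v.append("noise_sd must be >= 0")
        if self.n_frames < 2:
            v.append("n_frames must be >= 2")
        if self.frame_interval <= 0:
            v.append("frame_interval must be > 0")
        return v


def simulate_tracks(params: TrackSimParams, seed: int,
                    condition: str = "control", pca: float = 4.0) -> FilamentTrackSet:
    """Generate labelled synthetic tracks for one condition x pCa."""
    violations = params.validate()
    if violations:
        raise ValueError("invalid track parameters: " + "; ".join(violations))
    rng = np.random.default_rng(seed)
    n = params.n_filaments
    moving = rng.random(n) < params.fraction_moving
    t = np.arange(params.n_frames)[:, None] * params.frame_interval

    tracks = []
    for i in range(n):
        origin = rng.uniform(0.0, 100.0, size=2)
        if moving[i]:
            if params.speed_cv > 0:
                sln = np.sqrt(np.log1p(params.speed_cv**2))
                speed = params.mean_speed * np.exp(rng.normal(-0.5 * sln**2, sln))
            else:
                speed = params.mean_speed
            theta = rng.uniform(0.0, 2.0 * np.pi)
            direction = np.array([np.cos(theta), np.sin(theta)])
            xy = origin + speed * t * direction
        else:
            xy = np.tile(origin, (params.n_frames, 1))
        if params.noise_sd > 0:
            xy = xy + rng.normal(0.0, params.noise_sd, size=(params.n_frames, 2))
        tracks.append(FilamentTrack(i, params.frame_interval, xy))
    return FilamentTrackSet(condition=condition, pca=pca, tracks=tracks,
                            seed=seed, true_moving=moving)


def track_velocity(track: FilamentTrack) -> float:
    """Mean frame-to-frame centroid displacement divided by the frame interval."""
    steps = np.diff(track.xy, axis=0)
    return float(np.mean(np.hypot(steps[:, 0], steps[:, 1])) / track.frame_interval)


def _straightness(track: FilamentTrack) -> float:
    steps = np.diff(track.xy, axis=0)
    path = float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))
    if path == 0.0:
        return 0.0
    net = float(np.hypot(*(track.xy[-1] - track.xy[0])))
    return net / path


def classify_moving(track: FilamentTrack,
                    velocity_threshold: float = VELOCITY_THRESHOLD,
                    straightness_threshold: float = STRAIGHTNESS_THRESHOLD) -> bool:
    """Moving iff velocity exceeds the floor AND the path is directionally persistent.

    Localization noise alone produces a nonzero apparent velocity on stalled
    filaments (see :func:`stationary_velocity_floor`), but their paths are
    random walks with near-zero net-displacement-to-path-length ratio, which
    the straightness criterion rejects.
    """
    if velocity_threshold < 0 or straightness_threshold < 0:
        raise ValueError("thresholds must be >= 0")
    return (track_velocity(track) > velocity_threshold
            and _straightness(track) >= straightness_threshold)


def stationary_velocity_floor(noise_sd: float, frame_interval: float) -> float:
    """Expected apparent speed of a stalled filament from localization noise.

    Frame-to-frame displacements of a static point with isotropic per-frame
    noise sigma are 2D Rayleigh with scale sigma*sqrt(2); their mean is
    sigma*sqrt(pi), so the apparent speed floor is sigma*sqrt(pi)/dt.
    """
    return noise_sd * np.sqrt(np.pi) / frame_interval


def summarize(trackset: FilamentTrackSet,
              velocity_threshold: float = VELOCITY_THRESHOLD,
              straightness_threshold: float = STRAIGHTNESS_THRESHOLD) -> MotilitySummary:
    """Mean +/- SEM velocity of moving filaments, fraction moving, motility index."""
    velocities = np.array([track_velocity(t) for t in trackset.tracks])
    labels = np.array([classify_moving(t, velocity_threshold, straightness_threshold)
                       for t in trackset.tracks])
    n = len(trackset.tracks)
    n_moving = int(labels.sum())
    fraction = n_moving / n
    if n_moving == 0:
        return MotilitySummary(None, None, 0.0, 0.0, n, 0)
    moving_v = velocities[labels]
    mean_v = float(moving_v.mean())
    sem_v = float(moving_v.std(ddof=1) / np.sqrt(n_moving)) if n_moving > 1 else 0.0
    return MotilitySummary(mean_v, sem_v, fraction, mean_v * fraction, n, n_moving)


def hill_velocity(pca, vmax: float, pca50: float, n: float):
    """Hill velocity-pCa curve, decreasing in pCa (velocity falls as Ca2+ drops)."""
    return vmax / (1.0 + 10.0 ** (n * (np.asarray(pca, dtype=float) - pca50)))


def fit_hill(pca, velocity, sem=None) -> HillFitResult:
    """Weighted nonlinear least-squares Hill fit of a velocity-pCa curve.

    Weights are 1/SEM^2 when SEMs are given. Initialization: Vmax0 = max V,
    pCa50_0 = pCa at half-max by linear interpolation, n0 = 2; bounds keep
    Vmax positive, n in (0, 20] and pCa50 within the data range +/- 1.
    Non-convergence is flagged on the result, never silent.
    """
    pca = np.asarray(pca, dtype=float)
    v = np.asarray(velocity, dtype=float)
    if pca.size < 4 or np.unique(pca).size < 4:
        raise ValueError("need >= 4 distinct pCa points to fit the Hill curve")
    if np.ptp(v) == 0.0:
        raise ValueError("degenerate data: all velocities are equal")

    order = np.argsort(pca)
    vmax0 = float(v.max())
    half = vmax0 / 2.0
    # pCa where the (decreasing) curve crosses half-max, by linear interpolation.
    pca50_0 = float(np.interp(-half, -v[order], pca[order]))
    p0 = [vmax0, pca50_0, 2.0]
    bounds = ([1e-9, pca.min() - 1.0, 1e-9], [10.0 * vmax0, pca.max() + 1.0, 20.0])
    sigma = np.asarray(sem, dtype=float) if sem is not None else None
    if sigma is not None and (sigma <= 0).any():
        sigma = None  # fall back to the unweighted fit

    converged = True
    try:
        popt, pcov = optimize.curve_fit(hill_velocity, pca, v, p0=p0, bounds=bounds,
                                        sigma=sigma, absolute_sigma=False, maxfev=10000)
        ses = np.sqrt(np.diag(pcov))
    except RuntimeError:
        warnings.warn("Hill fit did not converge; returning the initial guess flagged")
        popt, ses, converged = np.array(p0), np.full(3, np.nan), False
    rss = float(np.sum((v - hill_velocity(pca, *popt)) ** 2))
    return HillFitResult(vmax=float(popt[0]), pca50=float(popt[1]), n=float(popt[2]),
                         se_vmax=float(ses[0]), se_pca50=float(ses[1]), se_n=float(ses[2]),
                         rss=rss, converged=converged)


def write_tracks(tracksets: list, path) -> None:
    """Write track sets as TSV: condition, pCa, filament_id, frame, x_um, y_um.

    Header comment lines carry the frame interval and per-set seeds.
    """
    if not tracksets:
        raise ValueError("nothing to write")
    dt = float(tracksets[0].tracks[0].frame_interval)
    with open(path, "w") as fh:
        fh.write(f"# frame_interval_s={dt!r}\n")
        for ts in tracksets:
            if ts.seed is not None:
                fh.write(f"# seed {ts.condition} pCa={float(ts.pca)!r} = {ts.seed}\n")
        fh.write("condition\tpCa\tfilament_id\tframe\tx_um\ty_um\n")
        for ts in tracksets:
            for track in ts.tracks:
                for frame, (x, y) in enumerate(track.xy):
                    fh.write(f"{ts.condition}\t{float(ts.pca)!r}\t{track.filament_id}\t"
                             f"{frame}\t{float(x)!r}\t{float(y)!r}\n")


def read_tracks(path) -> list:
    """Read a track TSV back into FilamentTrackSet objects."""
    dt = None
    rows: dict = {}
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("frame_interval_s="):
                    dt = float(body.split("=", 1)[1])
                continue
            if not header_seen:
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 tab-separated fields")
            cond, pca_s, fid, frame, x, y = parts
            rows.setdefault((cond, float(pca_s)), {}).setdefault(int(fid), []).append(
                (int(frame), float(x), float(y)))
    if dt is None:
        raise ValueError(f"{path}: missing '# frame_interval_s=' header")
    sets = []
    for (cond, pca), filaments in rows.items():
        tracks = []
        for fid in sorted(filaments):
            pts = sorted(filaments[fid])
            tracks.append(FilamentTrack(fid, dt, np.array([(x, y) for _, x, y in pts])))
        sets.append(FilamentTrackSet(condition=cond, pca=pca, tracks=tracks))
    return sets


def kruskal_wallis(groups) -> tuple[float, float]:
    """Rank-based Kruskal-Wallis H (tie-corrected) with chi-square p, k-1 df."""
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 groups with >= 1 value each")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(flat) == 0.0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def anova_tukey(groups, labels=None) -> tuple[float, float, dict]:
    """One-way ANOVA F and p plus pairwise Tukey HSD p-values.

    Zero within-group variance follows the t-test convention: all means equal
    gives F = 0 and p-values of 1; differing means give p = 0 for the pairs
    that differ.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    arrays = [np.asarray(g, dtype=float) for g in groups]

    within = sum(a.var(ddof=1) for a in arrays)
    if within == 0.0:
        means = [a.mean() for a in arrays]
        pairwise = {}
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                pairwise[(labels[i], labels[j])] = 1.0 if means[i] == means[j] else 0.0
        all_equal = len(set(means)) == 1
        return (0.0, 1.0, pairwise) if all_equal else (float(np.inf), 0.0, pairwise)

    f, p = stats.f_oneway(*arrays)
    values = np.concatenate(arrays)
    group_labels = np.concatenate([[lab] * len(a) for lab, a in zip(labels, arrays)])
    tukey = pairwise_tukeyhsd(values, group_labels)
    pairwise = {}
    for row in tukey.summary().data[1:]:
        pairwise[(str(row[0]), str(row[1]))] = float(row[3])
    return float(f), float(p), pairwise
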