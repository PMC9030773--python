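"""Synthetic wayfinding-cohort generator.

Real recordings of pedestrians following routes with a wearable eye tracker
are privacy-restricted, so every downstream stage (segmentation, features,
recognition) is exercised on synthetic cohorts instead.  Each subject gets a
trait profile — the oculomotor and attentional parameters the biometric
features are meant to capture — and each route a scene composition and a
recording-duration law.  A recording is a renewal process of fixations and
saccades, with blinks overlaid as a Poisson process, per-fixation semantic
labels, and an optional 60 Hz raw-sample rendering.

A single ``heterogeneity`` knob in [0, 1] scales the between-subject spread
of every trait: at 0 all profiles are identical (so identification must sit
at chance downstream), at 1 the spread is the generator's stated default.

Distribution families (lognormal fixation durations, gamma saccade
amplitudes, von Mises directions, a power-law "main sequence" linking peak
velocity to amplitude) are standard oculomotor approximations; the defaults
below define the test bed, not a claim about any particular dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import (
    SEMANTIC_CLASSES,
    Blink,
    Fixation,
    FixationSemanticLabel,
    Recording,
    RoutePixelStats,
    Saccade,
    SceneGeometry,
)

# Population-level trait means.  Subject traits are these values perturbed by
# heterogeneity-scaled lognormal/normal factors in sample_profiles.
_BASE = dict(
    mu_fd=math.log(0.28),   # log-mean fixation duration (s)
    sigma_fd=0.45,          # log-sd fixation duration
    shape_amp=2.0,          # gamma shape, saccade amplitude
    scale_amp=45.0,         # gamma scale (px); mean amplitude = 90 px
    mu_dir=0.0,             # von Mises mean direction (rad)
    kappa_dir=0.5,          # von Mises concentration
    blink_rate=12.0,        # blinks per minute
    pupil_baseline=3.5,     # mm
    pupil_drift=0.25,       # slow-drift amplitude (mm)
    sigma_b=220.0,          # spatial-bias Gaussian sd (px)
    map_rate=2.0,           # map glances per minute
    main_seq_c=250.0,       # peak_velocity = c * amplitude**0.6  (px/s)
    peak_mean_ratio=1.7,    # peak/mean velocity ratio of the saccade profile
)

#: Recording-duration law shared by all routes: truncated normal, seconds.
DURATION_MEAN = 418.58
DURATION_SD = 102.02
DURATION_BOUNDS = (87.0, 733.0)

#: Mean/SD of the tracking-ratio draw when raw samples are not rendered.
TRACKING_RATIO_MEAN = 0.9337
TRACKING_RATIO_SD = 0.0499

# Dirichlet pseudo-counts for route scene composition over the 19 street
# classes (road/building/vegetation/sky dominate a pedestrian's scene camera).
_AVAILABILITY_ALPHA = {
    "road": 8.0, "sidewalk": 4.0, "building": 8.0, "wall": 0.5, "fence": 0.5,
    "pole": 1.0, "traffic light": 0.3, "traffic sign": 0.5, "vegetation": 6.0,
    "terrain": 1.0, "sky": 6.0, "person": 2.0, "rider": 0.3, "car": 4.0,
    "truck": 0.5, "bus": 0.5, "train": 0.1, "motorcycle": 0.3, "bicycle": 0.5,
}

_NON_MAP_CLASSES = tuple(c for c in SEMANTIC_CLASSES if c != "map")


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject oculomotor and semantic-attention trait parameters."""

    subject_id: str
    mu_fd: float
    sigma_fd: float
    shape_amp: float
    scale_amp: float
    mu_dir: float
    kappa_dir: float
    blink_rate: float
    pupil_baseline: float
    pupil_drift: float
    bx: float
    by: float
    sigma_b: float
    semantic_preference: tuple[float, ...]  # 20-simplex, SEMANTIC_CLASSES order
    map_rate: float
    main_seq_c: float
    peak_mean_ratio: float

    def __post_init__(self) -> None:
        for name in ("sigma_fd", "shape_amp", "scale_amp", "kappa_dir",
                     "blink_rate", "pupil_baseline", "sigma_b", "main_seq_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not math.isclose(sum(self.semantic_preference), 1.0, abs_tol=1e-9):
            raise ValueError("semantic preference must sum to 1")


@dataclass(frozen=True)
class RouteSpec:
    """Scene composition and duration law of one route."""

    route_id: str
    availability: tuple[float, ...]  # 20-simplex, SEMANTIC_CLASSES order
    duration_mean: float = DURATION_MEAN
    duration_sd: float = DURATION_SD
    duration_bounds: tuple[float, float] = DURATION_BOUNDS

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.availability), 1.0, abs_tol=1e-9):
            raise ValueError("availability must sum to 1")


@dataclass
class Cohort:
    """One recording per subject x route, with labels and pixel stats."""

    recordings: list[Recording]
    labels: dict[tuple[str, str], list[FixationSemanticLabel]]
    pixel_stats: dict[tuple[str, str], RoutePixelStats]
    profiles: list[SubjectProfile] = field(default_factory=list)
    routes: list[RouteSpec] = field(default_factory=list)


def sample_profiles(
    n_subjects: int, heterogeneity: float = 1.0, seed: int = 0
) -> list[SubjectProfile]:
    """Draw subject trait profiles; ``heterogeneity`` scales the spread.

    At heterogeneity 0 every profile carries the population-mean parameters
    (only the ids differ); the draw is deterministic in the seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    h = float(heterogeneity)
    rng = np.random.default_rng(seed)
    geom = SceneGeometry()
    profiles = []
    for i in range(n_subjects):
        ln = lambda sd: math.exp(h * rng.normal(0.0, sd))  # noqa: E731
        pref_logits = h * rng.normal(0.0, 0.8, size=len(SEMANTIC_CLASSES))
        pref = np.exp(pref_logits)
        pref /= pref.sum()
        profiles.append(SubjectProfile(
            subject_id=f"S{i + 1:02d}",
            mu_fd=_BASE["mu_fd"] + h * rng.normal(0.0, 0.25),
            sigma_fd=_BASE["sigma_fd"] * ln(0.15),
            shape_amp=_BASE["shape_amp"] * ln(0.25),
            scale_amp=_BASE["scale_amp"] * ln(0.30),
            mu_dir=h * rng.normal(0.0, 0.5),
            kappa_dir=_BASE["kappa_dir"] * ln(0.5),
            blink_rate=_BASE["blink_rate"] * ln(0.4),
            pupil_baseline=float(np.clip(
                _BASE["pupil_baseline"] + h * rng.normal(0.0, 0.5), 2.0, 6.0)),
            pupil_drift=_BASE["pupil_drift"] * ln(0.3),
            bx=geom.width_px / 2 + h * rng.normal(0.0, 80.0),
            by=geom.height_px / 2 + h * rng.normal(0.0, 60.0),
            sigma_b=_BASE["sigma_b"] * ln(0.2),
            semantic_preference=tuple(pref),
            map_rate=_BASE["map_rate"] * ln(0.5),
            main_seq_c=_BASE["main_seq_c"] * ln(0.15),
            peak_mean_ratio=_BASE["peak_mean_ratio"] * ln(0.08),
        ))
    return profiles


def sample_routes(n_routes: int, seed: int = 0) -> list[RouteSpec]:
    """Draw route scene compositions ('map' availability is 0: map fixations
    come from explicit glances, not from the street scene)."""
    rng = np.random.default_rng(seed)
    alpha = np.array([_AVAILABILITY_ALPHA[c] for c in _NON_MAP_CLASSES])
    routes = []
    for j in range(n_routes):
        avail19 = rng.dirichlet(alpha)
        avail = dict(zip(_NON_MAP_CLASSES, avail19))
        avail["map"] = 0.0
        routes.append(RouteSpec(
            route_id=f"R{j + 1}",
            availability=tuple(avail[c] for c in SEMANTIC_CLASSES),
        ))
    return routes


def _draw_duration(route: RouteSpec, rng: np.random.Generator) -> float:
    lo, hi = route.duration_bounds
    a = (lo - route.duration_mean) / route.duration_sd
    b = (hi - route.duration_mean) / route.duration_sd
    return float(stats.truncnorm.rvs(
        a, b, loc=route.duration_mean, scale=route.duration_sd,
        random_state=rng))


def simulate_recording(
    profile: SubjectProfile,
    route: RouteSpec,
    seed: int = 0,
    *,
    geometry: SceneGeometry | None = None,
    with_samples: bool = False,
    reanchor_prob: float = 0.2,
    duration: float | None = None,
) -> tuple[Recording, list[FixationSemanticLabel], RoutePixelStats]:
    """Simulate one recording of ``profile`` walking ``route``.

    The gaze path is a mixture walk: most saccades are relative displacements
    (gamma amplitude, von Mises direction), a fraction ``reanchor_prob``
    re-centers on the subject's spatial-bias Gaussian, and map glances jump
    to a lower-central frame region.  Stored saccade amplitude/direction are
    always recomputed from the actual consecutive centroids, so events and
    scanpath are mutually consistent.
    """
    geometry = geometry or SceneGeometry()
    rng = np.random.default_rng(seed)
    W, H = geometry.width_px, geometry.height_px
    if duration is None:
        duration = _draw_duration(route, rng)

    # pupil trace: baseline + slow sinusoidal drift + noise (added per event)
    drift_period = 90.0
    drift_phase = rng.uniform(0.0, 2 * math.pi)

    def pupil(t: float) -> float:
        return (profile.pupil_baseline
                + profile.pupil_drift
                * math.sin(2 * math.pi * t / drift_period + drift_phase)
                + rng.normal(0.0, 0.03))

    avail = np.asarray(route.availability)
    pref = np.asarray(profile.semantic_preference)
    w = avail * pref
    w_nonmap = np.array([w[SEMANTIC_CLASSES.index(c)] for c in _NON_MAP_CLASSES])
    if w_nonmap.sum() <= 0:
        raise ValueError("route availability x subject preference is all zero")
    w_nonmap = w_nonmap / w_nonmap.sum()

    # per-fixation probability of a map glance, matched to the per-minute rate
    mean_fd = math.exp(profile.mu_fd + profile.sigma_fd**2 / 2)
    mean_amp = profile.shape_amp * profile.scale_amp
    mean_sacc = mean_amp / (profile.main_seq_c * mean_amp**0.6
                            / profile.peak_mean_ratio)
    p_map = min(1.0, profile.map_rate * (mean_fd + mean_sacc) / 60.0)

    def clip_frame(p: np.ndarray) -> np.ndarray:
        return np.clip(p, [0.0, 0.0], [W, H])

    fixations: list[Fixation] = []
    saccades: list[Saccade] = []
    labels: list[FixationSemanticLabel] = []
    current = clip_frame(rng.normal([profile.bx, profile.by], profile.sigma_b))
    next_is_map = False
    t = 0.0
    prev_sacc_offset = math.nan
    while True:
        fd = float(rng.lognormal(profile.mu_fd, profile.sigma_fd))
        if t + fd > duration:
            break
        idx = len(fixations)
        fixations.append(Fixation(
            onset=t, offset=t + fd, cx=float(current[0]), cy=float(current[1]),
            dispersion=float(abs(rng.normal(12.0, 4.0))) + 1e-6,
            mean_pupil=pupil(t + fd / 2),
        ))
        if next_is_map:
            labels.append(FixationSemanticLabel(idx, "map"))
        else:
            cls = _NON_MAP_CLASSES[rng.choice(len(_NON_MAP_CLASSES), p=w_nonmap)]
            labels.append(FixationSemanticLabel(idx, cls))
        t += fd

        amp = float(rng.gamma(profile.shape_amp, profile.scale_amp))
        drawn_dir = float(rng.vonmises(profile.mu_dir, profile.kappa_dir))
        peak_v = profile.main_seq_c * max(amp, 1e-9) ** 0.6
        sacc_dur = float(np.clip(amp / (peak_v / profile.peak_mean_ratio),
                                 0.015, 0.150))
        if t + sacc_dur > duration:
            break

        next_is_map = rng.random() < p_map
        if next_is_map:
            target = np.array([rng.uniform(0.35 * W, 0.65 * W),
                               rng.uniform(0.78 * H, 0.95 * H)])
        elif rng.random() < reanchor_prob:
            target = clip_frame(
                rng.normal([profile.bx, profile.by], profile.sigma_b))
        else:
            step = amp * np.array([math.cos(drawn_dir), -math.sin(drawn_dir)])
            target = clip_frame(current + step)
        disp = target - current
        actual_amp = float(np.hypot(*disp))
        # sub-pixel displacement (e.g. clipped at the frame edge) has no
        # meaningful geometric direction; keep the drawn one
        if actual_amp > 1.0:
            actual_dir = math.atan2(-disp[1], disp[0])
        else:
            actual_dir = drawn_dir
        mean_v = actual_amp / sacc_dur
        peak_v = max(profile.main_seq_c * actual_amp ** 0.6, mean_v)
        peak_acc = 2 * peak_v / sacc_dur * rng.uniform(0.9, 1.1)
        saccades.append(Saccade(
            onset=t, offset=t + sacc_dur,
            amplitude=actual_amp, direction=actual_dir,
            mean_velocity=mean_v, peak_velocity=peak_v,
            mean_acceleration=0.5 * peak_acc * rng.uniform(0.9, 1.1),
            peak_acceleration=peak_acc,
            peak_deceleration=2 * peak_v / sacc_dur * rng.uniform(0.9, 1.1),
            latency=t - prev_sacc_offset,
        ))
        prev_sacc_offset = t + sacc_dur
        t += sacc_dur
        current = target

    # blinks: homogeneous Poisson process, lognormal durations, merged
    n_blinks = rng.poisson(profile.blink_rate * duration / 60.0)
    onsets = np.sort(rng.uniform(0.0, duration, size=n_blinks))
    blinks: list[Blink] = []
    for onset in onsets:
        bd = float(rng.lognormal(math.log(0.18), 0.25))
        offset = min(onset + bd, duration)
        if offset <= onset:
            continue
        if blinks and onset < blinks[-1].offset:
            blinks[-1] = Blink(blinks[-1].onset, max(blinks[-1].offset, offset))
        else:
            blinks.append(Blink(float(onset), offset))

    samples = None
    if with_samples:
        samples = _render_samples(fixations, saccades, blinks, duration,
                                  geometry, pupil, rng)
        tracking_ratio = float(samples["valid"].mean())
    else:
        tracking_ratio = float(np.clip(
            rng.normal(TRACKING_RATIO_MEAN, TRACKING_RATIO_SD), 0.0, 1.0))

    recording = Recording(
        subject_id=profile.subject_id, route_id=route.route_id,
        geometry=geometry, fixations=fixations, saccades=saccades,
        blinks=blinks, samples=samples, tracking_ratio=tracking_ratio,
        duration=duration,
    )

    total_px = float(W * H)
    n_pixel = {}
    for c, a in zip(SEMANTIC_CLASSES, route.availability):
        if c == "map":
            n_pixel[c] = 0.02 * total_px * float(rng.lognormal(0.0, 0.1))
        else:
            n_pixel[c] = 0.98 * total_px * a * float(rng.lognormal(0.0, 0.1))
    return recording, labels, RoutePixelStats(n_pixel)


def _render_samples(fixations, saccades, blinks, duration, geometry,
                    pupil, rng):
    """Render a 60 Hz raw-sample table consistent with the event stream."""
    import pandas as pd

    dt = 1.0 / geometry.sampling_rate_hz
    ts = np.arange(0.0, duration, dt)
    x = np.empty_like(ts)
    y = np.empty_like(ts)
    # piecewise: hold centroid (plus jitter) in fixations, linear ramp in
    # saccades, hold last position elsewhere
    cx = fixations[0].cx if fixations else geometry.width_px / 2
    cy = fixations[0].cy if fixations else geometry.height_px / 2
    events = sorted(
        [("f", f) for f in fixations] + [("s", s) for s in saccades],
        key=lambda kv: kv[1].onset,
    )
    x[:], y[:] = cx, cy
    for kind, ev in events:
        m = (ts >= ev.onset) & (ts < ev.offset)
        if kind == "f":
            x[m] = ev.cx + rng.normal(0.0, 2.0, size=m.sum())
            y[m] = ev.cy + rng.normal(0.0, 2.0, size=m.sum())
            cx, cy = ev.cx, ev.cy
        else:
            frac = (ts[m] - ev.onset) / max(ev.duration, 1e-9)
            dx = ev.amplitude * math.cos(ev.direction)
            dy = -ev.amplitude * math.sin(ev.direction)
            x[m] = cx + frac * dx
            y[m] = cy + frac * dy
        after = ts >= ev.offset
        if kind == "f":
            x[after], y[after] = ev.cx, ev.cy
    valid = np.ones(ts.shape, dtype=bool)
    for b in blinks:
        valid &= ~((ts >= b.onset) & (ts < b.offset))
    pupils = np.array([pupil(t) for t in ts])
    return pd.DataFrame({
        "t": ts,
        "x": np.clip(x, 0, geometry.width_px),
        "y": np.clip(y, 0, geometry.height_px),
        "pupil_l": pupils + rng.normal(0.0, 0.02, size=ts.shape),
        "pupil_r": pupils + rng.normal(0.0, 0.02, size=ts.shape),
        "valid": valid,
    })


def simulate_cohort(
    n_subjects: int = 39,
    n_routes: int = 4,
    heterogeneity: float = 1.0,
    seed: int = 0,
    *,
    with_samples: bool = False,
    duration: float | None = None,
) -> Cohort:
    """One recording per subject x route; fully reproducible given the seed."""
    ss = np.random.SeedSequence(seed)
    profile_seed, route_seed, rec_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    profiles = sample_profiles(n_subjects, heterogeneity, profile_seed)
    routes = sample_routes(n_routes, route_seed)
    rec_ss = np.random.SeedSequence(rec_seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31))
                   for s in rec_ss.spawn(n_subjects * n_routes)]
    recordings, labels, pixel_stats = [], {}, {}
    k = 0
    for profile in profiles:
        for route in routes:
            rec, lab, px = simulate_recording(
                profile, route, child_seeds[k],
                with_samples=with_samples, duration=duration)
            recordings.append(rec)
            labels[(profile.subject_id, route.route_id)] = lab
            pixel_stats[(profile.subject_id, route.route_id)] = px
            k += 1
    return Cohort(recordings, labels, pixel_stats, profiles, routes)


__all__ = [
    "SubjectProfile", "RouteSpec", "Cohort",
    "sample_profiles", "sample_routes",
    "simulate_recording", "simulate_cohort",
    "DURATION_MEAN", "DURATION_SD", "DURATION_BOUNDS",
]
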