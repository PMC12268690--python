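"""From gridded height data to step positions, traces and velocities.

The stage emulates the AFM analysis workflow: sample a height profile along
a line, detect step risers as jumps between terrace plateaus, classify them
against the admissible (200) step-height classes (full and half a-axis),
follow one step across frames relative to a fixed reference point, and fit
the step velocity as the slope of displacement vs time.  A seeded
permutation test checks the velocity-independence claims (same v across
step-height classes and inter-step distances — the signature of direct
incorporation from solution).

Pixel coordinates are 0-based, row-major, row 0 at the top of the frame;
profile positions are physical nanometers.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import linregress

from .errors import ConfigError, DomainError, InsufficientDataError, TrackingError

__all__ = [
    "HeightMapSeries",
    "HeightProfile",
    "StepTrace",
    "VelocityEstimate",
    "DetectedStep",
    "extract_profile",
    "detect_steps",
    "track_step",
    "fit_velocity",
    "velocity_independence_test",
]


@dataclass(frozen=True)
class HeightMapSeries:
    """Time-ordered height frames on a shared uniform pixel lattice."""

    frames: tuple[np.ndarray, ...]  # each (rows, cols), heights in nm
    pixel_size: float  # nm per pixel
    timestamps: tuple[float, ...]  # s, strictly increasing
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise DomainError("series has no frames")
        shape = self.frames[0].shape
        if any(f.shape != shape for f in self.frames):
            raise DomainError("all frames must share one shape")
        if len(self.timestamps) != len(self.frames):
            raise DomainError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps) <= 0):
            raise DomainError("timestamps must be strictly increasing")
        if self.pixel_size <= 0:
            raise DomainError("pixel_size must be > 0")


@dataclass(frozen=True)
class HeightProfile:
    """Heights sampled along a line, positions in nm (strictly increasing)."""

    positions: np.ndarray  # nm
    heights: np.ndarray  # nm

    def __post_init__(self) -> None:
        if self.positions.shape != self.heights.shape:
            raise DomainError("positions/heights shape mismatch")
        if np.any(np.diff(self.positions) <= 0):
            raise DomainError("positions must be strictly increasing")


@dataclass(frozen=True)
class StepTrace:
    """Displacement of one step relative to its position at t0."""

    times: np.ndarray  # s
    displacements: np.ndarray  # nm, positive toward the reference point
    step_height_class: str = "full"
    direction_label: str = ""

    def __post_init__(self) -> None:
        if self.times.shape != self.displacements.shape:
            raise DomainError("times/displacements shape mismatch")
        if self.times.size < 2:
            raise DomainError("a trace needs >= 2 samples")


@dataclass(frozen=True)
class VelocityEstimate:
    """OLS slope of displacement vs time with its standard error."""

    velocity: float  # nm/s
    sd: float  # nm/s (standard error of the slope)
    n_points: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise DomainError("sd must be >= 0")


@dataclass(frozen=True)
class DetectedStep:
    position: float  # nm, riser midpoint along the profile
    height: float  # nm, signed terrace difference (downhill negative)
    height_class: str  # "full" | "half" | "unclassified"


def extract_profile(
    frame: np.ndarray,
    start: tuple[float, float],
    end: tuple[float, float],
    pixel_size: float,
    spacing_px: float = 1.0,
) -> HeightProfile:
    """Bilinear height profile between two pixel-coordinate endpoints.

    ``start``/``end`` are (row, col) in pixels and must lie inside the
    frame; sampling spacing is at most one pixel.
    """
    rows, cols = frame.shape
    for name, (r, c) in (("start", start), ("end", end)):
        if not (0 <= r <= rows - 1 and 0 <= c <= cols - 1):
            raise DomainError(f"{name} point {r, c} outside the {rows}x{cols} frame")
    if not 0 < spacing_px <= 1.0:
        raise ConfigError("spacing_px must be in (0, 1]")
    length_px = math.hypot(end[0] - start[0], end[1] - start[1])
    n = max(int(math.ceil(length_px / spacing_px)) + 1, 2)
    t = np.linspace(0.0, 1.0, n)
    rr = start[0] + t * (end[0] - start[0])
    cc = start[1] + t * (end[1] - start[1])
    heights = ndimage.map_coordinates(frame, np.vstack([rr, cc]), order=1, mode="nearest")
    positions = t * length_px * pixel_size
    return HeightProfile(positions=positions, heights=heights)


def _segment_terraces(heights: np.ndarray, tol: float) -> list[tuple[int, int]]:
    """Greedy piecewise-constant segmentation; returns [start, end) spans.

    A sample opens a new terrace when it departs from the running terrace
    mean by more than ``tol`` (earliest-position tie-break).
    """
    segments: list[tuple[int, int]] = []
    start = 0
    mean = heights[0]
    count = 1
    for i in range(1, heights.size):
        if abs(heights[i] - mean) <= tol:
            count += 1
            mean += (heights[i] - mean) / count
        else:
            segments.append((start, i))
            start = i
            mean = heights[i]
            count = 1
    segments.append((start, heights.size))
    return segments


def detect_steps(
    profile: HeightProfile,
    unit_height: float,
    tol: float,
    min_terrace_samples: int = 2,
) -> list[DetectedStep]:
    """Find risers between terrace plateaus and classify their heights.

    A riser within ``tol`` of ``unit_height`` is "full", within ``tol`` of
    ``unit_height/2`` is "half", anything else above ``tol`` is
    "unclassified".  ``tol`` must stay below ``unit_height/4`` so the two
    classes cannot overlap.
    """
    if unit_height <= 0:
        raise DomainError("unit_height must be > 0")
    if not 0 < tol < unit_height / 4:
        raise ConfigError(f"tol must be in (0, unit_height/4 = {unit_height / 4:.4g})")
    heights = np.asarray(profile.heights, dtype=float)
    segments = [s for s in _segment_terraces(heights, tol) if s[1] - s[0] >= min_terrace_samples]
    detections: list[DetectedStep] = []
    for (a0, a1), (b0, b1) in zip(segments[:-1], segments[1:]):
        h_a = float(np.median(heights[a0:a1]))
        h_b = float(np.median(heights[b0:b1]))
        dh = h_b - h_a
        if abs(dh) <= tol:
            continue
        pos = 0.5 * (profile.positions[a1 - 1] + profile.positions[b0])
        if abs(abs(dh) - unit_height) <= tol:
            cls = "full"
        elif abs(abs(dh) - unit_height / 2.0) <= tol:
            cls = "half"
        else:
            cls = "unclassified"
        detections.append(DetectedStep(position=float(pos), height=dh, height_class=cls))
    return detections


def track_step(
    series: HeightMapSeries,
    line: tuple[tuple[float, float], tuple[float, float]],
    unit_height: float,
    tol: float,
    reference_point_nm: float,
    initial_position_nm: float | None = None,
    gate_nm: float = 50.0,
    step_height_class: str = "full",
    direction_label: str = "",
) -> StepTrace:
    """Follow one step riser along a fixed profile line across frames.

    Per frame the riser nearest the previous position (within ``gate_nm``)
    is taken; losing the step, or finding two candidates inside the gate,
    raises :class:`TrackingError` with the frame index.  Displacements are
    measured positive toward ``reference_point_nm`` (growth advances the
    step toward the reference feature; dissolution gives negative values).
    """
    start, end = line
    positions = []
    prev = initial_position_nm
    for k, frame in enumerate(series.frames):
        profile = extract_profile(frame, start, end, series.pixel_size)
        detections = detect_steps(profile, unit_height, tol)
        if prev is None:
            if not detections:
                raise TrackingError(f"no step detected in frame 0 along the tracking line")
            candidates = detections
        else:
            candidates = [d for d in detections if abs(d.position - prev) <= gate_nm]
        if not candidates:
            raise TrackingError(f"step lost at frame {k}: no detection within the gate")
        if prev is not None and len(candidates) > 1:
            raise TrackingError(
                f"tracking ambiguous at frame {k}: {len(candidates)} steps inside the gate"
            )
        chosen = min(candidates, key=lambda d: abs(d.position - (prev if prev is not None else d.position)))
        positions.append(chosen.position)
        prev = chosen.position
    pos = np.array(positions)
    toward_ref = math.copysign(1.0, reference_point_nm - pos[0])
    displacements = (pos - pos[0]) * toward_ref
    return StepTrace(
        times=np.array(series.timestamps, dtype=float),
        displacements=displacements,
        step_height_class=step_height_class,
        direction_label=direction_label,
    )


def fit_velocity(trace: StepTrace) -> VelocityEstimate:
    """Step velocity as the OLS slope of displacement vs time."""
    t = np.asarray(trace.times, dtype=float)
    d = np.asarray(trace.displacements, dtype=float)
    if t.size < 3:
        raise InsufficientDataError(f"need >= 3 points for a velocity fit, got {t.size}")
    if np.ptp(t) == 0:
        raise DomainError("zero time span")
    res = linregress(t, d)
    sd = 0.0 if math.isnan(res.stderr) else float(res.stderr)
    r2 = float(res.rvalue**2) if not math.isnan(res.rvalue) else 1.0
    return VelocityEstimate(velocity=float(res.slope), sd=sd, n_points=int(t.size), r_squared=r2)


def velocity_independence_test(
    groups: dict[str, Sequence[float | VelocityEstimate]],
    n_permutations: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Permutation test of equal group-mean velocities.

    ``groups`` maps a label (step-height class or an inter-step-distance
    bin) to velocity estimates.  The statistic is the between-group sum of
    squares of the group means; the p-value is the fraction of seeded label
    permutations with a statistic at least as large.  A p-value above
    ``alpha`` is reported as "consistent with direct incorporation" — the
    supply field is three-dimensional and the step velocity does not care
    how the steps are arranged.
    """
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 groups")
    values: list[float] = []
    labels: list[int] = []
    for gi, (name, vs) in enumerate(groups.items()):
        if len(vs) < 3:
            raise InsufficientDataError(f"group {name!r} has fewer than 3 estimates")
        for v in vs:
            values.append(v.velocity if isinstance(v, VelocityEstimate) else float(v))
            labels.append(gi)
    x = np.array(values)
    lab = np.array(labels)
    if np.ptp(x) == 0:
        # degenerate but well-defined: every permutation ties the statistic
        means = {name: float(np.mean([v.velocity if isinstance(v, VelocityEstimate) else v for v in vs])) for name, vs in groups.items()}
        return {"p_value": 1.0, "group_means": means, "verdict": "consistent with direct incorporation"}

    def stat(labels_arr: np.ndarray) -> float:
        s = 0.0
        for g in np.unique(labels_arr):
            xg = x[labels_arr == g]
            s += xg.size * (xg.mean() - x.mean()) ** 2
        return s

    observed = stat(lab)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(lab)
        if stat(perm) >= observed - 1e-15:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    means = {}
    for name, vs in groups.items():
        means[name] = float(np.mean([v.velocity if isinstance(v, VelocityEstimate) else v for v in vs]))
    verdict = (
        "consistent with direct incorporation" if p > alpha else "velocity differs between groups"
    )
    return {"p_value": float(p), "group_means": means, "verdict": verdict}
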