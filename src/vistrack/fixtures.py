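"""Seeded synthetic-data generators with ground truth.

Three families of fixture cover the three stages of the pipeline:

* piecewise-constant-mean series with known changepoints (for the
  penalised segmentation stack),
* rigid-motion landmark clouds with known cluster labels and outliers
  (for the Procrustes/RANSAC/MDL motion models),
* rendered open-field trials -- a textured mouse-like ellipse moving on
  a static background according to a behaviour script (for the full
  tracking pipeline).

All generators are deterministic for a fixed seed: the same seed yields
bit-identical output across runs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "PiecewiseSpec",
    "ScriptSegment",
    "BehaviourScript",
    "SyntheticTrial",
    "generate_piecewise_series",
    "generate_rigid_motion_cloud",
    "render_synthetic_trial",
    "make_script",
    "freeze_script",
    "flight_script",
]

MODES = ("still", "locomote", "head_move", "flight", "freeze")

#: modes during which the body centre translates
_MOVING_MODES = ("locomote", "flight")


@dataclass(frozen=True)
class PiecewiseSpec:
    """Ground-truth description of a piecewise-constant-mean series."""

    segment_means: tuple[float, ...]
    segment_lengths: tuple[int, ...]
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        means = tuple(float(m) for m in self.segment_means)
        lengths = tuple(int(l) for l in self.segment_lengths)
        object.__setattr__(self, "segment_means", means)
        object.__setattr__(self, "segment_lengths", lengths)
        if len(means) != len(lengths) or not means:
            raise ValueError("segment_means and segment_lengths must be equal, non-empty")
        if any(l <= 0 for l in lengths):
            raise ValueError("segment lengths must be positive")
        if sum(lengths) < 2:
            raise ValueError("total series length must be >= 2")
        if not all(np.isfinite(means)) or not np.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ValueError("means must be finite and noise_sd >= 0")


def generate_piecewise_series(spec: PiecewiseSpec) -> tuple[np.ndarray, set[int]]:
    """Draw a Gaussian series around piecewise-constant means.

    Returns the series and the true changepoints, using the convention
    that a changepoint is the last index of each non-final segment
    (0-based).
    """
    rng = np.random.default_rng(spec.seed)
    series = np.repeat(spec.segment_means, spec.segment_lengths).astype(float)
    if spec.noise_sd > 0:
        series = series + rng.normal(0.0, spec.noise_sd, size=series.size)
    bounds = np.cumsum(spec.segment_lengths)[:-1]
    return series, {int(b - 1) for b in bounds}


def generate_rigid_motion_cloud(
    n_points: int,
    clusters: list[tuple[float, tuple[float, float], float]],
    noise_sd: float = 0.0,
    outlier_fraction: float = 0.0,
    bbox: tuple[float, float] = (200.0, 200.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate matched point clouds related by clustered rigid motions.

    Each cluster is ``(rotation_deg, (tx, ty), weight)``; weights must sum
    to 1.  The bounding box is centred on the origin so a rotation about
    the origin is a rotation about the box centre, and the returned
    ground-truth transform of cluster ``c`` is exactly ``p1 = R p + t``
    with the stated rotation and translation.  With K > 1 clusters the
    box is divided into K spatially separated square patches (one per
    cluster, spread along x) so that the clusters are spatially
    coherent and distinct, as body parts are.  Outliers have
    their second-frame position redrawn uniformly in the box and carry
    label ``-1``; inliers carry their cluster id.
    """
    if not clusters:
        raise ValueError("need at least one cluster")
    weights = np.array([w for _, _, w in clusters], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9 or (weights <= 0).any():
        raise ValueError("cluster weights must be positive and sum to 1")
    if not 0.0 <= outlier_fraction < 1.0:
        raise ValueError("outlier_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    K = len(clusters)
    w_box, h_box = float(bbox[0]), float(bbox[1])

    counts = np.floor(weights * n_points).astype(int)
    counts[: n_points - counts.sum()] += 1  # distribute remainder
    labels = np.repeat(np.arange(K), counts)

    pts_t = np.empty((n_points, 2))
    pts_t1 = np.empty((n_points, 2))
    strip_w = w_box / K
    half_side = 0.4 * strip_w  # compact patches, clearly separated
    start = 0
    for c, (rot_deg, (tx, ty), _) in enumerate(clusters):
        n_c = counts[c]
        if K == 1:
            p = np.column_stack(
                [
                    rng.uniform(-w_box / 2, w_box / 2, n_c),
                    rng.uniform(-h_box / 2, h_box / 2, n_c),
                ]
            )
        else:
            xc = -w_box / 2 + (c + 0.5) * strip_w
            p = np.column_stack(
                [
                    rng.uniform(xc - half_side, xc + half_side, n_c),
                    rng.uniform(-half_side, half_side, n_c),
                ]
            )
        th = np.deg2rad(rot_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        q = p @ rot.T + np.array([tx, ty])
        if noise_sd > 0:
            q = q + rng.normal(0.0, noise_sd, size=q.shape)
        pts_t[start : start + n_c] = p
        pts_t1[start : start + n_c] = q
        start += n_c

    n_out = int(round(outlier_fraction * n_points))
    if n_out:
        idx = rng.choice(n_points, size=n_out, replace=False)
        pts_t1[idx, 0] = rng.uniform(-w_box / 2, w_box / 2, n_out)
        pts_t1[idx, 1] = rng.uniform(-h_box / 2, h_box / 2, n_out)
        labels = labels.copy()
        labels[idx] = -1
    return pts_t, pts_t1, labels


# --------------------------------------------------------------------------
# rendered trials
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ScriptSegment:
    start_frame: int
    end_frame: int  # half-open
    mode: str
    body_velocity: tuple[float, float] = (0.0, 0.0)
    part_velocity: float = 0.0


@dataclass(frozen=True)
class BehaviourScript:
    """Frame-by-frame plan of what the synthetic mouse does.

    Segments must tile ``[0, n_frames)`` without gaps or overlap.  The
    body is a 2:1 ellipse whose major axis is ~8% of the arena width,
    carrying a fixed speckle texture so that corner detection finds
    plenty of landmarks, as it would on a real mouse's fur, ears and
    paws.  In ``head_move`` mode the anterior 40% of the ellipse rocks
    about the body centre while the posterior stays still, which is the
    kind of part-body motion that needs more than one rigid motion model.
    """

    segments: tuple[ScriptSegment, ...]
    arena_size: tuple[int, int] = (640, 640)
    framerate: float = 15.0
    start_position: tuple[float, float] | None = None
    heading: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ValueError("script needs at least one segment")
        if self.framerate <= 0:
            raise ValueError("framerate must be positive")
        pos = 0
        for seg in self.segments:
            if seg.start_frame != pos or seg.end_frame <= seg.start_frame:
                raise ValueError("segments must tile [0, n_frames) without overlap")
            if seg.mode not in MODES:
                raise ValueError(f"unknown mode {seg.mode!r}")
            if not np.all(np.isfinite(seg.body_velocity)) or not np.isfinite(seg.part_velocity):
                raise ValueError("velocities must be finite")
            pos = seg.end_frame

    @property
    def n_frames(self) -> int:
        return self.segments[-1].end_frame

    def frame_modes(self) -> list[str]:
        out: list[str] = []
        for seg in self.segments:
            out.extend([seg.mode] * (seg.end_frame - seg.start_frame))
        return out

    def body_half_length(self) -> float:
        return 0.04 * self.arena_size[0]  # semi-major axis: body length = 8% width

    def positions(self) -> np.ndarray:
        """Integrate the scripted body-centre path; error if out of bounds."""
        w, h = self.arena_size
        a = self.body_half_length()
        margin = a + 4.0
        if self.start_position is None:
            pos = np.array([w / 2.0, h / 2.0])
        else:
            pos = np.array(self.start_position, dtype=float)
        out = np.empty((self.n_frames, 2))
        t = 0
        for seg in self.segments:
            v = np.asarray(seg.body_velocity, float) if seg.mode in _MOVING_MODES else np.zeros(2)
            for _ in range(seg.start_frame, seg.end_frame):
                out[t] = pos
                pos = pos + v
                t += 1
        if (
            out[:, 0].min() < margin
            or out[:, 0].max() > w - margin
            or out[:, 1].min() < margin
            or out[:, 1].max() > h - margin
        ):
            raise ValueError("script drives the mouse out of the arena")
        return out


@dataclass
class SyntheticTrial:
    frames: np.ndarray  # (n_frames, H, W) uint8
    background: np.ndarray  # (H, W) uint8
    speed: np.ndarray  # ground-truth body speed, px/frame
    modes: list[str]
    positions: np.ndarray = field(repr=False, default=None)
    script: BehaviourScript | None = None

    def save(self, directory: str | Path) -> None:
        """Write frames as PNGs plus ground truth CSV (frame, speed, mode)."""
        import imageio.v3 as iio

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        iio.imwrite(directory / "background.png", self.background)
        for i, frame in enumerate(self.frames):
            iio.imwrite(directory / f"frame_{i:04d}.png", frame)
        with open(directory / "ground_truth.csv", "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["frame", "speed", "mode"])
            for i, (s, m) in enumerate(zip(self.speed, self.modes)):
                wr.writerow([i, f"{s:.6g}", m])


def _texture_tile(seed: int, size: int = 128) -> np.ndarray:
    """High-contrast speckle tile in [0, 1], fixed for a given seed."""
    rng = np.random.default_rng(seed)
    t = rng.random((size, size))
    t = ndimage.gaussian_filter(t, 1.0, mode="wrap")
    t -= t.min()
    t /= t.max()
    return t


_BG_LEVEL = 40.0
_BODY_LO, _BODY_HI = 90.0, 210.0
_HEAD_SWING = 0.35  # rad, oscillation bound for head_move


def render_synthetic_trial(
    script: BehaviourScript, seed: int = 0, noise_sd: float = 1.0
) -> SyntheticTrial:
    """Render a scripted trial as a grayscale frame stack with ground truth.

    Frame 0 equals the background outside the body region; the per-frame
    ground-truth speed is the body-centre displacement in px/frame.
    """
    w, h = script.arena_size
    a = script.body_half_length()
    b = a / 2.0  # 2:1 ellipse
    rng = np.random.default_rng(seed)
    tex = _texture_tile(seed=rng.integers(2**31))
    tex_scale = 2.0  # px per texture texel: speckle features a few px wide

    bg = np.full((h, w), _BG_LEVEL)
    bg += ndimage.gaussian_filter(rng.normal(0, 8, (h, w)), 3.0)
    bg = np.clip(bg, 0, 255)
    background = bg.astype(np.uint8)

    positions = script.positions()
    modes = script.frame_modes()
    n = script.n_frames
    frames = np.empty((n, h, w), dtype=np.uint8)
    cos_t, sin_t = np.cos(script.heading), np.sin(script.heading)

    phi = 0.0  # head angle, persists across segments
    phi_dir = 1.0
    pad = int(np.ceil(a + 3))
    for t in range(n):
        if modes[t] == "head_move":
            seg = next(s for s in script.segments if s.start_frame <= t < s.end_frame)
            omega = seg.part_velocity / a  # px/frame at snout -> rad/frame
            phi += phi_dir * omega
            if abs(phi) > _HEAD_SWING:
                phi_dir = -phi_dir
                phi = np.clip(phi, -_HEAD_SWING, _HEAD_SWING)
        cx, cy = positions[t]
        x0, x1 = int(cx) - pad, int(cx) + pad + 1
        y0, y1 = int(cy) - pad, int(cy) + pad + 1
        ys, xs = np.mgrid[y0:y1, x0:x1]
        dx, dy = xs - cx, ys - cy
        # body coordinates (u along the major axis)
        u = cos_t * dx + sin_t * dy
        v = -sin_t * dx + cos_t * dy
        cos_p, sin_p = np.cos(phi), np.sin(phi)
        u_part = cos_p * u + sin_p * v
        v_part = -sin_p * u + cos_p * v
        in_part = (u_part > 0.2 * a) & ((u_part / a) ** 2 + (v_part / b) ** 2 <= 1.0)
        uu = np.where(in_part, u_part, u)
        vv = np.where(in_part, v_part, v)
        rho = np.sqrt((uu / a) ** 2 + (vv / b) ** 2)
        alpha = np.clip((1.0 - rho) * b, 0.0, 1.0)
        tex_val = ndimage.map_coordinates(
            tex,
            [(vv / tex_scale) % tex.shape[0], (uu / tex_scale) % tex.shape[1]],
            order=1,
            mode="grid-wrap",
        )
        body = _BODY_LO + (_BODY_HI - _BODY_LO) * tex_val
        patch = bg[y0:y1, x0:x1] * (1 - alpha) + body * alpha
        if noise_sd > 0:
            patch = patch + rng.normal(0, noise_sd, patch.shape) * (alpha > 0)
        frame = background.copy()
        frame[y0:y1, x0:x1] = np.clip(patch, 0, 255).astype(np.uint8)
        frames[t] = frame

    speed = np.zeros(n)
    speed[1:] = np.linalg.norm(np.diff(positions, axis=0), axis=1)
    return SyntheticTrial(
        frames=frames,
        background=background,
        speed=speed,
        modes=modes,
        positions=positions,
        script=script,
    )


# --------------------------------------------------------------------------
# script builders
# --------------------------------------------------------------------------


def make_script(
    spans: list[tuple[int, str, float]],
    arena_size: tuple[int, int] = (640, 640),
    framerate: float = 15.0,
    seed: int = 0,
) -> BehaviourScript:
    """Build a script from (n_frames, mode, speed) spans, staying in-bounds.

    Moving spans walk at the given speed (px/frame); the builder reflects
    the direction off the arena walls, splitting a span into constant-
    velocity segments whenever the direction flips.  ``head_move`` spans
    use the speed as the snout-tip speed.  The initial direction is drawn
    from the seed so different seeds give different paths.
    """
    w, h = arena_size
    a = 0.04 * w
    margin = a + 6.0
    rng = np.random.default_rng(seed)
    ang = rng.uniform(0, 2 * np.pi)
    direction = np.array([np.cos(ang), np.sin(ang)])
    pos = np.array(
        [rng.uniform(margin + 1, w - margin - 1), rng.uniform(margin + 1, h - margin - 1)]
    )
    start = (float(pos[0]), float(pos[1]))
    segments: list[ScriptSegment] = []
    t = 0
    for n_frames, mode, speed in spans:
        if mode not in _MOVING_MODES:
            part_v = speed if mode == "head_move" else 0.0
            segments.append(ScriptSegment(t, t + n_frames, mode, (0.0, 0.0), part_v))
            t += n_frames
            continue
        done = 0
        while done < n_frames:
            v = direction * speed
            run = 0
            p = pos.copy()
            while done + run < n_frames:
                nxt = p + v
                if not (margin < nxt[0] < w - margin and margin < nxt[1] < h - margin):
                    break
                p = nxt
                run += 1
            if run == 0:  # reflect off whichever wall blocks us
                nxt = pos + v
                if not (margin < nxt[0] < w - margin):
                    direction[0] = -direction[0]
                if not (margin < nxt[1] < h - margin):
                    direction[1] = -direction[1]
                continue
            segments.append(ScriptSegment(t, t + run, mode, (v[0], v[1]), 0.0))
            pos = p
            t += run
            done += run
    return BehaviourScript(
        segments=tuple(segments),
        arena_size=arena_size,
        framerate=framerate,
        start_position=start,
        heading=0.0,
    )


def freeze_script(
    onset_frame: int = 90,
    n_frames: int = 200,
    locomotion_speed: float = 2.0,
    arena_size: tuple[int, int] = (640, 640),
    framerate: float = 15.0,
    seed: int = 0,
) -> BehaviourScript:
    """Locomotion up to stimulus onset, then an abrupt freeze (a looming-
    style response)."""
    return make_script(
        [
            (onset_frame, "locomote", locomotion_speed),
            (n_frames - onset_frame, "freeze", 0.0),
        ],
        arena_size=arena_size,
        framerate=framerate,
        seed=seed,
    )


def flight_script(
    onset_frame: int = 90,
    n_frames: int = 200,
    flight_speed: float = 5.0,
    flight_frames: int = 40,
    arena_size: tuple[int, int] = (640, 640),
    framerate: float = 15.0,
    seed: int = 0,
) -> BehaviourScript:
    """Quiescence up to onset, then a burst of fast locomotion (a flash-
    style startle/flight response)."""
    tail = n_frames - onset_frame - flight_frames
    return make_script(
        [
            (onset_frame, "still", 0.0),
            (flight_frames, "flight", flight_speed),
            (tail, "locomote", 1.5),
        ],
        arena_size=arena_size,
        framerate=framerate,
        seed=seed,
    )
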