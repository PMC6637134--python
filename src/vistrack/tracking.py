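"""Foreground extraction, pyramid Harris landmarks, and landmark matching.

The tracker isolates the animal by subtracting a static background frame
(followed by a morphological opening that removes droppings and speckle),
detects Harris corners on a 6-level image pyramid (downsample factor 1.25
with 13-tap Gaussian smoothing, sigma = 1.25) so that landmarks are found
at several spatial scales, and matches landmarks between consecutive
frames by Pearson correlation of local intensity patches.  A centroid
tracker (median of foreground pixel coordinates) is provided as the
conventional whole-body baseline.

Conventions: coordinates are 0-based pixel centres, (x, y) order;
bounding boxes are half-open ``(x0, y0, x1, y1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import corner_harris, corner_peaks
from skimage.morphology import disk
from skimage.transform import resize

__all__ = [
    "ForegroundMask",
    "LandmarkSet",
    "MatchedPairs",
    "compute_foreground",
    "detect_landmarks",
    "match_landmarks",
    "track_centroid",
]

PYRAMID_LEVELS = 6
PYRAMID_FACTOR = 1.25
PYRAMID_SIGMA = 1.25
_GAUSS_RADIUS = 6  # 13-tap kernel

DEFAULT_DIFF_THRESHOLD = 15.0
DEFAULT_OPENING_RADIUS = 3
DEFAULT_PATCH_RADIUS = 5
DEFAULT_SEARCH_RADIUS = 30.0
DEFAULT_MIN_CORRELATION = 0.5
HARRIS_K = 0.04
HARRIS_REL_THRESHOLD = 0.01


@dataclass
class ForegroundMask:
    mask: np.ndarray
    bbox: tuple[int, int, int, int] | None  # (x0, y0, x1, y1), half-open

    @property
    def empty(self) -> bool:
        return self.bbox is None


@dataclass
class LandmarkSet:
    positions: np.ndarray  # (n, 2) float, base-image (x, y)
    pyramid_level: np.ndarray  # (n,) int
    corner_score: np.ndarray  # (n,) float
    frame_index: int = 0

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self):
        """Landmarks as a DataFrame (frame, x, y, level, score)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": self.frame_index,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "level": self.pyramid_level,
                "score": self.corner_score,
            }
        )


@dataclass
class MatchedPairs:
    prev: np.ndarray  # (n, 2) (x, y) in previous frame
    curr: np.ndarray  # (n, 2) (x, y) in current frame
    correlation: np.ndarray  # (n,)
    frame_index: int = 0

    def __len__(self) -> int:
        return len(self.prev)

    @property
    def displacements(self) -> np.ndarray:
        return self.curr - self.prev

    def to_frame(self):
        """Matches as a DataFrame (frame, x0, y0, x1, y1, r)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": self.frame_index,
                "x0": self.prev[:, 0],
                "y0": self.prev[:, 1],
                "x1": self.curr[:, 0],
                "y1": self.curr[:, 1],
                "r": self.correlation,
            }
        )


def compute_foreground(
    frame: np.ndarray,
    background: np.ndarray,
    diff_threshold: float = DEFAULT_DIFF_THRESHOLD,
    opening_radius: int = DEFAULT_OPENING_RADIUS,
) -> ForegroundMask:
    """Threshold |frame - background| and clean up with an opening.

    The opening (erosion then dilation) with a disc structuring element
    removes structures smaller than the disc, e.g. droppings on the
    arena floor.  The bounding box tightly encloses the surviving
    foreground; an empty mask is flagged, not raised.
    """
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError("frame and background must share a shape")
    mask = np.abs(frame - background) > diff_threshold
    if opening_radius > 0:
        mask = ndimage.binary_opening(mask, structure=disk(opening_radius))
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        return ForegroundMask(mask=mask, bbox=None)
    bbox = (int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
    return ForegroundMask(mask=mask, bbox=bbox)


def _gaussian_13tap(image: np.ndarray, sigma: float = PYRAMID_SIGMA) -> np.ndarray:
    # truncate chosen so the kernel has exactly 2*6+1 = 13 taps
    return ndimage.gaussian_filter(image, sigma, truncate=_GAUSS_RADIUS / sigma)


def build_pyramid(image: np.ndarray, n_levels: int = PYRAMID_LEVELS) -> list[tuple[np.ndarray, float]]:
    """Smooth-and-downsample pyramid; returns (image, base-scale factor) pairs."""
    levels = [(np.asarray(image, dtype=float), 1.0)]
    for _ in range(1, n_levels):
        img, scale = levels[-1]
        new_shape = (
            max(int(round(img.shape[0] / PYRAMID_FACTOR)), 8),
            max(int(round(img.shape[1] / PYRAMID_FACTOR)), 8),
        )
        if new_shape == img.shape:
            break
        smoothed = _gaussian_13tap(img)
        down = resize(smoothed, new_shape, order=1, anti_aliasing=False, mode="edge")
        # actual factor from realised shapes, not the nominal 1.25
        factor = ((img.shape[0] / new_shape[0]) + (img.shape[1] / new_shape[1])) / 2.0
        levels.append((down, scale * factor))
    return levels


_ROI_PAD = 16  # context pixels around the ROI for border-free detection


def detect_landmarks(
    frame: np.ndarray,
    roi: tuple[int, int, int, int],
    mask: np.ndarray | None = None,
    n_levels: int = PYRAMID_LEVELS,
    harris_k: float = HARRIS_K,
    rel_threshold: float = HARRIS_REL_THRESHOLD,
    frame_index: int = 0,
) -> LandmarkSet:
    """Harris corners at every pyramid level, mapped to base coordinates.

    Applying the detector to the pyramid rather than only the base image
    yields a much denser landmark set (coarse levels respond to larger
    structures such as ears and haunches).  Detections from different
    levels that land within 1 base pixel of each other are merged,
    keeping the higher score.

    The ROI is extended by real image context (edge-replicated where the
    frame ends) before filtering, so detector responses near the ROI
    border are free of padding artefacts; detections outside the ROI are
    discarded.  Passing a foreground ``mask`` (full-frame boolean)
    additionally restricts detections to the animal body dilated by
    2 px, rejecting corners in the background texture.
    """
    frame = np.asarray(frame, dtype=float)
    x0, y0, x1, y1 = roi
    if not (0 <= x0 < x1 <= frame.shape[1] and 0 <= y0 < y1 <= frame.shape[0]):
        raise ValueError("roi outside frame")
    xp0, yp0 = max(x0 - _ROI_PAD, 0), max(y0 - _ROI_PAD, 0)
    xp1, yp1 = min(x1 + _ROI_PAD, frame.shape[1]), min(y1 + _ROI_PAD, frame.shape[0])
    patch = np.pad(
        frame[yp0:yp1, xp0:xp1],
        (
            (_ROI_PAD - (y0 - yp0), _ROI_PAD - (yp1 - y1)),
            (_ROI_PAD - (x0 - xp0), _ROI_PAD - (xp1 - x1)),
        ),
        mode="edge",
    )
    origin = np.array([x0 - _ROI_PAD, y0 - _ROI_PAD], dtype=float)
    positions: list[np.ndarray] = []
    levels: list[int] = []
    scores: list[np.ndarray] = []
    for lvl, (img, scale) in enumerate(build_pyramid(patch, n_levels)):
        if img.std() == 0:
            continue
        response = corner_harris(img, k=harris_k)
        # drop the context pad before thresholding: the detector's own
        # zero boundary produces spurious maxima at the patch edge that
        # would otherwise set the relative threshold
        crop = max(int(_ROI_PAD / scale) - 2, 0)
        if 2 * crop >= min(response.shape):
            crop = 0
        cropped = response[crop : response.shape[0] - crop, crop : response.shape[1] - crop]
        peaks = corner_peaks(
            cropped, min_distance=1, threshold_rel=rel_threshold, exclude_border=1
        )
        if len(peaks) == 0:
            continue
        peaks = peaks + crop
        base_xy = np.column_stack([peaks[:, 1], peaks[:, 0]]).astype(float) * scale
        positions.append(base_xy)
        levels.extend([lvl] * len(peaks))
        scores.append(response[peaks[:, 0], peaks[:, 1]])
    if not positions:
        return LandmarkSet(
            positions=np.empty((0, 2)),
            pyramid_level=np.empty(0, dtype=int),
            corner_score=np.empty(0),
            frame_index=frame_index,
        )
    pos = np.concatenate(positions) + origin
    lvl_arr = np.asarray(levels)
    score = np.concatenate(scores)
    inside = (
        (pos[:, 0] >= x0) & (pos[:, 0] < x1) & (pos[:, 1] >= y0) & (pos[:, 1] < y1)
    )
    if mask is not None:
        dilated = ndimage.binary_dilation(np.asarray(mask, bool), iterations=2)
        ij = np.clip(
            np.rint(pos).astype(int),
            0,
            [frame.shape[1] - 1, frame.shape[0] - 1],
        )
        inside &= dilated[ij[:, 1], ij[:, 0]]
    pos, lvl_arr, score = pos[inside], lvl_arr[inside], score[inside]
    if len(pos) == 0:
        return LandmarkSet(
            positions=np.empty((0, 2)),
            pyramid_level=np.empty(0, dtype=int),
            corner_score=np.empty(0),
            frame_index=frame_index,
        )
    keep = _merge_duplicates(pos, score, radius=1.0)
    return LandmarkSet(
        positions=pos[keep],
        pyramid_level=lvl_arr[keep],
        corner_score=score[keep],
        frame_index=frame_index,
    )


def _merge_duplicates(pos: np.ndarray, score: np.ndarray, radius: float) -> np.ndarray:
    """Indices of detections to keep: highest score within each radius-ball."""
    order = np.argsort(score)[::-1]
    kept: list[int] = []
    kept_pos: list[np.ndarray] = []
    for i in order:
        p = pos[i]
        if kept_pos and (np.linalg.norm(np.array(kept_pos) - p, axis=1) < radius).any():
            continue
        kept.append(i)
        kept_pos.append(p)
    return np.sort(np.array(kept, dtype=int))


def _extract_patches(
    frame: np.ndarray, pts: np.ndarray, radius: int
) -> tuple[np.ndarray, np.ndarray]:
    """Centred intensity patches around integer-rounded points.

    Returns (patches, valid): points whose patch would leave the image
    are marked invalid and skipped by the matcher.
    """
    h, w = frame.shape
    n = len(pts)
    side = 2 * radius + 1
    patches = np.zeros((n, side * side))
    valid = np.zeros(n, dtype=bool)
    ij = np.rint(pts).astype(int)
    for k, (x, y) in enumerate(ij):
        if radius <= x < w - radius and radius <= y < h - radius:
            p = frame[y - radius : y + radius + 1, x - radius : x + radius + 1].ravel()
            patches[k] = p - p.mean()
            valid[k] = True
    return patches, valid


def match_landmarks(
    prev: LandmarkSet,
    curr: LandmarkSet,
    prev_frame: np.ndarray,
    curr_frame: np.ndarray,
    patch_radius: int = DEFAULT_PATCH_RADIUS,
    search_radius: float = DEFAULT_SEARCH_RADIUS,
    min_correlation: float = DEFAULT_MIN_CORRELATION,
) -> MatchedPairs:
    """Greedy mutual-best matching by Pearson patch correlation.

    Every previous-frame landmark is compared against current-frame
    landmarks within ``search_radius``; pairs are accepted greedily in
    decreasing order of correlation (ties broken by smaller displacement)
    so the assignment is one-to-one in both directions.  Pairs below
    ``min_correlation`` are dropped.
    """
    prev_frame = np.asarray(prev_frame, dtype=float)
    curr_frame = np.asarray(curr_frame, dtype=float)
    if len(prev) == 0 or len(curr) == 0:
        return MatchedPairs(
            np.empty((0, 2)), np.empty((0, 2)), np.empty(0), frame_index=curr.frame_index
        )
    p_patches, p_valid = _extract_patches(prev_frame, prev.positions, patch_radius)
    c_patches, c_valid = _extract_patches(curr_frame, curr.positions, patch_radius)

    d2 = (
        (prev.positions[:, None, :] - curr.positions[None, :, :]) ** 2
    ).sum(-1)
    within = d2 <= search_radius**2
    within &= p_valid[:, None] & c_valid[None, :]
    if not within.any():
        return MatchedPairs(
            np.empty((0, 2)), np.empty((0, 2)), np.empty(0), frame_index=curr.frame_index
        )
    p_norm = np.linalg.norm(p_patches, axis=1)
    c_norm = np.linalg.norm(c_patches, axis=1)
    denom = np.outer(p_norm, c_norm)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (p_patches @ c_patches.T) / denom
    corr = np.where(np.isfinite(corr) & within, corr, -np.inf)

    pairs_prev, pairs_curr, pairs_r = [], [], []
    corr_work = corr.copy()
    while True:
        best = np.unravel_index(np.argmax(corr_work), corr_work.shape)
        r = corr_work[best]
        if not np.isfinite(r) or r < min_correlation:
            break
        i, j = best
        # correlation tie -> smaller displacement wins
        ties_i = np.flatnonzero(corr_work[i] == r)
        if len(ties_i) > 1:
            j = ties_i[np.argmin(d2[i, ties_i])]
        pairs_prev.append(prev.positions[i])
        pairs_curr.append(curr.positions[j])
        pairs_r.append(corr[i, j])
        corr_work[i, :] = -np.inf
        corr_work[:, j] = -np.inf
    if not pairs_prev:
        return MatchedPairs(
            np.empty((0, 2)), np.empty((0, 2)), np.empty(0), frame_index=curr.frame_index
        )
    return MatchedPairs(
        prev=np.array(pairs_prev),
        curr=np.array(pairs_curr),
        correlation=np.array(pairs_r),
        frame_index=curr.frame_index,
    )


def track_centroid(
    frame: np.ndarray,
    background: np.ndarray,
    diff_threshold: float = DEFAULT_DIFF_THRESHOLD,
    opening_radius: int = DEFAULT_OPENING_RADIUS,
) -> tuple[float, float] | None:
    """Whole-body position: median coordinates of foreground pixels.

    Returns ``None`` when no foreground survives the opening (flagged
    missing value rather than an exception).
    """
    fg = compute_foreground(frame, background, diff_threshold, opening_radius)
    if fg.empty:
        return None
    ys, xs = np.nonzero(fg.mask)
    return float(np.median(xs)), float(np.median(ys))
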