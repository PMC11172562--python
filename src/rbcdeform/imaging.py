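"""Segmentation and elongation-ratio morphometry of adherent cell fields.

Each segmented cell is reduced to the equivalent ellipse of its binary
mask: with area-normalised central second moments mu_xx, mu_yy, mu_xy and
moment-matrix eigenvalues lam_max >= lam_min, the full axes are
a = 4*sqrt(lam_max) and b = 4*sqrt(lam_min), and the elongation ratio is
ER = a/b = sqrt(lam_max/lam_min) >= 1.  The moment definition is exact
under rotation and translation, which a bounding-box axis estimate is not.

Quality-control flags (border contact, size limits, low solidity for
merged blobs) mark records that must not enter deformability statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .errors import InputError, ParameterError
from .synthimage import GroundTruthCell, ImageField

__all__ = [
    "SegParams",
    "CellRecord",
    "segment_cells",
    "measure_cell",
    "measure_mask",
    "analyze_field",
    "match_to_truth",
]

logger = logging.getLogger(__name__)

QC_FLAGS = ("border", "too_small", "too_large", "low_solidity")


@dataclass(frozen=True)
class SegParams:
    """Segmentation and quality-control parameters."""

    threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float = 0.5  # fraction of the image maximum, if fixed
    min_area_px: int = 50
    max_area_px: int = 5000
    exclude_border: bool = True
    split_touching: bool = False
    min_solidity: float = 0.9

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ParameterError(
                f"threshold_method must be 'otsu' or 'fixed', got {self.threshold_method!r}"
            )
        if self.min_area_px >= self.max_area_px:
            raise ParameterError("min_area_px must be below max_area_px")
        if not 0 < self.min_solidity <= 1:
            raise ParameterError("min_solidity must be in (0, 1]")
        if not 0 < self.fixed_threshold < 1:
            raise ParameterError("fixed_threshold must be in (0, 1)")


@dataclass
class CellRecord:
    """Geometry of one segmented cell."""

    label: int
    x: float
    y: float
    area_px: int
    a: float  # full major axis, px
    b: float  # full minor axis, px
    er: float
    orientation_deg: float
    qc: frozenset = field(default_factory=frozenset)

    @property
    def ok(self) -> bool:
        """True when no QC flag is set and the record may enter statistics."""
        return not self.qc


def _as_array(image) -> np.ndarray:
    arr = image.pixels if isinstance(image, ImageField) else np.asarray(image)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise InputError("image must be a non-empty 2-D array")
    if not np.isfinite(arr).all():
        raise InputError("image contains non-finite values")
    return arr


def segment_cells(image, params: SegParams | None = None) -> np.ndarray:
    """Threshold and label the foreground; 0 is background.

    Labels are 4-connected.  With ``split_touching``, a distance-transform
    watershed separates touching blobs.  A uniform image yields an empty
    label map with a warning rather than an error.
    """
    params = params or SegParams()
    arr = _as_array(image)
    if params.threshold_method == "otsu":
        if np.ptp(arr) == 0:
            warnings.warn("uniform image: no foreground found", stacklevel=2)
            return np.zeros(arr.shape, dtype=np.int32)
        thr = threshold_otsu(arr)
    else:
        thr = params.fixed_threshold * arr.max()
    binary = arr > thr
    if not binary.any():
        warnings.warn("no foreground above threshold", stacklevel=2)
        return np.zeros(arr.shape, dtype=np.int32)
    labels = sk_label(binary, connectivity=1).astype(np.int32)
    if params.split_touching:
        distance = ndi.distance_transform_edt(binary)
        min_sep = max(3, int(round(np.sqrt(params.min_area_px))))
        peaks = peak_local_max(
            distance, labels=labels, min_distance=min_sep, exclude_border=False
        )
        markers = np.zeros(arr.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        if markers.any():
            labels = watershed(
                -distance, markers, mask=binary, connectivity=1
            ).astype(np.int32)
    return labels


def measure_mask(mask: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Equivalent-ellipse measurement of a binary mask.

    Returns ``(x, y, a, b, er, orientation_deg)``; degenerate masks (single
    pixel or perfect line, lam_min = 0) give ``er = nan``.
    """
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise InputError("empty mask")
    cx, cy = xs.mean(), ys.mean()
    dx, dy = xs - cx, ys - cy
    mxx = float(np.mean(dx * dx))
    myy = float(np.mean(dy * dy))
    mxy = float(np.mean(dx * dy))
    half_tr = (mxx + myy) / 2.0
    disc = np.sqrt(((mxx - myy) / 2.0) ** 2 + mxy**2)
    lam_max, lam_min = half_tr + disc, half_tr - disc
    a = 4.0 * np.sqrt(max(lam_max, 0.0))
    b = 4.0 * np.sqrt(max(lam_min, 0.0))
    er = a / b if lam_min > 0 else float("nan")
    theta = 0.5 * np.degrees(np.arctan2(2.0 * mxy, mxx - myy))
    if theta <= -90.0:
        theta += 180.0
    return float(cx), float(cy), float(a), float(b), float(er), float(theta)


def measure_cell(label_map: np.ndarray, label: int,
                 params: SegParams | None = None,
                 _window: tuple[slice, slice] | None = None) -> CellRecord:
    """Measure one labelled region into a :class:`CellRecord` with QC flags.

    ``_window`` is an optional bounding-slice hint (as from
    ``scipy.ndimage.find_objects``) that avoids scanning the full map.
    """
    params = params or SegParams()
    label_map = np.asarray(label_map)
    h, w = label_map.shape
    if _window is None:
        locs = ndi.find_objects((label_map == label).astype(np.int8))
        if not locs or locs[0] is None:
            raise InputError(f"label {label} not present in label map")
        _window = locs[0]
        mask = (label_map == label)[_window]
    else:
        mask = label_map[_window] == label
        if not mask.any():
            raise InputError(f"label {label} not present in label map")
    x, y, a, b, er, theta = measure_mask(mask)
    x += _window[1].start
    y += _window[0].start
    area = int(mask.sum())

    flags = set()
    if area < params.min_area_px or not np.isfinite(er):
        flags.add("too_small")
    if area > params.max_area_px:
        flags.add("too_large")
    if params.exclude_border:
        if (_window[0].start == 0 or _window[1].start == 0
                or _window[0].stop == h or _window[1].stop == w):
            flags.add("border")
    if "too_small" not in flags:
        solidity = regionprops(mask.astype(np.uint8))[0].solidity
        if solidity < params.min_solidity:
            flags.add("low_solidity")
    return CellRecord(
        label=int(label), x=x, y=y, area_px=area, a=a, b=b, er=er,
        orientation_deg=theta, qc=frozenset(flags),
    )


def analyze_field(image, seg_params: SegParams | None = None) -> list[CellRecord]:
    """Segment a field and measure every labelled cell, ordered by label."""
    seg_params = seg_params or SegParams()
    labels = segment_cells(image, seg_params)
    records = [
        measure_cell(labels, lab + 1, seg_params, _window=loc)
        for lab, loc in enumerate(ndi.find_objects(labels))
        if loc is not None
    ]
    n_ok = sum(r.ok for r in records)
    logger.info("analyzed field: %d cells, %d unflagged", len(records), n_ok)
    return records


def match_to_truth(records: list[CellRecord], truth: list[GroundTruthCell],
                   max_dist_px: float = 5.0):
    """Greedy one-to-one nearest-centroid matching under a distance cutoff.

    Candidate pairs are taken in increasing centroid distance; a record or
    truth cell is used at most once.  Returns
    ``(pairs, unmatched_records, unmatched_truth)``.
    """
    if max_dist_px <= 0:
        raise ParameterError("max_dist_px must be positive")
    if not records or not truth:
        return [], list(records), list(truth)
    rc = np.array([[r.x, r.y] for r in records])
    tc = np.array([[t.x, t.y] for t in truth])
    d = np.sqrt(((rc[:, None, :] - tc[None, :, :]) ** 2).sum(axis=2))
    order = np.argsort(d, axis=None, kind="stable")
    used_r = np.zeros(len(records), dtype=bool)
    used_t = np.zeros(len(truth), dtype=bool)
    pairs = []
    for flat in order:
        i, j = divmod(int(flat), len(truth))
        if d[i, j] > max_dist_px:
            break
        if used_r[i] or used_t[j]:
            continue
        used_r[i] = used_t[j] = True
        pairs.append((records[i], truth[j]))
    unmatched_r = [r for k, r in enumerate(records) if not used_r[k]]
    unmatched_t = [t for k, t in enumerate(truth) if not used_t[k]]
    return pairs, unmatched_r, unmatched_t
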