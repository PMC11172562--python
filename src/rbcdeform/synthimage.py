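"""Synthetic flow-chamber image fields with per-cell ground truth.

Adherent red blood cells sheared in a narrow-gap flow chamber elongate along
the flow axis; each cell is scored by its elongation ratio ER = a/b (major
over minor full axis), with ER = 1 marking a round, non-deformed cell.  This
module renders fields of smooth elliptical intensity blobs whose ER values
are drawn from a configurable population distribution, together with the
exact geometry of every rendered cell, so the measurement pipeline can be
validated against known truth.

Coordinate conventions: pixels are 0-based, x increases rightward (the flow
direction), y increases downward; orientations are degrees of the major axis
away from +x, positive toward +y, reported in (-90, 90].
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GenerationError, ParameterError

__all__ = [
    "ERDistParams",
    "FieldSpec",
    "GroundTruthCell",
    "ImageField",
    "sample_er",
    "render_field",
    "rasterize_ellipse",
    "save_field",
    "load_field",
]

# fraction of the normalised elliptical radius over which the cell edge
# intensity tapers (cosine ramp); the flat top keeps the half-maximum
# contour close to the true outline while avoiding a hard aliased edge
EDGE_TAPER_FRACTION = 0.3
CELL_AMPLITUDE = 0.6
BACKGROUND_LEVEL = 0.15
AREA_JITTER_SD = 0.08


@dataclass(frozen=True)
class ERDistParams:
    """Population distribution of per-cell elongation ratios.

    The deformable sub-population is a shifted log-normal (support strictly
    above 1) whose location is chosen so the overall population mean equals
    ``aer_target``; a point mass of ``nd_fraction`` round cells sits exactly
    at ER = 1.

    Parameters
    ----------
    aer_target : float
        Desired population mean ER (>= 1).
    spread : float
        Standard deviation of the deformable component's ER.
    nd_fraction : float
        Fraction of non-deformable cells (ER exactly 1), in [0, 1].
    """

    aer_target: float = 1.58
    spread: float = 0.25
    nd_fraction: float = 0.02

    def __post_init__(self) -> None:
        if self.aer_target < 1:
            raise ParameterError(f"aer_target must be >= 1, got {self.aer_target}")
        if self.spread < 0:
            raise ParameterError(f"spread must be >= 0, got {self.spread}")
        if not 0 <= self.nd_fraction <= 1:
            raise ParameterError(
                f"nd_fraction must be in [0, 1], got {self.nd_fraction}"
            )


@dataclass(frozen=True)
class FieldSpec:
    """Geometry and photometry of one synthetic flow-chamber field."""

    width_px: int = 1280
    height_px: int = 960
    n_cells: int = 400
    er_dist: ERDistParams = field(default_factory=ERDistParams)
    mean_cell_area_px: float = 250.0
    orientation_jitter_deg: float = 8.0
    noise_sd: float = 0.01
    background_gradient: float = 0.05
    allow_touching: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ParameterError("field dimensions must be positive")
        if self.n_cells < 0:
            raise ParameterError("n_cells must be non-negative")
        if self.mean_cell_area_px <= 0:
            raise ParameterError("mean_cell_area_px must be positive")
        if self.orientation_jitter_deg < 0 or self.noise_sd < 0:
            raise ParameterError("jitter and noise_sd must be >= 0")
        if self.background_gradient < 0:
            raise ParameterError("background_gradient must be >= 0")
        budget = 0.4 * self.width_px * self.height_px
        if self.n_cells * self.mean_cell_area_px >= budget:
            raise ParameterError(
                "cell area budget exceeded: n_cells * mean_cell_area_px = "
                f"{self.n_cells * self.mean_cell_area_px:.0f} must stay below "
                f"0.4 * field area = {budget:.0f}"
            )


@dataclass(frozen=True)
class GroundTruthCell:
    """Exact geometry of one rendered cell."""

    cell_id: int
    x: float
    y: float
    a_true: float  # full major axis, px
    b_true: float  # full minor axis, px
    orientation_deg: float
    er_true: float


@dataclass
class ImageField:
    """One grayscale flow-chamber frame.

    ``pixels`` holds the rendered intensities (uint16 by convention); the
    flow axis is +x and ``pixel_size_um`` carries the optical scale as pure
    metadata.
    """

    pixels: np.ndarray
    pixel_size_um: float = 0.5
    flow_axis: str = "+x"

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def sample_er(params: ERDistParams, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` elongation ratios from the population distribution.

    Every value is >= 1; the expected share of values exactly 1 equals
    ``params.nd_fraction`` and the population mean equals
    ``params.aer_target`` by construction.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    f = params.nd_fraction
    out = np.ones(n, dtype=float)
    deformable = rng.random(n) >= f
    if f >= 1.0 or params.aer_target == 1.0:
        return out
    # mean excess over 1 among deformable cells so the overall mean hits target
    m = (params.aer_target - 1.0) / (1.0 - f)
    k = int(deformable.sum())
    if k == 0:
        return out
    if params.spread == 0:
        out[deformable] = 1.0 + m
        return out
    sigma2 = np.log1p((params.spread / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    out[deformable] = 1.0 + rng.lognormal(mu, np.sqrt(sigma2), size=k)
    return out


def _axes_from_area(area: float, er: float) -> tuple[float, float]:
    """Full (major, minor) axes of an ellipse with given area and ratio."""
    b = np.sqrt(4.0 * area / (np.pi * er))
    return er * b, b


def _paint_cell(canvas: np.ndarray, cx: float, cy: float, a: float, b: float,
                theta_deg: float, amplitude: float) -> None:
    """Add one flat-top, cosine-edge-tapered elliptical blob in place."""
    h, w = canvas.shape
    sa, sb = a / 2.0, b / 2.0
    r = int(np.ceil(sa)) + 2
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    th = np.deg2rad(theta_deg)
    u = np.cos(th) * dx + np.sin(th) * dy
    v = -np.sin(th) * dx + np.cos(th) * dy
    rho = np.sqrt((u / sa) ** 2 + (v / sb) ** 2)
    w_edge = EDGE_TAPER_FRACTION
    prof = np.zeros_like(rho)
    prof[rho <= 1.0 - w_edge] = 1.0
    edge = (rho > 1.0 - w_edge) & (rho < 1.0)
    prof[edge] = 0.5 * (1.0 + np.cos(np.pi * (rho[edge] - (1.0 - w_edge)) / w_edge))
    canvas[y0:y1, x0:x1] += amplitude * prof


def render_field(spec: FieldSpec) -> tuple[ImageField, list[GroundTruthCell]]:
    """Render one synthetic field and its ground-truth cell list.

    Cells are placed by random sequential adsorption; unless
    ``spec.allow_touching``, circumscribed circles (padded by 3 px) must not
    overlap, which guarantees disjoint foreground blobs.  Additive Gaussian
    noise and a linear background gradient along the flow axis are applied
    last.  Identical specs (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    ers = sample_er(spec.er_dist, spec.n_cells, rng) if spec.n_cells else np.empty(0)
    canvas = np.zeros((spec.height_px, spec.width_px), dtype=float)

    truths: list[GroundTruthCell] = []
    placed: list[tuple[float, float, float]] = []  # (cx, cy, clearance radius)
    max_attempts = 200 * max(spec.n_cells, 1)
    attempts = 0
    for i in range(spec.n_cells):
        area = spec.mean_cell_area_px * float(
            np.clip(rng.normal(1.0, AREA_JITTER_SD), 0.7, 1.3)
        )
        a, b = _axes_from_area(area, ers[i])
        theta = float(rng.normal(0.0, spec.orientation_jitter_deg))
        clearance = a / 2.0 + 3.0
        while True:
            attempts += 1
            if attempts > max_attempts:
                density = spec.n_cells * spec.mean_cell_area_px / (
                    spec.width_px * spec.height_px
                )
                raise GenerationError(
                    f"could not place cell {i} after {max_attempts} attempts; "
                    f"cell area density {density:.3f} is too high for "
                    "non-overlapping placement"
                )
            cx = rng.uniform(clearance, spec.width_px - clearance)
            cy = rng.uniform(clearance, spec.height_px - clearance)
            if spec.allow_touching or all(
                (cx - px) ** 2 + (cy - py) ** 2 > (clearance + pr) ** 2
                for px, py, pr in placed
            ):
                break
        placed.append((cx, cy, clearance))
        _paint_cell(canvas, cx, cy, a, b, theta, CELL_AMPLITUDE)
        truths.append(
            GroundTruthCell(
                cell_id=i, x=cx, y=cy, a_true=a, b_true=b,
                orientation_deg=theta, er_true=float(ers[i]),
            )
        )

    xs = np.linspace(0.0, 1.0, spec.width_px)
    canvas += BACKGROUND_LEVEL + spec.background_gradient * xs[np.newaxis, :]
    if spec.noise_sd > 0:
        canvas += rng.normal(0.0, spec.noise_sd, canvas.shape)
    pixels = (np.clip(canvas, 0.0, 1.0) * 65535.0).round().astype(np.uint16)
    return ImageField(pixels=pixels), truths


def rasterize_ellipse(shape: tuple[int, int], center: tuple[float, float],
                      a: float, b: float, orientation_deg: float = 0.0,
                      amplitude: float = 1.0) -> np.ndarray:
    """Rasterize a hard-edged filled ellipse (pixel centers inside).

    ``a`` and ``b`` are full axis lengths in px; used for desk-checkable
    worked examples where the exact analytic outline matters.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - center[0], yy - center[1]
    th = np.deg2rad(orientation_deg)
    u = np.cos(th) * dx + np.sin(th) * dy
    v = -np.sin(th) * dx + np.cos(th) * dy
    inside = (u / (a / 2.0)) ** 2 + (v / (b / 2.0)) ** 2 <= 1.0
    return inside.astype(float) * amplitude


TRUTH_COLUMNS = ["cell_id", "x", "y", "a_true", "b_true", "orientation_deg", "er_true"]


def save_field(image: ImageField, truths: list[GroundTruthCell],
               image_path, truth_path=None) -> None:
    """Write the frame (16-bit TIFF or 8-bit PNG) and sidecar truth CSV."""
    path = str(image_path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, image.pixels)
    elif path.lower().endswith(".png"):
        import imageio.v3 as iio

        iio.imwrite(path, (image.pixels >> 8).astype(np.uint8))
    else:
        raise ParameterError(f"unsupported image format: {path}")
    if truth_path is not None:
        pd.DataFrame([dataclasses.asdict(t) for t in truths],
                     columns=TRUTH_COLUMNS).to_csv(truth_path, index=False)


def load_field(image_path) -> ImageField:
    """Read a frame written by :func:`save_field`."""
    path = str(image_path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        return ImageField(pixels=tifffile.imread(path))
    import imageio.v3 as iio

    return ImageField(pixels=np.asarray(iio.imread(path)))
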