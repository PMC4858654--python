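"""Nuclei segmentation front-end.

Converts a raw fluorescence image (DAPI-stained nuclei) into a set of nucleus
centroids through a fixed pipeline: channel extraction, denoising, unsharp
sharpening, a limiting saturation stretch that drives the histogram towards
bimodality, Otsu thresholding, size-based mask cleanup, Moore-Neighbor contour
tracing with Jacob's stopping criterion, contour filling and centroid
computation.

Coordinates are 0-based ``(row, col)`` for pixels; centroids are reported as
``(x=col, y=row)`` in pixel units and optionally converted to micrometres via
a ``pixel_size_um`` calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage import filters as _skfilters
from skimage import measure as _skmeasure
from skimage import morphology as _skmorph
from skimage import restoration as _skrestore
from skimage.draw import line as _skline

logger = logging.getLogger(__name__)

_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}

# clockwise Moore neighbourhood: N, NE, E, SE, S, SW, W, NW
_MOORE = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))
_MOORE_INDEX = {off: i for i, off in enumerate(_MOORE)}


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the segmentation pipeline.

    ``denoise_strength`` is method-dependent: window size for ``median``,
    Gaussian sigma for ``gaussian``, TV regularisation weight for ``tv``.
    """

    channel: str = "blue"
    denoise_method: str = "tv"
    denoise_strength: float = 0.1
    sharpen_amount: float = 1.0
    sharpen_radius: float = 2.0
    saturate_low: float = 0.1
    saturate_high: float = 0.5
    min_size: int = 60
    pixel_size_um: float = 1.0
    override_csv: str | None = None

    def asdict(self) -> dict:
        return {
            "channel": self.channel,
            "denoise_method": self.denoise_method,
            "denoise_strength": self.denoise_strength,
            "sharpen_amount": self.sharpen_amount,
            "sharpen_radius": self.sharpen_radius,
            "saturate_low": self.saturate_low,
            "saturate_high": self.saturate_high,
            "min_size": self.min_size,
            "pixel_size_um": self.pixel_size_um,
            "override_csv": self.override_csv,
        }

    def with_overrides(self, **kwargs) -> "SegmentationConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


@dataclass(frozen=True)
class NucleusContour:
    """Closed pixel contour of one nucleus: ordered ``(row, col)`` points.

    Consecutive points are 8-adjacent; the walk is closed (the first point is
    reachable from the last). ``touches_border`` flags components clipped at
    the image boundary.
    """

    points: np.ndarray  # (n, 2) int array of (row, col)
    touches_border: bool = False

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class Nucleus:
    contour: NucleusContour
    mask: np.ndarray  # boolean, full image shape
    centroid: tuple[float, float]  # (x, y) pixel units
    area_px: int
    touches_border: bool


@dataclass
class NucleusSet:
    """Segmented nuclei of one image: contours, masks and centroids."""

    nuclei: list[Nucleus]
    image_shape: tuple[int, int]
    pixel_size_um: float = 1.0

    def __len__(self) -> int:
        return len(self.nuclei)

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) array of (x, y) centroids in pixel units."""
        if not self.nuclei:
            return np.empty((0, 2), dtype=float)
        return np.array([n.centroid for n in self.nuclei], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        c = self.centroids
        return pd.DataFrame(
            {
                "nucleus_id": np.arange(len(self.nuclei)),
                "x_px": c[:, 0] if len(self.nuclei) else [],
                "y_px": c[:, 1] if len(self.nuclei) else [],
                "x_um": c[:, 0] * self.pixel_size_um if len(self.nuclei) else [],
                "y_um": c[:, 1] * self.pixel_size_um if len(self.nuclei) else [],
                "area_px": [n.area_px for n in self.nuclei],
                "border_flag": [int(n.touches_border) for n in self.nuclei],
            }
        )


def _as_float01(image: np.ndarray) -> np.ndarray:
    """Scale an arbitrary-dtype image to float64 in [0, 1] by max-normalization."""
    out = np.asarray(image, dtype=float)
    m = out.max() if out.size else 0.0
    if m > 0:
        out = out / m
    return out


def extract_channel(image: np.ndarray, channel: str = "blue") -> np.ndarray:
    """Extract one channel of a multi-channel image, scaled to [0, 1].

    For 2-D (grayscale) input only ``"gray"`` (or the default for RGB,
    ``"blue"``, treated as identity) is accepted. An all-zero channel returns
    an all-zero image rather than dividing by zero.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim == 2:
        return _as_float01(image)
    if image.ndim == 3 and image.shape[2] >= 3:
        if channel == "gray":
            return _as_float01(image[..., :3].mean(axis=2))
        try:
            idx = _CHANNEL_INDEX[channel]
        except KeyError:
            raise ValueError(f"unknown channel {channel!r}") from None
        return _as_float01(image[..., idx])
    raise ValueError(f"unsupported image shape {image.shape}")


def denoise(image: np.ndarray, method: str = "tv", strength: float = 0.1) -> np.ndarray:
    """Denoise an intensity image.

    Methods: ``none`` (identity), ``median`` (window of ``strength`` px,
    default 3), ``gaussian`` (sigma = ``strength``), ``tv`` (total-variation,
    weight = ``strength``). Output stays in [0, 1].
    """
    image = np.asarray(image, dtype=float)
    if method == "none":
        return image.copy()
    if method == "median":
        size = int(strength) if strength >= 2 else 3
        return ndi.median_filter(image, size=size)
    if method == "gaussian":
        sigma = strength if strength > 0 else 1.0
        return np.clip(ndi.gaussian_filter(image, sigma=sigma), 0.0, 1.0)
    if method == "tv":
        weight = strength if strength > 0 else 0.1
        return np.clip(_skrestore.denoise_tv_chambolle(image, weight=weight), 0.0, 1.0)
    raise ValueError(f"unknown denoise method {method!r}")


def sharpen(image: np.ndarray, amount: float = 1.0, radius: float = 2.0) -> np.ndarray:
    """Unsharp masking: ``image + amount * (image - gaussian(image, radius))``.

    The high-pass component of a constant image is zero, so constants are
    fixed points; ``amount == 0`` is the identity. Result is clipped to [0, 1].
    """
    if amount < 0:
        raise ValueError("sharpen amount must be >= 0")
    if radius < 0:
        raise ValueError("sharpen radius must be >= 0")
    image = np.asarray(image, dtype=float)
    if amount == 0 or radius == 0:
        return image.copy()
    blurred = ndi.gaussian_filter(image, sigma=radius)
    return np.clip(image + amount * (image - blurred), 0.0, 1.0)


def saturate_stretch(
    image: np.ndarray, low: float = 0.1, high: float = 0.5
) -> np.ndarray:
    """Limiting saturation stretch producing a quasi-binary image.

    Intensities at or below ``low`` saturate to 0, at or above ``high`` to 1,
    and the transition range in between is expanded linearly onto [0, 1].
    """
    if not (0.0 <= low < high <= 1.0):
        raise ValueError("require 0 <= low < high <= 1")
    image = np.asarray(image, dtype=float)
    return np.clip((image - low) / (high - low), 0.0, 1.0)


def otsu_threshold(image: np.ndarray) -> np.ndarray:
    """Binarise by Otsu's method over a 256-bin histogram.

    The threshold maximises between-class variance; pixels strictly above it
    are foreground. A constant image has no valid threshold and raises.
    """
    image = np.asarray(image, dtype=float)
    if np.ptp(image) == 0:
        raise ValueError("constant image: Otsu threshold undefined")
    t = _skfilters.threshold_otsu(image, nbins=256)
    return image > t


def clean_mask(mask: np.ndarray, min_size: int = 60) -> np.ndarray:
    """Remove white components and fill black holes smaller than ``min_size``.

    Foreground components use 8-connectivity, holes 4-connectivity; both rules
    are strict (a ``min_size``-pixel feature is kept/left open). Idempotent.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    # max_size removes components of size <= max_size, so the strict
    # "< min_size" rule needs min_size - 1
    out = _skmorph.remove_small_objects(mask, max_size=min_size - 1, connectivity=2)
    out = _skmorph.remove_small_holes(out, max_size=min_size - 1, connectivity=1)
    return out


def _trace_component(mask: np.ndarray, start: tuple[int, int]) -> np.ndarray:
    """Moore-Neighbor boundary walk from ``start`` (uppermost-leftmost pixel).

    Walks clockwise around the 8-neighbourhood, terminating by Jacob's
    stopping criterion: the walk ends when the start pixel is re-entered from
    the same direction it was first entered (raster scan enters from the
    west). Returns the ordered (row, col) boundary pixels.
    """
    nrow, ncol = mask.shape

    def is_fg(p):
        r, c = p
        return 0 <= r < nrow and 0 <= c < ncol and mask[r, c]

    first_back = (start[0], start[1] - 1)  # entered from the west
    contour = [start]
    p, back = start, first_back
    max_steps = 4 * int(mask.sum()) + 8
    for _ in range(max_steps):
        i = _MOORE_INDEX[(back[0] - p[0], back[1] - p[1])]
        found = None
        prev = back
        for k in range(1, 9):
            off = _MOORE[(i + k) % 8]
            q = (p[0] + off[0], p[1] + off[1])
            if is_fg(q):
                found = q
                break
            prev = q
        if found is None:  # isolated pixel
            break
        if found == start and prev == first_back:
            break  # Jacob's criterion: re-entered start from original direction
        contour.append(found)
        p, back = found, prev
    return np.array(contour, dtype=int)


def trace_contours(mask: np.ndarray) -> list[NucleusContour]:
    """Trace one closed outer contour per 8-connected component."""
    mask = np.asarray(mask, dtype=bool)
    labels, n = _skmeasure.label(mask, connectivity=2, return_num=True)
    contours: list[NucleusContour] = []
    for lab in range(1, n + 1):
        comp = labels == lab
        rows, cols = np.nonzero(comp)
        first = np.lexsort((cols, rows))[0]  # uppermost, then leftmost
        start = (int(rows[first]), int(cols[first]))
        pts = _trace_component(comp, start)
        touches = bool(
            rows.min() == 0
            or cols.min() == 0
            or rows.max() == mask.shape[0] - 1
            or cols.max() == mask.shape[1] - 1
        )
        contours.append(NucleusContour(points=pts, touches_border=touches))
    return contours


def fill_contour(contour: NucleusContour | np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Raster-fill a closed contour: pixels inside or on the polygon are set.

    The closed polyline is drawn (consecutive points joined, last back to
    first) and its interior flood-filled. Contours with fewer than 3 points
    yield a mask of the listed pixels only.
    """
    pts = contour.points if isinstance(contour, NucleusContour) else np.asarray(contour)
    out = np.zeros(shape, dtype=bool)
    inb = (pts[:, 0] >= 0) & (pts[:, 0] < shape[0]) & (pts[:, 1] >= 0) & (pts[:, 1] < shape[1])
    out[pts[inb, 0], pts[inb, 1]] = True
    if len(pts) < 3:
        return out
    for (r0, c0), (r1, c1) in zip(pts, np.roll(pts, -1, axis=0)):
        rr, cc = _skline(int(r0), int(c0), int(r1), int(c1))
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        out[rr[keep], cc[keep]] = True
    return ndi.binary_fill_holes(out)


def compute_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Geometric centre of a binary mask as ``(x, y)`` = (mean col, mean row)."""
    rows, cols = np.nonzero(np.asarray(mask, dtype=bool))
    if rows.size == 0:
        raise ValueError("empty mask has no centroid")
    return float(cols.mean()), float(rows.mean())


def apply_overrides(nucleus_set: NucleusSet, override_csv: str | Path) -> NucleusSet:
    """Apply a centroid override table (replaces interactive manual fixing).

    CSV columns: ``action`` ({add, remove}), ``x``, ``y`` in pixel units.
    ``remove`` drops the nearest existing centroid within 5 px; ``add``
    appends a synthetic single-point nucleus at the given position.
    """
    table = pd.read_csv(override_csv, comment="#")
    nuclei = list(nucleus_set.nuclei)
    for _, row in table.iterrows():
        action = str(row["action"]).strip().lower()
        x, y = float(row["x"]), float(row["y"])
        if action == "remove":
            if not nuclei:
                continue
            d = [np.hypot(n.centroid[0] - x, n.centroid[1] - y) for n in nuclei]
            i = int(np.argmin(d))
            if d[i] <= 5.0:
                nuclei.pop(i)
            else:
                logger.warning("override remove (%g, %g): no centroid within 5 px", x, y)
        elif action == "add":
            r, c = int(round(y)), int(round(x))
            pts = np.array([[r, c]], dtype=int)
            mask = np.zeros(nucleus_set.image_shape, dtype=bool)
            if 0 <= r < nucleus_set.image_shape[0] and 0 <= c < nucleus_set.image_shape[1]:
                mask[r, c] = True
            nuclei.append(
                Nucleus(
                    contour=NucleusContour(points=pts),
                    mask=mask,
                    centroid=(x, y),
                    area_px=1,
                    touches_border=False,
                )
            )
        else:
            raise ValueError(f"unknown override action {action!r}")
    return NucleusSet(
        nuclei=nuclei,
        image_shape=nucleus_set.image_shape,
        pixel_size_um=nucleus_set.pixel_size_um,
    )


def segment_nuclei(
    image: np.ndarray, config: SegmentationConfig | None = None
) -> NucleusSet:
    """Run the full segmentation pipeline on a raw image.

    Deterministic for a fixed config. An image with no nuclei yields an empty
    :class:`NucleusSet` with a warning rather than an error.
    """
    config = config or SegmentationConfig()
    chan = extract_channel(image, config.channel)
    den = denoise(chan, config.denoise_method, config.denoise_strength)
    sharp = sharpen(den, config.sharpen_amount, config.sharpen_radius)
    stretched = saturate_stretch(sharp, config.saturate_low, config.saturate_high)
    try:
        binary = otsu_threshold(stretched)
    except ValueError:
        logger.warning("constant image after preprocessing: no nuclei found")
        return NucleusSet([], chan.shape, config.pixel_size_um)
    cleaned = clean_mask(binary, config.min_size)
    contours = trace_contours(cleaned)
    nuclei: list[Nucleus] = []
    for contour in contours:
        mask = fill_contour(contour, cleaned.shape)
        area = int(mask.sum())
        if area < config.min_size:
            continue
        nuclei.append(
            Nucleus(
                contour=contour,
                mask=mask,
                centroid=compute_centroid(mask),
                area_px=area,
                touches_border=contour.touches_border,
            )
        )
    result = NucleusSet(nuclei, cleaned.shape, config.pixel_size_um)
    if config.override_csv:
        result = apply_overrides(result, config.override_csv)
    if not result.nuclei:
        logger.warning("segmentation produced zero nuclei")
    return result


def load_image(path: str | Path) -> np.ndarray:
    """Read a TIFF or PNG image (8/16-bit, RGB or single channel)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        return tifffile.imread(path)
    import imageio.v3 as iio

    return iio.imread(path)
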