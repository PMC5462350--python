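"""Leaf image preprocessing: from color photograph to 32x16 binary orientation image.

The stages mirror the registration-based representation the classifier needs:

1. luminance grayscale conversion, Gray = 0.2989 R + 0.5870 G + 0.1140 B;
2. background segmentation by a small gray threshold (default 30) — leaf
   photographs are assumed to sit on a simple low-intensity background;
3. rotation about the foreground centroid so the geometric long axis of the
   leaf is vertical (the 180-degree ambiguity is resolved by putting the
   mass-heavier half at the bottom);
4. bounding-box crop and resampling to exactly 32 x 16, optionally followed
   by histogram equalization;
5. edge-orientation extraction — either Canny (default, single sensitivity
   threshold on the max-normalized gradient magnitude, hysteresis low
   threshold = high / 2.5) or the explicit four-step variant (Gaussian
   smoothing, Roberts-cross gradient, 3x3 dilation, non-maximum suppression,
   single-threshold binarization);
6. row-major flattening to a binary vector of length D = 32 * 16 = 512.

Because every similarity downstream is computed pixel-by-pixel on these
binary maps, registration (steps 3-4) matters more than in feature-based
pipelines: the representation is deliberately not transformation-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage import exposure, feature, filters, morphology, transform
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DegenerateImageError, InvalidInputError

__all__ = [
    "GrayImage",
    "BinaryOrientationImage",
    "PreprocessConfig",
    "to_grayscale",
    "segment_background",
    "align_long_axis",
    "normalize_size",
    "extract_orientation",
    "vectorize",
    "preprocess_image",
    "OrientationTransformer",
]

GRAY_WEIGHTS = np.array([0.2989, 0.5870, 0.1140])


@dataclass
class GrayImage:
    """A real-valued grayscale image in [0, 255] with an optional foreground mask."""

    pixels: np.ndarray
    mask: Optional[np.ndarray] = None

    @property
    def shape(self):
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryOrientationImage:
    """A 32 x 16 binary edge map; the feature all similarity computation uses."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.shape != (32, 16):
            raise InvalidInputError(f"orientation image must be 32x16, got {px.shape}")
        if not np.isin(px, (0, 1)).all():
            raise InvalidInputError("orientation image must be binary")
        object.__setattr__(self, "pixels", px.astype(np.uint8))


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable knobs of the preprocessing chain.

    sensitivity_threshold : Canny binarization threshold r in (0, 1) applied
        to the max-normalized gradient magnitude; smaller r keeps more edge
        pixels (default 0.12).
    background_threshold : gray level below which a pixel is background
        (default 30).
    canny_low_ratio : hysteresis low threshold = sensitivity_threshold / ratio.
    extractor_mode : "canny" (default) or "fourstep" (Roberts cross + NMS).
    """

    sensitivity_threshold: float = 0.12
    background_threshold: int = 30
    target_shape: tuple = (32, 16)
    gaussian_sigma: float = 1.0
    do_hist_equalize: bool = True
    do_align: bool = True
    extractor_mode: str = "canny"
    canny_low_ratio: float = 2.5

    def __post_init__(self):
        if not (0.0 < self.sensitivity_threshold < 1.0):
            raise InvalidInputError("sensitivity_threshold must be in (0, 1)")
        if not (0 <= self.background_threshold <= 255):
            raise InvalidInputError("background_threshold must be in [0, 255]")
        if self.gaussian_sigma <= 0:
            raise InvalidInputError("gaussian_sigma must be positive")
        if self.extractor_mode not in ("canny", "fourstep"):
            raise InvalidInputError(f"unknown extractor_mode {self.extractor_mode!r}")


def to_grayscale(img) -> GrayImage:
    """Luminance conversion Gray = 0.2989 R + 0.5870 G + 0.1140 B (no rounding)."""
    arr = np.asarray(img, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("empty image")
    if arr.ndim == 2:  # already gray
        return GrayImage(pixels=arr.copy())
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise InvalidInputError(f"expected an H x W x 3 color image, got shape {arr.shape}")
    return GrayImage(pixels=arr[..., :3] @ GRAY_WEIGHTS)


def segment_background(img: GrayImage, background_threshold: int = 30) -> GrayImage:
    """Foreground mask: gray value >= threshold is leaf, below is background."""
    px = np.asarray(img.pixels, dtype=float)
    mask = (px >= background_threshold).astype(np.uint8)
    if mask.sum() == 0:
        raise DegenerateImageError("segmentation produced an empty foreground mask")
    return GrayImage(pixels=px.copy(), mask=mask)


def _principal_axis_angle(mask: np.ndarray) -> tuple[float, float]:
    """Angle (degrees) of the foreground principal axis measured from vertical,
    and the eigenvalue anisotropy ratio (>= 1)."""
    rows, cols = np.nonzero(mask)
    coords = np.stack([rows, cols]).astype(float)
    cov = np.cov(coords)
    evals, evecs = np.linalg.eigh(cov)
    # eigh returns ascending eigenvalues; principal axis is the last column
    v = evecs[:, -1]  # (d_row, d_col)
    ratio = float(evals[-1] / max(evals[0], 1e-12))
    angle = float(np.degrees(np.arctan2(v[1], v[0])))  # 0 when axis is vertical
    if angle > 90.0:
        angle -= 180.0
    elif angle < -90.0:
        angle += 180.0
    return angle, ratio


def align_long_axis(img: GrayImage, *, isotropy_tol: float = 1.05) -> GrayImage:
    """Rotate about the foreground centroid so the shape's long axis is vertical.

    A nearly isotropic foreground (principal/secondary second-moment ratio
    below ``isotropy_tol``) has no meaningful long axis: the image is
    returned unrotated with a warning.  After axis alignment the image is
    flipped, if needed, so the heavier half of the foreground lies in the
    bottom half of the frame — a cheap deterministic resolution of the
    180-degree ambiguity.
    """
    if img.mask is None or img.mask.sum() == 0:
        raise InvalidInputError("align_long_axis requires a non-empty foreground mask")
    angle, ratio = _principal_axis_angle(img.mask)
    if ratio < isotropy_tol:
        warnings.warn(
            "foreground is nearly isotropic; skipping long-axis alignment",
            RuntimeWarning,
            stacklevel=2,
        )
        return GrayImage(pixels=img.pixels.copy(), mask=img.mask.copy())
    rows, cols = np.nonzero(img.mask)
    center = (float(cols.mean()), float(rows.mean()))  # (x, y) for skimage
    # rotating the image content by -angle brings the axis to vertical
    px = transform.rotate(
        np.asarray(img.pixels, float), -angle, center=center, order=1, preserve_range=True
    )
    mk = transform.rotate(
        img.mask.astype(float), -angle, center=center, order=0, preserve_range=True
    )
    mk = (mk > 0.5).astype(np.uint8)
    if mk.sum() == 0:  # rotated out of frame — pathological, keep original
        warnings.warn("alignment rotated the foreground out of frame; skipping",
                      RuntimeWarning, stacklevel=2)
        return GrayImage(pixels=img.pixels.copy(), mask=img.mask.copy())
    # 180-degree disambiguation: heavier half at the bottom
    r = np.nonzero(mk)[0]
    rc = r.mean()
    below = int((r > rc).sum())
    above = int((r < rc).sum())
    if above > below:
        px = px[::-1, ::-1].copy()
        mk = mk[::-1, ::-1].copy()
    return GrayImage(pixels=px, mask=mk)


def normalize_size(
    img: GrayImage,
    target_shape: tuple = (32, 16),
    *,
    do_hist_equalize: bool = False,
) -> GrayImage:
    """Crop the foreground bounding box and resample to ``target_shape``.

    Bilinear resampling on the gray values, nearest-neighbor (re-binarized)
    on the mask.  Histogram equalization, when enabled, is applied to the
    resampled crop and rescaled back to [0, 255].
    """
    if img.mask is None or img.mask.sum() == 0:
        raise InvalidInputError("normalize_size requires a non-empty foreground mask")
    rows, cols = np.nonzero(img.mask)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    if r1 - r0 < 1 or c1 - c0 < 1:
        raise DegenerateImageError("foreground bounding box has zero extent")
    crop = np.asarray(img.pixels, float)[r0:r1, c0:c1]
    mcrop = img.mask[r0:r1, c0:c1].astype(float)
    out = transform.resize(crop, target_shape, order=1, preserve_range=True,
                           anti_aliasing=crop.shape[0] > target_shape[0])
    mout = (transform.resize(mcrop, target_shape, order=0, preserve_range=True) > 0.5)
    if do_hist_equalize:
        out = exposure.equalize_hist(out / 255.0) * 255.0
    return GrayImage(pixels=out, mask=mout.astype(np.uint8))


def _normalized_gradient(smoothed: np.ndarray, mode: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradient magnitude normalized to max 1, plus the two components."""
    if mode == "roberts":
        gp = filters.roberts_pos_diag(smoothed)
        gn = filters.roberts_neg_diag(smoothed)
        mag = np.hypot(gp, gn)
        # convert diagonal derivatives to row/col components for NMS direction
        grow = (gp + gn) / np.sqrt(2.0)
        gcol = (gp - gn) / np.sqrt(2.0)
    else:
        grow = filters.sobel_h(smoothed)
        gcol = filters.sobel_v(smoothed)
        mag = np.hypot(grow, gcol)
    peak = mag.max()
    if peak > 0:
        mag = mag / peak
    return mag, grow, gcol


def _non_max_suppress(mag: np.ndarray, grow: np.ndarray, gcol: np.ndarray) -> np.ndarray:
    """Keep ridge tops only: zero any pixel not a local max along its gradient."""
    H, W = mag.shape
    angle = np.mod(np.degrees(np.arctan2(grow, gcol)), 180.0)
    out = np.zeros_like(mag)
    padded = np.pad(mag, 1, mode="constant")
    # neighbor offsets per quantized direction (gradient direction bins)
    offsets = {
        0: ((0, 1), (0, -1)),      # horizontal gradient -> compare left/right
        45: ((1, 1), (-1, -1)),
        90: ((1, 0), (-1, 0)),     # vertical gradient -> compare up/down
        135: ((1, -1), (-1, 1)),
    }
    bins = (np.round(angle / 45.0).astype(int) % 4) * 45
    for d, ((dr1, dc1), (dr2, dc2)) in offsets.items():
        sel = bins == d
        n1 = padded[1 + dr1: H + 1 + dr1, 1 + dc1: W + 1 + dc1]
        n2 = padded[1 + dr2: H + 1 + dr2, 1 + dc2: W + 1 + dc2]
        keep = sel & (mag >= n1) & (mag >= n2)
        out[keep] = mag[keep]
    return out


def extract_orientation(img: GrayImage, cfg: PreprocessConfig | None = None) -> BinaryOrientationImage:
    """Binary edge-orientation map of a normalized grayscale leaf image.

    Mode "canny": Canny edge detection with the high hysteresis threshold set
    to ``sensitivity_threshold`` on the max-normalized gradient magnitude and
    the low threshold at high / canny_low_ratio.  Mode "fourstep": Gaussian
    smoothing, Roberts-cross gradient, 3x3 morphological dilation,
    non-maximum suppression along the gradient direction, then a single
    threshold at ``sensitivity_threshold``.

    An all-zero output (e.g. from a uniform image) is permitted here;
    downstream Jaccard operations guard the degenerate case.
    """
    cfg = cfg or PreprocessConfig()
    px = np.asarray(img.pixels, dtype=float) / 255.0
    if px.ndim != 2:
        raise InvalidInputError("extract_orientation expects a 2-D grayscale image")
    if cfg.extractor_mode == "canny":
        smoothed = filters.gaussian(px, sigma=cfg.gaussian_sigma, preserve_range=True)
        peak = float(np.hypot(filters.sobel_h(smoothed), filters.sobel_v(smoothed)).max())
        if peak <= 1e-9:  # flat image up to float noise
            edges = np.zeros_like(px, dtype=bool)
        else:
            # scale the image so skimage's internal gradient magnitude is
            # max-normalized, making the thresholds act on a [0, 1] scale
            edges = feature.canny(
                px / peak,
                sigma=cfg.gaussian_sigma,
                low_threshold=cfg.sensitivity_threshold / cfg.canny_low_ratio,
                high_threshold=cfg.sensitivity_threshold,
                use_quantiles=False,
            )
    else:
        smoothed = filters.gaussian(px, sigma=cfg.gaussian_sigma, preserve_range=True)
        mag, grow, gcol = _normalized_gradient(smoothed, "roberts")
        mag = morphology.dilation(mag, morphology.footprint_rectangle((3, 3)))
        mag = _non_max_suppress(mag, grow, gcol)
        peak = mag.max()
        if peak > 0:
            mag = mag / peak
        edges = mag >= cfg.sensitivity_threshold
    return BinaryOrientationImage(pixels=edges.astype(np.uint8))


def vectorize(img) -> np.ndarray:
    """Row-major flattening of a 32 x 16 binary map into a length-512 vector."""
    px = np.asarray(img.pixels if hasattr(img, "pixels") else img)
    if px.shape != (32, 16):
        raise InvalidInputError(f"expected a 32x16 image, got shape {px.shape}")
    if not np.isin(px, (0, 1)).all():
        raise InvalidInputError("vectorize expects a binary image")
    return px.astype(np.uint8).ravel(order="C")


def preprocess_image(img, cfg: PreprocessConfig | None = None, source_id: str = "") -> BinaryOrientationImage:
    """Full chain: grayscale -> segment -> align -> normalize -> edges."""
    cfg = cfg or PreprocessConfig()
    gray = to_grayscale(img)
    gray = segment_background(gray, cfg.background_threshold)
    if cfg.do_align:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            gray = align_long_axis(gray)
    gray = normalize_size(gray, cfg.target_shape, do_hist_equalize=cfg.do_hist_equalize)
    boi = extract_orientation(gray, cfg)
    if source_id:
        boi = BinaryOrientationImage(pixels=boi.pixels, source_id=source_id)
    return boi


class OrientationTransformer(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer mapping raw color leaf images to binary vectors.

    ``transform`` accepts a sequence of H x W x 3 arrays (sizes may differ
    per image) and returns an (n, 512) uint8 matrix ready for the
    coarse-to-fine classifier, so the whole recognizer composes into an
    ordinary sklearn ``Pipeline``.
    """

    def __init__(
        self,
        sensitivity_threshold: float = 0.12,
        background_threshold: int = 30,
        gaussian_sigma: float = 1.0,
        do_hist_equalize: bool = True,
        do_align: bool = True,
        extractor_mode: str = "canny",
    ):
        self.sensitivity_threshold = sensitivity_threshold
        self.background_threshold = background_threshold
        self.gaussian_sigma = gaussian_sigma
        self.do_hist_equalize = do_hist_equalize
        self.do_align = do_align
        self.extractor_mode = extractor_mode

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            sensitivity_threshold=self.sensitivity_threshold,
            background_threshold=self.background_threshold,
            gaussian_sigma=self.gaussian_sigma,
            do_hist_equalize=self.do_hist_equalize,
            do_align=self.do_align,
            extractor_mode=self.extractor_mode,
        )

    def fit(self, X, y=None):
        self.config_ = self._config()  # stateless otherwise
        return self

    def transform(self, X) -> np.ndarray:
        cfg = getattr(self, "config_", None) or self._config()
        return np.stack([vectorize(preprocess_image(img, cfg)) for img in X])
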