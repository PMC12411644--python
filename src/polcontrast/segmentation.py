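"""Fluorescence-based tumor masking and fiducial co-registration.

The mask pipeline is: threshold the fluorescence image at a fraction of its
maximum (boundary-inclusive ``>=``), optionally keep the largest connected
component, then extract an N-pixel-thick outline by square (Chebyshev)
erosion.  Registration between the fluorescence and polarimetry frames is a
least-squares rigid/similarity/affine fit to user-supplied fiducial point
correspondences; masks are moved between frames by inverse warping with
nearest-neighbour interpolation.

Coordinates are 0-based (row, col) with the origin at the top-left.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage import transform as sktf

__all__ = [
    "RegionMask",
    "OutlineImage",
    "RegistrationTransform",
    "threshold_fluorescence",
    "extract_outline",
    "estimate_transform",
    "apply_transform",
]


@dataclass
class RegionMask:
    """Binary tumor mask (True = tumor) tagged with its coordinate frame."""

    mask: np.ndarray
    frame: str = "polarimetry"
    threshold_fraction: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.frame not in ("fluorescence", "polarimetry"):
            raise ValueError(f"unknown frame tag {self.frame!r}")


@dataclass
class OutlineImage:
    """Border band of a region mask, ``thickness`` pixels thick (Chebyshev)."""

    outline: np.ndarray
    thickness: int
    frame: str = "polarimetry"

    def __post_init__(self) -> None:
        self.outline = np.asarray(self.outline, dtype=bool)
        if self.outline.ndim != 2:
            raise ValueError("outline must be 2-D")


def threshold_fluorescence(
    fluor,
    fraction: float = 0.95,
    keep_largest: bool = False,
    frame: str = "fluorescence",
) -> RegionMask:
    """Binarize a fluorescence image at ``fraction`` of its maximum intensity.

    A pixel belongs to the tumor iff ``value >= fraction * max(image)``
    (boundary inclusive).  A constant image has no meaningful relative
    threshold and raises.  ``keep_largest`` optionally retains only the
    largest 8-connected component (off by default).
    """
    img = np.asarray(fluor, dtype=float)
    if img.ndim != 2:
        raise ValueError("fluorescence image must be 2-D")
    if np.any(img < 0):
        raise ValueError("fluorescence image contains negative intensities")
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    if img.max() == img.min():
        raise ValueError("constant fluorescence image: relative threshold undefined")
    mask = img >= fraction * img.max()
    if keep_largest and mask.any():
        labels = measure.label(mask, connectivity=2)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == int(counts.argmax())
    return RegionMask(mask=mask, frame=frame, threshold_fraction=fraction)


def extract_outline(mask: RegionMask, thickness: int = 5) -> OutlineImage:
    """Mask pixels within Chebyshev distance ``thickness`` of a non-mask pixel.

    Implemented as ``mask AND NOT erode(mask)`` with a square structuring
    element of size ``2*thickness + 1``; pixels beyond the image border are
    treated as mask so the frame edge itself does not produce an outline.
    """
    if thickness < 1:
        raise ValueError("thickness must be >= 1")
    m = mask.mask
    footprint = np.ones((2 * thickness + 1, 2 * thickness + 1), dtype=bool)
    eroded = ndimage.binary_erosion(m, structure=footprint, border_value=1)
    return OutlineImage(outline=m & ~eroded, thickness=thickness, frame=mask.frame)


_MODELS = {
    "rigid": sktf.EuclideanTransform,
    "similarity": sktf.SimilarityTransform,
    "affine": sktf.AffineTransform,
}
_MIN_POINTS = {"rigid": 2, "similarity": 2, "affine": 3}


@dataclass
class RegistrationTransform:
    """2-D point transform ``dst = A @ (row, col, 1)`` with fit diagnostics."""

    model: str
    matrix: np.ndarray
    residual_rmse: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("transform matrix must be 3x3 homogeneous")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("transform matrix contains non-finite entries")

    @classmethod
    def identity(cls, model: str = "rigid") -> "RegistrationTransform":
        return cls(model=model, matrix=np.eye(3))

    @property
    def scale(self) -> float:
        return float(np.sqrt(abs(np.linalg.det(self.matrix[:2, :2]))))

    @property
    def rotation(self) -> float:
        """Rotation (radians) in the row-down (row, col) frame."""
        return float(np.arctan2(self.matrix[1, 0], self.matrix[0, 0]))

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:2, 2].copy()

    def apply(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        hom = np.hstack([pts, np.ones((len(pts), 1))])
        return (self.matrix @ hom.T).T[:, :2]

    def inverse(self) -> "RegistrationTransform":
        return RegistrationTransform(model=self.model, matrix=np.linalg.inv(self.matrix))


def estimate_transform(src_points, dst_points, model: str = "similarity") -> RegistrationTransform:
    """Least-squares (Procrustes-type) transform from point correspondences.

    ``src_points`` and ``dst_points`` are matched lists of (row, col)
    coordinates; the returned transform maps src onto dst and carries the
    residual RMSE of the fit.  Degenerate configurations (too few or
    coincident/collinear points for the model class) raise; a nearly
    degenerate spread triggers a condition warning.
    """
    if model not in _MODELS:
        raise ValueError(f"model must be one of {sorted(_MODELS)}, got {model!r}")
    src = np.atleast_2d(np.asarray(src_points, dtype=float))
    dst = np.atleast_2d(np.asarray(dst_points, dtype=float))
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("src and dst must be matched (n, 2) point arrays")
    n = len(src)
    if n < _MIN_POINTS[model]:
        raise ValueError(f"{model} transform needs >= {_MIN_POINTS[model]} point pairs, got {n}")

    centered = src - src.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[0] == 0:
        raise ValueError("all source points coincide; transform is degenerate")
    if model == "affine" and (sv[1] == 0 or sv[0] / sv[1] > 1e8):
        raise ValueError("source points are (near-)collinear; affine fit is degenerate")
    if sv[1] == 0 or sv[0] / max(sv[1], np.finfo(float).tiny) > 1e6:
        warnings.warn("fiducial points are nearly collinear; transform may be ill-conditioned", stacklevel=2)

    # skimage fits dst = A @ src on whatever 2-D coordinates it is given, so
    # (row, col) points can be passed straight through.
    tf = sktf.estimate_transform(
        {"rigid": "euclidean", "similarity": "similarity", "affine": "affine"}[model], src, dst
    )
    matrix = np.asarray(tf.params, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("transform estimation failed (degenerate point configuration)")
    result = RegistrationTransform(model=model, matrix=matrix)
    resid = result.apply(src) - dst
    result.residual_rmse = float(np.sqrt(np.mean(np.sum(resid**2, axis=1)))) if n else 0.0
    return result


def apply_transform(obj, t: RegistrationTransform, target_shape: tuple[int, int]):
    """Warp a mask or outline into the transform's destination frame.

    Inverse-warps with nearest-neighbour interpolation (the data are binary);
    pixels mapping from outside the source frame become False.  Returns the
    same type as the input, tagged ``frame='polarimetry'``.
    """
    inv = t.inverse().matrix
    if isinstance(obj, RegionMask):
        data = obj.mask
    elif isinstance(obj, OutlineImage):
        data = obj.outline
    else:
        raise TypeError(f"expected RegionMask or OutlineImage, got {type(obj).__name__}")
    warped = ndimage.affine_transform(
        data.astype(np.uint8),
        matrix=inv[:2, :2],
        offset=inv[:2, 2],
        output_shape=tuple(target_shape),
        order=0,
        mode="constant",
        cval=0,
    ).astype(bool)
    if isinstance(obj, RegionMask):
        return RegionMask(mask=warped, frame="polarimetry", threshold_fraction=obj.threshold_fraction)
    return OutlineImage(outline=warped, thickness=obj.thickness, frame="polarimetry")
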