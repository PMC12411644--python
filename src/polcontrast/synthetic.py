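"""Seeded synthetic scenes for exercising the full analysis offline.

A scene is a two-class field (elliptical "tumor" inside "non-tumor"
background) whose per-pixel signed circular and linear DOP values are drawn
from class-conditional truncated normals.  Intensity frames are constructed
so that the DOP operations recover the drawn values exactly before noise; a
co-located fluorescence blob is rendered in a separate coordinate frame
linked by a known similarity transform, with fiducial disks stamped in both
frames.  Everything is driven by a single seeded generator stream in a
documented draw order, so a scene is bit-reproducible from its config.

Draw order for :func:`make_dop_scene`: tumor circular values, non-tumor
circular values, tumor linear values, non-tumor linear values, frame noise in
the fixed frame order (R/R, R/L, hv pair, diag pair), fluorescence noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.special import ndtr

from .polarimetry import (
    DEFAULT_SCHEME,
    PolarimetricMeasurementSet,
    forward_intensities,
)
from .segmentation import RegistrationTransform

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "ExpectedContrast",
    "make_dop_scene",
    "make_mueller_scene",
    "closed_form_expectations",
]


@dataclass
class SceneConfig:
    """Full parameterization of a synthetic scene.  ``seed`` is mandatory."""

    seed: int
    shape: tuple[int, int] = (256, 256)
    # tumor ellipse: center (row, col), semi-axes (a, b) in px, rotation rad
    ellipse_center: tuple[float, float] = (120.0, 128.0)
    ellipse_axes: tuple[float, float] = (60.0, 40.0)
    ellipse_rotation: float = 0.3
    # class-conditional (mean, sd) of the signed DOP distributions; defaults
    # give the tumor a more negative, higher-magnitude circular DOP and a
    # slightly more negative linear DOP with |linear| > |circular| overall
    docp_tumor: tuple[float, float] = (-0.45, 0.12)
    docp_nontumor: tuple[float, float] = (-0.15, 0.12)
    dolp_tumor: tuple[float, float] = (-0.65, 0.08)
    dolp_nontumor: tuple[float, float] = (-0.55, 0.08)
    # optional spatial smoothing of the per-class fields (approximate: the
    # marginals are restandardized after filtering); 0 = i.i.d. pixels
    correlation_sigma: float = 0.0
    # intensity model
    base_intensity: float = 1.0
    noise_sd: float = 0.003
    poisson_noise: bool = False
    incident_helicity: str = "R"
    incident_hv: str = "H"
    incident_diag: str = "P45"
    # fraction of the signed linear DOP realized in the H/V experiment
    dolp_split: float = 1.0
    # fluorescence rendering
    fluor_background: float = 10.0
    fluor_contrast: float = 200.0
    fluor_blur_sd: float = 1.5
    fluor_noise_sd: float = 2.0
    # fluorescence -> polarimetry similarity transform parameters
    transform_rotation: float = 0.03
    transform_scale: float = 1.01
    transform_translation: tuple[float, float] = (2.0, -3.0)
    # fiducial marker centers in the polarimetry frame
    fiducials: tuple[tuple[float, float], ...] = (
        (20.0, 20.0),
        (20.0, 236.0),
        (236.0, 20.0),
        (236.0, 236.0),
        (128.0, 16.0),
        (16.0, 128.0),
    )
    fiducial_radius: float = 4.0
    fiducial_gain: float = 3.0

    def validate(self) -> None:
        for name in ("docp_tumor", "docp_nontumor", "dolp_tumor", "dolp_nontumor"):
            mean, sd = getattr(self, name)
            if not (-1.0 < mean < 1.0):
                raise ValueError(f"{name} mean {mean} outside (-1, 1)")
            if sd <= 0:
                raise ValueError(f"{name} sd must be positive, got {sd}")
        if not (0.0 <= self.dolp_split <= 1.0):
            raise ValueError("dolp_split must lie in [0, 1]")
        rows, cols = self.shape
        cr, cc = self.ellipse_center
        r = max(self.ellipse_axes)
        if cr - r < 0 or cc - r < 0 or cr + r > rows - 1 or cc + r > cols - 1:
            raise ValueError("tumor ellipse does not fit inside the frame")
        if self.base_intensity <= 0:
            raise ValueError("base_intensity must be positive")


@dataclass
class SceneTruth:
    """Ground truth accompanying a generated scene."""

    class_map: np.ndarray  # True = tumor, polarimetry frame
    docp_true: np.ndarray | None
    dolp_true: np.ndarray | None
    transform: RegistrationTransform  # fluorescence -> polarimetry
    fiducials_pol: np.ndarray  # (n, 2) of (row, col)
    fiducials_fluor: np.ndarray
    config: SceneConfig
    frame_order: tuple = ()


@dataclass
class ExpectedContrast:
    auc: float
    overlap: float | None


def rasterize_ellipse(shape, center, axes, rotation) -> np.ndarray:
    """Boolean map of pixels whose centers lie inside the rotated ellipse."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dr * math.cos(rotation) + dc * math.sin(rotation)
    v = -dr * math.sin(rotation) + dc * math.cos(rotation)
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _sample_truncnorm(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Rejection sampling of N(mean, sd) truncated to [-1, 1]."""
    out = rng.normal(mean, sd, size)
    bad = np.flatnonzero((out < -1.0) | (out > 1.0))
    while bad.size:
        out[bad] = rng.normal(mean, sd, bad.size)
        bad = bad[(out[bad] < -1.0) | (out[bad] > 1.0)]
    return out


def _class_field(rng, class_map, tumor_params, nontumor_params, corr_sigma) -> np.ndarray:
    field_ = np.empty(class_map.shape, dtype=float)
    n_t = int(class_map.sum())
    field_[class_map] = _sample_truncnorm(rng, *tumor_params, n_t)
    field_[~class_map] = _sample_truncnorm(rng, *nontumor_params, class_map.size - n_t)
    if corr_sigma > 0:
        for sel, (mean, sd) in ((class_map, tumor_params), (~class_map, nontumor_params)):
            z = (field_[sel] - mean) / sd
            smooth = np.zeros_like(field_)
            smooth[sel] = z
            smooth = ndimage.gaussian_filter(smooth, corr_sigma)
            zs = smooth[sel]
            if zs.std() > 0:
                zs = (zs - zs.mean()) / zs.std()
            field_[sel] = np.clip(mean + sd * zs, -1.0, 1.0)
    return field_


def _similarity_matrix(rotation: float, scale: float, translation) -> np.ndarray:
    c, s = math.cos(rotation), math.sin(rotation)
    m = np.eye(3)
    m[:2, :2] = scale * np.array([[c, -s], [s, c]])
    m[:2, 2] = translation
    return m


def _true_transform(config: SceneConfig) -> RegistrationTransform:
    return RegistrationTransform(
        model="similarity",
        matrix=_similarity_matrix(
            config.transform_rotation, config.transform_scale, config.transform_translation
        ),
    )


def _stamp_disks(img: np.ndarray, centers: np.ndarray, radius: float, value: float) -> None:
    rr, cc = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    for r0, c0 in centers:
        img[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2] = value


def _fiducial_gain_map(config: SceneConfig, centers: np.ndarray) -> np.ndarray:
    gain = np.ones(config.shape)
    _stamp_disks(gain, centers, config.fiducial_radius, config.fiducial_gain)
    return gain


def _add_noise(rng, frame: np.ndarray, config: SceneConfig) -> np.ndarray:
    out = frame
    if config.poisson_noise:
        out = rng.poisson(np.maximum(out, 0.0) * 1e4) / 1e4
    if config.noise_sd > 0:
        out = out + rng.normal(0.0, config.noise_sd * config.base_intensity, out.shape)
    return np.maximum(out, 0.0)


_HV_SIGN = {"H": 1.0, "V": -1.0}
_DIAG_SIGN = {"P45": 1.0, "M45": -1.0}
_CIRC_SIGN = {"R": 1.0, "L": -1.0}


def make_dop_scene(config: SceneConfig):
    """Generate DOP intensity frames, a fluorescence image, and ground truth.

    Returns ``(truth, measurement_set, fluorescence)``.  The six intensity
    frames realize the drawn signed DOP fields exactly before noise: the
    circular pair splits S0 so the signed circular DOP equals the drawn
    value under the configured incident helicity, and the two linear pairs
    split the drawn linear value in the configured ratio between the H/V and
    diagonal experiments.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    class_map = rasterize_ellipse(
        config.shape, config.ellipse_center, config.ellipse_axes, config.ellipse_rotation
    )

    docp = _class_field(rng, class_map, config.docp_tumor, config.docp_nontumor, config.correlation_sigma)
    dolp = _class_field(rng, class_map, config.dolp_tumor, config.dolp_nontumor, config.correlation_sigma)

    s0 = config.base_intensity
    # invert the signed-DOP definitions to per-pair intensity ratios
    r_circ = _CIRC_SIGN[config.incident_helicity] * docp
    r_hv = -_HV_SIGN[config.incident_hv] * (config.dolp_split * dolp)
    r_diag = _DIAG_SIGN[config.incident_diag] * ((1.0 - config.dolp_split) * dolp)

    h = config.incident_helicity
    hv = config.incident_hv
    dg = config.incident_diag
    clean = {
        (h, "R"): s0 * (1.0 + r_circ) / 2.0,
        (h, "L"): s0 * (1.0 - r_circ) / 2.0,
        (hv, "H"): s0 * (1.0 + r_hv) / 2.0,
        (hv, "V"): s0 * (1.0 - r_hv) / 2.0,
        (dg, "P45"): s0 * (1.0 + r_diag) / 2.0,
        (dg, "M45"): s0 * (1.0 - r_diag) / 2.0,
    }
    frame_order = tuple(clean)

    t = _true_transform(config)
    fid_pol = np.asarray(config.fiducials, dtype=float)
    fid_fluor = t.inverse().apply(fid_pol)
    gain = _fiducial_gain_map(config, fid_pol)

    frames = {key: _add_noise(rng, img * gain, config) for key, img in clean.items()}

    # fluorescence frame: inverse-warp the class map through the true
    # fluorescence->polarimetry transform, blur, stamp fiducials, add noise
    base_pol = config.fluor_background + config.fluor_contrast * class_map.astype(float)
    m = t.matrix
    fluor = ndimage.affine_transform(
        base_pol,
        matrix=m[:2, :2],
        offset=m[:2, 2],
        output_shape=config.shape,
        order=1,
        mode="constant",
        cval=config.fluor_background,
    )
    if config.fluor_blur_sd > 0:
        fluor = ndimage.gaussian_filter(fluor, config.fluor_blur_sd)
    _stamp_disks(fluor, fid_fluor, config.fiducial_radius, config.fluor_background + 0.6 * config.fluor_contrast)
    if config.fluor_noise_sd > 0:
        fluor = fluor + rng.normal(0.0, config.fluor_noise_sd, fluor.shape)
    fluor = np.maximum(fluor, 0.0)

    truth = SceneTruth(
        class_map=class_map,
        docp_true=docp,
        dolp_true=dolp,
        transform=t,
        fiducials_pol=fid_pol,
        fiducials_fluor=fid_fluor,
        config=config,
        frame_order=frame_order,
    )
    mset = PolarimetricMeasurementSet(frames=frames, metadata={"seed": config.seed})
    return truth, mset, fluor


def make_mueller_scene(
    config: SceneConfig,
    tumor_diag: tuple[float, float, float, float] = (1.0, 0.55, 0.55, -0.35),
    nontumor_diag: tuple[float, float, float, float] = (1.0, 0.6, 0.6, 0.15),
    bs_illumination: np.ndarray | None = None,
    bs_detection: np.ndarray | None = None,
    scheme=DEFAULT_SCHEME,
):
    """Forward-simulate a 16-frame measurement set from per-class diagonal matrices.

    Each class's sample matrix is ``diag(m11, a, a, b)`` with ``|a|, |b| <= 1``
    (relative to m11); optional beam-splitter matrices multiply the sample on
    the detection/illumination side.  Returns ``(truth, measurement_set)``.
    """
    config.validate()
    for name, diag in (("tumor_diag", tumor_diag), ("nontumor_diag", nontumor_diag)):
        m11 = diag[0]
        if m11 <= 0 or any(abs(x) > m11 for x in diag[1:]):
            raise ValueError(f"{name}={diag} is not physical: need |elements| <= m11 and m11 > 0")
    rng = np.random.default_rng(config.seed)
    class_map = rasterize_ellipse(
        config.shape, config.ellipse_center, config.ellipse_axes, config.ellipse_rotation
    )

    m_field = np.zeros((*config.shape, 4, 4))
    idx = np.arange(4)
    m_field[..., idx, idx] = np.where(
        class_map[..., None], np.asarray(tumor_diag), np.asarray(nontumor_diag)
    )
    effective = m_field
    if bs_illumination is not None or bs_detection is not None:
        ill = np.eye(4) if bs_illumination is None else np.asarray(bs_illumination, dtype=float)
        det = np.eye(4) if bs_detection is None else np.asarray(bs_detection, dtype=float)
        effective = np.einsum("ij,rcjk,kl->rcil", det, m_field, ill)

    stack = forward_intensities(effective, scheme) * config.base_intensity
    frames = {}
    for k, (g, a) in enumerate(scheme):
        frames[(g, a)] = _add_noise(rng, stack[k], config)

    t = _true_transform(config)
    fid_pol = np.asarray(config.fiducials, dtype=float)
    truth = SceneTruth(
        class_map=class_map,
        docp_true=None,
        dolp_true=None,
        transform=t,
        fiducials_pol=fid_pol,
        fiducials_fluor=t.inverse().apply(fid_pol),
        config=config,
        frame_order=tuple(scheme),
    )
    return truth, PolarimetricMeasurementSet(frames=frames, metadata={"seed": config.seed})


def closed_form_expectations(config: SceneConfig, metric: str = "circular") -> ExpectedContrast:
    """Analytic AUC and overlap for the configured Gaussian class distributions.

    Valid only when truncation to [-1, 1] is negligible (|mean| + 4 sd < 1
    for both classes); otherwise refuses.  AUC uses the binormal form
    ``Phi((mu_T - mu_N) / sqrt(sd_T^2 + sd_N^2))`` under the signed-value
    positive orientation; the overlapping coefficient ``2 Phi(-|dmu| / 2 sd)``
    is returned only for equal class SDs (None otherwise).
    """
    if metric == "circular":
        (mu_t, sd_t), (mu_n, sd_n) = config.docp_tumor, config.docp_nontumor
    elif metric == "linear":
        (mu_t, sd_t), (mu_n, sd_n) = config.dolp_tumor, config.dolp_nontumor
    else:
        raise ValueError(f"metric must be 'circular' or 'linear', got {metric!r}")
    for mu, sd in ((mu_t, sd_t), (mu_n, sd_n)):
        if abs(mu) + 4.0 * sd >= 1.0:
            raise ValueError(
                f"truncation is significant for (mean={mu}, sd={sd}); closed forms do not apply"
            )
    auc = float(ndtr((mu_t - mu_n) / math.hypot(sd_t, sd_n)))
    overlap = None
    if math.isclose(sd_t, sd_n, rel_tol=1e-9):
        overlap = float(2.0 * ndtr(-abs(mu_t - mu_n) / (2.0 * sd_t)))
    return ExpectedContrast(auc=auc, overlap=overlap)


def default_scene_config(seed: int, **overrides) -> SceneConfig:
    """Convenience constructor used by the CLI; overrides are field names."""
    return replace(SceneConfig(seed=seed), **overrides)
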