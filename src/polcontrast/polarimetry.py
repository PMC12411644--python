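"""Stokes components, signed degree-of-polarization images, and Mueller-matrix imaging.

Conventions (fixed, since polarimetric handedness is often left implicit):

* Stokes components from analyzed intensities:
  ``S0 = I_H + I_V``, ``S1 = I_H - I_V``, ``S2 = I_+45 - I_-45``,
  ``S3 = I_R - I_L`` with right-circular positive.
* Signed circular DOP: ``sign(S3_in) * (I_R - I_L) / (I_R + I_L)``; negative
  values encode helicity flipping, positive values helicity preservation.
* Signed linear DOP (two-experiment definition):
  ``-sign(S1_in) * (I_H - I_V)/(I_H + I_V) + sign(S2_in) * (I_45 - I_-45)/(I_45 + I_-45)``
  so that co-linear dominance in the H/V basis drives the value negative.
  The value can mathematically leave [-1, +1] when the two experiments agree
  strongly (e.g. an ideal mirror gives -2); such pixels are flagged, never
  clamped.
* Mueller matrices are indexed M11..M44, first index = row.

All per-pixel operations are vectorized over 2-D images.  Pixels whose total
intensity falls below ``intensity_floor`` (relative to the image maximum) are
placed in the invalid mask instead of producing division warnings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "STATES",
    "UNIT_STOKES",
    "DEFAULT_SCHEME",
    "DEFAULT_INTENSITY_FLOOR",
    "PolarimetricMeasurementSet",
    "StokesImage",
    "MuellerImage",
    "DOPImage",
    "stokes_from_intensities",
    "signed_docp",
    "signed_dolp",
    "design_matrix",
    "forward_intensities",
    "mueller_from_measurements",
    "correct_beam_splitter",
    "total_dop_magnitude",
]

#: Recognised polarization state labels.
STATES = ("H", "V", "P45", "M45", "R", "L")

#: Unit Stokes (s1, s2, s3) vector of each pure state.
UNIT_STOKES = {
    "H": (1.0, 0.0, 0.0),
    "V": (-1.0, 0.0, 0.0),
    "P45": (0.0, 1.0, 0.0),
    "M45": (0.0, -1.0, 0.0),
    "R": (0.0, 0.0, 1.0),
    "L": (0.0, 0.0, -1.0),
}

_CIRCULAR_SIGN = {"R": 1.0, "L": -1.0}
_HV_SIGN = {"H": 1.0, "V": -1.0}
_DIAG_SIGN = {"P45": 1.0, "M45": -1.0}

#: Minimal invertible 16-state generator/analyzer scheme.
DEFAULT_SCHEME = tuple((g, a) for g in ("H", "V", "P45", "R") for a in ("H", "V", "P45", "R"))

#: Valid-pixel intensity floor, as a fraction of the image maximum.
DEFAULT_INTENSITY_FLOOR = 1e-6

_S0_CONSISTENCY_RTOL = 1e-6
_RANGE_EPS = 1e-12


def _as_image(arr, name: str) -> np.ndarray:
    out = np.asarray(arr, dtype=float)
    if out.ndim != 2:
        raise ValueError(f"{name} must be a 2-D image, got ndim={out.ndim}")
    if np.any(out < 0):
        raise ValueError(f"{name} contains negative intensities")
    return out


def _check_same_shape(images: Sequence[np.ndarray]) -> tuple[int, int]:
    shapes = {im.shape for im in images}
    if len(shapes) != 1:
        raise ValueError(f"intensity frames disagree on shape: {sorted(shapes)}")
    return images[0].shape


@dataclass
class PolarimetricMeasurementSet:
    """Raw intensity frames indexed by ``(incident_state, analyzed_state)``."""

    frames: Mapping[tuple[str, str], np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        frames = {}
        for key, img in self.frames.items():
            inc, ana = key
            if inc not in STATES or ana not in STATES:
                raise ValueError(f"unknown state pair {key!r}; states must be in {STATES}")
            frames[(inc, ana)] = _as_image(img, f"frame {key}")
        _check_same_shape(list(frames.values()))
        self.frames = frames

    @property
    def image_shape(self) -> tuple[int, int]:
        return next(iter(self.frames.values())).shape

    def frame(self, incident: str, analyzed: str) -> np.ndarray:
        try:
            return self.frames[(incident, analyzed)]
        except KeyError:
            raise KeyError(f"no frame for incident={incident!r}, analyzed={analyzed!r}") from None


@dataclass
class StokesImage:
    """Per-pixel Stokes components of the analyzed beam."""

    s0: np.ndarray
    s1: np.ndarray
    s2: np.ndarray
    s3: np.ndarray
    convention: str = "S1=IH-IV, S2=I45-IM45, S3=IR-IL (right-circular positive)"
    s0_consistent: bool = True

    def realizability_violations(self, rtol: float = 1e-9) -> np.ndarray:
        """Boolean image: pixels where S1^2+S2^2+S3^2 exceeds S0^2 (noise artefact)."""
        lhs = self.s1**2 + self.s2**2 + self.s3**2
        return lhs > self.s0**2 * (1.0 + rtol) + rtol


@dataclass
class MuellerImage:
    """Per-pixel 4x4 Mueller matrix field, shape (rows, cols, 4, 4)."""

    m: np.ndarray
    normalized: bool = False
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if self.m.ndim != 4 or self.m.shape[-2:] != (4, 4):
            raise ValueError("Mueller field must have shape (rows, cols, 4, 4)")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.m.shape[:2], dtype=bool)

    def element(self, row: int, col: int) -> np.ndarray:
        """1-based element image, e.g. ``element(4, 4)`` for M44."""
        if not (1 <= row <= 4 and 1 <= col <= 4):
            raise ValueError("element indices are 1-based in 1..4")
        return self.m[..., row - 1, col - 1]


@dataclass
class DOPImage:
    """Signed degree-of-polarization image.

    ``metric`` is one of ``circular`` (values in [-1, 1]), ``linear`` (values
    can mathematically leave [-1, 1]; such pixels appear in ``flagged``) or
    ``total_magnitude`` (values in [0, 1]).
    """

    values: np.ndarray
    metric: str
    valid_mask: np.ndarray
    flagged: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask shape mismatch")
        if self.metric not in ("circular", "linear", "total_magnitude"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.flagged is None:
            self.flagged = np.zeros(self.values.shape, dtype=bool)

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]


def _valid_from_total(total: np.ndarray, intensity_floor: float) -> np.ndarray:
    peak = float(total.max()) if total.size else 0.0
    floor = intensity_floor * peak
    return total > floor


def _safe_ratio(num: np.ndarray, den: np.ndarray, valid: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=valid)
    return out


def stokes_from_intensities(frames: Mapping[str, np.ndarray]) -> StokesImage:
    """Stokes components from the six analyzed-state intensities of one beam.

    ``frames`` maps analyzed-state labels (all six of H, V, P45, M45, R, L) to
    nonnegative images.  S0 is taken from the H/V pair and cross-checked
    against the diagonal and circular pairs; disagreement beyond tolerance
    clears ``s0_consistent`` (warning, not an error — noise does this).
    """
    missing = [s for s in STATES if s not in frames]
    if missing:
        raise ValueError(f"missing analyzed states: {missing}")
    imgs = {s: _as_image(frames[s], f"I_{s}") for s in STATES}
    _check_same_shape(list(imgs.values()))

    s0 = imgs["H"] + imgs["V"]
    s0_diag = imgs["P45"] + imgs["M45"]
    s0_circ = imgs["R"] + imgs["L"]
    scale = max(float(s0.max()), 1.0)
    consistent = bool(
        np.allclose(s0, s0_diag, atol=_S0_CONSISTENCY_RTOL * scale)
        and np.allclose(s0, s0_circ, atol=_S0_CONSISTENCY_RTOL * scale)
    )
    if not consistent:
        warnings.warn("S0 cross-check (H+V vs 45 pair vs circular pair) disagrees beyond tolerance", stacklevel=2)
    return StokesImage(
        s0=s0,
        s1=imgs["H"] - imgs["V"],
        s2=imgs["P45"] - imgs["M45"],
        s3=imgs["R"] - imgs["L"],
        s0_consistent=consistent,
    )


def signed_docp(
    i_r_out,
    i_l_out,
    incident_helicity: str,
    intensity_floor: float = DEFAULT_INTENSITY_FLOOR,
) -> DOPImage:
    """Signed circular DOP: ``sign(S3_in) * (I_R - I_L) / (I_R + I_L)``.

    Negative values mean the scattered helicity flipped relative to the
    incident circular state; positive values mean it was preserved.
    """
    if incident_helicity not in _CIRCULAR_SIGN:
        raise ValueError(f"incident helicity must be 'R' or 'L', got {incident_helicity!r}")
    i_r = _as_image(i_r_out, "I_R")
    i_l = _as_image(i_l_out, "I_L")
    _check_same_shape([i_r, i_l])
    total = i_r + i_l
    valid = _valid_from_total(total, intensity_floor)
    values = _CIRCULAR_SIGN[incident_helicity] * _safe_ratio(i_r - i_l, total, valid)
    return DOPImage(values=values, metric="circular", valid_mask=valid)


def signed_dolp(
    i_h_out,
    i_v_out,
    i_p45_out,
    i_m45_out,
    incident_hv: str,
    incident_diag: str,
    intensity_floor: float = DEFAULT_INTENSITY_FLOOR,
) -> DOPImage:
    """Signed linear DOP combining an H/V and a +-45 experiment.

    ``i_h_out``/``i_v_out`` must be analyzed under a pure H or V incident
    state and ``i_p45_out``/``i_m45_out`` under a pure +-45 incident state
    (impure incident states make the in-beam sign factors ill-defined and are
    rejected).  Per pixel::

        value = -sign(S1_in) * (I_H - I_V)/(I_H + I_V)
                + sign(S2_in) * (I_45 - I_M45)/(I_45 + I_M45)

    Pixels outside [-1, +1] (possible when both experiments pull the same
    way, e.g. an ideal mirror gives -2) are flagged, not clamped.
    """
    if incident_hv not in _HV_SIGN:
        raise ValueError(f"incident_hv must be 'H' or 'V', got {incident_hv!r}")
    if incident_diag not in _DIAG_SIGN:
        raise ValueError(f"incident_diag must be 'P45' or 'M45', got {incident_diag!r}")
    i_h = _as_image(i_h_out, "I_H")
    i_v = _as_image(i_v_out, "I_V")
    i_p = _as_image(i_p45_out, "I_P45")
    i_m = _as_image(i_m45_out, "I_M45")
    _check_same_shape([i_h, i_v, i_p, i_m])

    tot_hv = i_h + i_v
    tot_diag = i_p + i_m
    valid = _valid_from_total(tot_hv, intensity_floor) & _valid_from_total(tot_diag, intensity_floor)
    term_hv = -_HV_SIGN[incident_hv] * _safe_ratio(i_h - i_v, tot_hv, valid)
    term_diag = _DIAG_SIGN[incident_diag] * _safe_ratio(i_p - i_m, tot_diag, valid)
    values = term_hv + term_diag
    flagged = valid & (np.abs(values) > 1.0 + _RANGE_EPS)
    return DOPImage(values=values, metric="linear", valid_mask=valid, flagged=flagged)


def _generator_stokes(state: str) -> np.ndarray:
    return np.array([1.0, *UNIT_STOKES[state]])


def _analyzer_row(state: str) -> np.ndarray:
    # ideal analyzer: transmitted intensity = 1/2 (1, s_a) . S
    return 0.5 * np.array([1.0, *UNIT_STOKES[state]])


def design_matrix(scheme: Sequence[tuple[str, str]] = DEFAULT_SCHEME) -> np.ndarray:
    """16x16 design matrix mapping the row-major Mueller vector to intensities.

    Row k corresponds to scheme pair (generator g, analyzer a) and holds
    ``kron(a_row, s_g)`` so that ``I_k = D @ vec(M)``.
    """
    if len(scheme) != 16:
        raise ValueError(f"scheme must contain 16 (generator, analyzer) pairs, got {len(scheme)}")
    return np.array([np.kron(_analyzer_row(a), _generator_stokes(g)) for g, a in scheme])


def forward_intensities(m: np.ndarray, scheme: Sequence[tuple[str, str]] = DEFAULT_SCHEME) -> np.ndarray:
    """Noise-free detector intensities for Mueller field ``m`` under ``scheme``.

    ``m`` may be a single 4x4 matrix or a (rows, cols, 4, 4) field; the result
    is stacked along a leading axis of length 16 in scheme order.  This is the
    forward model that :func:`mueller_from_measurements` inverts.
    """
    m = np.asarray(m, dtype=float)
    single = m.ndim == 2
    if single:
        m = m[None, None]
    d = design_matrix(scheme)
    vec = m.reshape(*m.shape[:2], 16)
    out = np.einsum("kv,rcv->krc", d, vec)
    return out[:, 0, 0] if single else out


def mueller_from_measurements(
    mset: PolarimetricMeasurementSet,
    scheme: Sequence[tuple[str, str]] = DEFAULT_SCHEME,
    normalize: bool = False,
    intensity_floor: float = DEFAULT_INTENSITY_FLOOR,
) -> MuellerImage:
    """Per-pixel Mueller matrix by exact inversion of the 16-measurement design.

    Solves ``intensity(g, a) = a_row . (M . s_g)`` for the 16 elements of M at
    every pixel.  With ``normalize=True`` all elements are divided by M11 and
    pixels with M11 at or below the intensity floor are marked invalid.
    """
    d = design_matrix(scheme)
    cond = np.linalg.cond(d)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(f"measurement scheme {list(scheme)} is singular (condition number {cond:.3g})")
    frames = [mset.frame(g, a) for g, a in scheme]
    shape = _check_same_shape(frames)
    stack = np.stack([f.ravel() for f in frames])  # (16, npix)
    vec = np.linalg.solve(d, stack)  # (16, npix)
    m = vec.T.reshape(*shape, 4, 4)

    m11 = m[..., 0, 0]
    peak = float(np.abs(m11).max()) if m11.size else 0.0
    valid = np.abs(m11) > intensity_floor * peak
    if normalize:
        out = np.zeros_like(m)
        np.divide(m, m11[..., None, None], out=out, where=valid[..., None, None])
        return MuellerImage(m=out, normalized=True, valid_mask=valid)
    return MuellerImage(m=m, normalized=False, valid_mask=valid)


def _checked_inverse(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (4, 4):
        raise ValueError(f"{name} must be 4x4")
    cond = np.linalg.cond(mat)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(f"{name} is not invertible (condition number {cond:.3g})")
    return np.linalg.inv(mat)


def correct_beam_splitter(raw: MuellerImage, m_bs_illumination: np.ndarray, m_bs_detection: np.ndarray) -> MuellerImage:
    """Remove beam-splitter action: ``M_sample = M_det^-1 . M_raw . M_ill^-1``.

    Identity corrections return the input field bit-identically.
    """
    inv_ill = _checked_inverse(m_bs_illumination, "illumination beam-splitter matrix")
    inv_det = _checked_inverse(m_bs_detection, "detection beam-splitter matrix")
    if np.array_equal(inv_ill, np.eye(4)) and np.array_equal(inv_det, np.eye(4)):
        return MuellerImage(m=raw.m.copy(), normalized=raw.normalized, valid_mask=raw.valid_mask.copy())
    m = np.einsum("ij,rcjk,kl->rcil", inv_det, raw.m, inv_ill)
    return MuellerImage(m=m, normalized=False, valid_mask=raw.valid_mask.copy())


def total_dop_magnitude(dolp: DOPImage, docp: DOPImage) -> DOPImage:
    """Per-pixel ``(|DOLP| + |DOCP|) / 2``; valid where both inputs are valid."""
    if dolp.metric != "linear":
        raise ValueError(f"first argument must have metric 'linear', got {dolp.metric!r}")
    if docp.metric != "circular":
        raise ValueError(f"second argument must have metric 'circular', got {docp.metric!r}")
    if dolp.values.shape != docp.values.shape:
        raise ValueError("DOP images disagree on shape")
    values = 0.5 * (np.abs(dolp.values) + np.abs(docp.values))
    return DOPImage(
        values=values,
        metric="total_magnitude",
        valid_mask=dolp.valid_mask & docp.valid_mask,
    )
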