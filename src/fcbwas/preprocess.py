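"""Temporal and spatial post-processing of normalized 4D fMRI data.

Covers the in-scope cleanup applied after spatial normalization: motion
screening, linear detrending, band-pass filtering (default 0.01-0.08 Hz),
Gaussian spatial smoothing (default FWHM 8 mm), nuisance regression and
motion scrubbing.  Scanner-level steps (slice timing, realignment,
normalization) are assumed done upstream.

Conventions: time-series matrices are (n_timepoints, n_series) unless a
function says otherwise; motion parameters are per-volume translations in
mm and rotations in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
HEAD_RADIUS_MM = 50.0  # rotation -> arc-length conversion for FD


@dataclass
class MotionRecord:
    """Per-volume rigid-body motion estimates for one subject.

    translations: (T, 3) in mm; rotations: (T, 3) in degrees.
    """

    translations: np.ndarray
    rotations: np.ndarray

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, float))
        if self.translations.shape != self.rotations.shape:
            raise ValueError("translations and rotations must share shape")
        if self.translations.shape[1] != 3:
            raise ValueError("expected 3 translation and 3 rotation axes")
        if self.translations.shape[0] < 1:
            raise ValueError("empty motion series")

    @property
    def n_volumes(self) -> int:
        return self.translations.shape[0]

    def framewise_displacement(self, head_radius_mm: float = HEAD_RADIUS_MM) -> np.ndarray:
        """Power-style FD: sum of absolute backward differences of the six
        parameters, rotations converted to mm on a sphere of
        ``head_radius_mm``.  FD[0] = 0 by convention."""
        rot_mm = np.deg2rad(self.rotations) * head_radius_mm
        params = np.hstack([self.translations, rot_mm])
        fd = np.zeros(self.n_volumes)
        fd[1:] = np.abs(np.diff(params, axis=0)).sum(axis=1)
        return fd


@dataclass
class PreprocessReport:
    subject_id: str
    excluded: bool = False
    reason: str = ""
    volumes_scrubbed: list = field(default_factory=list)
    filter_band: tuple = (0.01, 0.08)


def exclude_by_motion(
    motion: MotionRecord,
    max_translation_mm: float = 3.0,
    max_rotation_deg: float = 3.0,
    measure: str = "between",
) -> bool:
    """True iff the subject exceeds the motion exclusion limits.

    ``measure="between"`` screens volume-to-volume parameter changes (the
    default reading of "maximal motion between volumes"); ``"absolute"``
    screens the raw parameter excursions.  The comparison is strictly
    greater-than, so exactly 3 mm / 3 deg is retained.
    """
    if measure == "between":
        trans = np.abs(np.diff(motion.translations, axis=0))
        rot = np.abs(np.diff(motion.rotations, axis=0))
        if trans.size == 0:  # single volume: nothing "between"
            return False
    elif measure == "absolute":
        trans = np.abs(motion.translations)
        rot = np.abs(motion.rotations)
    else:
        raise ValueError("measure must be 'between' or 'absolute'")
    return bool((trans > max_translation_mm).any() or (rot > max_rotation_deg).any())


def detrend_and_bandpass(
    series: np.ndarray,
    tr_seconds: float,
    band: tuple[float, float] = (0.01, 0.08),
    order: int = 4,
    compensate_corners: bool = True,
) -> np.ndarray:
    """Linear detrend then zero-phase Butterworth band-pass along time.

    ``series`` is (T, n_series) or (T,).  The filter runs forward and
    backward (filtfilt), which squares the magnitude response; with
    ``compensate_corners`` the design corners are pre-shifted so the
    *two-pass* response is 3 dB down exactly at the nominal band edges
    (otherwise each pass is 3 dB down there and the passband sags near
    the edges).  The band must lie inside (0, Nyquist).
    """
    series = np.asarray(series, dtype=float)
    squeeze = series.ndim == 1
    x = series[:, None] if squeeze else series
    if x.shape[0] < 20:
        raise ValueError("need at least 20 timepoints to filter")
    low, high = band
    nyquist = 0.5 / tr_seconds
    if not 0 < low < high < nyquist:
        raise ValueError(
            f"band {band} must satisfy 0 < low < high < Nyquist ({nyquist:g} Hz)"
        )
    if compensate_corners:
        shrink = (np.sqrt(2.0) - 1.0) ** (1.0 / (2 * order))
        low, high = low * shrink, min(high / shrink, nyquist * 0.999)
    x = signal.detrend(x, axis=0, type="linear")
    sos = signal.butter(
        order, (low, high), btype="bandpass", fs=1.0 / tr_seconds, output="sos"
    )
    y = signal.sosfiltfilt(sos, x, axis=0)
    return y[:, 0] if squeeze else y


def regress_nuisance(series: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """Residualize each series column against the regressors plus intercept.

    Residuals are orthogonal to every regressor column.  A rank-deficient
    design raises, naming the offending columns.
    """
    series = np.asarray(series, dtype=float)
    squeeze = series.ndim == 1
    y = series[:, None] if squeeze else series
    reg = np.atleast_2d(np.asarray(regressors, dtype=float))
    if reg.shape[0] != y.shape[0]:
        raise ValueError("regressor rows must equal timepoints")
    design = np.column_stack([np.ones(y.shape[0]), reg])
    # detect collinear/degenerate columns via the R diagonal of a QR
    r_diag = np.abs(np.diag(np.linalg.qr(design, mode="r")))
    scale = np.linalg.norm(design, axis=0)
    scale[scale == 0] = 1.0
    bad = np.flatnonzero(r_diag / scale < 1e-10)
    if bad.size:
        cols = [("intercept" if b == 0 else f"regressor {b - 1}") for b in bad]
        raise ValueError(f"rank-deficient nuisance design; collinear: {cols}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return resid[:, 0] if squeeze else resid


def scrub(
    series: np.ndarray,
    fd: np.ndarray,
    fd_threshold_mm: float = 0.5,
    n_back: int = 1,
    n_forward: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Censor high-motion volumes (FD > threshold) and their neighbours.

    By default one volume before and two after each spike are also
    removed; pass ``n_back=0, n_forward=0`` to censor spikes only.
    Returns the censored series and the kept indices (strictly
    increasing).  Raises if every volume is censored.
    """
    series = np.asarray(series)
    fd = np.asarray(fd, dtype=float)
    if fd.shape[0] != series.shape[0]:
        raise ValueError("fd length must equal timepoints")
    spikes = np.flatnonzero(fd > fd_threshold_mm)
    censor = np.zeros(len(fd), dtype=bool)
    for s in spikes:
        censor[max(0, s - n_back) : min(len(fd), s + n_forward + 1)] = True
    kept = np.flatnonzero(~censor)
    if kept.size == 0:
        raise ValueError("all volumes censored by scrubbing")
    return series[kept], kept


def smooth_spatial(image: np.ndarray, affine: np.ndarray, fwhm_mm: float = 8.0) -> np.ndarray:
    """Gaussian-smooth each volume of a 4D image in space.

    The kernel sigma per axis is FWHM/(2*sqrt(2 ln 2)) in mm, divided by
    that axis's voxel size read off the affine.  ``fwhm_mm=0`` is the
    identity.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 4:
        raise ValueError("expected a 4D image")
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return image.copy()
    affine = np.asarray(affine, dtype=float)
    voxel_sizes = np.linalg.norm(affine[:3, :3], axis=0)
    sigma_vox = (fwhm_mm * FWHM_TO_SIGMA) / voxel_sizes
    return ndimage.gaussian_filter(image, sigma=(*sigma_vox, 0.0), mode="nearest")


def preprocess_image(
    image: np.ndarray,
    affine: np.ndarray,
    motion: MotionRecord,
    tr_seconds: float,
    nuisance: np.ndarray | None = None,
    band: tuple[float, float] = (0.01, 0.08),
    fwhm_mm: float = 8.0,
    fd_threshold_mm: float = 0.5,
    subject_id: str = "",
) -> tuple[np.ndarray | None, PreprocessReport]:
    """Run the full pipeline: detrend -> band-pass -> smooth -> nuisance -> scrub.

    Returns ``(None, report)`` if the subject fails motion exclusion.
    Nuisance regressors are band-pass filtered identically before
    regression to avoid reintroducing out-of-band variance.
    """
    report = PreprocessReport(subject_id=subject_id, filter_band=band)
    if exclude_by_motion(motion):
        report.excluded = True
        report.reason = "motion exceeds 3 mm / 3 deg"
        return None, report
    shape = image.shape
    flat = image.reshape(-1, shape[3]).T  # (T, voxels)
    flat = detrend_and_bandpass(flat, tr_seconds, band)
    image = flat.T.reshape(shape)
    image = smooth_spatial(image, affine, fwhm_mm)
    flat = image.reshape(-1, shape[3]).T
    if nuisance is not None and np.size(nuisance):
        nuis = detrend_and_bandpass(np.asarray(nuisance, float), tr_seconds, band)
        flat = regress_nuisance(flat, nuis)
    fd = motion.framewise_displacement()
    flat, kept = scrub(flat, fd, fd_threshold_mm)
    report.volumes_scrubbed = sorted(set(range(shape[3])) - set(kept.tolist()))
    out = np.moveaxis(flat, 0, -1).reshape(*shape[:3], len(kept))
    return out, report
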