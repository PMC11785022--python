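"""Single-vessel diametry from two-photon frames.

Surface vessels: average a rectangular box along the vessel axis and take the
full-width at half-maximum of the resulting intensity profile. Penetrating
vessels: threshold the sinogram of the cross-section frame in Radon space,
back-project, re-threshold, and convert the lumen area to an equivalent-circle
diameter. Frames where a measurement fails are flagged invalid and dropped
(never interpolated); the drop count is part of the QC output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.registration import phase_cross_correlation
from skimage.transform import iradon, radon

from .errors import MeasurementError, ParameterError

RADON_THRESHOLD_DEFAULT = 0.5
IMAGE_THRESHOLD_DEFAULT = 0.18


@dataclass
class VesselROI:
    """Frames plus geometry for one vessel measurement."""

    frames: np.ndarray  # (n_frames, h, w)
    kind: str  # "surface_profile" | "cross_section"
    pixel_size_um: float
    box: tuple[int, int, int, int] | None = None  # (row0, row1, col0, col1)
    baseline_window_s: tuple[float, float] | None = None
    fs: float = 30.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size must be positive")
        if self.box is not None:
            r0, r1, c0, c1 = self.box
            h, w = self.frames.shape[1:]
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise ParameterError("box outside frame bounds")


@dataclass
class DiameterTrace:
    """Diameter per frame with percent change and resting variance."""

    diameter_um: np.ndarray
    percent_change: np.ndarray
    baseline_um: float
    resting_variance: float  # %^2, NaN when no rest events
    n_invalid: int = 0


# ---------------------------------------------------------------------------
# per-frame measurements
# ---------------------------------------------------------------------------

def fwhm_diameter(profile: np.ndarray, pixel_size_um: float = 1.0) -> float:
    """Full-width-at-half-maximum diameter of a 1-D lumen intensity profile.

    Background is the mean of the outer 10% of samples; half-height is
    background + 0.5 * (peak - background). Crossings are located with
    sub-pixel linear interpolation. Raises MeasurementError when either
    crossing is absent.
    """
    p = np.asarray(profile, dtype=float)
    if p.size < 5:
        raise ParameterError("profile too short")
    n_edge = max(1, int(round(0.05 * p.size)))
    background = float(np.mean(np.concatenate([p[:n_edge], p[-n_edge:]])))
    peak_idx = int(np.argmax(p))
    peak = p[peak_idx]
    if peak <= background:
        raise MeasurementError("no lumen peak above background")
    half = background + 0.5 * (peak - background)

    left = _crossing(p, peak_idx, half, direction=-1)
    right = _crossing(p, peak_idx, half, direction=+1)
    return (right - left) * pixel_size_um


def _crossing(p: np.ndarray, start: int, level: float, direction: int) -> float:
    """Sub-pixel position where p crosses `level` walking from `start`."""
    i = start
    while 0 <= i + direction < p.size:
        j = i + direction
        if p[j] < level <= p[i] or p[j] <= level < p[i]:
            frac = (p[i] - level) / (p[i] - p[j])
            return i + direction * frac
        i = j
    raise MeasurementError("half-height crossing not found")


def tirs_diameter(
    image: np.ndarray,
    pixel_size_um: float = 1.0,
    radon_threshold: float = RADON_THRESHOLD_DEFAULT,
    image_threshold: float = IMAGE_THRESHOLD_DEFAULT,
) -> float:
    """Cross-section diameter by thresholding in Radon space.

    Radon transform over 0-179 degrees; each angle's projection is binarized
    at ``radon_threshold`` of its own maximum; the binarized sinogram is
    back-projected; the reconstruction is thresholded at ``image_threshold``
    of its maximum; the connected component containing the reconstruction
    maximum gives the lumen area A and the diameter ``2*sqrt(A/pi)``.

    Thresholding a convex lumen's projection at a fraction tau of its own
    maximum keeps the chord set where the projection exceeds tau, which for
    circular/elliptical sections shrinks every radius by sqrt(1 - tau^2);
    the returned diameter divides this bias out.

    Accuracy is validated for lumen radii of roughly 10-25 px in frames at
    least 4x the radius across; lumens filling most of the frame bias low
    because the back-projection of a binarized sinogram is peaked rather
    than flat over a wide support.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ParameterError("cross-section frame must be 2-D")
    if np.any(img < 0):
        raise ParameterError("image must be non-negative")
    # remove the background pedestal (median of a mostly-background frame)
    # so additive noise does not ramp the projections
    img = np.clip(img - np.median(img), 0.0, None)
    if img.sum() <= 0:
        raise MeasurementError("empty sinogram")
    # align the lumen centroid with the projection rotation center (n//2);
    # an off-center lumen smears the per-angle projections and biases the
    # thresholded widths low
    com = ndimage.center_of_mass(img)
    shift = (img.shape[0] // 2 - int(round(com[0])), img.shape[1] // 2 - int(round(com[1])))
    if shift != (0, 0):
        img = ndimage.shift(img, shift, order=0, mode="constant")
    theta = np.arange(180.0)
    sino = radon(img, theta=theta, circle=False)
    colmax = sino.max(axis=0)
    if np.all(colmax <= 0):
        raise MeasurementError("empty sinogram")
    binarized = (sino >= radon_threshold * colmax[None, :]).astype(float)
    recon = iradon(binarized, theta=theta, circle=False, filter_name="ramp")
    recon = recon[: img.shape[0], : img.shape[1]]
    mask = recon >= image_threshold * recon.max()
    if not mask.any():
        raise MeasurementError("empty component after image threshold")
    labels = cc_label(mask)
    seed = np.unravel_index(np.argmax(recon), recon.shape)
    lab = labels[seed]
    if lab == 0:
        raise MeasurementError("reconstruction maximum outside any component")
    area = float(np.sum(labels == lab))
    calibration = np.sqrt(1.0 - radon_threshold**2)
    return 2.0 * np.sqrt(area / np.pi) / calibration * pixel_size_um


# ---------------------------------------------------------------------------
# frame registration and trace-level processing
# ---------------------------------------------------------------------------

def register_frames(frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rigid integer-pixel x-y registration of each frame to the median frame.

    Returns (registered_frames, shifts) where shifts has shape (n, 2).
    """
    frames = np.asarray(frames, dtype=float)
    ref = np.median(frames, axis=0)
    out = np.empty_like(frames)
    shifts = np.zeros((frames.shape[0], 2), dtype=int)
    for i, fr in enumerate(frames):
        shift, _, _ = phase_cross_correlation(ref, fr, upsample_factor=1)
        shift = np.round(shift).astype(int)
        out[i] = ndimage.shift(fr, shift, order=0, mode="nearest")
        shifts[i] = shift
    return out, shifts


def measure_roi(
    roi: VesselROI,
    register: bool = True,
    radon_threshold: float = RADON_THRESHOLD_DEFAULT,
    image_threshold: float = IMAGE_THRESHOLD_DEFAULT,
) -> tuple[np.ndarray, int]:
    """Per-frame diameters (um) for a VesselROI; invalid frames are NaN.

    Returns (diameters, n_invalid).
    """
    frames = roi.frames
    if register and frames.shape[0] > 1:
        frames, _ = register_frames(frames)
    diam = np.full(frames.shape[0], np.nan)
    n_invalid = 0
    for i, fr in enumerate(frames):
        try:
            if roi.kind == "surface_profile":
                r0, r1, c0, c1 = roi.box if roi.box else (0, fr.shape[0], 0, fr.shape[1])
                profile = fr[r0:r1, c0:c1].mean(axis=0)
                diam[i] = fwhm_diameter(profile, roi.pixel_size_um)
            elif roi.kind == "cross_section":
                diam[i] = tirs_diameter(
                    fr, roi.pixel_size_um, radon_threshold, image_threshold
                )
            else:
                raise ParameterError(f"unknown ROI kind {roi.kind!r}")
        except MeasurementError:
            n_invalid += 1
    return diam, n_invalid


def summarize_trace(
    diameter_um: np.ndarray,
    fs: float,
    rest_events: list[tuple[float, float]],
    baseline_window_s: tuple[float, float] | None = None,
    min_rest_s: float = 10.0,
) -> DiameterTrace:
    """Percent-change trace and resting variance for a diameter time series.

    ``percent_change = 100 * (d - d0) / d0`` with d0 the baseline mean
    (baseline window, else the whole-trace mean of valid frames).
    ``resting_variance`` is the mean across rest events (>= 10 s) of the
    per-event variance of percent_change; NaN when no rest events qualify.
    """
    d = np.asarray(diameter_um, dtype=float)
    valid = ~np.isnan(d)
    if baseline_window_s is not None:
        a, b = (int(round(t * fs)) for t in baseline_window_s)
        base_sel = np.zeros(d.size, dtype=bool)
        base_sel[a:b] = True
        base_sel &= valid
    else:
        base_sel = valid
    if not base_sel.any():
        raise MeasurementError("no valid frames for baseline")
    d0 = float(np.mean(d[base_sel]))
    pct = 100.0 * (d - d0) / d0

    variances = []
    for t0, t1 in rest_events:
        if t1 - t0 < min_rest_s:
            continue
        a, b = int(round(t0 * fs)), int(round(t1 * fs))
        seg = pct[a:b]
        seg = seg[~np.isnan(seg)]
        if seg.size >= 2:
            variances.append(float(np.var(seg)))
    resting_variance = float(np.mean(variances)) if variances else float("nan")
    return DiameterTrace(
        diameter_um=d,
        percent_change=pct,
        baseline_um=d0,
        resting_variance=resting_variance,
        n_invalid=int(np.sum(~valid)),
    )
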