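"""Peak detection, deconvolution and quantifier-ion (EIC) extraction.

Scan-level input is a ``(scan_times, mz_axis, intensity)`` triple with
``intensity`` of shape (n_scans, n_mz) on a uniform scan grid — the layout
produced by :func:`oocyteflux.simulate.render_scans` or readable from a wide
CSV. Detection follows the classic slope-threshold scheme: the smoothed,
baseline-subtracted total ion chromatogram (TIC) must rise faster than
``slope_threshold`` into an apex; retained peaks must clear the printed
minimum height (500), area (1,000), width (5 scans) and purity-factor (2)
thresholds.

Numerical choices the upstream software leaves unstated, fixed here:
smoothing is a 5-point moving average (tied to the minimum peak width);
baseline is a 51-scan rolling minimum; symmetry is the smaller-to-larger
ratio of the half-areas about the peak centroid (threshold 0.5); the purity
factor of an isolated component is reported as the sentinel 1e6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal
from scipy.ndimage import minimum_filter1d
from scipy.optimize import nnls

from .library import SCAN_MZ_MAX, SCAN_MZ_MIN
from .rindex import RICalibration, assign_ri, invert_ri

__all__ = ["PeakDetectionParams", "DetectedPeak", "EICResult",
           "detect_peaks", "deconvolve", "extract_eic_height",
           "PURITY_SENTINEL"]

PURITY_SENTINEL = 1.0e6

_SMOOTH_WINDOW = 5
_BASELINE_WINDOW = 51


@dataclass(frozen=True)
class PeakDetectionParams:
    """Peak-detection thresholds (arbitrary MS abundance units)."""

    slope_threshold: float = 200.0   # abundance units / scan
    min_area: float = 1000.0
    min_height: float = 500.0
    min_purity_factor: float = 2.0
    min_width_scans: int = 5
    min_symmetry: float = 0.5

    def __post_init__(self) -> None:
        for name in ("slope_threshold", "min_area", "min_height",
                     "min_purity_factor", "min_width_scans"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class DetectedPeak:
    apex_time_s: float
    apex_scan: int
    height: float
    area: float
    width_scans: int
    purity_factor: float
    symmetry: float
    spectrum: tuple[tuple[int, float], ...]  # baseline-subtracted, at apex
    region: tuple[int, int] = (0, 0)
    assigned_ri: float | None = None
    ri_extrapolated: bool = False


def _smooth(x: np.ndarray, window: int = _SMOOTH_WINDOW) -> np.ndarray:
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="same")


def _baseline(x: np.ndarray, window: int = _BASELINE_WINDOW) -> np.ndarray:
    return minimum_filter1d(x, size=window, mode="nearest")


def _apex_spectrum(intensity: np.ndarray, mz_axis: np.ndarray,
                   scan: int) -> tuple[tuple[int, float], ...]:
    base = np.minimum(intensity[0], intensity[-1])  # per-channel region floor
    spec = intensity[scan] - base
    spec[spec < 0] = 0.0
    keep = spec > 1e-9 * max(spec.max(), 1.0)
    return tuple((int(mz), float(v))
                 for mz, v in zip(mz_axis[keep], spec[keep]))


def _region_bounds(sig: np.ndarray, apex: int) -> tuple[int, int]:
    """Expand from the apex to the surrounding local minima / near-zero."""
    floor = 0.01 * sig[apex]
    lo = apex
    while lo > 0 and sig[lo - 1] <= sig[lo] * 1.001 and sig[lo - 1] > floor:
        lo -= 1
    hi = apex
    n = sig.size
    while hi < n - 1 and sig[hi + 1] <= sig[hi] * 1.001 and sig[hi + 1] > floor:
        hi += 1
    return lo, hi


def _symmetry(sig: np.ndarray, lo: int, hi: int) -> float:
    seg = sig[lo:hi + 1]
    total = seg.sum()
    if total <= 0:
        return 0.0
    scans = np.arange(lo, hi + 1)
    centroid = float((seg * scans).sum() / total)
    on_centre = np.isclose(scans, centroid)
    left = seg[(scans < centroid) & ~on_centre].sum() \
        + 0.5 * seg[on_centre].sum()
    right = seg[(scans > centroid) & ~on_centre].sum() \
        + 0.5 * seg[on_centre].sum()
    if max(left, right) == 0:
        return 0.0
    return float(min(left, right) / max(left, right))


def detect_peaks(run_scans, params: PeakDetectionParams | None = None,
                 calib: RICalibration | None = None) -> list[DetectedPeak]:
    """Detect peaks on the TIC of scan-level data.

    A peak is a maximal region whose smoothed, baseline-subtracted TIC rises
    into an apex with slope exceeding ``slope_threshold`` at some point of the
    rising flank; candidates failing the minimum height, trapezoidal area or
    scan-width thresholds are dropped. When a calibration is supplied each
    retained peak carries its assigned retention index.
    """
    params = params or PeakDetectionParams()
    times, mz_axis, intensity = run_scans
    if intensity.size == 0:
        return []
    dt = times[1] - times[0] if times.size > 1 else 1.0
    if times.size > 2 and not np.allclose(np.diff(times), dt, rtol=1e-6):
        raise ValueError("scan grid must be uniform")
    tic = intensity.sum(axis=1)
    raw = tic - _baseline(tic)        # heights/areas from the raw TIC
    raw[raw < 0] = 0.0
    sig = _smooth(tic) - _baseline(_smooth(tic))   # detection on smoothed
    sig[sig < 0] = 0.0

    apexes, _ = _signal.find_peaks(sig, height=params.min_height)
    peaks: list[DetectedPeak] = []
    for apex in apexes:
        lo, hi = _region_bounds(sig, apex)
        rising = np.diff(sig[lo:apex + 1])
        if rising.size == 0 or rising.max() < params.slope_threshold:
            continue
        apex = lo + int(np.argmax(raw[lo:hi + 1]))  # refine on raw TIC
        height = float(raw[apex])
        area = float(np.trapezoid(raw[lo:hi + 1]))
        width = int(np.count_nonzero(raw[lo:hi + 1] >= 0.5 * height))
        if height < params.min_height or area < params.min_area \
                or width < params.min_width_scans:
            continue
        ri = riflag = None
        if calib is not None:
            ri, riflag = assign_ri(float(times[apex]), calib, with_flag=True)
        peaks.append(DetectedPeak(
            apex_time_s=float(times[apex]), apex_scan=int(apex),
            height=height, area=area, width_scans=width,
            purity_factor=PURITY_SENTINEL,
            symmetry=_symmetry(sig, lo, hi),
            spectrum=_apex_spectrum(intensity[lo:hi + 1], mz_axis,
                                    apex - lo),
            region=(lo, hi), assigned_ri=ri,
            ri_extrapolated=bool(riflag) if riflag is not None else False))

    # purity: co-eluting apexes sharing a region compete head-to-head
    for i, p in enumerate(peaks):
        rivals = [q.height for j, q in enumerate(peaks) if j != i
                  and not (q.region[1] < p.region[0]
                           or q.region[0] > p.region[1])]
        if rivals:
            p.purity_factor = float(p.height / max(rivals))
    return peaks


def deconvolve(run_scans, peak_region: tuple[int, int]):
    """Separate co-eluting components inside one detected region.

    Each local maximum of the region's TIC defines a component, modelled as a
    unit-height Gaussian at its apex; every m/z trace is attributed to the
    components by non-negative least squares. Returns a list of dicts with
    ``apex_scan``, ``height``, ``purity_factor`` and ``spectrum``.
    """
    times, mz_axis, intensity = run_scans
    lo, hi = peak_region
    seg = intensity[lo:hi + 1]
    tic = seg.sum(axis=1)
    if tic.size == 0 or tic.max() <= 0:
        return []

    # component apexes from the individual m/z traces (the TIC alone cannot
    # resolve components a couple of scans apart), clustered to 1 scan
    cand = []
    floor = 0.01 * seg.max()
    for k in range(mz_axis.size):
        y = seg[:, k]
        if y.max() <= floor:
            continue
        local, _ = _signal.find_peaks(y)
        if local.size == 0:
            local = np.array([int(np.argmax(y))])
        cand.extend(int(i) for i in local if y[i] > floor)
    if not cand:
        cand = [int(np.argmax(tic))]
    cand.sort()
    apexes = []
    for c in cand:
        if apexes and c - apexes[-1][-1] <= 1:
            apexes[-1].append(c)
        else:
            apexes.append([c])
    apexes = np.array([int(round(np.mean(group))) for group in apexes])

    # width estimate from the tallest single m/z trace — a single channel
    # follows one component's shape, unlike the merged TIC
    k_top = int(np.argmax(seg.max(axis=0)))
    y = seg[:, k_top]
    top = int(np.argmax(y))
    half = 0.5 * y[top]
    below = y[:top + 1] < half
    lw = top - int(np.argmax(below[::-1])) if below.any() else 0
    sigma = max((top - lw) / 1.177, 1.5)

    scans = np.arange(tic.size)
    models = np.stack([np.exp(-0.5 * ((scans - a) / sigma) ** 2)
                       for a in apexes], axis=1)
    spectra = np.zeros((apexes.size, mz_axis.size))
    singular = False
    for k in range(mz_axis.size):
        y = seg[:, k]
        if y.max() <= 0:
            continue
        try:
            coef, _ = nnls(models, y)
        except RuntimeError:
            singular = True
            coef = np.zeros(apexes.size)
            coef[np.argmin(np.abs(apexes[:, None] - np.argmax(y)), axis=0)
                 if apexes.size else 0] = y.max()
        spectra[:, k] = coef
    if singular:
        warnings.warn("NNLS deconvolution failed for some traces; "
                      "fell back to apex-spectrum attribution", stacklevel=2)

    heights = spectra.sum(axis=1)
    out = []
    for i, a in enumerate(apexes):
        rivals = np.delete(heights, i)
        purity = PURITY_SENTINEL if rivals.size == 0 or rivals.max() <= 0 \
            else float(heights[i] / rivals.max())
        keep = spectra[i] > 1e-9 * max(spectra[i].max(), 1.0)
        spec = tuple((int(mz), float(v))
                     for mz, v in zip(mz_axis[keep], spectra[i][keep]))
        out.append({"apex_scan": int(a + lo), "height": float(heights[i]),
                    "purity_factor": purity, "spectrum": spec})
    return out


@dataclass(frozen=True)
class EICResult:
    height: float
    censored: bool
    source: str = ""


def extract_eic_height(run, quantifier_mz: int, expected_ri: float,
                       calib: RICalibration, ri_window: float = 4.0,
                       floor: float = 500.0) -> EICResult:
    """Height of the quantifier-ion trace at the expected retention index.

    ``run`` may be a peak-level :class:`~oocyteflux.simulate.ChromatogramRun`
    (the quantifier trace height is peak height x relative intensity at the
    quantifier m/z) or a scan-level triple (maximum baseline-subtracted
    intensity of the m/z channel inside the RI window). Heights below the
    detection floor are reported at the floor with a censoring flag.
    """
    if not (SCAN_MZ_MIN <= quantifier_mz <= SCAN_MZ_MAX):
        raise ValueError(f"quantifier m/z {quantifier_mz} outside scan range")
    if hasattr(run, "peaks"):  # peak-level representation
        best = 0.0
        for peak in run.peaks:
            ri = assign_ri(peak.apex_time_s, calib)
            if abs(ri - expected_ri) > ri_window:
                continue
            rel = dict(peak.spectrum).get(quantifier_mz, 0.0)
            best = max(best, peak.height * rel)
        if best < floor:
            return EICResult(height=floor, censored=True, source="peaks")
        return EICResult(height=float(best), censored=False, source="peaks")

    times, mz_axis, intensity = run
    t_lo = invert_ri(expected_ri - ri_window, calib)
    t_hi = invert_ri(expected_ri + ri_window, calib)
    col = int(np.searchsorted(mz_axis, quantifier_mz))
    if col >= mz_axis.size or mz_axis[col] != quantifier_mz:
        return EICResult(height=floor, censored=True, source="scans")
    trace = intensity[:, col]
    trace = trace - _baseline(trace)
    mask = (times >= t_lo) & (times <= t_hi)
    best = float(trace[mask].max()) if mask.any() else 0.0
    if best < floor:
        return EICResult(height=floor, censored=True, source="scans")
    return EICResult(height=best, censored=False, source="scans")
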