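"""Emission-anisotropy TIRF analysis of focal-adhesion orientational order.

The pipeline mirrors standard polarized-emission workflows: a fluorescein
calibration pair yields the detection G-factor; per-pixel anisotropy is
r = (I_pa - G*I_pe) / (I_pa + 2*G*I_pe); focal adhesions are segmented from
a background-subtracted paxillin channel with a moment-preserving
("Moments") threshold; each adhesion contributes its mean anisotropy and
the angle theta of its long axis to the excitation polarization (the image
x-axis, theta in [0, 180) degrees).  Binning mean anisotropies into twelve
15-degree bins and fitting

    r(theta) = A * cos^2(theta + p) + C

gives the orientational-order amplitude A, phase p and background offset C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from skimage import measure

__all__ = [
    "PolarizedImagePair",
    "AnisotropyMap",
    "FARecord",
    "ModulationFit",
    "SIZE_BIN_EDGES",
    "estimate_background",
    "threshold_moments",
    "compute_g_factor",
    "register_pair",
    "anisotropy_map",
    "segment_fas",
    "fa_properties",
    "filter_fas",
    "assign_size_bin",
    "bin_and_fit",
    "size_binned_fits",
]

#: FA size classes (um^2): small [0.1, 0.25), medium [0.25, 1), large [1, 5]
SIZE_BIN_EDGES = (0.1, 0.25, 1.0, 5.0)


@dataclass
class PolarizedImagePair:
    """Co-registered parallel/perpendicular emission rasters (counts)."""

    i_pa: np.ndarray
    i_pe: np.ndarray
    pixel_size: float = 0.1  # um/px
    polarization_axis: str = "x"

    def __post_init__(self) -> None:
        self.i_pa = np.asarray(self.i_pa, dtype=float)
        self.i_pe = np.asarray(self.i_pe, dtype=float)
        if self.i_pa.shape != self.i_pe.shape:
            raise ValueError("parallel and perpendicular channels must share a shape")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be positive")
        if np.any(self.i_pa < 0) or np.any(self.i_pe < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class AnisotropyMap:
    """Per-pixel anisotropy with the G-factor used; NaN marks undefined pixels."""

    r: np.ndarray
    g_factor: float

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.r)


@dataclass
class FARecord:
    """One segmented focal adhesion."""

    label: int
    area: float            # um^2
    orientation: float     # deg in [0, 180) from the polarization axis
    eccentricity: float
    mean_r: float
    size_bin: str | None = None
    touches_border: bool = False

    @property
    def valid(self) -> bool:
        return np.isfinite(self.mean_r)


@dataclass
class ModulationFit:
    """Fitted cos^2 modulation of mean FA anisotropy versus orientation."""

    amplitude: float
    phase: float           # deg, modulo 180
    offset: float
    r_squared: float
    n_fas: int
    bin_centers: np.ndarray = field(default_factory=lambda: np.array([]))
    bin_means: np.ndarray = field(default_factory=lambda: np.array([]))
    bin_sds: np.ndarray = field(default_factory=lambda: np.array([]))
    bin_counts: np.ndarray = field(default_factory=lambda: np.array([]))

    def predict(self, theta_deg) -> np.ndarray:
        th = np.deg2rad(np.asarray(theta_deg, dtype=float) + self.phase)
        return self.amplitude * np.cos(th) ** 2 + self.offset


# ---------------------------------------------------------------------------
# background and thresholding primitives
# ---------------------------------------------------------------------------

def estimate_background(image: np.ndarray, kappa: float = 3.0,
                        iters: int = 5) -> float:
    """Iterative sigma-clipped background level.

    Repeatedly rejects pixels more than ``kappa`` standard deviations from
    the median of the kept set and returns the final median.
    """
    vals = np.asarray(image, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("cannot estimate background of an empty image")
    for _ in range(iters):
        med = np.median(vals)
        sd = np.std(vals)
        if sd == 0:
            break
        kept = vals[np.abs(vals - med) <= kappa * sd]
        if kept.size == vals.size or kept.size == 0:
            break
        vals = kept
    return float(np.median(vals))


def threshold_moments(image: np.ndarray, nbins: int = 256) -> float:
    """Tsai moment-preserving ("Moments") threshold.

    Chooses the threshold so that a two-level image with the appropriate
    below/above fractions preserves the first three gray-level moments of
    the input.  Returns a threshold in image units; pixels strictly above
    it are foreground.
    """
    vals = np.asarray(image, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return lo
    hist, edges = np.histogram(vals, bins=nbins, range=(lo, hi))
    p = hist.astype(float) / hist.sum()
    z = 0.5 * (edges[:-1] + edges[1:])
    m1 = float(np.sum(p * z))
    m2 = float(np.sum(p * z**2))
    m3 = float(np.sum(p * z**3))
    cd = m2 - m1 * m1
    if cd <= 0:
        return lo
    # z0, z1 are the two representative levels preserving m1..m3
    c0 = (m1 * m3 - m2 * m2) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = max(c1 * c1 - 4.0 * c0, 0.0)
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        return lo
    p0 = (z1 - m1) / (z1 - z0)  # fraction of pixels assigned below threshold
    p0 = min(max(p0, 0.0), 1.0)
    cum = np.cumsum(p)
    idx = int(np.searchsorted(cum, p0))
    idx = min(idx, nbins - 1)
    thr = edges[idx + 1]
    # with a gapped histogram any cut inside the gap preserves the moments;
    # place it mid-gap so boundary pixels classify cleanly
    above = np.flatnonzero(hist[idx + 1:])
    if above.size:
        thr = 0.5 * (thr + edges[idx + 1 + above[0]])
    return float(thr)


# ---------------------------------------------------------------------------
# calibration, registration, anisotropy
# ---------------------------------------------------------------------------

def compute_g_factor(pair: PolarizedImagePair, background_floor: float = 0.0) -> float:
    """G-factor from a uniform (fluorescein-like) calibration pair.

    Robust central value: the median of per-pixel I_pa/I_pe over pixels with
    both channels above ``background_floor``.
    """
    keep = (pair.i_pa > background_floor) & (pair.i_pe > background_floor)
    if not keep.any():
        raise ValueError("calibration pair has no pixels above the background floor")
    return float(np.median(pair.i_pa[keep] / pair.i_pe[keep]))


def register_pair(pair: PolarizedImagePair, min_correlation: float = 0.2
                  ) -> tuple[PolarizedImagePair, tuple[int, int]]:
    """Translational registration of I_pe onto I_pa.

    Finds the integer-pixel circular shift maximizing the normalized
    cross-correlation between the zero-mean channels (FFT-based).  If the
    correlation peak is weaker than ``min_correlation`` the identity
    transform is applied with a warning.  Returns the registered pair and
    the recovered (row, col) shift.
    """
    a = pair.i_pa - pair.i_pa.mean()
    b = pair.i_pe - pair.i_pe.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        warnings.warn("flat channel; registration skipped", stacklevel=2)
        return pair, (0, 0)
    xc = np.real(np.fft.ifft2(np.fft.fft2(a) * np.conj(np.fft.fft2(b)))) / denom
    peak = np.unravel_index(int(np.argmax(xc)), xc.shape)
    if xc[peak] < min_correlation:
        warnings.warn(
            f"registration correlation {xc[peak]:.3f} below {min_correlation}; "
            "applying identity transform",
            stacklevel=2,
        )
        return pair, (0, 0)
    shift = tuple(
        int(s if s <= n // 2 else s - n) for s, n in zip(peak, a.shape)
    )
    registered = np.roll(pair.i_pe, shift, axis=(0, 1))
    out = PolarizedImagePair(pair.i_pa, registered, pair.pixel_size,
                             pair.polarization_axis)
    return out, shift


def anisotropy_map(pair: PolarizedImagePair, g_factor: float) -> AnisotropyMap:
    """Per-pixel emission anisotropy r = (I_pa - G*I_pe)/(I_pa + 2*G*I_pe).

    Pixels with non-positive denominator are undefined (NaN).
    """
    if not (g_factor > 0):
        raise ValueError("G-factor must be positive")
    denom = pair.i_pa + 2.0 * g_factor * pair.i_pe
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (pair.i_pa - g_factor * pair.i_pe) / denom
    r = np.where(denom > 0, r, np.nan)
    return AnisotropyMap(r=r, g_factor=float(g_factor))


# ---------------------------------------------------------------------------
# segmentation and per-FA properties
# ---------------------------------------------------------------------------

def segment_fas(paxillin: np.ndarray, kappa: float = 3.0, iters: int = 5,
                median_prefilter: bool = False) -> np.ndarray:
    """Label focal adhesions in a paxillin channel.

    Background (iterative sigma-clip) is subtracted, the moment-preserving
    threshold binarizes, and 8-connected components are labeled.  A blank
    image yields zero labels.
    """
    img = np.asarray(paxillin, dtype=float)
    if median_prefilter:
        img = ndimage.median_filter(img, size=3)
    sub = img - estimate_background(img, kappa=kappa, iters=iters)
    if np.all(sub == sub.ravel()[0]):
        return np.zeros(img.shape, dtype=np.int32)
    thr = threshold_moments(sub)
    binary = sub > thr
    return measure.label(binary, connectivity=2).astype(np.int32)


def _orientation_from_x(props) -> float:
    """Angle of the region's major axis to the image x-axis, deg in [0, 180).

    skimage measures orientation from the row axis in (row, col)
    coordinates; with rows pointing down, the angle measured from the
    column (x) axis, counterclockwise on screen, is 90 deg plus that value.
    Negative results map up by 180 into [0, 180).
    """
    theta = 90.0 + np.rad2deg(props.orientation)
    return float(np.mod(theta, 180.0))


def fa_properties(labels: np.ndarray, r_map: AnisotropyMap, pixel_size: float,
                  exclude_border: bool = True) -> list[FARecord]:
    """Per-component area, orientation, eccentricity and mean anisotropy.

    Components whose anisotropy is undefined everywhere are flagged
    (``mean_r`` NaN) so downstream filtering drops them.  Border-touching
    components are marked; by default they are excluded later because their
    moment-based orientation is biased.
    """
    if labels.shape != r_map.r.shape:
        raise ValueError("labels and anisotropy map must share a shape")
    if not (pixel_size > 0):
        raise ValueError("pixel_size must be positive")
    records = []
    nrow, ncol = labels.shape
    for props in measure.regionprops(labels):
        rr, cc = props.coords[:, 0], props.coords[:, 1]
        vals = r_map.r[rr, cc]
        vals = vals[np.isfinite(vals)]
        mean_r = float(vals.mean()) if vals.size else float("nan")
        touches = bool(
            (props.bbox[0] == 0) or (props.bbox[1] == 0)
            or (props.bbox[2] == nrow) or (props.bbox[3] == ncol)
        )
        area = props.num_pixels * pixel_size**2
        rec = FARecord(
            label=int(props.label),
            area=float(area),
            orientation=_orientation_from_x(props),
            eccentricity=float(props.eccentricity),
            mean_r=mean_r,
            size_bin=assign_size_bin(area),
            touches_border=touches,
        )
        if not (exclude_border and touches):
            records.append(rec)
    return records


def assign_size_bin(area: float) -> str | None:
    """Size class for an FA area (um^2); edges are left-closed."""
    lo, mid1, mid2, hi = SIZE_BIN_EDGES
    if lo <= area < mid1:
        return "small"
    if mid1 <= area < mid2:
        return "medium"
    if mid2 <= area <= hi:
        return "large"
    return None


def filter_fas(records: Sequence[FARecord], area_min: float = 0.1,
               area_max: float = 5.0, ecc_max: float = 0.9) -> list[FARecord]:
    """Retain FAs with area in [area_min, area_max] and eccentricity < ecc_max.

    ``ecc_max=0.7`` reproduces the stricter blebbistatin-washout setting.
    Records with undefined mean anisotropy are dropped as well.
    """
    return [
        r for r in records
        if r.valid and area_min <= r.area <= area_max and r.eccentricity < ecc_max
    ]


# ---------------------------------------------------------------------------
# modulation fit
# ---------------------------------------------------------------------------

def _cos2(theta_deg, amplitude, phase_deg, offset):
    return amplitude * np.cos(np.deg2rad(theta_deg + phase_deg)) ** 2 + offset


def bin_and_fit(records: Sequence[FARecord], bin_width: float = 15.0,
                min_bins: int = 4) -> ModulationFit:
    """Bin mean anisotropies by orientation and fit the cos^2 law.

    Twelve ``bin_width``-degree bins cover [0, 180); the least-squares fit
    (multi-start over initial phases 0/45/90/135 deg to dodge the cos^2
    local minima) runs on the bin means, as does the reported R^2.  The
    amplitude is reported non-negative with the phase folded modulo 180.
    Fewer than ``min_bins`` non-empty bins refuses the fit.
    """
    records = [r for r in records if r.valid]
    n_bins = int(round(180.0 / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    theta = np.mod(np.asarray([r.orientation for r in records], dtype=float), 180.0)
    vals = np.asarray([r.mean_r for r in records], dtype=float)
    idx = np.clip(np.floor(theta / bin_width).astype(int), 0, n_bins - 1)
    means = np.full(n_bins, np.nan)
    sds = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = vals[idx == b]
        counts[b] = sel.size
        if sel.size:
            means[b] = sel.mean()
            sds[b] = sel.std(ddof=1) if sel.size > 1 else 0.0
    filled = np.isfinite(means)
    if filled.sum() < min_bins:
        raise ValueError(
            f"modulation fit refused: only {int(filled.sum())} non-empty "
            f"orientation bins (need >= {min_bins}); bin counts {counts.tolist()}"
        )
    xb, yb = centers[filled], means[filled]
    span = float(yb.max() - yb.min())
    best = None
    for p0 in (0.0, 45.0, 90.0, 135.0):
        try:
            popt, _ = curve_fit(
                _cos2, xb, yb, p0=(max(span, 1e-6), p0, float(yb.min())),
                maxfev=10_000,
            )
        except RuntimeError:
            continue
        ssr = float(np.sum((_cos2(xb, *popt) - yb) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt)
    if best is None:
        raise RuntimeError("modulation fit failed to converge from all starts")
    ssr, (amp, phase, offset) = best
    if amp < 0:  # cos^2 degeneracy: -A*cos^2(t+p) + C == |A|*cos^2(t+p+90) + C - |A|
        amp, phase, offset = -amp, phase + 90.0, offset + amp
    phase = float(np.mod(phase, 180.0))
    sst = float(np.sum((yb - yb.mean()) ** 2))
    r_squared = 1.0 - ssr / sst if sst > 0 else 1.0
    return ModulationFit(
        amplitude=float(amp), phase=phase, offset=float(offset),
        r_squared=float(r_squared), n_fas=len(records),
        bin_centers=centers, bin_means=means, bin_sds=sds, bin_counts=counts,
    )


def size_binned_fits(records: Sequence[FARecord], bin_width: float = 15.0
                     ) -> dict[str, ModulationFit | str]:
    """Independent modulation fits for the small/medium/large FA classes.

    An under-filled class maps to a string explaining why the fit is absent
    rather than to a silent zero.
    """
    out: dict[str, ModulationFit | str] = {}
    for name in ("small", "medium", "large"):
        subset = [r for r in records if r.size_bin == name]
        if not subset:
            out[name] = "absent: no FAs in this size class"
            continue
        try:
            out[name] = bin_and_fit(subset, bin_width=bin_width)
        except (ValueError, RuntimeError) as exc:
            out[name] = f"absent: {exc}"
    return out
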