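"""Synthetic-scene generators with known ground truth.

Every stage of the imaging pipeline is testable without microscopy data:
polarized pairs are rendered by inverting the anisotropy formula, FA scenes
carry a known cos^2 orientational-order law, calibration pairs a known
polarization bias G, and cell scenes a known nuclear/cytoplasmic YAP ratio.
The detection-side bias convention makes rendering exactly inverse to the
analysis: the perpendicular channel is divided by G, so analysing with the
same G recovers the assigned anisotropy to machine precision (noiseless).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anisotropy import PolarizedImagePair

__all__ = [
    "SceneTruth",
    "FATruth",
    "render_polarized_pair",
    "generate_fa_scene",
    "generate_calibration_pair",
    "generate_cell_scene",
]


@dataclass
class FATruth:
    """Ground truth for one rendered focal adhesion."""

    center: tuple[float, float]   # (row, col) px
    semi_axes: tuple[float, float]  # (major, minor) px
    orientation: float            # deg from image x-axis, [0, 180)
    r_true: float
    area: float                   # um^2


@dataclass
class SceneTruth:
    """Parameters of a synthetic FA scene.

    ``a_true``, ``p_true``, ``c_true`` define the orientational-order law
    r(theta) = A*cos^2(theta + p) + C assigned per FA; ``peak_counts`` is
    the expected photon count at an FA peak, ``bg_counts`` the background
    level in the total-intensity channel.
    """

    n_fas: int = 200
    a_true: float = 0.2
    p_true: float = 0.0
    c_true: float = 0.1
    g_true: float = 1.0
    pixel_size: float = 0.1       # um/px
    shape: tuple[int, int] = (512, 512)
    peak_counts: float = 2000.0
    bg_counts: float = 200.0
    area_range: tuple[float, float] = (0.1, 5.0)  # um^2, log-uniform
    aspect_range: tuple[float, float] = (1.5, 2.2)
    r_scatter: float = 0.0        # per-FA Gaussian scatter on r
    noise: bool = True            # Poisson shot noise on detected channels
    seed: int = 0
    fas: list[FATruth] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.c_true and self.c_true + self.a_true <= 1.0):
            raise ValueError("need 0 <= C and C + A <= 1")
        if self.g_true <= 0:
            raise ValueError("G must be positive")


def render_polarized_pair(i_tot: np.ndarray, r: np.ndarray, g_factor: float = 1.0,
                          noise: bool = False,
                          rng: np.random.Generator | None = None,
                          pixel_size: float = 0.1) -> PolarizedImagePair:
    """Render parallel/perpendicular channels from total intensity and anisotropy.

    Noiseless physics: I_pa = I_tot*(1+2r)/3 and I_pe_true = I_tot*(1-r)/3;
    the detected perpendicular channel is I_pe_true/G (detection-side bias),
    so analysis with the same G inverts the rendering exactly.  Optional
    Poisson noise is applied to each detected channel independently.
    """
    i_tot = np.asarray(i_tot, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(i_tot < 0):
        raise ValueError("total intensity must be non-negative")
    if np.any((r <= -0.5) | (r > 1.0)):
        raise ValueError("anisotropy must lie in (-0.5, 1]")
    i_pa = i_tot * (1.0 + 2.0 * r) / 3.0
    i_pe = i_tot * (1.0 - r) / 3.0 / g_factor
    if noise:
        if rng is None:
            rng = np.random.default_rng()
        i_pa = rng.poisson(i_pa).astype(float)
        i_pe = rng.poisson(i_pe).astype(float)
    return PolarizedImagePair(i_pa, i_pe, pixel_size=pixel_size)


def _ellipse_profile(shape: tuple[int, int], center: tuple[float, float],
                     semi_axes: tuple[float, float], theta_deg: float,
                     taper: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Smooth elliptical intensity profile and its support footprint.

    Intensity is 1 inside the ellipse core and falls off as a Gaussian of
    width ``taper`` (in units of the normalized elliptical radius) outside
    it, giving the segmentation realistic gradients.  The footprint marks
    normalized radius <= 2.5, covering every pixel the segmentation can
    plausibly assign to the adhesion, so its anisotropy is painted there.
    """
    a, b = semi_axes
    cr, cc = center
    pad = int(np.ceil(max(a, b) * (1.0 + 4.0 * taper))) + 2
    r0, r1 = int(cr) - pad, int(cr) + pad + 1
    c0, c1 = int(cc) - pad, int(cc) + pad + 1
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, shape[0]), min(c1, shape[1])
    rows, cols = np.mgrid[r0:r1, c0:c1]
    # x along image columns, angle measured from the x-axis toward -rows
    # (counterclockwise on screen)
    th = np.deg2rad(theta_deg)
    u = (cols - cc) * np.cos(th) - (rows - cr) * np.sin(th)
    v = (cols - cc) * np.sin(th) + (rows - cr) * np.cos(th)
    q = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    prof = np.where(q <= 1.0, 1.0, np.exp(-0.5 * ((q - 1.0) / taper) ** 2))
    full_prof = np.zeros(shape)
    full_foot = np.zeros(shape, dtype=bool)
    full_prof[r0:r1, c0:c1] = prof
    full_foot[r0:r1, c0:c1] = q <= 2.5
    return full_prof, full_foot


def generate_fa_scene(truth: SceneTruth
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, SceneTruth]:
    """Render a focal-adhesion scene: (I_pa, I_pe, paxillin, truth).

    FAs are non-overlapping tapered ellipses with orientations uniform on
    [0, 180) and areas log-uniform over ``area_range`` (populating all three
    size classes); each FA's anisotropy follows the scene's cos^2 law plus
    optional per-FA Gaussian scatter.  Channels come from
    :func:`render_polarized_pair`; ``truth.fas`` is filled in the returned
    (deep-copied) truth.  Infeasible packing raises after bounded retries.
    """
    rng = np.random.default_rng(truth.seed)
    shape = truth.shape
    placed: list[FATruth] = []
    max_tries = 200 * truth.n_fas
    tries = 0
    lo, hi = truth.area_range
    margin = 6.0
    while len(placed) < truth.n_fas:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not pack {truth.n_fas} FAs after {max_tries} tries; "
                "reduce n_fas or enlarge the scene"
            )
        tries += 1
        area_um2 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        aspect = float(rng.uniform(*truth.aspect_range))
        area_px = area_um2 / truth.pixel_size**2
        b = np.sqrt(area_px / (np.pi * aspect))
        a = aspect * b
        theta = float(rng.uniform(0.0, 180.0))
        rad = a + margin
        cr = float(rng.uniform(rad, shape[0] - rad))
        cc = float(rng.uniform(rad, shape[1] - rad))
        ok = True
        for other in placed:
            orad = other.semi_axes[0] + margin
            if np.hypot(cr - other.center[0], cc - other.center[1]) < rad + orad:
                ok = False
                break
        if not ok:
            continue
        r_val = truth.a_true * np.cos(np.deg2rad(theta + truth.p_true)) ** 2 + truth.c_true
        if truth.r_scatter > 0:
            r_val += truth.r_scatter * rng.standard_normal()
        r_val = float(np.clip(r_val, -0.49, 1.0))
        placed.append(FATruth(center=(cr, cc), semi_axes=(a, b),
                              orientation=theta, r_true=r_val, area=area_um2))

    paxillin = np.zeros(shape)
    i_tot = np.full(shape, truth.bg_counts, dtype=float)
    r_map = np.full(shape, truth.c_true, dtype=float)
    for fa in placed:
        prof, foot = _ellipse_profile(shape, fa.center, fa.semi_axes,
                                      fa.orientation)
        paxillin += prof * truth.peak_counts
        i_tot += prof * truth.peak_counts
        r_map[foot] = fa.r_true
    pair = render_polarized_pair(i_tot, r_map, truth.g_true, noise=truth.noise,
                                 rng=rng, pixel_size=truth.pixel_size)
    if truth.noise:
        paxillin = rng.poisson(paxillin + truth.bg_counts).astype(float)
    else:
        paxillin = paxillin + truth.bg_counts
    out_truth = SceneTruth(**{**truth.__dict__, "fas": placed})
    return pair.i_pa, pair.i_pe, paxillin, out_truth


def generate_calibration_pair(g_true: float = 1.0, mean_counts: float = 1000.0,
                              noise: bool = False, seed: int = 0,
                              shape: tuple[int, int] = (256, 256),
                              pixel_size: float = 0.1) -> PolarizedImagePair:
    """Spatially uniform fluorescein-like pair with I_pa/I_pe = G in expectation.

    The sample is isotropic (r = 0), so both true channels equal
    mean_counts and only the detection bias separates them.
    """
    if not (mean_counts > 0):
        raise ValueError("mean_counts must be positive")
    i_tot = np.full(shape, 3.0 * mean_counts)
    r = np.zeros(shape)
    rng = np.random.default_rng(seed)
    return render_polarized_pair(i_tot, r, g_true, noise=noise, rng=rng,
                                 pixel_size=pixel_size)


def generate_cell_scene(nc_true: float = 2.0, shape: tuple[int, int] = (512, 512),
                        cell_axes: tuple[float, float] = (200.0, 150.0),
                        nucleus_axes: tuple[float, float] = (60.0, 50.0),
                        cyto_level: float = 100.0, bg_level: float = 10.0,
                        noise_sd: float = 2.0, seed: int = 0
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Render (yap, nucleus, actin) channels for one synthetic cell.

    A centred elliptical cell carries cytoplasmic YAP at ``cyto_level`` and
    nuclear YAP at ``nc_true * cyto_level``; the nucleus and actin channels
    mark the nucleus and cell footprints.  Returns the rasters plus a truth
    dict (masks, levels, analytic areas).
    """
    if nc_true <= 0:
        raise ValueError("nc_true must be positive")
    if nucleus_axes[0] >= cell_axes[0] or nucleus_axes[1] >= cell_axes[1]:
        raise ValueError("nucleus must fit strictly inside the cell footprint")
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    cr, cc = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    cell = ((rows - cr) / cell_axes[1]) ** 2 + ((cols - cc) / cell_axes[0]) ** 2 <= 1.0
    nucleus = ((rows - cr) / nucleus_axes[1]) ** 2 + (
        (cols - cc) / nucleus_axes[0]) ** 2 <= 1.0
    if not (nucleus & ~cell).sum() == 0:
        raise ValueError("nucleus extends outside the cell footprint")
    rng = np.random.default_rng(seed)
    yap = np.full(shape, bg_level)
    yap = np.where(cell, cyto_level, yap)
    yap = np.where(nucleus, nc_true * cyto_level, yap)
    yap = yap + noise_sd * rng.standard_normal(shape)
    nucleus_ch = np.where(nucleus, 1000.0, bg_level) + noise_sd * rng.standard_normal(shape)
    actin_ch = np.where(cell, 500.0, bg_level) + noise_sd * rng.standard_normal(shape)
    truth = {
        "nc_true": nc_true,
        "cell_mask": cell,
        "nucleus_mask": nucleus,
        "cell_area_px": int(cell.sum()),
        "cell_area_analytic_px": float(np.pi * cell_axes[0] * cell_axes[1]),
        "cyto_level": cyto_level,
    }
    return np.clip(yap, 0, None), np.clip(nucleus_ch, 0, None), np.clip(actin_ch, 0, None), truth
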