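"""Synthetic UAV hyperspectral canopy scenes with ground truth.

Emulates the structure of a nitrogen-gradient field trial so every pipeline
stage is testable end to end: a grid of fertiliser plots, each a clumpy
canopy of sunlit and shaded leaves over bright soil, leaf spectra whose
green / red-edge features co-vary with leaf nitrogen content (LNC), mixed
soil/leaf edge pixels, per-band sensor noise, and per-plot ground sampling
points with known LNC.

The leaf model is analytic, not radiative-transfer: reflectance is a convex
blend of two smooth endmember spectra (a nitrogen-poor and a nitrogen-rich
leaf built by monotone spline through anchor wavelengths), so every band is
linear and monotone in LNC.  Nitrogen-rich leaves are darker in the green
(550 nm), have deeper blue/red absorption wells and a lower, right-shifted
red edge — the chlorophyll-nitrogen link the classifier and indices exploit.
Shadows are multiplicative attenuation with slightly stronger loss in the
NIR; soil is a bright, quasi-linear ramp with no red edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import binary_dilation, gaussian_filter

from .io import SamplePoint, SpectralCube

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "MATERIAL_SOIL",
    "MATERIAL_SUNLIT",
    "MATERIAL_SHADED",
    "leaf_spectrum",
    "soil_spectrum",
    "generate_scene",
]

MATERIAL_SOIL = 0
MATERIAL_SUNLIT = 1
MATERIAL_SHADED = 2

# anchor wavelengths (nm) and endmember reflectance for nitrogen-poor (lo)
# and nitrogen-rich (hi) leaves; spectra in between are convex blends.
_LEAF_ANCHORS_NM = np.array(
    [400.0, 450.0, 500.0, 550.0, 600.0, 670.0, 700.0, 715.0, 740.0, 800.0, 860.0, 1000.0]
)
_LEAF_LO = np.array(
    [0.060, 0.048, 0.110, 0.245, 0.130, 0.060, 0.105, 0.250, 0.430, 0.480, 0.475, 0.455]
)
_LEAF_HI = np.array(
    [0.050, 0.038, 0.085, 0.210, 0.100, 0.040, 0.070, 0.155, 0.345, 0.380, 0.375, 0.360]
)

# soil ramp endpoints at 400 and 1000 nm: a bright dry field soil, clearly
# brighter than the canopy in the green so soil-contaminated pixels land in
# the top intensity levels and the green-level cascade can shed them.
_SOIL_400 = 0.20
_SOIL_1000 = 0.52

#: extra fractional attenuation of shadows in the NIR (on top of the flat
#: shade factor), ramped in with the red edge.  Scenes draw the strength
#: per pixel from _SHADE_NIR_RANGE (diffuse illumination varies from gap to
#: gap); the single-spectrum helper uses the midpoint.
_SHADE_NIR_EXTRA = 0.15
_SHADE_NIR_RANGE = (0.05, 0.30)


def default_wavelengths() -> np.ndarray:
    """270 bands at a 2.2 nm sampling interval starting at 400 nm."""
    return 400.0 + 2.2 * np.arange(270)


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions of a simulated flight scene.

    Defaults mirror a small nitrogen-rate trial: 18 plots (3 × 6 tiling of
    ``plot_size``-pixel squares) over 5 applied fertiliser levels with
    three-plus replicates, LNC in g·kg⁻¹ dry mass spanning ``lnc_range``,
    six ground sampling points per plot (108 samples per scene), clumped
    canopy covering ``canopy_cover`` of each plot with ``shadow_fraction``
    of the canopy shaded, and i.i.d. Gaussian band noise of ``noise_sd``.

    ``confounder_sd`` decouples spectra from nitrogen the way real leaves
    do: the pigment state driving the visible bands and the structure
    driving the NIR each track LNC only up to smooth, spatially clumped
    deviations of this magnitude (in units of the normalised LNC range), so
    no single index is a clean nitrogen probe and regression must combine
    several.
    """

    plot_size: int = 64
    plot_rows: int = 3
    plot_cols: int = 6
    n_levels_applied: int = 5
    lnc_range: tuple[float, float] = (25.0, 55.0)
    plot_lnc_jitter: float = 1.0
    within_plot_lnc_sd: float = 1.2
    assay_sd: float = 0.3
    confounder_sd: float = 0.18
    canopy_cover: float = 0.65
    shadow_fraction: float = 0.30
    shade_factor_range: tuple[float, float] = (0.2, 0.5)
    brightness_jitter: float = 0.30
    mixed_alpha_range: tuple[float, float] = (0.2, 0.85)
    noise_sd: float = 0.008
    samples_per_plot: int = 6
    wavelengths: np.ndarray = field(default_factory=default_wavelengths)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("canopy_cover", "shadow_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.lnc_range
        if not lo < hi:
            raise ValueError("lnc_range must satisfy lo < hi")
        if self.plot_size < 8:
            raise ValueError("grid too small: plot_size must be >= 8 pixels")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def n_plots(self) -> int:
        return self.plot_rows * self.plot_cols

    @property
    def grid(self) -> tuple[int, int]:
        return self.plot_rows * self.plot_size, self.plot_cols * self.plot_size


@dataclass
class SceneTruth:
    """Ground truth of a simulated scene."""

    material: np.ndarray  # {0 soil, 1 sunlit leaf, 2 shaded leaf} per pixel
    plot_id: np.ndarray  # plot ordinal per pixel
    lnc: np.ndarray  # per-plot mean LNC, g/kg
    lnc_map: np.ndarray  # per-pixel local LNC field
    sample_points: list[SamplePoint]

    def material_fractions(self) -> dict[str, float]:
        total = self.material.size
        return {
            "soil": float((self.material == MATERIAL_SOIL).sum() / total),
            "sunlit_leaf": float((self.material == MATERIAL_SUNLIT).sum() / total),
            "shaded_leaf": float((self.material == MATERIAL_SHADED).sum() / total),
        }


def _lnc_to_u(lnc, lnc_range) -> np.ndarray:
    lo, hi = lnc_range
    lnc = np.asarray(lnc, dtype=float)
    if np.any(lnc < lo) or np.any(lnc > hi):
        raise ValueError(f"lnc outside configured range [{lo}, {hi}]")
    return (lnc - lo) / (hi - lo)


def _leaf_endmembers(wavelengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p_lo = PchipInterpolator(_LEAF_ANCHORS_NM, _LEAF_LO)(wavelengths)
    p_hi = PchipInterpolator(_LEAF_ANCHORS_NM, _LEAF_HI)(wavelengths)
    return p_lo, p_hi


def _red_edge_weight(wavelengths: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(wavelengths - 715.0) / 10.0))


def leaf_spectrum(
    lnc: float,
    wavelengths: np.ndarray | None = None,
    shaded: bool = False,
    rng: np.random.Generator | None = None,
    lnc_range: tuple[float, float] = (25.0, 55.0),
    shade_factor_range: tuple[float, float] = (0.2, 0.5),
) -> np.ndarray:
    """Noise-free leaf reflectance for a given LNC (g·kg⁻¹).

    Green (550 nm) reflectance decreases monotonically with LNC while
    absorption wells at 450/670 nm deepen; a logistic-shaped red edge rises
    to the NIR plateau.  ``shaded`` multiplies by a shade factor drawn from
    ``shade_factor_range`` with slightly stronger attenuation in the NIR.
    """
    wavelengths = default_wavelengths() if wavelengths is None else np.asarray(wavelengths)
    u = float(_lnc_to_u(lnc, lnc_range))
    p_lo, p_hi = _leaf_endmembers(wavelengths)
    spectrum = (1.0 - u) * p_lo + u * p_hi
    if shaded:
        rng = np.random.default_rng(0) if rng is None else rng
        factor = rng.uniform(*shade_factor_range)
        spectrum = spectrum * factor * (1.0 - _SHADE_NIR_EXTRA * _red_edge_weight(wavelengths))
    return spectrum


def soil_spectrum(
    wavelengths: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.004,
) -> np.ndarray:
    """Bright dry-soil reflectance: a monotone quasi-linear ramp, no red edge."""
    wavelengths = default_wavelengths() if wavelengths is None else np.asarray(wavelengths)
    t = (wavelengths - 400.0) / 600.0
    base = _SOIL_400 + (_SOIL_1000 - _SOIL_400) * t
    if rng is not None and noise_sd > 0:
        base = base + rng.normal(0.0, noise_sd, size=base.shape)
    return base


def _clumpy_mask(shape, fraction, sigma, rng) -> np.ndarray:
    """Boolean mask covering ~``fraction`` of ``shape``, spatially clumped."""
    if fraction <= 0:
        return np.zeros(shape, dtype=bool)
    if fraction >= 1:
        return np.ones(shape, dtype=bool)
    fld = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    return fld >= np.quantile(fld, 1.0 - fraction)


def generate_scene(config: SceneConfig) -> tuple[SpectralCube, SceneTruth]:
    """Generate a full scene cube plus ground truth, fully seed-determined.

    Plot fertiliser levels cycle through the gradient; per-plot LNC adds
    replicate jitter, and a smooth within-plot field supplies local LNC
    variation so sampling points within one plot differ.  Canopy and shadow
    masks are clumped random fields; soil pixels adjacent to canopy are
    mixed soil/leaf blends (still truth-labelled soil).  Sensor noise is
    i.i.d. Gaussian per band; reflectance is clipped to [0.001, 1.4].
    """
    rng = np.random.default_rng(config.seed)
    wavelengths = np.asarray(config.wavelengths, dtype=float)
    nrows, ncols = config.grid
    ps = config.plot_size
    lo, hi = config.lnc_range

    p_lo, p_hi = _leaf_endmembers(wavelengths)
    soil_base = soil_spectrum(wavelengths)
    edge_w = _red_edge_weight(wavelengths)

    material = np.zeros((nrows, ncols), dtype=np.int8)
    plot_id = np.zeros((nrows, ncols), dtype=np.int32)
    lnc_map = np.zeros((nrows, ncols), dtype=float)
    u_vis_map = np.zeros((nrows, ncols), dtype=float)  # pigment state
    u_nir_map = np.zeros((nrows, ncols), dtype=float)  # structure state
    mixed_alpha = np.zeros((nrows, ncols), dtype=float)

    # fertiliser gradient, centred inside lnc_range to leave jitter headroom
    margin = 0.08 * (hi - lo)
    levels = np.linspace(lo + margin, hi - margin, config.n_levels_applied)
    plot_lnc = np.empty(config.n_plots)
    sample_points: list[SamplePoint] = []

    for p in range(config.n_plots):
        pr, pc = divmod(p, config.plot_cols)
        r0, c0 = pr * ps, pc * ps
        sl = (slice(r0, r0 + ps), slice(c0, c0 + ps))
        plot_id[sl] = p

        base_lnc = levels[p % config.n_levels_applied] + rng.normal(0, config.plot_lnc_jitter)
        base_lnc = float(np.clip(base_lnc, lo + 0.02 * (hi - lo), hi - 0.02 * (hi - lo)))
        plot_lnc[p] = base_lnc

        canopy = _clumpy_mask((ps, ps), config.canopy_cover, sigma=5.0, rng=rng)
        if canopy.any():
            shadow_local = _clumpy_mask((ps, ps), config.shadow_fraction, sigma=3.0, rng=rng)
            shadow = canopy & shadow_local
        else:
            shadow = np.zeros((ps, ps), dtype=bool)
        material[sl][canopy & ~shadow] = MATERIAL_SUNLIT
        material[sl][shadow] = MATERIAL_SHADED

        # mixed soil/leaf pixels in a 2-px collar around canopy blobs
        collar = binary_dilation(canopy, iterations=2) & ~canopy
        mixed_alpha[sl][collar] = rng.uniform(*config.mixed_alpha_range, size=int(collar.sum()))

        # smooth within-plot nitrogen field around the plot mean
        local = gaussian_filter(rng.standard_normal((ps, ps)), 8.0, mode="reflect")
        sd = local.std()
        local = local / sd * config.within_plot_lnc_sd if sd > 0 else local * 0.0
        lnc_local = np.clip(base_lnc + local, lo, hi)
        lnc_map[sl] = lnc_local
        u_local = (lnc_local - lo) / (hi - lo)

        # pigment and structure states: nitrogen plus smooth clumped deviations
        def _conf_field() -> np.ndarray:
            f = gaussian_filter(rng.standard_normal((ps, ps)), 10.0, mode="reflect")
            s = f.std()
            return f / s * config.confounder_sd if s > 0 else f * 0.0

        u_vis_map[sl] = np.clip(u_local + _conf_field(), 0.0, 1.0)
        u_nir_map[sl] = np.clip(u_local + _conf_field(), 0.0, 1.0)

        # sampling points: snap nominal grid positions to nearby sunlit canopy
        half = min(15, ps // 4)  # keeps a (2*half+1)-wide ROI inside the plot
        n_r = 2 if config.samples_per_plot > 3 else 1
        n_c = int(np.ceil(config.samples_per_plot / n_r))
        rows_nom = np.linspace(half + 4, ps - half - 5, n_r).round().astype(int)
        cols_nom = np.linspace(half + 1, ps - half - 2, n_c).round().astype(int)
        sunlit_local = canopy & ~shadow
        placed = 0
        for rr in rows_nom:
            for cc in cols_nom:
                if placed >= config.samples_per_plot:
                    break
                cand_r, cand_c = np.nonzero(sunlit_local)
                if cand_r.size == 0:
                    cand_r, cand_c = np.nonzero(canopy) if canopy.any() else (
                        np.array([rr]),
                        np.array([cc]),
                    )
                inside = (
                    (cand_r >= half)
                    & (cand_r < ps - half)
                    & (cand_c >= half)
                    & (cand_c < ps - half)
                )
                if inside.any():
                    cand_r, cand_c = cand_r[inside], cand_c[inside]
                d2 = (cand_r - rr) ** 2 + (cand_c - cc) ** 2
                j = int(np.argmin(d2))
                prow, pcol = int(cand_r[j]) + r0, int(cand_c[j]) + c0
                lnc_val = float(lnc_map[prow, pcol] + rng.normal(0, config.assay_sd))
                lnc_val = float(np.clip(lnc_val, 1e-6, None))
                sample_points.append(
                    SamplePoint(f"P{p:02d}S{placed}", prow, pcol, lnc_val)
                )
                placed += 1

    # --- scene-scale contamination fields ------------------------------------
    # soil brightness and colour vary in patches (moisture, roughness), so
    # the soil contamination entering a ROI mean differs from sample to
    # sample in more than one dimension; shadow depth varies per pixel.
    def _scene_field(sigma: float = 9.0) -> np.ndarray:
        f = gaussian_filter(rng.standard_normal((nrows, ncols)), sigma, mode="reflect")
        s = f.std()
        return (f / s if s > 0 else f).ravel()

    soil_bright_field = 1.0 + 0.15 * np.clip(_scene_field(), -2, 2)
    soil_tilt_field = 0.06 * np.clip(_scene_field(), -2, 2)
    soil_tilt_shape = (wavelengths - 700.0) / 600.0  # recolours the soil ramp

    # --- assemble reflectance ------------------------------------------------
    # per-band nitrogen state: visible bands follow the pigment field, NIR
    # bands the structure field, cross-faded through the red edge
    delta = p_hi - p_lo
    uv = u_vis_map.ravel()
    un = u_nir_map.ravel()
    leaf_flat = (
        p_lo[None, :]
        + np.outer(uv, delta * (1.0 - edge_w))
        + np.outer(un, delta * edge_w)
    )

    reflectance = np.empty((nrows * ncols, wavelengths.size))
    mat_flat = material.ravel()
    alpha_flat = mixed_alpha.ravel()

    soil_sel = mat_flat == MATERIAL_SOIL
    n_soil = int(soil_sel.sum())
    soil_bright = soil_bright_field[soil_sel] * rng.uniform(0.9, 1.1, size=n_soil)
    reflectance[soil_sel] = soil_bright[:, None] * (
        soil_base[None, :] + soil_tilt_field[soil_sel][:, None] * soil_tilt_shape[None, :]
    )
    # blend leaf signal into the mixed collar pixels (truth stays soil)
    mixed_sel = soil_sel & (alpha_flat > 0)
    a = alpha_flat[mixed_sel][:, None]
    reflectance[mixed_sel] = (
        a * leaf_flat[mixed_sel] + (1.0 - a) * reflectance[mixed_sel]
    )

    leaf_sel = ~soil_sel
    bj = config.brightness_jitter
    brightness = rng.uniform(1.0 - bj, 1.0 + bj, size=int(leaf_sel.sum()))
    reflectance[leaf_sel] = brightness[:, None] * leaf_flat[leaf_sel]

    shade_sel = mat_flat == MATERIAL_SHADED
    n_shade = int(shade_sel.sum())
    factors = rng.uniform(*config.shade_factor_range, size=n_shade)
    nir_extra = rng.uniform(*_SHADE_NIR_RANGE, size=n_shade)
    reflectance[shade_sel] *= factors[:, None] * (
        1.0 - nir_extra[:, None] * edge_w[None, :]
    )

    if config.noise_sd > 0:
        reflectance += rng.normal(0.0, config.noise_sd, size=reflectance.shape)
    np.clip(reflectance, 0.001, 1.4, out=reflectance)

    cube = SpectralCube(
        reflectance.reshape(nrows, ncols, wavelengths.size),
        wavelengths,
        origin_note=f"simulated scene seed={config.seed}",
    )
    truth = SceneTruth(
        material=material,
        plot_id=plot_id,
        lnc=plot_lnc,
        lnc_map=lnc_map,
        sample_points=sample_points,
    )
    return cube, truth
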