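"""Green-band intensity pixel classification for de-interference.

The core method of the package.  Canopy scenes mix sunlit leaves, shaded
leaves and soil; soil and leaf shadows bias canopy spectra and weaken the
link between vegetation indices and leaf nitrogen.  The remedy implemented
here:

1. an unsupervised vegetation mask (k-means on brightness-normalised pixel
   spectra; clusters with high NIR/red ratio are vegetation),
2. a first 10-level classification of masked pixels by green-band (550 nm)
   reflectance intensity,
3. a second 10-level classification refitted on the pixels of the retained
   mid-intensity classes (default levels {4, 5}),
4. retention of the central second-stage levels (default {3, 4, 5}) as the
   least-contaminated canopy pixels.

Shadows concentrate in the darkest green levels and bright soil / mixed
soil-edge pixels in the brightest, so the cascade trims both tails twice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import Roi, SpectralCube, band_index, roi_window

__all__ = [
    "VegetationMask",
    "LevelScheme",
    "PixelClassMap",
    "vegetation_mask",
    "fit_level_scheme",
    "classify_stage",
    "cascade_classify",
    "class_pixel_stats",
    "class_mean_spectrum",
]

logger = logging.getLogger(__name__)

GREEN_NM = 550.0
NIR_NM = 800.0
RED_NM = 670.0

DEFAULT_STAGE1_KEEP = frozenset({4, 5})
DEFAULT_STAGE2_KEEP = frozenset({3, 4, 5})


@dataclass
class VegetationMask:
    """Boolean per-pixel mask (True = vegetation) with a provenance note."""

    mask: np.ndarray
    method_note: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_vegetation(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class LevelScheme:
    """Green-intensity level boundaries.

    ``edges`` has ``n_levels + 1`` strictly increasing entries spanning
    ``[lo, hi]``.  Levels are half-open ``[edge_i, edge_{i+1})`` except the
    last, which is closed on the right.
    """

    n_levels: int
    mode: str
    lo: float
    hi: float
    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        if len(edges) != self.n_levels + 1:
            raise ValueError("edges must have n_levels + 1 entries")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("edges must be strictly increasing")
        if edges[0] != self.lo or edges[-1] != self.hi:
            raise ValueError("edges must span [lo, hi]")

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Level label per value; values at ``hi`` map to the last level."""
        edges = np.asarray(self.edges)
        labels = np.digitize(np.asarray(values, dtype=float), edges[1:-1], right=False)
        return np.clip(labels, 0, self.n_levels - 1)


@dataclass
class PixelClassMap:
    """Per-pixel integer level labels plus the scheme that produced them.

    Labels are in ``{-1, 0..n_levels-1}``; -1 marks pixels outside the
    classified population.  ``label_prefix`` mirrors the two-stage naming
    convention ("1-" for the first pass, "2-" for the second), so level 4 of
    stage 1 prints as "1-4".
    """

    labels: np.ndarray
    scheme: LevelScheme
    stage: int = 1
    label_prefix: str = "1-"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")

    def label_name(self, level: int) -> str:
        return f"{self.label_prefix}{level}"

    def in_levels(self, levels) -> np.ndarray:
        """Boolean mask of pixels whose label is in ``levels``."""
        return np.isin(self.labels, sorted(set(int(l) for l in levels)))


# ---------------------------------------------------------------------------
# vegetation masking
# ---------------------------------------------------------------------------

def _nir_red_ratio(cube: SpectralCube) -> np.ndarray:
    nir = cube.band_image(NIR_NM)
    red = cube.band_image(RED_NM)
    return nir / np.maximum(red, 1e-6)


def vegetation_mask(
    cube: SpectralCube,
    k: int = 3,
    seed: int = 0,
    ratio_fraction: float = 0.5,
) -> VegetationMask:
    """Unsupervised soil/vegetation separation.

    Pixel spectra are brightness-normalised (each divided by its mean) so
    that shaded leaves cluster with sunlit leaves by spectral *shape*
    rather than amplitude, then partitioned by k-means.  Initial centroids
    are taken deterministically at quantile-spaced positions of the
    NIR(800)/red(670) ratio ordering, so the mask is reproducible.  Clusters
    whose mean NIR/red ratio reaches ``ratio_fraction`` of the highest
    cluster ratio are flagged vegetation (leaves have a strong red edge,
    soil does not).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n_pixels = cube.nrows * cube.ncols
    if n_pixels < 2:
        raise ValueError("degenerate cube: need at least 2 pixels to cluster")

    spectra = cube.spectra()
    ratio = _nir_red_ratio(cube).ravel()
    if np.allclose(spectra, spectra[0]):
        warnings.warn("all pixels identical; returning an all-true mask")
        return VegetationMask(
            np.ones((cube.nrows, cube.ncols), dtype=bool),
            method_note="degenerate: single cluster, all pixels identical",
        )

    brightness = spectra.mean(axis=1, keepdims=True)
    shape = spectra / np.maximum(brightness, 1e-9)

    order = np.argsort(ratio, kind="stable")
    q_pos = ((np.arange(k) + 0.5) / k * (n_pixels - 1)).round().astype(int)
    init = shape[order[q_pos]]
    km = KMeans(n_clusters=k, init=init, n_init=1, max_iter=100, random_state=seed)
    assignment = km.fit_predict(shape)

    cluster_ratio = np.array(
        [ratio[assignment == j].mean() if np.any(assignment == j) else -np.inf for j in range(k)]
    )
    veg_clusters = np.flatnonzero(cluster_ratio >= ratio_fraction * cluster_ratio.max())
    mask = np.isin(assignment, veg_clusters).reshape(cube.nrows, cube.ncols)
    note = (
        f"kmeans k={k} seed={seed} on brightness-normalised spectra; "
        f"vegetation clusters {veg_clusters.tolist()} by NIR/red ratio "
        f"(cluster ratios {np.round(cluster_ratio, 2).tolist()})"
    )
    return VegetationMask(mask, method_note=note)


# ---------------------------------------------------------------------------
# level schemes and staged classification
# ---------------------------------------------------------------------------

def fit_level_scheme(
    green_values: np.ndarray, n_levels: int = 10, mode: str = "equal_width"
) -> LevelScheme:
    """Fit level boundaries to observed green reflectance values.

    ``equal_width`` spaces edges evenly on [min, max] of the data (the
    default: levels are intervals of an intensity scale); ``quantile``
    places edges at the i/n quantiles so levels are equally populated.
    """
    values = np.asarray(green_values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("no values to fit a level scheme on")
    if not np.all(np.isfinite(values)):
        raise ValueError("green values contain non-finite entries")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    lo, hi = float(values.min()), float(values.max())
    if mode == "equal_width":
        if hi <= lo:
            raise ValueError("constant input: equal-width levels are undefined")
        edges = np.linspace(lo, hi, n_levels + 1)
    elif mode == "quantile":
        if np.unique(values).size < n_levels:
            raise ValueError(
                f"quantile mode needs >= {n_levels} distinct values, got "
                f"{np.unique(values).size}"
            )
        edges = np.quantile(values, np.linspace(0, 1, n_levels + 1))
        if not np.all(np.diff(edges) > 0):
            raise ValueError("quantile edges not strictly increasing (heavy ties)")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return LevelScheme(n_levels, mode, lo, hi, tuple(edges.tolist()))


def classify_stage(
    cube: SpectralCube,
    mask: VegetationMask,
    n_levels: int = 10,
    mode: str = "equal_width",
    scheme: LevelScheme | None = None,
    stage: int = 1,
    restrict: np.ndarray | None = None,
) -> PixelClassMap:
    """Label masked pixels by their green-band intensity level.

    The scheme is fitted on the masked (optionally further ``restrict``-ed)
    pixel population unless one is supplied; pixels outside the population
    get label -1.
    """
    if mask.mask.shape != (cube.nrows, cube.ncols):
        raise ValueError("mask dimensions do not match cube")
    population = mask.mask if restrict is None else (mask.mask & restrict)
    if not population.any():
        raise ValueError("empty pixel population: nothing to classify")
    green = cube.band_image(GREEN_NM)
    if scheme is None:
        scheme = fit_level_scheme(green[population], n_levels=n_levels, mode=mode)
    labels = np.full(population.shape, -1, dtype=np.int32)
    labels[population] = scheme.assign(green[population])
    return PixelClassMap(labels, scheme, stage=stage, label_prefix=f"{stage}-")


def cascade_classify(
    cube: SpectralCube,
    mask: VegetationMask,
    stage1_keep=DEFAULT_STAGE1_KEEP,
    n_levels: int = 10,
    mode: str = "equal_width",
) -> tuple[PixelClassMap, PixelClassMap]:
    """Two sequential 10-level green-intensity classifications.

    Stage 1 bins all vegetation pixels; stage 2 refits the level scheme on
    the union of pixels whose stage-1 label is in ``stage1_keep`` (default
    {4, 5}: the mid-intensity canopy candidates) and rebins only those.
    """
    keep = sorted(set(int(l) for l in stage1_keep))
    if not keep:
        raise ValueError("stage1_keep must be a non-empty label set")
    stage1 = classify_stage(cube, mask, n_levels=n_levels, mode=mode, stage=1)
    kept = stage1.in_levels(keep)
    if not kept.any():
        raise ValueError(f"stage1_keep={keep} selects zero pixels")
    stage2 = classify_stage(
        cube, mask, n_levels=n_levels, mode=mode, stage=2, restrict=kept
    )
    return stage1, stage2


# ---------------------------------------------------------------------------
# statistics and spectra per class
# ---------------------------------------------------------------------------

def class_pixel_stats(obj: PixelClassMap | VegetationMask) -> pd.DataFrame:
    """Per-label pixel counts and percentages of the total, plus a total row.

    For a :class:`VegetationMask` the rows are vegetation / other; for a
    :class:`PixelClassMap` one row per level (prefixed labels) plus an
    ``outside`` row for unclassified pixels.
    """
    if isinstance(obj, VegetationMask):
        total = obj.mask.size
        veg = int(obj.mask.sum())
        rows = [("vegetation", veg), ("other", total - veg)]
    else:
        total = obj.labels.size
        rows = [
            (obj.label_name(lv), int((obj.labels == lv).sum()))
            for lv in range(obj.scheme.n_levels)
        ]
        outside = int((obj.labels == -1).sum())
        if outside:
            rows.append(("outside", outside))
    table = pd.DataFrame(rows, columns=["label", "count"])
    table["percent"] = 100.0 * table["count"] / total
    total_row = pd.DataFrame(
        [{"label": "total", "count": total, "percent": 100.0}]
    )
    return pd.concat([table, total_row], ignore_index=True)


def class_mean_spectrum(
    cube: SpectralCube,
    pixmap: PixelClassMap | VegetationMask,
    roi: Roi,
    levels=None,
) -> np.ndarray | None:
    """Unweighted mean spectrum over ROI pixels carrying the given label(s).

    ``levels`` may be a single level, a set of levels, or None (meaning all
    labelled / masked pixels).  Returns None — a missing-value marker, not
    an exception — when the ROI holds no matching pixel; callers drop the
    sample row and log it.
    """
    rows, cols = roi_window((cube.nrows, cube.ncols), roi)
    if isinstance(pixmap, VegetationMask):
        selected = pixmap.mask[rows, cols]
    else:
        window = pixmap.labels[rows, cols]
        if levels is None:
            selected = window >= 0
        else:
            if np.isscalar(levels):
                levels = [levels]
            selected = np.isin(window, sorted(set(int(l) for l in levels)))
    if not selected.any():
        logger.info(
            "ROI at %s has no pixel with label %s; emitting missing marker",
            roi.center,
            levels,
        )
        return None
    sub = cube.reflectance[rows, cols, :]
    return sub[selected].mean(axis=0)
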