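"""The 20 vegetation indices and sample × index table assembly.

Each index is an arithmetic combination of reflectance at fixed wavelengths
(R_λ = reflectance of the band nearest λ on the cube's grid).  The generic
red / green / NIR anchors used by R/G and MACI default to 670, 550 and
800 nm — the same anchors the named-band indices use — and are
configurable through :func:`make_registry`.

Note that NDVI here uses the (810, 560) band pair of its source definition
rather than the conventional (800, 670); HNDVI covers the conventional
pair at (827, 668).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .io import Roi, SamplePoint, SpectralCube, extract_roi, roi_window
from .classify import PixelClassMap, VegetationMask, class_mean_spectrum
from .preprocess import PreprocessSpec, preprocess_spectrum

__all__ = [
    "IndexDefinition",
    "INDEX_REGISTRY",
    "INDEX_NAMES",
    "make_registry",
    "compute_index",
    "compute_all_indices",
    "build_vi_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IndexDefinition:
    """One vegetation index: name, required wavelengths, and formula."""

    name: str
    wavelengths_nm: tuple[float, ...]
    formula: Callable[[Mapping[float, float]], float]
    expression: str

    def evaluate(self, bands: Mapping[float, float]) -> float:
        return self.formula(bands)


def make_registry(
    red_nm: float = 670.0, green_nm: float = 550.0, nir_nm: float = 800.0
) -> dict[str, IndexDefinition]:
    """Build the 20-index registry with configurable generic anchors."""

    def d(name, wls, formula, expression):
        return IndexDefinition(name, tuple(float(w) for w in wls), formula, expression)

    return {
        idx.name: idx
        for idx in [
            d("ZMI", (750, 710), lambda R: R[750] / R[710], "R750/R710"),
            d("VOG1", (740, 720), lambda R: R[740] / R[720], "R740/R720"),
            d("GRVI", (800, 550), lambda R: R[800] / R[550], "R800/R550"),
            d("RVI", (800, 700), lambda R: R[800] / R[700], "R800/R700"),
            d(
                "R/G",
                (red_nm, green_nm),
                lambda R: R[red_nm] / R[green_nm],
                f"R{red_nm:g}/R{green_nm:g}",
            ),
            d(
                "MACI",
                (nir_nm, green_nm),
                lambda R: R[nir_nm] / R[green_nm],
                f"R{nir_nm:g}/R{green_nm:g}",
            ),
            d("RECI", (750, 550), lambda R: R[750] / R[550] - 1.0, "(R750/R550) - 1"),
            d("GMI", (750, 720), lambda R: R[750] / R[720] - 1.0, "(R750/R720) - 1"),
            d(
                "GNDVI",
                (780, 550),
                lambda R: (R[780] - R[550]) / (R[780] + R[550]),
                "(R780 - R550)/(R780 + R550)",
            ),
            d(
                "NDVI",
                (810, 560),
                lambda R: (R[810] - R[560]) / (R[810] + R[560]),
                "(R810 - R560)/(R810 + R560)",
            ),
            d(
                "IPVI",
                (800, 670),
                lambda R: R[800] / (R[800] + R[670]),
                "R800/(R800 + R670)",
            ),
            d(
                "MTCI",
                (754, 709, 681),
                lambda R: (R[754] - R[709]) / (R[709] - R[681]),
                "(R754 - R709)/(R709 - R681)",
            ),
            d(
                "SIPI",
                (800, 450),
                lambda R: (R[800] - R[450]) / (R[800] + R[450]),
                "(R800 - R450)/(R800 + R450)",
            ),
            d(
                "mSR705",
                (750, 705, 445),
                lambda R: (R[750] - R[445]) / (R[705] + R[445]),
                "(R750 - R445)/(R705 + R445)",
            ),
            d(
                "NDVI801",
                (801, 550),
                lambda R: (R[801] - R[550]) / (R[801] + R[550]),
                "(R801 - R550)/(R801 + R550)",
            ),
            d(
                "RENDVI",
                (750, 705),
                lambda R: (R[750] - R[705]) / (R[750] + R[705]),
                "(R750 - R705)/(R750 + R705)",
            ),
            d(
                "mND705",
                (750, 705, 445),
                lambda R: (R[750] - R[705]) / (R[750] + R[705] - 2.0 * R[445]),
                "(R750 - R705)/(R750 + R705 - 2*R445)",
            ),
            d(
                "NPQI",
                (415, 435),
                lambda R: (R[415] - R[435]) / (R[415] + R[435]),
                "(R415 - R435)/(R415 + R435)",
            ),
            d(
                "HNDVI",
                (827, 668),
                lambda R: (R[827] - R[668]) / (R[827] + R[668]),
                "(R827 - R668)/(R827 + R668)",
            ),
            d(
                "SAVI",
                (800, 670),
                lambda R: 1.5 * (R[800] - R[670]) / (R[800] - R[670] + 0.5),
                "1.5*(R800 - R670)/(R800 - R670 + 0.5)",
            ),
        ]
    }


INDEX_REGISTRY: dict[str, IndexDefinition] = make_registry()
INDEX_NAMES: tuple[str, ...] = tuple(INDEX_REGISTRY)


class _BandLookup(dict):
    """λ → reflectance map that raises a clear error on unresolvable bands."""


def _resolve_bands(
    spectrum: np.ndarray,
    wavelengths: np.ndarray,
    required: tuple[float, ...],
    tol_nm: float,
) -> _BandLookup:
    wl = np.asarray(wavelengths, dtype=float)
    spec = np.asarray(spectrum, dtype=float)
    lookup = _BandLookup()
    for target in required:
        dist = np.abs(wl - target)
        idx = int(np.argmin(dist))
        if dist[idx] > tol_nm:
            raise ValueError(
                f"no band within {tol_nm} nm of {target} nm "
                f"(nearest center {wl[idx]:.2f} nm)"
            )
        lookup[target] = spec[idx]
    return lookup


def compute_index(
    spectrum: np.ndarray,
    wavelengths: np.ndarray,
    name: str,
    tol_nm: float = 2.2,
    registry: Mapping[str, IndexDefinition] | None = None,
) -> float:
    """Evaluate one index on a spectrum.

    A vanishing denominator (e.g. MTCI when R709 = R681) yields NaN — a
    logged missing-value marker, not an exception.
    """
    registry = INDEX_REGISTRY if registry is None else registry
    if name not in registry:
        raise KeyError(f"unknown index {name!r}; known: {sorted(registry)}")
    definition = registry[name]
    bands = _resolve_bands(spectrum, wavelengths, definition.wavelengths_nm, tol_nm)
    with np.errstate(divide="ignore", invalid="ignore"):
        value = float(definition.evaluate(bands))
    if not np.isfinite(value):
        logger.info("index %s undefined on this spectrum (zero denominator)", name)
        return float("nan")
    return value


def compute_all_indices(
    spectrum: np.ndarray,
    wavelengths: np.ndarray,
    tol_nm: float = 2.2,
    registry: Mapping[str, IndexDefinition] | None = None,
) -> dict[str, float]:
    registry = INDEX_REGISTRY if registry is None else registry
    return {
        name: compute_index(spectrum, wavelengths, name, tol_nm, registry)
        for name in registry
    }


def registry_as_records(registry: Mapping[str, IndexDefinition] | None = None) -> list[dict]:
    """JSON-serialisable export of the index registry."""
    registry = INDEX_REGISTRY if registry is None else registry
    return [
        {
            "name": idx.name,
            "wavelengths_nm": list(idx.wavelengths_nm),
            "expression": idx.expression,
        }
        for idx in registry.values()
    ]


def build_vi_table(
    cube: SpectralCube,
    samples: list[SamplePoint],
    pixmap: PixelClassMap | VegetationMask | None = None,
    levels=None,
    pretreat: PreprocessSpec | None = None,
    roi_shape: tuple[int, int] = (30, 30),
    tol_nm: float = 2.2,
    smooth_before_average: bool = True,
    registry: Mapping[str, IndexDefinition] | None = None,
) -> pd.DataFrame:
    """Assemble the samples × indices table for one pixel class and pretreatment.

    For each sample: extract the ROI around its location, restrict to pixels
    of the requested class (``pixmap`` + ``levels``; None keeps every ROI
    pixel), pretreat spectra, average, and evaluate all indices.  Samples
    whose ROI holds no matching pixel are dropped and logged — the table
    never carries silent NaN rows.

    The class label and pretreatment method are recorded in ``DataFrame.attrs``.
    """
    pretreat = pretreat or PreprocessSpec("OS")
    registry = INDEX_REGISTRY if registry is None else registry
    height, width = roi_shape
    rows = []
    lnc = []
    dropped = []
    for point in samples:
        roi = Roi((point.row, point.col), height, width)
        if pixmap is None:
            sub = extract_roi(cube, roi)
            pix = sub.spectra()
        else:
            rslice, cslice = roi_window((cube.nrows, cube.ncols), roi)
            if isinstance(pixmap, VegetationMask):
                selected = pixmap.mask[rslice, cslice]
            else:
                window = pixmap.labels[rslice, cslice]
                if levels is None:
                    selected = window >= 0
                else:
                    lv = [levels] if np.isscalar(levels) else levels
                    selected = np.isin(window, sorted(set(int(l) for l in lv)))
            if not selected.any():
                dropped.append(point.sample_id)
                continue
            pix = cube.reflectance[rslice, cslice, :][selected]
        if smooth_before_average:
            mean_spec = preprocess_spectrum(pix, pretreat).mean(axis=0)
        else:
            mean_spec = preprocess_spectrum(pix.mean(axis=0), pretreat)
        rows.append(
            {"sample_id": point.sample_id}
            | compute_all_indices(mean_spec, cube.wavelengths_nm, tol_nm, registry)
        )
        lnc.append(point.lnc)

    if dropped:
        logger.info(
            "dropped %d sample(s) with no pixel in class %s: %s",
            len(dropped),
            levels,
            dropped,
        )
    table = pd.DataFrame(rows)
    if len(table):
        table = table.set_index("sample_id")
        table["lnc"] = lnc
    if levels is None:
        table.attrs["levels"] = None
    else:
        lv = [levels] if np.isscalar(levels) else list(levels)
        table.attrs["levels"] = sorted(int(v) for v in set(lv))
    table.attrs["method"] = pretreat.method
    table.attrs["dropped"] = dropped
    return table
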