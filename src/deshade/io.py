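"""Hyperspectral cube and sample-table I/O.

Cubes are stored on disk in the ENVI convention: a small text header
(``.hdr``) describing dimensions, interleave, data type and the band-center
wavelength list, next to a flat binary array.  In memory a cube is always a
``(rows, cols, bands)`` float array plus a strictly increasing wavelength
vector in nanometres.  Ground sampling points (pixel position + measured
leaf nitrogen content) travel as a plain CSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectralCube",
    "SamplePoint",
    "Roi",
    "read_envi_cube",
    "write_envi_cube",
    "band_index",
    "extract_roi",
    "read_sample_table",
    "write_sample_table",
]

#: default wavelength matching tolerance: one sampling interval of the
#: 400-1000 nm push-broom sensor the pipeline targets (2.2 nm).
DEFAULT_TOL_NM = 2.2

_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
    14: np.int64,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class SpectralCube:
    """Reflectance grid indexed ``(row, col, band)`` with band wavelengths.

    Parameters
    ----------
    reflectance : ndarray, shape (rows, cols, bands)
        Dimensionless reflectance (fractions, typically in [0, 1]).
    wavelengths_nm : ndarray, shape (bands,)
        Strictly increasing band-center wavelengths in nanometres.
    origin_note : str
        Free-text provenance tag (file path, simulation seed, ...).
    clipped : bool
        True when the cube is an edge-clipped region-of-interest extract.
    """

    reflectance: np.ndarray
    wavelengths_nm: np.ndarray
    origin_note: str = ""
    clipped: bool = False

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.reflectance.ndim != 3:
            raise ValueError(
                f"reflectance must be 3-D (rows, cols, bands); got shape "
                f"{self.reflectance.shape}"
            )
        r, c, b = self.reflectance.shape
        if r < 1 or c < 1:
            raise ValueError("cube must have at least one row and column")
        if self.wavelengths_nm.ndim != 1 or len(self.wavelengths_nm) != b:
            raise ValueError(
                f"wavelength vector length {self.wavelengths_nm.size} does not "
                f"match band count {b}"
            )
        dw = np.diff(self.wavelengths_nm)
        if len(dw) and not np.all(dw > 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains non-finite values")

    @property
    def nrows(self) -> int:
        return self.reflectance.shape[0]

    @property
    def ncols(self) -> int:
        return self.reflectance.shape[1]

    @property
    def nbands(self) -> int:
        return self.reflectance.shape[2]

    def band_index(self, target_nm: float, tol_nm: float = DEFAULT_TOL_NM) -> int:
        return band_index(self, target_nm, tol_nm)

    def band_image(self, target_nm: float, tol_nm: float = DEFAULT_TOL_NM) -> np.ndarray:
        """2-D image of the band nearest ``target_nm``."""
        return self.reflectance[:, :, self.band_index(target_nm, tol_nm)]

    def spectra(self) -> np.ndarray:
        """Pixels flattened row-major to shape (rows*cols, bands)."""
        return self.reflectance.reshape(-1, self.nbands)


@dataclass(frozen=True)
class SamplePoint:
    """A ground sampling point: pixel location plus measured LNC.

    ``lnc`` is leaf nitrogen content per dry leaf mass; the unit is whatever
    the sample table declares (g·kg⁻¹ by convention).
    """

    sample_id: str
    row: int
    col: int
    lnc: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.lnc) or self.lnc <= 0:
            raise ValueError(f"sample {self.sample_id!r}: lnc must be > 0, got {self.lnc}")


@dataclass(frozen=True)
class Roi:
    """Pixel window centered on a sampling point.

    Odd sizes center exactly; for even sizes the center pixel is the
    upper-left element of the central 2×2 block, so the default 30×30 window
    around ``(r, c)`` spans rows ``r-14..r+15`` and cols ``c-14..c+15``
    (900 pixels).
    """

    center: tuple[int, int]
    height: int = 30
    width: int = 30

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI height and width must be >= 1")

    def bounds(self) -> tuple[int, int, int, int]:
        """Inclusive-exclusive (row0, row1, col0, col1), unclipped."""
        r, c = self.center
        r0 = r - (self.height - 1) // 2
        c0 = c - (self.width - 1) // 2
        return r0, r0 + self.height, c0, c0 + self.width


# ---------------------------------------------------------------------------
# ENVI header + raw binary
# ---------------------------------------------------------------------------

def _parse_envi_header(header_path: Path) -> dict:
    text = header_path.read_text()
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError(f"{header_path}: not an ENVI header (missing ENVI magic)")
    # join brace-delimited multiline values, then split on key = value
    fields: dict[str, str] = {}
    body = text.split("\n", 1)[1] if "\n" in text else ""
    pattern = re.compile(r"^\s*([^={}\n]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        fields[key] = val
    return fields

def _parse_list(raw: str) -> list[float]:
    inner = raw.strip().lstrip("{").rstrip("}")
    return [float(tok) for tok in re.split(r"[,\s]+", inner.strip()) if tok]

def _data_path_for(header_path: Path, fields: dict) -> Path:
    if "data file" in fields:
        cand = header_path.parent / fields["data file"].strip("{} ")
        if cand.exists():
            return cand
    stem = header_path.with_suffix("")
    for ext in (".img", ".dat", ".raw", ".bsq", ".bil", ".bip", ""):
        cand = stem.with_suffix(ext) if ext else stem
        if cand.exists() and cand != header_path:
            return cand
    raise FileNotFoundError(f"no binary data file found next to {header_path}")


def read_envi_cube(header_path: str | Path, permissive: bool = False) -> SpectralCube:
    """Read an ENVI header + raw binary pair into a :class:`SpectralCube`.

    The interleave (BSQ/BIL/BIP) is normalised to ``(row, col, band)`` order
    and a header-declared ``reflectance scale factor`` is divided out.
    Values outside the physically plausible reflectance range [0, 1.5] are
    rejected unless ``permissive`` is set.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    fields = _parse_envi_header(header_path)

    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise ValueError(f"{header_path}: missing required header field {exc}") from exc
    if "wavelength" not in fields:
        raise ValueError(f"{header_path}: header declares no wavelength list")
    wavelengths = np.array(_parse_list(fields["wavelength"]))
    if wavelengths.size != bands:
        raise ValueError(
            f"{header_path}: wavelength list length {wavelengths.size} != bands {bands}"
        )
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"{header_path}: unsupported ENVI data type {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    offset = int(fields.get("header offset", "0"))

    data_path = _data_path_for(header_path, fields)
    raw = np.fromfile(data_path, dtype=dtype, offset=offset)
    expected = lines * samples * bands
    if raw.size != expected:
        raise ValueError(
            f"{data_path}: binary size {raw.size} elements does not match header "
            f"dims {lines}x{samples}x{bands} = {expected}"
        )
    if interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"{header_path}: unknown interleave {interleave!r}")
    cube = np.ascontiguousarray(cube, dtype=float)

    scale = float(fields.get("reflectance scale factor", "1"))
    if scale not in (0.0, 1.0):
        cube = cube / scale
    if not permissive:
        lo, hi = cube.min(), cube.max()
        if lo < 0 or hi > 1.5:
            raise ValueError(
                f"{data_path}: reflectance outside [0, 1.5] (min {lo:.4g}, max "
                f"{hi:.4g}); pass permissive=True to accept"
            )
    return SpectralCube(cube, wavelengths, origin_note=str(header_path))


def write_envi_cube(
    cube: SpectralCube,
    header_path: str | Path,
    interleave: str = "bsq",
    dtype: str | np.dtype = "float64",
    scale_factor: float | None = None,
) -> Path:
    """Write ``cube`` as an ENVI header + ``.img`` binary pair.

    Returns the header path.  Integer dtypes require a ``scale_factor``
    (values are multiplied before rounding; the factor is recorded in the
    header so :func:`read_envi_cube` restores fractions).
    """
    header_path = Path(header_path)
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unknown interleave {interleave!r}")
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_CODES:
        raise ValueError(f"dtype {dtype} has no ENVI type code")

    data = cube.reflectance
    if scale_factor:
        data = data * scale_factor
    if dtype.kind in "iu":
        if not scale_factor:
            raise ValueError("integer dtypes require a scale_factor")
        data = np.round(data)
    if interleave == "bsq":
        arr = data.transpose(2, 0, 1)
    elif interleave == "bil":
        arr = data.transpose(0, 2, 1)
    else:
        arr = data
    data_path = header_path.with_suffix(".img")
    np.ascontiguousarray(arr, dtype=dtype).tofile(data_path)

    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths_nm)
    lines = [
        "ENVI",
        "description = {deshade spectral cube}",
        f"samples = {cube.ncols}",
        f"lines = {cube.nrows}",
        f"bands = {cube.nbands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_CODES[dtype]}",
        f"interleave = {interleave}",
        "byte order = 0",
        f"data file = {data_path.name}",
    ]
    if scale_factor:
        lines.append(f"reflectance scale factor = {scale_factor:g}")
    lines.append("wavelength units = Nanometers")
    lines.append("wavelength = {" + wl + "}")
    header_path.write_text("\n".join(lines) + "\n")
    return header_path


# ---------------------------------------------------------------------------
# band lookup and ROI extraction
# ---------------------------------------------------------------------------

def band_index(cube: SpectralCube, target_nm: float, tol_nm: float = DEFAULT_TOL_NM) -> int:
    """Ordinal of the band whose center is nearest ``target_nm``.

    Ties break to the lower wavelength.  If the nearest center is farther
    than ``tol_nm`` the lookup fails (the grid simply does not cover the
    requested wavelength).
    """
    if tol_nm <= 0:
        raise ValueError("tol_nm must be > 0")
    wl = cube.wavelengths_nm
    dist = np.abs(wl - target_nm)
    idx = int(np.argmin(dist))  # argmin takes the first (lower-wavelength) tie
    if dist[idx] > tol_nm:
        raise ValueError(
            f"no band within {tol_nm} nm of {target_nm} nm "
            f"(nearest available center: {wl[idx]:.2f} nm)"
        )
    return idx


def extract_roi(cube: SpectralCube, roi: Roi) -> SpectralCube:
    """Sub-cube of ``roi.height × roi.width`` pixels centered on the ROI.

    The center must lie inside the cube; windows running past the edge are
    clipped and the result carries ``clipped=True``.
    """
    r, c = roi.center
    if not (0 <= r < cube.nrows and 0 <= c < cube.ncols):
        raise ValueError(
            f"ROI center {roi.center} outside cube of shape "
            f"({cube.nrows}, {cube.ncols})"
        )
    r0, r1, c0, c1 = roi.bounds()
    cr0, cr1 = max(r0, 0), min(r1, cube.nrows)
    cc0, cc1 = max(c0, 0), min(c1, cube.ncols)
    clipped = (cr0, cr1, cc0, cc1) != (r0, r1, c0, c1)
    sub = cube.reflectance[cr0:cr1, cc0:cc1, :]
    return SpectralCube(
        sub.copy(),
        cube.wavelengths_nm,
        origin_note=f"{cube.origin_note} [roi {roi.center} {roi.height}x{roi.width}]",
        clipped=clipped,
    )


def roi_window(cube_shape: tuple[int, int], roi: Roi) -> tuple[slice, slice]:
    """Clipped (row, col) slices of ``roi`` within an image of ``cube_shape``."""
    r0, r1, c0, c1 = roi.bounds()
    return (
        slice(max(r0, 0), min(r1, cube_shape[0])),
        slice(max(c0, 0), min(c1, cube_shape[1])),
    )


# ---------------------------------------------------------------------------
# sample tables
# ---------------------------------------------------------------------------

def read_sample_table(csv_path: str | Path) -> list[SamplePoint]:
    """Read and validate a ground sampling point table.

    Required columns: ``sample_id,row,col,lnc``.  Duplicate ids and
    non-numeric or non-positive LNC values are hard errors that name the
    offending row (1-based, excluding the header).
    """
    df = pd.read_csv(csv_path)
    required = {"sample_id", "row", "col", "lnc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{csv_path}: missing columns {sorted(missing)}")
    dup = df["sample_id"].duplicated()
    if dup.any():
        rownum = int(np.flatnonzero(dup.values)[0]) + 1
        raise ValueError(
            f"{csv_path}: duplicate sample_id {df['sample_id'][dup].iloc[0]!r} at row {rownum}"
        )
    points = []
    for i, rec in df.iterrows():
        try:
            lnc = float(rec["lnc"])
        except (TypeError, ValueError):
            raise ValueError(f"{csv_path}: non-numeric lnc at row {i + 1}") from None
        if not np.isfinite(lnc) or lnc <= 0:
            raise ValueError(f"{csv_path}: lnc must be > 0 at row {i + 1}")
        points.append(
            SamplePoint(str(rec["sample_id"]), int(rec["row"]), int(rec["col"]), lnc)
        )
    return points


def write_sample_table(points: list[SamplePoint], csv_path: str | Path) -> Path:
    csv_path = Path(csv_path)
    pd.DataFrame(
        [{"sample_id": p.sample_id, "row": p.row, "col": p.col, "lnc": p.lnc} for p in points]
    ).to_csv(csv_path, index=False)
    return csv_path
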