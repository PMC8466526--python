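"""Core data model for mid-IR absorbance spectra and hyperspectral maps.

Conventions
-----------
* Wavenumber grids are stored strictly ascending in cm^-1.  FTIR
  instruments commonly emit spectra from 4000 down to 800 cm^-1; files
  stored that way are flipped (grid and absorbance together) at ingestion
  so that every integral, derivative and region window downstream works
  on one single convention.
* Absorbance is dimensionless (AU).  Region windows are closed intervals
  and select actual grid points — edges are never interpolated.
* The on-disk exchange format is a UTF-8 delimited table: first column
  wavenumber, one column per spectrum, header cells carrying
  ``cell_line/treatment/sample_id`` labels.  A JCAMP-DX reader covers the
  common ``(X++(Y..Y))`` affine-scaled single-spectrum case.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "Spectrum",
    "SpectrumSet",
    "HyperMap",
    "SpectraFormatError",
    "validate_grid",
    "load_spectra",
    "save_spectra",
    "load_jcamp",
    "extract_region",
    "resample_to_grid",
    "load_map",
    "save_map",
    "DEFAULT_GRID",
    "REGIONS",
]

GRID_MIN, GRID_MAX = 400.0, 8000.0
MIN_GRID_POINTS = 9  # smallest Savitzky-Golay window used anywhere


class SpectraFormatError(ValueError):
    """A spectra file violates the table or JCAMP-DX format contract."""


def validate_grid(values: np.ndarray) -> np.ndarray:
    """Validate a wavenumber grid (ascending, in range, long enough)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < MIN_GRID_POINTS:
        raise ValueError(f"grid needs >= {MIN_GRID_POINTS} points, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise ValueError("grid contains non-finite wavenumbers")
    if np.any(np.diff(v) <= 0):
        raise ValueError("grid must be strictly ascending (flip at ingestion)")
    if v[0] < GRID_MIN or v[-1] > GRID_MAX:
        raise ValueError(f"grid outside plausible mid/near-IR range [{GRID_MIN}, {GRID_MAX}] cm^-1")
    return v


@dataclass(frozen=True)
class Region:
    """A closed wavenumber interval [lo, hi] in cm^-1 with a name."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"region {self.name!r}: lo must be < hi ({self.lo} >= {self.hi})")

    def mask(self, wavenumbers: np.ndarray) -> np.ndarray:
        return (wavenumbers >= self.lo) & (wavenumbers <= self.hi)


#: The study's standard analysis windows.
REGIONS = {
    "dna": Region("dna", 900.0, 1350.0),
    "fingerprint": Region("fingerprint", 1000.0, 1800.0),
    "protein": Region("protein", 1480.0, 1800.0),
    "amide_i": Region("amide_i", 1600.0, 1700.0),
    "amide_ii": Region("amide_ii", 1480.0, 1600.0),
    "lipids": Region("lipids", 2800.0, 3000.0),
    "bh": Region("bh", 2460.0, 2620.0),
}


def _ingest(wavenumbers: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip descending input to ascending; values flipped along the grid axis."""
    w = np.asarray(wavenumbers, dtype=float)
    y = np.asarray(values, dtype=float)
    if w.size >= 2 and w[0] > w[-1]:
        w = w[::-1].copy()
        y = np.flip(y, axis=-1).copy()
    return w, y


class Spectrum:
    """A single absorbance spectrum on an ascending wavenumber grid."""

    def __init__(self, wavenumbers: Sequence[float], absorbance: Sequence[float],
                 meta: dict | None = None):
        w, a = _ingest(np.asarray(wavenumbers, float), np.asarray(absorbance, float))
        self.wavenumbers = validate_grid(w)
        a = np.asarray(a, dtype=float)
        if a.shape != self.wavenumbers.shape:
            raise ValueError("absorbance length must equal grid length")
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance contains non-finite values")
        self.absorbance = a
        self.meta: dict = dict(meta or {})

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def spacing(self) -> float:
        """Median grid spacing in cm^-1."""
        return float(np.median(np.diff(self.wavenumbers)))

    def copy_with(self, absorbance: np.ndarray, **meta) -> "Spectrum":
        s = Spectrum(self.wavenumbers, absorbance, {**self.meta, **meta})
        return s

    def __repr__(self) -> str:
        return (f"Spectrum({self.wavenumbers[0]:.0f}-{self.wavenumbers[-1]:.0f} cm^-1, "
                f"{len(self)} pts)")


class SpectrumSet:
    """A labeled collection of spectra sharing one wavenumber grid.

    ``labels`` is a DataFrame with columns ``cell_line``, ``treatment``,
    ``sample_id`` (one row per spectrum); values must be non-empty tokens.
    """

    LABEL_COLS = ("cell_line", "treatment", "sample_id")

    def __init__(self, wavenumbers: Sequence[float], absorbance: np.ndarray,
                 labels: pd.DataFrame, meta: dict | None = None):
        w = np.asarray(wavenumbers, float)
        A = np.asarray(absorbance, float)
        if A.ndim != 2:
            raise ValueError("absorbance must be a 2-D array (n_spectra, n_points)")
        w, A = _ingest(w, A)
        self.wavenumbers = validate_grid(w)
        if A.shape[1] != self.wavenumbers.size:
            raise ValueError("absorbance columns must match grid length")
        if not np.all(np.isfinite(A)):
            raise ValueError("absorbance contains non-finite values")
        labels = labels.reset_index(drop=True)
        if list(labels.columns) != list(self.LABEL_COLS):
            missing = set(self.LABEL_COLS) - set(labels.columns)
            if missing:
                raise ValueError(f"labels missing columns: {sorted(missing)}")
            labels = labels[list(self.LABEL_COLS)]
        if len(labels) != A.shape[0]:
            raise ValueError("one label row per spectrum required")
        if labels.isna().any().any() or (labels.astype(str) == "").any().any():
            raise ValueError("labels must be complete non-empty tokens")
        self.absorbance = A
        self.labels = labels.astype(str)
        self.meta: dict = dict(meta or {})

    def __len__(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.wavenumbers.size

    def spectrum(self, i: int) -> Spectrum:
        row = self.labels.iloc[i]
        return Spectrum(self.wavenumbers, self.absorbance[i],
                        {c: row[c] for c in self.LABEL_COLS})

    def __iter__(self) -> Iterable[Spectrum]:
        return (self.spectrum(i) for i in range(len(self)))

    def select(self, **where: str) -> "SpectrumSet":
        """Subset by label equality, e.g. ``select(treatment="control")``."""
        mask = np.ones(len(self), dtype=bool)
        for col, val in where.items():
            if col not in self.LABEL_COLS:
                raise KeyError(col)
            mask &= (self.labels[col] == val).to_numpy()
        if not mask.any():
            raise ValueError(f"no spectra match {where}")
        return SpectrumSet(self.wavenumbers, self.absorbance[mask],
                           self.labels.loc[mask].reset_index(drop=True), self.meta)

    def groups(self) -> list[tuple[str, str]]:
        """Distinct (cell_line, treatment) pairs in label order."""
        seen: list[tuple[str, str]] = []
        for _, row in self.labels.iterrows():
            key = (row["cell_line"], row["treatment"])
            if key not in seen:
                seen.append(key)
        return seen

    def mean_spectrum(self, **where: str) -> Spectrum:
        sub = self.select(**where) if where else self
        return Spectrum(sub.wavenumbers, sub.absorbance.mean(axis=0), dict(where))

    def copy_with(self, absorbance: np.ndarray, **meta) -> "SpectrumSet":
        return SpectrumSet(self.wavenumbers, absorbance, self.labels,
                           {**self.meta, **meta})


class HyperMap:
    """Raster of per-pixel spectra on a micrometre grid.

    Index convention: pixel (ix, iy) with (0, 0) at the top-left, ix
    rightward and iy downward; the spectra cube is ``(ny, nx, n_points)``.
    """

    def __init__(self, wavenumbers: Sequence[float], cube: np.ndarray,
                 step_um: float, meta: dict | None = None):
        cube = np.asarray(cube, float)
        if cube.ndim != 3:
            raise ValueError("cube must be (ny, nx, n_points)")
        w, cube = _ingest(np.asarray(wavenumbers, float), cube)
        self.wavenumbers = validate_grid(w)
        if cube.shape[2] != self.wavenumbers.size:
            raise ValueError("cube last axis must match grid length")
        if not np.all(np.isfinite(cube)):
            raise ValueError("cube contains non-finite values")
        if step_um <= 0:
            raise ValueError("step_um must be > 0")
        self.cube = cube
        self.step_um = float(step_um)
        self.meta: dict = dict(meta or {})

    @property
    def ny(self) -> int:
        return self.cube.shape[0]

    @property
    def nx(self) -> int:
        return self.cube.shape[1]

    @property
    def extent_um(self) -> tuple[float, float]:
        """Physical extent (x, y) in micrometres spanned by pixel centres."""
        return ((self.nx - 1) * self.step_um, (self.ny - 1) * self.step_um)

    def pixel(self, ix: int, iy: int) -> Spectrum:
        return Spectrum(self.wavenumbers, self.cube[iy, ix],
                        {"ix": ix, "iy": iy, "step_um": self.step_um})


# ---------------------------------------------------------------------------
# Table I/O

_PROVENANCE_PREFIX = "#"


def save_spectra(sset: SpectrumSet, path: str | Path, sep: str = ",",
                 provenance: str = "") -> None:
    """Write a SpectrumSet as a delimited table.

    First column ``wavenumber``; each spectrum column is headed
    ``cell_line/treatment/sample_id``.  A provenance comment line is
    always written first.  Values round-trip to 1e-12 relative.
    """
    path = Path(path)
    header = ["wavenumber"] + [
        "/".join(row) for row in _label_tuples(sset)
    ]
    lines = [f"{_PROVENANCE_PREFIX} cosan-ftirm spectra table"
             + (f" | {provenance}" if provenance else "")]
    lines.append(sep.join(header))
    for j, w in enumerate(sset.wavenumbers):
        cells = [f"{w:.17g}"] + [f"{sset.absorbance[i, j]:.17g}" for i in range(len(sset))]
        lines.append(sep.join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _label_tuples(sset: SpectrumSet) -> list[tuple[str, str, str]]:
    return [tuple(row) for row in sset.labels.itertuples(index=False)]


def _parse_label(token: str, col: int) -> tuple[str, str, str]:
    parts = token.strip().split("/")
    if len(parts) == 3 and all(parts):
        return parts[0], parts[1], parts[2]
    # fall back: bare index-style headers get placeholder labels
    return "unknown", "unknown", token.strip() or f"col{col}"


def load_spectra(path: str | Path, dialect: str = "table", sep: str | None = None) -> SpectrumSet:
    """Load a SpectrumSet from a delimited table or a JCAMP-DX file.

    Table dialect: first column wavenumber, remaining columns absorbance;
    descending files are flipped to the ascending convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "jcamp":
        spec = load_jcamp(path)
        labels = pd.DataFrame([{
            "cell_line": spec.meta.get("cell_line", "unknown"),
            "treatment": spec.meta.get("treatment", "unknown"),
            "sample_id": spec.meta.get("sample_id", path.stem),
        }])
        return SpectrumSet(spec.wavenumbers, spec.absorbance[None, :], labels)
    if dialect != "table":
        raise ValueError(f"unknown dialect {dialect!r}")

    raw_lines = [ln for ln in path.read_text(encoding="utf-8").splitlines()
                 if ln.strip() and not ln.lstrip().startswith(_PROVENANCE_PREFIX)]
    if not raw_lines:
        raise SpectraFormatError(f"{path}: empty table")
    if sep is None:
        sep = "\t" if "\t" in raw_lines[0] else ","
    header = [c.strip() for c in raw_lines[0].split(sep)]
    ncol = len(header)
    if ncol < 2:
        raise SpectraFormatError(f"{path}: need a wavenumber column plus >= 1 spectrum")
    rows: list[list[float]] = []
    for r, ln in enumerate(raw_lines[1:], start=2):
        cells = ln.split(sep)
        if len(cells) != ncol:
            raise SpectraFormatError(
                f"{path}: ragged row {r} ({len(cells)} cells, expected {ncol})")
        try:
            rows.append([float(c) for c in cells])
        except ValueError:
            bad = next(i for i, c in enumerate(cells)
                       if not re.fullmatch(r"\s*[-+0-9.eE]+\s*", c))
            raise SpectraFormatError(
                f"{path}: non-numeric cell at row {r}, column {bad + 1}") from None
    data = np.asarray(rows, dtype=float)
    w = data[:, 0]
    if np.unique(w).size != w.size:
        raise SpectraFormatError(f"{path}: duplicate wavenumbers")
    labels = pd.DataFrame(
        [_parse_label(tok, i) for i, tok in enumerate(header[1:], start=1)],
        columns=list(SpectrumSet.LABEL_COLS))
    return SpectrumSet(w, data[:, 1:].T, labels)


# ---------------------------------------------------------------------------
# JCAMP-DX (X++(Y..Y)) reader

_LDR = re.compile(r"^##([^=]+)=(.*)$")


def load_jcamp(path: str | Path) -> Spectrum:
    """Read a single-spectrum JCAMP-DX file in (X++(Y..Y)) AFFN form.

    Supports the affine-scaled tabular layout: each data line starts with
    an unscaled X value followed by unscaled Y values; true values are
    ``X * XFACTOR`` and ``Y * YFACTOR``.  Compressed (SQZ/DIF/DUP) forms
    are out of scope.  Descending files (DELTAX < 0) are flipped.
    """
    path = Path(path)
    fields: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for ln in path.read_text(encoding="utf-8", errors="replace").splitlines():
        m = _LDR.match(ln.strip())
        if m:
            key = m.group(1).strip().upper().replace(" ", "")
            val = m.group(2).strip()
            if key == "XYDATA":
                if "(X++(Y..Y))" not in val.replace(" ", ""):
                    raise SpectraFormatError(f"{path}: unsupported XYDATA form {val!r}")
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            fields[key] = val
            continue
        if in_data and ln.strip():
            data_lines.append(ln.strip())
    if not data_lines:
        raise SpectraFormatError(f"{path}: no XYDATA block found")

    xfactor = float(fields.get("XFACTOR", "1"))
    yfactor = float(fields.get("YFACTOR", "1"))
    npoints = int(float(fields["NPOINTS"])) if "NPOINTS" in fields else None
    firstx = float(fields["FIRSTX"]) if "FIRSTX" in fields else None
    lastx = float(fields["LASTX"]) if "LASTX" in fields else None

    ys: list[float] = []
    xs_starts: list[tuple[float, int]] = []
    for ln in data_lines:
        toks = ln.replace(",", " ").split()
        xs_starts.append((float(toks[0]) * xfactor, len(ys)))
        ys.extend(float(t) * yfactor for t in toks[1:])
    y = np.asarray(ys, float)
    if npoints is not None and y.size != npoints:
        raise SpectraFormatError(
            f"{path}: NPOINTS={npoints} but decoded {y.size} ordinates")
    if firstx is None or lastx is None:
        raise SpectraFormatError(f"{path}: FIRSTX/LASTX required")
    x = np.linspace(firstx, lastx, y.size)
    # cross-check line-start abscissae against the reconstructed grid
    for xstart, idx in xs_starts:
        if abs(x[idx] - xstart) > max(1e-6, 1e-6 * abs(xstart)) + abs(x[1] - x[0]) * 0.51:
            raise SpectraFormatError(f"{path}: line-start X {xstart} inconsistent with grid")
    return Spectrum(x, y, {"source": str(path), "format": "jcamp"})


# ---------------------------------------------------------------------------
# Region extraction and resampling

def extract_region(obj: Spectrum | SpectrumSet, region: Region):
    """Restrict a spectrum or set to the closed interval [lo, hi].

    Keeps exactly the grid points with ``lo <= nu <= hi``; raises if the
    intersection is empty or too small to be a valid grid.
    """
    mask = region.mask(obj.wavenumbers)
    if not mask.any():
        raise ValueError(
            f"region {region.name!r} [{region.lo}, {region.hi}] does not intersect grid "
            f"[{obj.wavenumbers[0]}, {obj.wavenumbers[-1]}]")
    w = obj.wavenumbers[mask]
    if w.size < MIN_GRID_POINTS:
        raise ValueError(f"region {region.name!r} keeps only {w.size} grid points")
    if isinstance(obj, Spectrum):
        return Spectrum(w, obj.absorbance[mask], {**obj.meta, "region": region.name})
    if isinstance(obj, SpectrumSet):
        return SpectrumSet(w, obj.absorbance[:, mask], obj.labels,
                           {**obj.meta, "region": region.name})
    raise TypeError(type(obj))


def resample_to_grid(s: Spectrum, target: Sequence[float]) -> Spectrum:
    """Linearly interpolate a spectrum onto a new grid (no extrapolation)."""
    t = validate_grid(np.asarray(target, float))
    if t[0] < s.wavenumbers[0] or t[-1] > s.wavenumbers[-1]:
        raise ValueError("target grid extends beyond source span (extrapolation refused)")
    a = np.interp(t, s.wavenumbers, s.absorbance)
    return Spectrum(t, a, {**s.meta, "resampled": True})


# ---------------------------------------------------------------------------
# Hyperspectral map container: directory with geometry header + pixel table

def save_map(hmap: HyperMap, directory: str | Path, provenance: str = "") -> None:
    """Write a map as ``geometry.txt`` plus a pixel-column spectra table.

    Pixel columns are row-major: ``px_{iy}_{ix}`` scanning ix fastest.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    geom = (f"{_PROVENANCE_PREFIX} cosan-ftirm map geometry"
            + (f" | {provenance}" if provenance else "") + "\n"
            f"nx={hmap.nx}\nny={hmap.ny}\nstep_um={hmap.step_um:.17g}\n")
    (directory / "geometry.txt").write_text(geom, encoding="utf-8")
    cols = [f"px_{iy}_{ix}" for iy in range(hmap.ny) for ix in range(hmap.nx)]
    lines = [f"{_PROVENANCE_PREFIX} cosan-ftirm map spectra (row-major pixels)",
             ",".join(["wavenumber"] + cols)]
    flat = hmap.cube.reshape(hmap.ny * hmap.nx, -1)
    for j, w in enumerate(hmap.wavenumbers):
        lines.append(",".join([f"{w:.17g}"] + [f"{flat[p, j]:.17g}" for p in range(flat.shape[0])]))
    (directory / "spectra.csv").write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_map(directory: str | Path) -> HyperMap:
    directory = Path(directory)
    geom_text = (directory / "geometry.txt").read_text(encoding="utf-8")
    geom: dict[str, str] = {}
    for ln in geom_text.splitlines():
        if "=" in ln and not ln.startswith(_PROVENANCE_PREFIX):
            k, v = ln.split("=", 1)
            geom[k.strip()] = v.strip()
    nx, ny = int(geom["nx"]), int(geom["ny"])
    step = float(geom["step_um"])
    lines = [ln for ln in (directory / "spectra.csv").read_text(encoding="utf-8").splitlines()
             if ln.strip() and not ln.startswith(_PROVENANCE_PREFIX)]
    ncol = len(lines[0].split(","))
    data = np.asarray([[float(c) for c in ln.split(",")] for ln in lines[1:]], float)
    if data.shape[1] != ncol or ncol != 1 + nx * ny:
        raise SpectraFormatError(f"{directory}: pixel columns do not match geometry")
    w = data[:, 0]
    cube = data[:, 1:].T.reshape(ny, nx, -1)
    return HyperMap(w, cube, step)


#: Default synthetic acquisition grid: 800-4000 cm^-1 at 2 cm^-1 spacing
#: (4 cm^-1 instrument resolution stored with ~2x oversampling).
DEFAULT_GRID = np.arange(800.0, 4000.0 + 1e-9, 2.0)
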