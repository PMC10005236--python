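"""Domain types and file I/O for mid-infrared absorbance spectra.

The atom of every pipeline stage is a :class:`Spectrum`: an absorbance
vector A(nu) on a strictly increasing wavenumber grid (cm^-1), carrying
sample metadata.  A :class:`SpectrumSet` is an aligned collection of
spectra sharing one grid, with group labels and replicate structure.

Measured tissue spectra cover 800-3500 cm^-1 with the 1800-2800 cm^-1
window (diamond-ATR / CO2 region) excluded, so the canonical grid is
*piecewise* uniform: uniform spacing within each contiguous block, with
gaps between blocks.  Operations that need a uniform grid (derivatives,
median filters) act per contiguous block.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

GROUPS = ("control", "classic", "desmoplastic", "anaplastic")
ALL_GROUPS = GROUPS + ("unknown",)

#: Canonical 1 cm^-1 analysis grid: 800-1800 and 2800-3500 cm^-1.
CANONICAL_GRID = np.concatenate(
    [np.arange(800.0, 1801.0), np.arange(2800.0, 3501.0)]
)

CSV_HEADER = "wavenumber_cm1,absorbance"


class SpectrumError(ValueError):
    """Invariant violation on a Spectrum or SpectrumSet."""


class ParseError(ValueError):
    """Malformed spectrum file."""


@dataclass(frozen=True)
class Region:
    """Closed wavenumber interval [lo, hi] in cm^-1."""

    lo: float
    hi: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise SpectrumError(f"Region requires lo < hi, got [{self.lo}, {self.hi}]")
        if self.lo < 400 or self.hi > 4000:
            raise SpectrumError(f"Region [{self.lo}, {self.hi}] outside 400-4000 cm^-1")

    def mask(self, wavenumbers: np.ndarray) -> np.ndarray:
        return (wavenumbers >= self.lo) & (wavenumbers <= self.hi)


#: Fingerprint region used for multivariate analysis and dynamics.
FINGERPRINT = Region(800.0, 1800.0, "fingerprint")
#: Paraffin CH2/CH3 deformation window excluded from fingerprint analyses.
PARAFFIN_WINDOW = Region(1350.0, 1500.0, "paraffin")
#: Amide I band of protein backbone C=O stretching.
AMIDE_I = Region(1600.0, 1700.0, "amide I")


@dataclass
class Spectrum:
    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""
    group: str = "unknown"
    replicate: int = 1
    provenance: str = ""
    excised: tuple[Region, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.ndim != 1 or self.absorbance.ndim != 1:
            raise SpectrumError("wavenumbers and absorbance must be 1-D")
        if self.wavenumbers.size != self.absorbance.size:
            raise SpectrumError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.absorbance.size} absorbance values"
            )
        if self.wavenumbers.size < 2:
            raise SpectrumError("a spectrum needs at least 2 points")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise SpectrumError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise SpectrumError("absorbance contains non-finite values")
        if self.group not in ALL_GROUPS:
            raise SpectrumError(f"unknown group {self.group!r}; expected one of {ALL_GROUPS}")

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_absorbance(self, absorbance: np.ndarray, **meta_updates) -> "Spectrum":
        """Copy of this spectrum with a new absorbance vector (same grid)."""
        out = replace(self, absorbance=np.asarray(absorbance, dtype=float))
        out.meta = dict(self.meta, **meta_updates)
        return out

    def slice(self, region: Region) -> "Spectrum":
        """Closed-interval sub-spectrum over ``region``."""
        m = region.mask(self.wavenumbers)
        if m.sum() < 2:
            raise SpectrumError(
                f"grid does not cover region [{region.lo}, {region.hi}]"
            )
        return replace(self, wavenumbers=self.wavenumbers[m], absorbance=self.absorbance[m])

    def segments(self, rtol: float = 1e-6) -> list[slice]:
        """Maximal contiguous runs of uniform grid spacing.

        The canonical grid has a gap at 1800-2800 cm^-1; derivative and
        filtering operations are applied independently per segment.
        """
        d = np.diff(self.wavenumbers)
        step = np.median(d)
        breaks = np.nonzero(np.abs(d - step) > rtol * max(step, 1.0))[0]
        edges = [0, *(b + 1 for b in breaks), len(self.wavenumbers)]
        out = [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]
        for s in out:
            seg = np.diff(self.wavenumbers[s])
            if seg.size and np.ptp(seg) > rtol * max(step, 1.0):
                raise SpectrumError("grid is not piecewise uniform")
        return out


class SpectrumSet:
    """Aligned collection of spectra sharing one wavenumber grid."""

    def __init__(self, spectra: Sequence[Spectrum]):
        spectra = list(spectra)
        if not spectra:
            raise SpectrumError("SpectrumSet needs at least one spectrum")
        grid = spectra[0].wavenumbers
        for s in spectra[1:]:
            if not np.array_equal(s.wavenumbers, grid):
                raise SpectrumError(
                    f"spectrum {s.sample_id!r} is not on the shared grid; resample first"
                )
        self.spectra = spectra
        self.grid = grid

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i):
        return self.spectra[i]

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.spectra])

    @property
    def sample_ids(self) -> np.ndarray:
        return np.array([s.sample_id for s in self.spectra])

    def matrix(self) -> np.ndarray:
        return np.vstack([s.absorbance for s in self.spectra])

    def select(self, group: str) -> "SpectrumSet":
        sub = [s for s in self.spectra if s.group == group]
        if not sub:
            raise SpectrumError(f"no spectra in group {group!r}")
        return SpectrumSet(sub)

    def map(self, fn) -> "SpectrumSet":
        return SpectrumSet([fn(s) for s in self.spectra])


# ---------------------------------------------------------------------------
# readers / writers


def _parse_two_column(path: Path) -> tuple[np.ndarray, np.ndarray]:
    xs: list[float] = []
    ys: list[float] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ParseError(f"{path}:{lineno}: expected two columns, got {row!r}")
            try:
                x, y = float(row[0]), float(row[1])
            except ValueError:
                if lineno == 1 and any(c.isalpha() for c in "".join(row)):
                    continue  # header line
                raise ParseError(f"{path}:{lineno}: non-numeric row {row!r}") from None
            xs.append(x)
            ys.append(y)
    if len(xs) < 2:
        raise ParseError(f"{path}: fewer than 2 data points")
    return np.array(xs), np.array(ys)


def _parse_jcamp(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal JCAMP-DX reader: ##XUNITS=1/CM with ##XYDATA=(X++(Y..Y)).

    Only the plain AFFN table dialect is honored; compressed (SQZ/DIF/DUP)
    forms and other x-units raise :class:`ParseError`.
    """
    header: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "XYDATA":
                if value.replace(" ", "") != "(X++(Y..Y))":
                    raise ParseError(f"{path}: unsupported XYDATA dialect {value!r}")
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            header[key] = value
            continue
        if in_data:
            data_lines.append(line)
    xunits = header.get("XUNITS", "").upper().replace(" ", "")
    if xunits != "1/CM":
        raise ParseError(f"{path}: unsupported XUNITS {header.get('XUNITS')!r} (need 1/CM)")
    if not data_lines:
        raise ParseError(f"{path}: no XYDATA table found")
    rows: list[tuple[float, list[float]]] = []
    for lineno, line in enumerate(data_lines, start=1):
        toks = line.replace(",", " ").split()
        try:
            vals = [float(t) for t in toks]
        except ValueError:
            raise ParseError(f"{path}: non-numeric XYDATA line {lineno}: {line!r}") from None
        if len(vals) < 2:
            raise ParseError(f"{path}: XYDATA line {lineno} has no Y values")
        rows.append((vals[0], vals[1:]))
    if "DELTAX" in header:
        dx = float(header["DELTAX"])
    elif {"FIRSTX", "LASTX", "NPOINTS"} <= header.keys():
        n = int(float(header["NPOINTS"]))
        dx = (float(header["LASTX"]) - float(header["FIRSTX"])) / (n - 1)
    elif len(rows) > 1:
        x0, y0 = rows[0]
        dx = (rows[1][0] - x0) / len(y0)
    elif len(rows[0][1]) == 1:
        raise ParseError(f"{path}: single-point spectrum")
    else:
        raise ParseError(f"{path}: cannot determine x spacing (need ##DELTAX)")
    xs: list[float] = []
    ys: list[float] = []
    for x0, yvals in rows:
        xs.extend(x0 + i * dx for i in range(len(yvals)))
        ys.extend(yvals)
    return np.array(xs), np.array(ys)


def read_spectrum(
    path: str | Path,
    format: str = "csv",
    sample_id: str | None = None,
    group: str = "unknown",
    replicate: int = 1,
) -> Spectrum:
    """Read a two-column CSV or minimal JCAMP-DX spectrum.

    Descending-axis files (common in instrument exports) are silently
    reversed to ascending.  Duplicate wavenumbers are an error.
    """
    path = Path(path)
    if format == "csv":
        x, y = _parse_two_column(path)
    elif format == "jcamp":
        x, y = _parse_jcamp(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'jcamp'")
    if x.size > 1 and x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    dup = np.nonzero(np.diff(x) == 0)[0]
    if dup.size:
        raise ParseError(f"{path}: duplicate wavenumber {x[dup[0]]:g}")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    return Spectrum(
        x,
        y,
        sample_id=sample_id if sample_id is not None else path.stem,
        group=group,
        replicate=replicate,
        provenance=str(path),
    )


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as a round-trippable two-column CSV."""
    path = Path(path)
    lines = [CSV_HEADER]
    lines += [
        f"{x:.17g},{y:.17g}"
        for x, y in zip(spectrum.wavenumbers, spectrum.absorbance)
    ]
    path.write_text("\n".join(lines) + "\n")


def resample_to_grid(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linear interpolation onto ``grid``.  No extrapolation is performed."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] < spectrum.wavenumbers[0] or grid[-1] > spectrum.wavenumbers[-1]:
        raise SpectrumError(
            f"target grid [{grid[0]}, {grid[-1]}] extends beyond data span "
            f"[{spectrum.wavenumbers[0]}, {spectrum.wavenumbers[-1]}]"
        )
    y = np.interp(grid, spectrum.wavenumbers, spectrum.absorbance)
    return replace(spectrum, wavenumbers=grid, absorbance=y)


def excise_regions(spectrum: Spectrum, drop: Iterable[Region]) -> Spectrum:
    """Remove all grid points inside the closed intervals ``drop``.

    The removed regions are recorded on the returned spectrum so that
    downstream axes remain honest about what was resected.
    """
    drop = tuple(drop)
    keep = np.ones(len(spectrum), dtype=bool)
    for region in drop:
        if region.lo > spectrum.wavenumbers[-1] or region.hi < spectrum.wavenumbers[0]:
            raise SpectrumError(
                f"excision region [{region.lo}, {region.hi}] lies outside the grid span"
            )
        keep &= ~region.mask(spectrum.wavenumbers)
    if not keep.any():
        raise SpectrumError("excision would remove every grid point")
    out = replace(
        spectrum,
        wavenumbers=spectrum.wavenumbers[keep],
        absorbance=spectrum.absorbance[keep],
        excised=spectrum.excised + drop,
    )
    return out


# ---------------------------------------------------------------------------
# cohort manifests

MANIFEST_COLUMNS = ("path", "sample_id", "group", "replicate")


def write_manifest(rows: Iterable[dict], path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(list(rows), columns=list(MANIFEST_COLUMNS))
    df.to_csv(path, index=False)


def load_cohort(manifest_path: str | Path, grid: np.ndarray | None = None) -> SpectrumSet:
    """Load a cohort from a manifest CSV (columns path,sample_id,group,replicate).

    Relative paths are resolved against the manifest's directory.  If
    ``grid`` is given, every spectrum is resampled onto it.
    """
    import pandas as pd

    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{manifest_path}: manifest missing columns {sorted(missing)}")
    spectra = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        s = read_spectrum(
            p,
            sample_id=str(row.sample_id),
            group=str(row.group),
            replicate=int(row.replicate),
        )
        if grid is not None:
            s = resample_to_grid(s, grid)
        spectra.append(s)
    return SpectrumSet(spectra)
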