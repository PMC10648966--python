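"""Spectrum containers and file I/O.

A spectrum is a pair of aligned vectors: a chemical-shift axis in ppm and an
intensity vector in arbitrary units.  Libraries are directories of two-column
delimited text files plus a YAML manifest declaring the shared grid; augmented
pair datasets are stored in a single HDF5 container.

A small subset of JCAMP-DX is supported for exchange: single-block files with
an ``##XYDATA=(X++(Y..Y))`` or ``(XY..XY)`` table in AFFN form.  Bruker/Varian
raw acquisition directories are out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import yaml

__all__ = [
    "Spectrum",
    "SpectralLibrary",
    "read_spectrum",
    "write_spectrum",
    "load_library",
    "write_library",
    "save_dataset",
    "load_dataset",
]

_DATASET_FORMAT_VERSION = 1

MANIFEST_NAME = "manifest.yaml"


@dataclass
class Spectrum:
    """A 1D NMR spectrum: ppm axis plus aligned intensity vector.

    The axis must be strictly monotone.  Descending axes (the native NMR
    plotting convention) are accepted and normalized to ascending order, with
    the intensity vector reversed alongside.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("ppm and intensity must be one-dimensional")
        if self.ppm.shape != self.intensity.shape:
            raise ValueError(
                f"axis/intensity length mismatch: {self.ppm.size} vs {self.intensity.size}"
            )
        if self.ppm.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        d = np.diff(self.ppm)
        if np.all(d < 0):  # descending source axis: flip both
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(d > 0):
            raise ValueError("ppm axis must be strictly monotone")

    def __len__(self) -> int:
        return self.ppm.size

    def copy(self, *, intensity: np.ndarray | None = None, name: str | None = None) -> "Spectrum":
        """Return a copy, optionally replacing the intensity vector or name."""
        return Spectrum(
            self.ppm.copy(),
            self.intensity.copy() if intensity is None else np.asarray(intensity, float),
            self.name if name is None else name,
        )

    def resample(self, grid: np.ndarray) -> "Spectrum":
        """Linear interpolation onto a new ascending ppm grid (edge-value fill)."""
        grid = np.asarray(grid, dtype=np.float64)
        return Spectrum(grid, np.interp(grid, self.ppm, self.intensity), self.name)


@dataclass
class SpectralLibrary:
    """Named spectra on one shared ppm grid.

    Rows of ``matrix`` (shape N x P) align with ``names``; this is the library
    matrix D whose rows are paired one-by-one with a query spectrum during
    mixture identification.
    """

    names: list[str]
    grid: np.ndarray
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (N x P)")
        if self.matrix.shape[0] != len(self.names):
            raise ValueError("one name per matrix row required")
        if self.matrix.shape[0] < 1:
            raise ValueError("library needs at least one spectrum")
        if self.matrix.shape[1] != self.grid.size:
            raise ValueError("grid length must match matrix columns")
        if len(set(self.names)) != len(self.names):
            raise ValueError("library names must be unique")
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("library grid must be strictly ascending")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_points(self) -> int:
        return self.grid.size

    def spectrum(self, name: str) -> Spectrum:
        """Return one entry as a Spectrum."""
        i = self.names.index(name)
        return Spectrum(self.grid, self.matrix[i], name)

    def spectra(self):
        """Iterate over entries as Spectrum objects."""
        for name, row in zip(self.names, self.matrix):
            yield Spectrum(self.grid, row, name)


# ---------------------------------------------------------------------------
# single-spectrum readers / writers
# ---------------------------------------------------------------------------

def _read_delimited(path: Path) -> Spectrum:
    try:
        data = np.loadtxt(path, comments="#", delimiter=None, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"malformed delimited spectrum file {path}: {exc}") from exc
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (ppm, intensity)")
    return Spectrum(data[:, 0], data[:, 1], name=path.stem)


_JCAMP_NUM = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")


def _jcamp_fields(text: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    for m in re.finditer(r"^##([^=\n]*)=\s*(.*)$", text, flags=re.M):
        key = m.group(1).strip().upper().replace(" ", "")
        fields.setdefault(key, m.group(2).strip())
    return fields


def _read_jcamp(path: Path) -> Spectrum:
    """Parse a single-block JCAMP-DX file with a simple AFFN XYDATA table."""
    text = path.read_text()
    fields = _jcamp_fields(text)
    m = re.search(
        r"^##(?:XYDATA|XYPOINTS)=([^\n]*)\n(.*?)(?=^##|\Z)",
        text,
        flags=re.M | re.S,
    )
    if m is None:
        raise ValueError(f"{path}: no XYDATA/XYPOINTS table found")
    variable_list = (m.group(1) or "").replace(" ", "").upper()
    body = m.group(2)
    xfactor = float(fields.get("XFACTOR", "1"))
    yfactor = float(fields.get("YFACTOR", "1"))

    if "XY..XY" in variable_list:
        nums = [float(v) for v in _JCAMP_NUM.findall(body)]
        if len(nums) % 2:
            raise ValueError(f"{path}: odd number of values in (XY..XY) table")
        arr = np.asarray(nums, dtype=float).reshape(-1, 2)
        x, y = arr[:, 0] * xfactor, arr[:, 1] * yfactor
    else:  # (X++(Y..Y)): each line starts with an X value, then Y values
        xs: list[float] = []
        ys: list[float] = []
        for line in body.splitlines():
            line = line.split("$$")[0].strip()
            if not line:
                continue
            vals = [float(v) for v in _JCAMP_NUM.findall(line)]
            if len(vals) < 2:
                continue
            xs.append(vals[0])
            ys.extend(vals[1:])
        if not ys:
            raise ValueError(f"{path}: empty XYDATA table")
        npoints = int(float(fields.get("NPOINTS", len(ys))))
        if npoints != len(ys):
            raise ValueError(
                f"{path}: NPOINTS={npoints} but table holds {len(ys)} ordinates"
            )
        firstx = float(fields.get("FIRSTX", xs[0] * xfactor))
        lastx = float(fields.get("LASTX", firstx))
        x = np.linspace(firstx, lastx, len(ys))
        y = np.asarray(ys, dtype=float) * yfactor

    name = fields.get("TITLE", path.stem) or path.stem
    return Spectrum(x, y, name=name)


def read_spectrum(path: str | Path, format: str | None = None) -> Spectrum:
    """Read a spectrum from a JCAMP-DX or two-column delimited text file.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"jcamp-dx"`` or ``"delimited"``; inferred from the suffix
        (``.jdx``/``.dx`` vs anything else) when omitted.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    if format is None:
        format = "jcamp-dx" if path.suffix.lower() in {".jdx", ".dx", ".jcamp"} else "delimited"
    if format == "jcamp-dx":
        return _read_jcamp(path)
    if format == "delimited":
        return _read_delimited(path)
    raise ValueError(f"unknown spectrum format {format!r}")


def write_spectrum(spectrum: Spectrum, path: str | Path) -> Path:
    """Write a spectrum as two-column delimited text (ppm, intensity)."""
    path = Path(path)
    header = spectrum.name or path.stem
    np.savetxt(
        path,
        np.column_stack([spectrum.ppm, spectrum.intensity]),
        fmt="%.10g",
        header=header,
    )
    return path


# ---------------------------------------------------------------------------
# libraries
# ---------------------------------------------------------------------------

def write_library(library: SpectralLibrary, directory: str | Path) -> Path:
    """Write a library as one delimited file per spectrum plus a YAML manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    for spec in library.spectra():
        fname = f"{spec.name}.txt"
        write_spectrum(spec, directory / fname)
        files[spec.name] = fname
    manifest = {
        "grid": {
            "start": float(library.grid[0]),
            "stop": float(library.grid[-1]),
            "num": int(library.grid.size),
        },
        "spectra": files,
    }
    with open(directory / MANIFEST_NAME, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return directory


def load_library(directory: str | Path) -> SpectralLibrary:
    """Load a library directory written by :func:`write_library`.

    Spectra are resampled onto the manifest-declared grid by linear
    interpolation; entries are ordered lexicographically by name so that row
    order is stable across platforms.
    """
    directory = Path(directory)
    manifest_path = directory / MANIFEST_NAME
    if not manifest_path.is_file():
        raise FileNotFoundError(f"no {MANIFEST_NAME} in {directory}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    g = manifest["grid"]
    grid = np.linspace(float(g["start"]), float(g["stop"]), int(g["num"]))
    entries = manifest["spectra"]
    if not entries:
        raise ValueError(f"{directory}: manifest lists no spectra")
    names = sorted(entries)
    if len(set(names)) != len(names):
        raise ValueError("duplicate spectrum names in manifest")
    rows = []
    for name in names:
        spec = read_spectrum(directory / entries[name])
        rows.append(spec.resample(grid).intensity)
    return SpectralLibrary(names, grid, np.vstack(rows))


# ---------------------------------------------------------------------------
# augmented-pair dataset container
# ---------------------------------------------------------------------------

def save_dataset(pairs, path: str | Path) -> Path:
    """Write a pair collection to a single HDF5 container (lossless)."""
    from .augment import PairSet  # local import: augment depends on io

    if not isinstance(pairs, PairSet):
        pairs = PairSet.from_pairs(list(pairs))
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = _DATASET_FORMAT_VERSION
        fh.create_dataset("references", data=pairs.references)
        fh.create_dataset("composites", data=pairs.composites)
        fh.create_dataset("labels", data=pairs.labels)
        str_dt = h5py.string_dtype()
        fh.create_dataset("ref_names", data=np.asarray(pairs.ref_names, dtype=object), dtype=str_dt)
        fh.create_dataset(
            "component_names",
            data=np.asarray(["|".join(c) for c in pairs.component_names], dtype=object),
            dtype=str_dt,
        )
    return path


def load_dataset(path: str | Path):
    """Read a pair collection written by :func:`save_dataset`."""
    from .augment import PairSet

    with h5py.File(path, "r") as fh:
        version = int(fh.attrs.get("format_version", -1))
        if version != _DATASET_FORMAT_VERSION:
            raise ValueError(
                f"dataset format version mismatch: file={version}, "
                f"supported={_DATASET_FORMAT_VERSION}"
            )
        refs = fh["references"][...]
        comps = fh["composites"][...]
        labels = fh["labels"][...]
        ref_names = [s.decode() if isinstance(s, bytes) else s for s in fh["ref_names"][...]]
        comp_names = [
            tuple(s.split("|")) if s else ()
            for s in (
                v.decode() if isinstance(v, bytes) else v for v in fh["component_names"][...]
            )
        ]
    return PairSet(refs, comps, labels, ref_names, comp_names)
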