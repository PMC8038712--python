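"""Reading, writing and gridding of mid-infrared absorbance spectra.

A :class:`Spectrum` is a single absorbance trace on a strictly monotone
wavenumber axis; a :class:`SpectraSet` is a stack of spectra sharing one
grid, with per-row sample ids, group labels and replicate indices.
Wavenumbers are stored ascending internally; instrument text exports
(typically descending, high wavenumber first) are reversed on input.

Supported text formats: two-column spectrometer exports (DPT-style),
wide CSV (one wavenumber column plus one column per sample) with an
optional metadata table, and minimal JCAMP-DX with AFFN-encoded
XYPOINTS/XYDATA pairs.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectraSet",
    "SpectraFormatError",
    "read_two_column",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_jcamp_xy",
    "resample_to_grid",
]

#: absolute tolerance (cm^-1) for deciding two grids are "the same grid";
#: covers round-trip noise of decimal text formats
GRID_ATOL = 1e-6


class SpectraFormatError(ValueError):
    """A spectral file could not be parsed or violates a format contract."""


def _canonical_axis(wavenumbers: np.ndarray, absorbance: np.ndarray):
    """Validate monotonicity/finiteness and return both arrays ascending."""
    w = np.asarray(wavenumbers, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if w.ndim != 1 or a.shape[-1] != w.size:
        raise ValueError("wavenumber and absorbance lengths differ")
    if w.size < 1:
        raise ValueError("a spectrum needs at least 1 point")
    if not np.all(np.isfinite(w)) or not np.all(np.isfinite(a)):
        raise ValueError("non-finite values in spectrum")
    dw = np.diff(w)
    if np.all(dw > 0):
        return w, a
    if np.all(dw < 0):
        return w[::-1].copy(), a[..., ::-1].copy()
    raise ValueError("wavenumbers must be strictly monotone (duplicate or unordered values found)")


@dataclass(frozen=True)
class Spectrum:
    """One absorbance spectrum on a strictly ascending wavenumber grid.

    Readers require >= 2 points; a single-point Spectrum can arise from
    cropping to a one-point region and is accepted by the container.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_id: str = "spectrum"
    group: str = "unlabeled"
    replicate: int = 1

    def __post_init__(self):
        w, a = _canonical_axis(self.wavenumbers, self.absorbance)
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "absorbance", a)
        if self.replicate < 1:
            raise ValueError("replicate index must be a positive integer")

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_absorbance(self, values: np.ndarray, wavenumbers: np.ndarray | None = None) -> "Spectrum":
        """Copy of this spectrum with new values (and optionally a new grid)."""
        return replace(
            self,
            absorbance=np.asarray(values, dtype=float),
            wavenumbers=self.wavenumbers if wavenumbers is None else np.asarray(wavenumbers, dtype=float),
        )


@dataclass
class SpectraSet:
    """n_samples x n_points absorbance matrix on one shared ascending grid."""

    grid: np.ndarray
    matrix: np.ndarray
    sample_ids: list[str]
    labels: list[str]
    replicates: list[int]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != self.grid.size:
            raise ValueError("matrix width does not match grid length")
        if self.matrix.shape[0] < 1:
            raise ValueError("SpectraSet needs at least one sample")
        n = self.matrix.shape[0]
        if not (len(self.sample_ids) == len(self.labels) == len(self.replicates) == n):
            raise ValueError("per-row metadata length mismatch")
        if any(not lbl for lbl in self.labels):
            raise ValueError("every group label must be nonempty")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly ascending")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite absorbance values")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def row(self, i: int) -> Spectrum:
        return Spectrum(
            self.grid, self.matrix[i], sample_id=self.sample_ids[i],
            group=self.labels[i], replicate=self.replicates[i],
        )

    def rows(self):
        return [self.row(i) for i in range(self.n_samples)]

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum], provenance: dict | None = None) -> "SpectraSet":
        """Stack spectra that already share one grid (within ``GRID_ATOL``)."""
        if not spectra:
            raise ValueError("no spectra given")
        grid = spectra[0].wavenumbers
        for s in spectra[1:]:
            if s.wavenumbers.size != grid.size or np.max(np.abs(s.wavenumbers - grid)) > GRID_ATOL:
                raise ValueError(
                    f"sample {s.sample_id!r} is not on the shared grid; resample_to_grid first"
                )
        return cls(
            grid=grid,
            matrix=np.vstack([s.absorbance for s in spectra]),
            sample_ids=[s.sample_id for s in spectra],
            labels=[s.group for s in spectra],
            replicates=[s.replicate for s in spectra],
            provenance=dict(provenance or {}),
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_SEP = re.compile(r"[,\t;]|\s+")


def read_two_column(path: str | Path, sample_id: str | None = None) -> Spectrum:
    """Read a two-column (wavenumber, absorbance) text export.

    Comma, tab, semicolon or whitespace separated; lines starting with
    ``#`` and blank lines are skipped. The sample id defaults to the file
    stem. Descending files are stored ascending.
    """
    path = Path(path)
    wn, ab = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in _SEP.split(line) if p]
            if len(parts) < 2:
                raise SpectraFormatError(f"{path.name}:{lineno}: expected two numbers, got {line!r}")
            try:
                x, y = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise SpectraFormatError(f"{path.name}:{lineno}: cannot parse {line!r}") from exc
            wn.append(x)
            ab.append(y)
    if len(wn) < 2:
        raise SpectraFormatError(f"{path.name}: fewer than 2 data points")
    return Spectrum(np.array(wn), np.array(ab), sample_id=sample_id or path.stem)


def read_spectra_csv(path: str | Path, metadata_path: str | Path | None = None) -> SpectraSet:
    """Read a wide CSV: first column wavenumber, one column per sample.

    The header row supplies sample ids. An optional metadata CSV with
    columns ``sample_id, group, replicate`` attaches labels; samples
    without metadata get group ``"unlabeled"`` and replicate 1. Metadata
    rows whose sample_id is absent from the header are ignored with a
    warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SpectraFormatError(f"{path.name}: need a wavenumber column plus at least one sample column")
    first = df.columns[0]
    try:
        float(first)
    except ValueError:
        pass
    else:
        raise SpectraFormatError(f"{path.name}: missing header row (first cell is numeric: {first!r})")

    grid = df.iloc[:, 0].to_numpy(dtype=float)
    mat = df.iloc[:, 1:].to_numpy(dtype=float).T  # samples x points
    if grid.size >= 2 and grid[0] > grid[-1]:
        grid = grid[::-1].copy()
        mat = mat[:, ::-1].copy()
    sample_ids = [str(c) for c in df.columns[1:]]

    groups = {sid: "unlabeled" for sid in sample_ids}
    reps = {sid: 1 for sid in sample_ids}
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path)
        required = {"sample_id", "group"}
        if not required.issubset(meta.columns):
            raise SpectraFormatError("metadata must have columns sample_id, group[, replicate]")
        for _, rec in meta.iterrows():
            sid = str(rec["sample_id"])
            if sid not in groups:
                warnings.warn(f"metadata sample_id {sid!r} not present in {path.name}; row ignored")
                continue
            groups[sid] = str(rec["group"])
            if "replicate" in meta.columns and not pd.isna(rec["replicate"]):
                reps[sid] = int(rec["replicate"])

    return SpectraSet(
        grid=grid,
        matrix=mat,
        sample_ids=sample_ids,
        labels=[groups[s] for s in sample_ids],
        replicates=[reps[s] for s in sample_ids],
        provenance={"source": str(path)},
    )


def write_spectra_csv(sset: SpectraSet, path: str | Path,
                      metadata_path: str | Path | None = None) -> None:
    """Write a SpectraSet as wide CSV (and optionally its metadata table).

    Wide-CSV column names must be unique, so when several rows share one
    sample_id (technical replicates) the column is named
    ``<sample_id>#r<replicate>``; the metadata table keys on the column
    name so a read round-trips groups and replicate indices.
    """
    ids = list(sset.sample_ids)
    if len(set(ids)) < len(ids):
        ids = [f"{sid}#r{rep}" for sid, rep in zip(ids, sset.replicates)]
    df = pd.DataFrame({"wavenumber": sset.grid})
    for i, cid in enumerate(ids):
        df[cid] = sset.matrix[i]
    df.to_csv(path, index=False, float_format="%.17g")
    if metadata_path is not None:
        pd.DataFrame(
            {"sample_id": ids, "group": sset.labels, "replicate": sset.replicates}
        ).to_csv(metadata_path, index=False)


_JCAMP_DATA = re.compile(r"##(XYPOINTS|XYDATA)\s*=\s*(.*)", re.IGNORECASE)
# AFFN tokens are plain decimal numbers; SQZ/DIF/DUP compressed forms pack
# digits into letters (@, A-I, a-i, J-R, j-r, %, S-Z)
_AFFN_TOKEN = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def read_jcamp_xy(path: str | Path, sample_id: str | None = None) -> Spectrum:
    """Read a minimal JCAMP-DX file with an AFFN XYPOINTS/XYDATA block.

    Only uncompressed (X, Y) pairs are supported; SQZ/DIF/DUP encodings
    raise an "unsupported encoding" error.
    """
    path = Path(path)
    lines = Path(path).read_text().splitlines()
    start = None
    for i, line in enumerate(lines):
        if _JCAMP_DATA.match(line.strip()):
            start = i
            break
    if start is None:
        raise SpectraFormatError(f"{path.name}: no ##XYDATA/##XYPOINTS block found")

    values: list[float] = []
    for line in lines[start + 1:]:
        stripped = line.strip()
        if stripped.startswith("##"):
            break
        if not stripped or stripped.startswith("$$"):
            continue
        for tok in (t for t in _SEP.split(stripped) if t):
            if not _AFFN_TOKEN.match(tok):
                raise SpectraFormatError(
                    f"{path.name}: unsupported encoding (non-AFFN token {tok!r}); "
                    "compressed JCAMP forms (SQZ/DIF/DUP) are not supported"
                )
            values.append(float(tok))
    if len(values) < 4 or len(values) % 2:
        raise SpectraFormatError(f"{path.name}: XY data must hold >= 2 complete (X, Y) pairs")
    arr = np.array(values).reshape(-1, 2)
    return Spectrum(arr[:, 0], arr[:, 1], sample_id=sample_id or path.stem)


# ---------------------------------------------------------------------------
# gridding
# ---------------------------------------------------------------------------

def _target_from_spacing(lo: float, hi: float, spacing: float) -> np.ndarray:
    n = int(np.floor((hi - lo) / spacing + 1e-9)) + 1
    return lo + spacing * np.arange(n)


def resample_to_grid(obj: Spectrum | SpectraSet, spacing_cm1: float | None = None,
                     target_grid: np.ndarray | None = None):
    """Linearly interpolate a spectrum or set onto a new wavenumber grid.

    Exactly one of ``spacing_cm1`` (uniform grid spanning the source) or
    ``target_grid`` must be given. The target must lie within the source
    span; no extrapolation is performed. A target identical to the source
    grid returns the values unchanged.
    """
    if (spacing_cm1 is None) == (target_grid is None):
        raise ValueError("give exactly one of spacing_cm1 or target_grid")
    src = obj.wavenumbers if isinstance(obj, Spectrum) else obj.grid
    if target_grid is None:
        target = _target_from_spacing(src[0], src[-1], float(spacing_cm1))
    else:
        target = np.sort(np.asarray(target_grid, dtype=float))
    if target[0] < src[0] - GRID_ATOL or target[-1] > src[-1] + GRID_ATOL:
        raise ValueError(
            f"target grid [{target[0]}, {target[-1]}] extends beyond source span [{src[0]}, {src[-1]}]"
        )
    if target.size == src.size and np.max(np.abs(target - src)) <= GRID_ATOL:
        return obj

    if isinstance(obj, Spectrum):
        return obj.with_absorbance(np.interp(target, src, obj.absorbance), wavenumbers=target)
    mat = np.vstack([np.interp(target, src, row) for row in obj.matrix])
    return SpectraSet(
        grid=target, matrix=mat, sample_ids=list(obj.sample_ids),
        labels=list(obj.labels), replicates=list(obj.replicates),
        provenance=dict(obj.provenance),
    )
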