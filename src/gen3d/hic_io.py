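"""Contact-list parsing, matrix binning, gap removal and normalization.

The raw input is a whitespace/tab-delimited list of intra-chromosomal
contacts, one per line: ``chrom pos_a pos_b`` (``#`` starts a comment).
Contacts are binned into a symmetric contact matrix at a fixed
resolution; centromere/assembly-gap regions (which carry no Hi-C signal)
are removed; the matrix can optionally be balanced.

Binning convention: bins are half-open, 0-based; a coordinate maps to
region ``floor((pos − origin) / resolution)`` with origin defaulting to
the lowest coordinate observed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "ContactRecord",
    "GapAnnotation",
    "ContactMatrix",
    "parse_contacts",
    "write_contacts",
    "build_matrix",
    "remove_gaps",
    "normalize",
    "read_bed_gaps",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_matrix_triplets",
    "read_matrix_triplets",
    "write_matrix_hdf5",
    "read_matrix_hdf5",
]


@dataclass(frozen=True)
class ContactRecord:
    """One Hi-C contact: a chromosome and two genomic coordinates (bp)."""

    chrom: str
    pos_a: int
    pos_b: int

    def __post_init__(self) -> None:
        if self.pos_a < 0 or self.pos_b < 0:
            raise ValueError("genomic coordinates must be non-negative")


@dataclass
class GapAnnotation:
    """Half-open genomic intervals (bp) to omit from the matrix."""

    intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        ivs = sorted((int(s), int(e)) for s, e in self.intervals)
        for s, e in ivs:
            if e <= s:
                raise ValueError(f"empty or inverted interval ({s}, {e})")
        for (_, e0), (s1, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError("gap intervals overlap")
        self.intervals = ivs

    def overlaps(self, start: int, end: int) -> bool:
        """True if [start, end) intersects any gap interval."""
        return any(s < end and start < e for s, e in self.intervals)


@dataclass
class ContactMatrix:
    """Symmetric per-chromosome interaction-frequency matrix.

    ``gap_mask`` is indexed over the *pre-omission* region count; True
    marks a removed region.  ``region_index`` maps each retained row to
    its original region number.  Diagonal entries are stored but ignored
    by all scoring.
    """

    freq: np.ndarray
    resolution: int
    origin: int = 0
    gap_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    region_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        f = np.asarray(self.freq)
        if f.ndim != 2 or f.shape[0] != f.shape[1]:
            raise ValueError(f"freq must be square, got shape {f.shape}")
        if not np.allclose(f, f.T):
            raise ValueError("freq must be symmetric")
        if np.any(f < 0):
            raise ValueError("freq must be non-negative")
        self.freq = f
        n = f.shape[0]
        if self.region_index is None:
            self.region_index = np.arange(n)
        else:
            self.region_index = np.asarray(self.region_index, dtype=int)
        if self.gap_mask is None:
            pre = int(self.region_index.max()) + 1 if self.region_index.size else 0
            self.gap_mask = np.zeros(pre, dtype=bool)
        else:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if len(self.region_index) != n:
            raise ValueError("region_index length must match matrix size")

    @property
    def n_regions(self) -> int:
        """Number of retained regions (matrix size)."""
        return self.freq.shape[0]

    def region_span(self, row: int) -> tuple[int, int]:
        """Genomic half-open interval [start, end) of a retained row."""
        orig = int(self.region_index[row])
        start = self.origin + orig * self.resolution
        return start, start + self.resolution

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            freq=self.freq.copy(),
            resolution=self.resolution,
            origin=self.origin,
            gap_mask=self.gap_mask.copy(),
            region_index=self.region_index.copy(),
        )


def _iter_lines(stream) -> Iterator[str]:
    if isinstance(stream, (str, Path)):
        with open(stream) as fh:
            yield from fh
    else:
        yield from stream


def parse_contacts(stream, chrom: str) -> list[ContactRecord]:
    """Parse a delimited contact list, keeping records on *chrom*.

    *stream* may be a path or an iterable of lines.  Lines starting with
    ``#`` and blank lines are skipped.  A malformed line raises
    ``ValueError`` naming the line number.  An empty result triggers a
    warning.
    """
    records: list[ContactRecord] = []
    for lineno, raw in enumerate(_iter_lines(stream), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ValueError(
                f"line {lineno}: expected at least 3 fields, got {len(fields)}"
            )
        try:
            pos_a, pos_b = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: coordinates must be integers") from exc
        if pos_a < 0 or pos_b < 0:
            raise ValueError(f"line {lineno}: coordinates must be non-negative")
        if fields[0] == chrom:
            records.append(ContactRecord(fields[0], pos_a, pos_b))
    if not records:
        warnings.warn(f"no contacts found for chromosome {chrom!r}", stacklevel=2)
    return records


def write_contacts(records: Sequence[ContactRecord], path) -> None:
    """Write records back out in the 3-column input format."""
    with open(path, "w") as fh:
        fh.write("# chrom pos_a pos_b\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos_a}\t{r.pos_b}\n")


def build_matrix(
    records: Sequence[ContactRecord],
    resolution: int,
    origin: int | None = None,
) -> ContactMatrix:
    """Bin contact records into a symmetric contact matrix.

    The origin defaults to the lowest coordinate observed; pass
    ``origin=0`` for a dataset-independent frame.  Each record increments
    ``freq[i, j]`` and ``freq[j, i]`` by one (duplicates are counted).
    """
    if not records:
        raise ValueError("cannot build a matrix from an empty record list")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    pos = np.array([[r.pos_a, r.pos_b] for r in records], dtype=np.int64)
    if origin is None:
        origin = int(pos.min())
    elif pos.min() < origin:
        raise ValueError("records contain coordinates below the requested origin")
    span = int(pos.max()) - origin
    # span // resolution is the highest occupied bin; one more bin covers it
    # (equals ceil(span/resolution) except exactly at a bin boundary).
    n = span // resolution + 1
    bins = (pos - origin) // resolution
    freq = np.zeros((n, n), dtype=np.int64)
    # both mirror entries are bumped, so a same-bin record adds 2 to the
    # diagonal; record count = strict upper triangle + half the diagonal
    np.add.at(freq, (bins[:, 0], bins[:, 1]), 1)
    np.add.at(freq, (bins[:, 1], bins[:, 0]), 1)
    return ContactMatrix(
        freq=freq,
        resolution=int(resolution),
        origin=origin,
        gap_mask=np.zeros(n, dtype=bool),
        region_index=np.arange(n),
    )


def _auto_gap_rows(freq: np.ndarray) -> np.ndarray:
    """Rows of the single longest contiguous run of all-zero rows."""
    zero = ~np.any(freq != 0, axis=1)
    best_start, best_len = 0, 0
    run_start = None
    for k, z in enumerate(list(zero) + [False]):
        if z and run_start is None:
            run_start = k
        elif not z and run_start is not None:
            if k - run_start > best_len:
                best_start, best_len = run_start, k - run_start
            run_start = None
    if best_len == 0:
        return np.array([], dtype=int)
    return np.arange(best_start, best_start + best_len)


def remove_gaps(m: ContactMatrix, gaps: GapAnnotation | str) -> ContactMatrix:
    """Delete rows/columns overlapping gap intervals.

    With ``gaps="auto"`` the single longest contiguous run of all-zero
    rows is removed (no-op when every row carries signal).  The returned
    matrix records the surviving original indices in ``region_index`` and
    flags removed regions in ``gap_mask``.
    """
    if isinstance(gaps, str):
        if gaps != "auto":
            raise ValueError(f"unknown gap mode {gaps!r}")
        drop_rows = _auto_gap_rows(m.freq)
    else:
        drop_rows = np.array(
            [
                row
                for row in range(m.n_regions)
                if gaps.overlaps(*m.region_span(row))
            ],
            dtype=int,
        )
    if drop_rows.size == 0:
        return m.copy()
    if drop_rows.size == m.n_regions:
        raise ValueError("gap annotation covers every region")
    keep = np.setdiff1d(np.arange(m.n_regions), drop_rows)
    gap_mask = m.gap_mask.copy()
    gap_mask[m.region_index[drop_rows]] = True
    return ContactMatrix(
        freq=m.freq[np.ix_(keep, keep)].copy(),
        resolution=m.resolution,
        origin=m.origin,
        gap_mask=gap_mask,
        region_index=m.region_index[keep].copy(),
    )


def normalize(
    m: ContactMatrix,
    method: str = "ice",
    tol: float = 1e-6,
    max_iter: int = 200,
) -> ContactMatrix:
    """Balance a contact matrix.

    ``"ice"`` iteratively divides rows/columns by their marginal sums
    (rescaled to mean 1 over non-empty rows) until the marginals agree
    within *tol*; ``"coverage"`` is a single-pass division by
    ``sqrt(rowsum_i · rowsum_j)``; ``"none"`` returns a copy.  All-zero
    rows are left untouched.  Non-convergence warns and returns the best
    iterate.
    """
    if method == "none":
        return m.copy()
    w = m.freq.astype(float)
    rowsum = w.sum(axis=1)
    nz = rowsum > 0
    if method == "coverage":
        scale = np.ones_like(rowsum)
        scale[nz] = np.sqrt(rowsum[nz])
        w = w / np.outer(scale, scale)
    elif method == "ice":
        converged = False
        residual = math.inf
        for _ in range(max_iter):
            s = w.sum(axis=1)
            s = s / s[nz].mean()
            residual = float(np.abs(s[nz] - 1.0).max()) if nz.any() else 0.0
            if residual < tol:
                converged = True
                break
            s[~nz] = 1.0
            s[s == 0] = 1.0
            w = w / np.outer(s, s)
        if not converged:
            warnings.warn(
                f"ICE did not converge in {max_iter} iterations "
                f"(residual {residual:.3g}); returning best iterate",
                stacklevel=2,
            )
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    w = (w + w.T) / 2.0  # enforce exact symmetry against float drift
    return ContactMatrix(
        freq=w,
        resolution=m.resolution,
        origin=m.origin,
        gap_mask=m.gap_mask.copy(),
        region_index=m.region_index.copy(),
    )


# ---------------------------------------------------------------------------
# File formats


def read_bed_gaps(path, chrom: str | None = None) -> GapAnnotation:
    """Read gap intervals from a BED(-like) file, optionally filtering."""
    intervals = []
    for raw in _iter_lines(path):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ValueError(f"BED line needs 3 fields: {line!r}")
        if chrom is not None and fields[0] != chrom:
            continue
        intervals.append((int(fields[1]), int(fields[2])))
    return GapAnnotation(intervals)


def write_matrix_tsv(m: ContactMatrix, path) -> None:
    """Dense tab-delimited matrix with metadata in ``#`` header lines."""
    with open(path, "w") as fh:
        fh.write(f"# resolution={m.resolution}\n")
        fh.write(f"# origin={m.origin}\n")
        fh.write("# region_index=" + ",".join(map(str, m.region_index)) + "\n")
        fh.write("# gap_mask=" + "".join("1" if g else "0" for g in m.gap_mask) + "\n")
        fmt = "%d" if np.issubdtype(m.freq.dtype, np.integer) else "%.10g"
        np.savetxt(fh, m.freq, fmt=fmt, delimiter="\t")


def read_matrix_tsv(path) -> ContactMatrix:
    meta: dict[str, str] = {}
    rows = []
    for raw in _iter_lines(path):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
            continue
        rows.append([float(x) for x in line.split("\t")])
    freq = np.array(rows)
    if np.allclose(freq, np.round(freq)):
        freq = freq.astype(np.int64)
    n = freq.shape[0]
    region_index = (
        np.array([int(x) for x in meta["region_index"].split(",")])
        if "region_index" in meta
        else np.arange(n)
    )
    gap_mask = (
        np.array([c == "1" for c in meta["gap_mask"]])
        if "gap_mask" in meta
        else np.zeros(n, dtype=bool)
    )
    return ContactMatrix(
        freq=freq,
        resolution=int(meta.get("resolution", 1)),
        origin=int(meta.get("origin", 0)),
        gap_mask=gap_mask,
        region_index=region_index,
    )


def write_matrix_triplets(m: ContactMatrix, path) -> None:
    """Sparse ``i j count`` triplets over the upper triangle (with diag)."""
    with open(path, "w") as fh:
        fh.write(f"# resolution={m.resolution}\n")
        fh.write(f"# origin={m.origin}\n")
        fh.write(f"# n={m.n_regions}\n")
        ii, jj = np.nonzero(np.triu(m.freq))
        for i, j in zip(ii, jj):
            v = m.freq[i, j]
            sval = f"{int(v)}" if float(v).is_integer() else f"{v:.10g}"
            fh.write(f"{i}\t{j}\t{sval}\n")


def read_matrix_triplets(path) -> ContactMatrix:
    meta: dict[str, str] = {}
    trips = []
    for raw in _iter_lines(path):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
            continue
        i, j, v = line.split()
        trips.append((int(i), int(j), float(v)))
    if "n" in meta:
        n = int(meta["n"])
    elif trips:
        n = max(max(i, j) for i, j, _ in trips) + 1
    else:
        raise ValueError("empty triplet file without an '# n=' header")
    freq = np.zeros((n, n))
    for i, j, v in trips:
        freq[i, j] = v
        freq[j, i] = v
    if np.allclose(freq, np.round(freq)):
        freq = freq.astype(np.int64)
    return ContactMatrix(
        freq=freq,
        resolution=int(meta.get("resolution", 1)),
        origin=int(meta.get("origin", 0)),
    )


def write_matrix_hdf5(m: ContactMatrix, path, group: str = "matrix") -> None:
    import h5py

    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        g.create_dataset("freq", data=m.freq)
        g.create_dataset("gap_mask", data=m.gap_mask)
        g.create_dataset("region_index", data=m.region_index)
        g.attrs["resolution"] = m.resolution
        g.attrs["origin"] = m.origin


def read_matrix_hdf5(path, group: str = "matrix") -> ContactMatrix:
    import h5py

    with h5py.File(path, "r") as fh:
        g = fh[group]
        return ContactMatrix(
            freq=g["freq"][()],
            resolution=int(g.attrs["resolution"]),
            origin=int(g.attrs["origin"]),
            gap_mask=g["gap_mask"][()],
            region_index=g["region_index"][()],
        )
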