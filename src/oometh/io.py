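"""Readers and writers for the on-disk formats used throughout the pipeline.

Three coordinate conventions meet here and are reconciled at the I/O
boundary only:

* internal coordinates are 0-based half-open;
* Bismark-dialect coverage files are 1-based inclusive
  (``chrom  start  end  percent  count_methylated  count_unmethylated``);
* BED is already 0-based half-open.

CG dinucleotides are indexed at the position of the plus-strand C. Calls
reported at the G of a CG (position C+1) are folded onto the C by summing
counts whenever a :class:`GenomeIndex` is supplied, which halves the index
and matches how genomic CG occurrences are counted; per-strand counting is
available by passing ``fold_strands=False``.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

__all__ = [
    "CpGCall",
    "ChromCalls",
    "MethylomeLibrary",
    "GenomeIndex",
    "Feature",
    "AnnotationTrack",
    "CoverageParseError",
    "read_coverage",
    "write_coverage",
    "read_bed",
    "build_genome_index",
    "write_results_table",
    "read_results_table",
    "RESULTS_COLUMNS",
]

RESULTS_COLUMNS = [
    "region",
    "group_a_pct",
    "group_b_pct",
    "n_meth_a",
    "n_unmeth_a",
    "n_meth_b",
    "n_unmeth_b",
    "statistic",
    "p",
    "fdr",
    "flags",
]


class CoverageParseError(ValueError):
    """A coverage file line could not be parsed; carries the line number."""


@dataclass(frozen=True)
class CpGCall:
    """One cytosine observation: methylated/unmethylated call counts.

    ``pos`` is the 0-based position of the C of a plus-strand CG dinucleotide
    (or of the cytosine itself for non-CG context).
    """

    chrom: str
    pos: int
    n_meth: int
    n_unmeth: int
    context: str = "CG"

    def __post_init__(self) -> None:
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError("negative call counts")
        if self.n_meth + self.n_unmeth < 1:
            raise ValueError("stored calls need at least one observation")

    @property
    def total(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def pct(self) -> float:
        return 100.0 * self.n_meth / self.total


@dataclass
class ChromCalls:
    """Column-oriented calls for one chromosome, sorted by position."""

    pos: np.ndarray
    n_meth: np.ndarray
    n_unmeth: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.n_meth = np.asarray(self.n_meth, dtype=np.int64)
        self.n_unmeth = np.asarray(self.n_unmeth, dtype=np.int64)
        if not (len(self.pos) == len(self.n_meth) == len(self.n_unmeth)):
            raise ValueError("column length mismatch")
        if len(self.pos) > 1 and np.any(np.diff(self.pos) <= 0):
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.pos)


CallsByChrom = dict[str, ChromCalls]


@dataclass
class MethylomeLibrary:
    """Per-cytosine methylation calls of one single-cell library.

    ``calls`` holds CpG-context observations, ``ch_calls`` the parallel
    non-CG (CH) context; both are keyed by chromosome and sorted by position
    with no duplicate positions within a context.
    """

    library_id: str
    donor_id: str = ""
    group: str = ""
    calls: CallsByChrom = field(default_factory=dict)
    ch_calls: CallsByChrom = field(default_factory=dict)

    def context(self, context: str = "CG") -> CallsByChrom:
        if context == "CG":
            return self.calls
        if context == "CH":
            return self.ch_calls
        raise ValueError(f"unknown context {context!r}")

    def n_calls(self, context: str = "CG") -> int:
        return sum(len(c) for c in self.context(context).values())

    def iter_calls(self, context: str = "CG") -> Iterator[CpGCall]:
        for chrom in sorted(self.context(context)):
            cc = self.context(context)[chrom]
            for p, m, u in zip(cc.pos, cc.n_meth, cc.n_unmeth):
                yield CpGCall(chrom, int(p), int(m), int(u), context=context)

    def to_frame(self, context: str = "CG") -> pd.DataFrame:
        parts = []
        for chrom in sorted(self.context(context)):
            cc = self.context(context)[chrom]
            parts.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": cc.pos,
                        "n_meth": cc.n_meth,
                        "n_unmeth": cc.n_unmeth,
                    }
                )
            )
        if not parts:
            return pd.DataFrame(columns=["chrom", "pos", "n_meth", "n_unmeth"])
        return pd.concat(parts, ignore_index=True)


@dataclass
class GenomeIndex:
    """Ordered plus-strand CG positions per chromosome.

    The coordinate backbone for CG-count tiling: ``positions[chrom]`` is a
    strictly increasing array of 0-based positions of the C of every CG
    dinucleotide. ``allosomes`` flags sex chromosomes (by default any
    chromosome whose name ends in X or Y, case-insensitive).
    """

    positions: dict[str, np.ndarray]
    lengths: dict[str, int]
    allosomes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if len(pos) > 1 and np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: CG positions not strictly increasing")
            self.positions[chrom] = pos
        if not self.allosomes:
            self.allosomes = {
                c for c in self.positions if c.upper().rstrip("XY") != c.upper()
            }

    @property
    def chroms(self) -> list[str]:
        return sorted(self.positions)

    def autosomes(self) -> list[str]:
        return [c for c in self.chroms if c not in self.allosomes]

    def largest_autosome(self) -> str:
        autos = self.autosomes()
        if not autos:
            raise ValueError("index has no autosome")
        return max(autos, key=lambda c: self.lengths.get(c, len(self.positions[c])))

    def n_cg(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.positions.get(chrom, ()))
        return sum(len(p) for p in self.positions.values())

    def membership(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Boolean mask: which of ``pos`` are indexed CG positions on ``chrom``."""
        ref = self.positions.get(chrom)
        if ref is None or len(ref) == 0:
            return np.zeros(len(pos), dtype=bool)
        idx = np.searchsorted(ref, pos)
        idx = np.clip(idx, 0, len(ref) - 1)
        return ref[idx] == pos


@dataclass(frozen=True)
class Feature:
    """A 0-based half-open annotated interval."""

    chrom: str
    start: int
    end: int
    label: str
    oe_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"feature {self.label!r} ({self.chrom}:{self.start}-{self.end}): "
                "start must be < end"
            )


@dataclass
class AnnotationTrack:
    """A named, sorted collection of features with unique labels."""

    name: str
    features: list[Feature]

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.chrom, f.start, f.end))
        labels = [f.label for f in self.features]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"track {self.name!r}: duplicate labels {dupes}")

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def on_chrom(self, chrom: str) -> list[Feature]:
        return [f for f in self.features if f.chrom == chrom]

    def to_bed(self, path: str | Path) -> None:
        with _open_write(path) as fh:
            for f in self.features:
                cols = [f.chrom, str(f.start), str(f.end), f.label]
                if f.oe_ratio is not None:
                    cols.append(repr(float(f.oe_ratio)))
                fh.write("\t".join(cols) + "\n")


def _open_read(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _open_write(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "w")


def read_coverage(
    path: str | Path,
    context: str = "CG",
    index: GenomeIndex | None = None,
    fold_strands: bool = True,
) -> CallsByChrom:
    """Read a Bismark-dialect coverage file into per-chromosome call arrays.

    Columns: chrom, start (1-based), end, percent, n_meth, n_unmeth. The
    percent column is ignored and recomputed downstream from the counts.
    Records with zero total calls are skipped with a warning (sparse
    single-cell files legitimately contain them after strand splitting).

    When ``index`` is given and ``fold_strands`` is true (CG context only),
    calls at the G of an indexed CG are folded onto the C position by summing
    counts; positions matching neither strand of an indexed CG are an error.
    """
    rows: dict[str, list[tuple[int, int, int]]] = {}
    n_skipped = 0
    with _open_read(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise CoverageParseError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, "
                    f"got {len(parts)}"
                )
            chrom = parts[0]
            try:
                start = int(parts[1])
                n_meth = int(parts[4])
                n_unmeth = int(parts[5])
            except ValueError as exc:
                raise CoverageParseError(f"{path}:{lineno}: {exc}") from exc
            if n_meth < 0 or n_unmeth < 0:
                raise CoverageParseError(f"{path}:{lineno}: negative count")
            if n_meth + n_unmeth == 0:
                n_skipped += 1
                continue
            rows.setdefault(chrom, []).append((start - 1, n_meth, n_unmeth))
    if n_skipped:
        warnings.warn(
            f"{path}: skipped {n_skipped} record(s) with zero total calls",
            stacklevel=2,
        )

    out: CallsByChrom = {}
    for chrom, recs in rows.items():
        arr = np.array(recs, dtype=np.int64)
        pos, meth, unmeth = arr[:, 0], arr[:, 1], arr[:, 2]
        if index is not None and fold_strands and context == "CG":
            on_c = index.membership(chrom, pos)
            on_g = index.membership(chrom, pos - 1)
            bad = ~(on_c | on_g)
            if bad.any():
                first = int(pos[bad][0])
                raise ValueError(
                    f"{path}: {chrom}:{first + 1} is not a strand of an indexed CG"
                )
            pos = np.where(on_c, pos, pos - 1)
        order = np.argsort(pos, kind="stable")
        pos, meth, unmeth = pos[order], meth[order], unmeth[order]
        upos, inv = np.unique(pos, return_inverse=True)
        out[chrom] = ChromCalls(
            pos=upos,
            n_meth=np.bincount(inv, weights=meth).astype(np.int64),
            n_unmeth=np.bincount(inv, weights=unmeth).astype(np.int64),
        )
    return out


def write_coverage(calls: CallsByChrom, path: str | Path) -> None:
    """Write per-chromosome call arrays as a Bismark-dialect coverage file."""
    with _open_write(path) as fh:
        for chrom in sorted(calls):
            cc = calls[chrom]
            for p, m, u in zip(cc.pos, cc.n_meth, cc.n_unmeth):
                pct = 100.0 * m / (m + u)
                fh.write(f"{chrom}\t{p + 1}\t{p + 1}\t{pct:.6g}\t{m}\t{u}\n")


def read_bed(path: str | Path, name: str | None = None) -> AnnotationTrack:
    """Read BED3/BED4(+optional numeric column reused as the CpG o/e ratio)."""
    feats: list[Feature] = []
    with _open_read(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: interval {chrom}:{start}-{end} has start >= end"
                )
            label = parts[3] if len(parts) > 3 and parts[3] else f"{chrom}:{start}-{end}"
            oe = None
            if len(parts) > 4 and parts[4] not in ("", "."):
                try:
                    oe = float(parts[4])
                except ValueError:
                    oe = None
            feats.append(Feature(chrom, start, end, label, oe))
    return AnnotationTrack(name or Path(path).stem, feats)


def build_genome_index(fasta_path: str | Path, allosomes: set[str] | None = None) -> GenomeIndex:
    """Scan a FASTA for plus-strand CG dinucleotides (case-insensitive)."""
    fa = Fasta(str(fasta_path), rebuild=True, read_ahead=None)
    names = list(fa.keys())
    if not names:
        raise ValueError(f"{fasta_path}: empty FASTA")
    positions: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    for chrom in names:
        seq = str(fa[chrom][:]).upper()
        lengths[chrom] = len(seq)
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        if len(arr) < 2:
            positions[chrom] = np.empty(0, dtype=np.int64)
            continue
        is_cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
        positions[chrom] = np.flatnonzero(is_cg).astype(np.int64)
    return GenomeIndex(positions=positions, lengths=lengths, allosomes=allosomes or set())


def write_results_table(records: Iterable[Mapping | object], path: str | Path) -> None:
    """Write result records as a TSV with the fixed result schema.

    Floats are written with Python's shortest-round-trip repr so that
    reading the table back reproduces every value bit-identically.
    """
    rows = []
    for rec in records:
        if not isinstance(rec, Mapping):
            rec = rec.to_record()  # type: ignore[union-attr]
        rows.append({col: rec.get(col, "") for col in RESULTS_COLUMNS})
    with _open_write(path) as fh:
        fh.write("\t".join(RESULTS_COLUMNS) + "\n")
        for row in rows:
            cells = []
            for col in RESULTS_COLUMNS:
                v = row[col]
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    cells.append("")
                elif isinstance(v, float):
                    cells.append(repr(v))
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read a results TSV back; raises on a missing column."""
    df = pd.read_csv(_open_read(path), sep="\t", dtype={"region": str, "flags": str})
    missing = [c for c in RESULTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing result columns {missing}")
    return df
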