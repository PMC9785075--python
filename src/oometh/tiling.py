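"""CG-count tiling, methylation quantitation, and domain segmentation.

The genome is partitioned into consecutive windows containing a fixed number
of CG dinucleotides (500 CGs for the unbiased landscape, 100 CGs for the
segmentation pass). Windows are quantitated by pooling methylated and
unmethylated calls over one or more libraries, and a window only yields a
percentage when enough distinct CG positions were observed in it (5 for
500-CG tiles, 10 for domains). Adjacent 100-CG tiles sharing a methylation
state (methylated at >=50%, unmethylated below) are merged into contiguous
domains by run-length encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import CallsByChrom, GenomeIndex, MethylomeLibrary

__all__ = [
    "Tile",
    "Domain",
    "MethylationQuant",
    "make_cg_tiles",
    "quantitate",
    "quantitate_tiles",
    "classify_tile",
    "global_mean",
    "mean_of_tile_pcts",
    "segment_domains",
    "quantitate_domains",
]


@dataclass(frozen=True)
class Tile:
    """A window of ``n_cg_genomic`` consecutive genomic CG positions.

    ``start``/``end`` are 0-based half-open and span from the first CG to one
    past the end of the last CG dinucleotide in the window. ``index`` is the
    ordinal of the tile within its chromosome; the final tile of a
    chromosome may hold fewer CGs and is flagged ``partial``.
    """

    chrom: str
    start: int
    end: int
    n_cg_genomic: int
    index: int
    partial: bool = False

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Domain:
    """A run of contiguous same-state 100-CG tiles.

    ``state`` is ``"M"`` (methylated) or ``"U"`` (unmethylated);
    ``member_tiles`` lists the per-chromosome indices of the quantified tiles
    that define the run (unquantified tiles absorbed inside the run are part
    of the territory but contribute no state).
    """

    chrom: str
    start: int
    end: int
    state: str
    member_tiles: tuple[int, ...]
    n_cg_genomic: int

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.state}"


@dataclass
class MethylationQuant:
    """Pooled methylation counts for one region.

    ``n_cg_observed`` counts distinct CG positions with at least one call
    (not total calls); ``pct_read_cgs`` relates it to the genomic CG content
    of the region when that is known.
    """

    region_id: str
    n_meth: int
    n_unmeth: int
    n_cg_observed: int
    n_cg_genomic: int | None = None

    @property
    def total(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def pct(self) -> float:
        return 100.0 * self.n_meth / self.total

    @property
    def pct_read_cgs(self) -> float | None:
        if not self.n_cg_genomic:
            return None
        return 100.0 * self.n_cg_observed / self.n_cg_genomic


def make_cg_tiles(index: GenomeIndex, tile_size_cg: int) -> list[Tile]:
    """Cut each chromosome into consecutive windows of ``tile_size_cg`` CGs.

    The trailing window of a chromosome is emitted even when it holds fewer
    CGs, flagged partial; downstream minimum-CG filters handle it naturally.
    """
    if tile_size_cg < 1:
        raise ValueError("tile_size_cg must be >= 1")
    tiles: list[Tile] = []
    for chrom in index.chroms:
        pos = index.positions[chrom]
        if len(pos) == 0:
            continue
        for i, lo in enumerate(range(0, len(pos), tile_size_cg)):
            chunk = pos[lo : lo + tile_size_cg]
            tiles.append(
                Tile(
                    chrom=chrom,
                    start=int(chunk[0]),
                    end=int(chunk[-1]) + 2,
                    n_cg_genomic=len(chunk),
                    index=i,
                    partial=len(chunk) < tile_size_cg,
                )
            )
    return tiles


def _pool_libs(libs: MethylomeLibrary | Iterable[MethylomeLibrary], context: str = "CG") -> CallsByChrom:
    """Pool call counts of one or more libraries per position."""
    if isinstance(libs, MethylomeLibrary):
        libs = [libs]
    pooled: dict[str, list] = {}
    for lib in libs:
        for chrom, cc in lib.context(context).items():
            pooled.setdefault(chrom, []).append(cc)
    out: CallsByChrom = {}
    from .io import ChromCalls

    for chrom, parts in pooled.items():
        if len(parts) == 1:
            out[chrom] = parts[0]
            continue
        pos = np.concatenate([p.pos for p in parts])
        meth = np.concatenate([p.n_meth for p in parts])
        unmeth = np.concatenate([p.n_unmeth for p in parts])
        upos, inv = np.unique(pos, return_inverse=True)
        out[chrom] = ChromCalls(
            pos=upos,
            n_meth=np.bincount(inv, weights=meth).astype(np.int64),
            n_unmeth=np.bincount(inv, weights=unmeth).astype(np.int64),
        )
    return out


def quantitate(
    region: tuple[str, int, int] | Tile | Domain,
    libs: MethylomeLibrary | Iterable[MethylomeLibrary],
    min_cg_obs: int = 1,
    index: GenomeIndex | None = None,
    region_id: str | None = None,
) -> MethylationQuant | None:
    """Pool calls over ``libs`` inside one region; None below the CG minimum."""
    if min_cg_obs < 1:
        raise ValueError("min_cg_obs must be >= 1")
    if isinstance(region, (Tile, Domain)):
        chrom, start, end = region.chrom, region.start, region.end
        rid = region_id or region.region_id
        n_genomic: int | None = region.n_cg_genomic
    else:
        chrom, start, end = region
        rid = region_id or f"{chrom}:{start}-{end}"
        n_genomic = None
    if index is not None:
        pos = index.positions.get(chrom)
        n_genomic = (
            0
            if pos is None
            else int(np.searchsorted(pos, end) - np.searchsorted(pos, start))
        )
    pooled = _pool_libs(libs)
    cc = pooled.get(chrom)
    if cc is None or len(cc) == 0:
        return None
    lo, hi = np.searchsorted(cc.pos, [start, end])
    n_obs = hi - lo
    if n_obs < min_cg_obs:
        return None
    return MethylationQuant(
        region_id=rid,
        n_meth=int(cc.n_meth[lo:hi].sum()),
        n_unmeth=int(cc.n_unmeth[lo:hi].sum()),
        n_cg_observed=int(n_obs),
        n_cg_genomic=n_genomic,
    )


def quantitate_tiles(
    tiles: Sequence[Tile],
    libs: MethylomeLibrary | Iterable[MethylomeLibrary],
    min_cg_obs: int = 5,
) -> list[MethylationQuant | None]:
    """Quantitate every tile at once (vectorised per chromosome).

    Returns one entry per tile, aligned with ``tiles``; entries with fewer
    than ``min_cg_obs`` observed CG positions are None.
    """
    pooled = _pool_libs(libs)
    by_chrom: dict[str, list[Tile]] = {}
    for t in tiles:
        by_chrom.setdefault(t.chrom, []).append(t)
    out: dict[tuple[str, int], MethylationQuant] = {}
    for chrom, chrom_tiles in by_chrom.items():
        cc = pooled.get(chrom)
        if cc is None or len(cc) == 0:
            continue
        chrom_tiles.sort(key=lambda t: t.index)
        starts = np.array([t.start for t in chrom_tiles])
        ends = np.array([t.end for t in chrom_tiles])
        lo = np.searchsorted(cc.pos, starts)
        hi = np.searchsorted(cc.pos, ends)
        cmeth = np.concatenate([[0], np.cumsum(cc.n_meth)])
        cunmeth = np.concatenate([[0], np.cumsum(cc.n_unmeth)])
        for t, l, h in zip(chrom_tiles, lo, hi):
            n_obs = int(h - l)
            if n_obs < min_cg_obs:
                continue
            out[(chrom, t.index)] = MethylationQuant(
                region_id=t.region_id,
                n_meth=int(cmeth[h] - cmeth[l]),
                n_unmeth=int(cunmeth[h] - cunmeth[l]),
                n_cg_observed=n_obs,
                n_cg_genomic=t.n_cg_genomic,
            )
    return [out.get((t.chrom, t.index)) for t in tiles]


def classify_tile(pct: float, hyper_cutoff: float = 75.0, hypo_cutoff: float = 25.0) -> str:
    """Classify a tile percentage: hyper (>75), hypo (<25), else intermediate.

    Both inequalities are strict, so a tile at exactly a cutoff is
    intermediate.
    """
    if not 0.0 <= pct <= 100.0:
        raise ValueError("pct must be within [0, 100]")
    if pct > hyper_cutoff:
        return "hyper"
    if pct < hypo_cutoff:
        return "hypo"
    return "intermediate"


def global_mean(libs: MethylomeLibrary | Iterable[MethylomeLibrary]) -> float:
    """Call-weighted global CpG methylation percent over pooled libraries."""
    pooled = _pool_libs(libs)
    n_meth = sum(int(cc.n_meth.sum()) for cc in pooled.values())
    total = n_meth + sum(int(cc.n_unmeth.sum()) for cc in pooled.values())
    if total == 0:
        raise ValueError("no CpG calls to average")
    return 100.0 * n_meth / total


def mean_of_tile_pcts(quants: Iterable[MethylationQuant | None]) -> float:
    """Unweighted mean of per-tile percentages (alternative global summary)."""
    pcts = [q.pct for q in quants if q is not None]
    if not pcts:
        raise ValueError("no quantified tiles")
    return float(np.mean(pcts))


def segment_domains(
    tiles: Sequence[Tile],
    quants: Sequence[MethylationQuant | None],
    threshold: float = 50.0,
    tie_state: str = "M",
    break_on_gap: bool = False,
) -> list[Domain]:
    """Merge adjacent same-state tiles into methylation domains.

    A tile is methylated (``M``) when its percentage exceeds ``threshold``
    and unmethylated (``U``) below it; a tile at exactly the threshold takes
    ``tie_state`` (the >50/<50 definition leaves the boundary open, so the
    tie rule is explicit and configurable). Unquantified tiles are absorbed
    into the surrounding run without contributing a state, unless
    ``break_on_gap`` is set, in which case they terminate the run. Domains
    never span chromosomes, and consecutive domains on a chromosome always
    alternate state.
    """
    if len(tiles) != len(quants):
        raise ValueError("tiles and quants must align")
    if tie_state not in ("M", "U"):
        raise ValueError("tie_state must be 'M' or 'U'")
    order = sorted(range(len(tiles)), key=lambda i: (tiles[i].chrom, tiles[i].index))
    domains: list[Domain] = []
    cur: list[int] = []  # positions into `tiles` of member tiles
    cur_state: str | None = None
    cur_chrom: str | None = None

    def flush() -> None:
        nonlocal cur, cur_state
        if cur:
            members = [tiles[i] for i in cur]
            domains.append(
                Domain(
                    chrom=members[0].chrom,
                    start=members[0].start,
                    end=members[-1].end,
                    state=cur_state,  # type: ignore[arg-type]
                    member_tiles=tuple(t.index for t in members),
                    n_cg_genomic=sum(t.n_cg_genomic for t in members),
                )
            )
        cur, cur_state = [], None

    for i in order:
        tile, quant = tiles[i], quants[i]
        if tile.chrom != cur_chrom:
            flush()
            cur_chrom = tile.chrom
        if quant is None:
            if break_on_gap:
                flush()
            continue
        pct = quant.pct
        state = (
            "M" if pct > threshold else "U" if pct < threshold else tie_state
        )
        if state != cur_state:
            flush()
            cur_state = state
        cur.append(i)
    flush()
    return domains


def quantitate_domains(
    domains: Sequence[Domain],
    libs: MethylomeLibrary | Iterable[MethylomeLibrary],
    min_cg_obs: int = 10,
) -> list[MethylationQuant | None]:
    """Quantitate domains for a single library or a merged group.

    Requires at least ``min_cg_obs`` observed individual CG sites per domain
    (default 10) for a domain to be included.
    """
    pooled = _pool_libs(libs)
    out: list[MethylationQuant | None] = []
    by_chrom: dict[str, list[tuple[int, Domain]]] = {}
    for i, d in enumerate(domains):
        by_chrom.setdefault(d.chrom, []).append((i, d))
    results: dict[int, MethylationQuant] = {}
    for chrom, items in by_chrom.items():
        cc = pooled.get(chrom)
        if cc is None or len(cc) == 0:
            continue
        cmeth = np.concatenate([[0], np.cumsum(cc.n_meth)])
        cunmeth = np.concatenate([[0], np.cumsum(cc.n_unmeth)])
        starts = np.array([d.start for _, d in items])
        ends = np.array([d.end for _, d in items])
        lo = np.searchsorted(cc.pos, starts)
        hi = np.searchsorted(cc.pos, ends)
        for (i, d), l, h in zip(items, lo, hi):
            n_obs = int(h - l)
            if n_obs < min_cg_obs:
                continue
            results[i] = MethylationQuant(
                region_id=d.region_id,
                n_meth=int(cmeth[h] - cmeth[l]),
                n_unmeth=int(cunmeth[h] - cunmeth[l]),
                n_cg_observed=n_obs,
                n_cg_genomic=d.n_cg_genomic,
            )
    for i in range(len(domains)):
        out.append(results.get(i))
    return out
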