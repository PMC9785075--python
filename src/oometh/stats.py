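"""Differential-methylation statistics.

Two testing modes mirror the two analysis designs:

* pooled mode — single cells of each treatment group merged into one
  dataset; a Pearson chi-square (no continuity correction) on the 2x2 table of
  pooled methylated/unmethylated counts, filtered by a minimum absolute
  methylation change (default 10 points) at raw p < alpha;
* replicate mode — individual cells as biological replicates; a two-sided
  pooled-variance Student t-test on per-cell percentages followed by
  Benjamini-Hochberg correction, significant at adjusted p < alpha.

The BH step-up here accepts a total test count ``m`` larger than the number
of p-values supplied, so that an FDR column computed over a full panel can
be reproduced from its reported subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import AnnotationTrack, Feature, GenomeIndex, MethylomeLibrary
from .tiling import MethylationQuant, quantitate

__all__ = [
    "ContingencyTable2x2",
    "DMRResult",
    "VennPartition",
    "ZeroMarginError",
    "chisq_2x2",
    "ttest_groups",
    "bh_adjust",
    "call_dmrs_pooled",
    "call_dmrs_replicates",
    "venn_partition",
    "panel_analysis",
    "export_gene_lists",
]

_TINY = np.nextafter(0.0, 1.0)  # smallest positive double, reported on underflow


class ZeroMarginError(ValueError):
    """The 2x2 test is undefined because a table margin is zero."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Pooled methylated/unmethylated counts for two groups."""

    n_meth_a: int
    n_unmeth_a: int
    n_meth_b: int
    n_unmeth_b: int

    def __post_init__(self) -> None:
        if min(self.n_meth_a, self.n_unmeth_a, self.n_meth_b, self.n_unmeth_b) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def margins(self) -> tuple[int, int, int, int]:
        a, b, c, d = self.n_meth_a, self.n_unmeth_a, self.n_meth_b, self.n_unmeth_b
        return (a + b, c + d, a + c, b + d)


@dataclass
class DMRResult:
    """Per-region comparison between group A and group B."""

    region_id: str
    pct_a: float
    pct_b: float
    n_meth_a: int = 0
    n_unmeth_a: int = 0
    n_meth_b: int = 0
    n_unmeth_b: int = 0
    statistic: float | None = None
    p_raw: float | None = None
    p_adj: float | None = None
    passes: bool = False
    flags: tuple[str, ...] = ()
    chrom: str | None = None
    start: int | None = None
    end: int | None = None

    @property
    def abs_diff(self) -> float:
        return abs(self.pct_a - self.pct_b)

    def to_record(self) -> dict:
        return {
            "region": self.region_id,
            "group_a_pct": float(self.pct_a),
            "group_b_pct": float(self.pct_b),
            "n_meth_a": self.n_meth_a,
            "n_unmeth_a": self.n_unmeth_a,
            "n_meth_b": self.n_meth_b,
            "n_unmeth_b": self.n_unmeth_b,
            "statistic": None if self.statistic is None else float(self.statistic),
            "p": None if self.p_raw is None else float(self.p_raw),
            "fdr": None if self.p_adj is None else float(self.p_adj),
            "flags": ",".join(
                list(self.flags) + (["significant"] if self.passes else [])
            ),
        }


@dataclass(frozen=True)
class VennPartition:
    """Set algebra of one tile class (hyper or hypo) between two groups."""

    label: str
    n_a_total: int
    n_b_total: int
    n_common: int
    n_a_only_significant: int = 0
    n_b_only_significant: int = 0

    def __post_init__(self) -> None:
        if self.n_common > min(self.n_a_total, self.n_b_total):
            raise ValueError("common count exceeds a set size")
        if self.n_a_only_significant > self.n_a_only:
            raise ValueError("significant exclusive count exceeds exclusive count")
        if self.n_b_only_significant > self.n_b_only:
            raise ValueError("significant exclusive count exceeds exclusive count")

    @property
    def n_a_only(self) -> int:
        return self.n_a_total - self.n_common

    @property
    def n_b_only(self) -> int:
        return self.n_b_total - self.n_common

    @classmethod
    def from_sets(
        cls,
        label: str,
        set_a: set,
        set_b: set,
        significant: set | None = None,
    ) -> "VennPartition":
        common = set_a & set_b
        sig = significant or set()
        return cls(
            label=label,
            n_a_total=len(set_a),
            n_b_total=len(set_b),
            n_common=len(common),
            n_a_only_significant=len((set_a - set_b) & sig),
            n_b_only_significant=len((set_b - set_a) & sig),
        )


def chisq_2x2(table: ContingencyTable2x2, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, 1 df, upper-tail p.

    No continuity correction by default (contingency behaviour of the
    standard tile comparison); Yates' correction available via ``yates``.
    """
    if 0 in table.margins:
        raise ZeroMarginError(f"zero margin in table {table}")
    obs = np.array(
        [
            [table.n_meth_a, table.n_unmeth_a],
            [table.n_meth_b, table.n_unmeth_b],
        ],
        dtype=np.float64,
    )
    stat, p, _, _ = sps.chi2_contingency(obs, correction=yates)
    return float(stat), float(p)


def ttest_groups(
    pcts_a: Sequence[float],
    pcts_b: Sequence[float],
    equal_var: bool = True,
) -> tuple[float, float] | None:
    """Two-sided two-sample Student t-test on per-replicate percentages.

    Pooled-variance by default (Welch via ``equal_var=False``). Returns None
    for degenerate inputs (fewer than two replicates in a group, or zero
    variance making the statistic undefined), so such regions can be
    excluded rather than mis-scored.
    """
    a = np.asarray(pcts_a, dtype=float)
    b = np.asarray(pcts_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return None
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    if not (np.isfinite(res.statistic) and np.isfinite(res.pvalue)):
        return None
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``adj_i = min_{j >= i} (p_(j) * m / j)`` over the ascending order,
    capped at 1. ``m`` defaults to ``len(p_values)`` but may be larger when
    the supplied values are the reported subset of a bigger family (the
    unreported tests then occupy the trailing ranks and, having larger p,
    cannot alter the adjusted values of the reported ones).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if m is None:
        m = n
    if m < n:
        raise ValueError(f"m ({m}) must be >= number of p-values ({n})")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(n, dtype=float)
    out[order] = adj_sorted
    return out


def _dmr_from_quants(
    qa: MethylationQuant,
    qb: MethylationQuant,
) -> DMRResult:
    return DMRResult(
        region_id=qa.region_id,
        pct_a=qa.pct,
        pct_b=qb.pct,
        n_meth_a=qa.n_meth,
        n_unmeth_a=qa.n_unmeth,
        n_meth_b=qb.n_meth,
        n_unmeth_b=qb.n_unmeth,
    )


def call_dmrs_pooled(
    quants_a: Sequence[MethylationQuant | None],
    quants_b: Sequence[MethylationQuant | None],
    alpha: float = 0.05,
    min_abs_diff: float = 10.0,
    correction: str | None = None,
    yates: bool = False,
) -> list[DMRResult]:
    """Chi-square DMR calling on pooled (merged single-cell) group counts.

    A region passes when its raw p (adjusted p if ``correction="bh"``) is
    below ``alpha`` and the absolute methylation difference is at least
    ``min_abs_diff`` points. Regions unquantified in either group are
    skipped; regions whose table has a zero margin are reported with a null
    p and an ``undefined_test`` flag. Chi-square p-values that underflow to
    zero are reported as the smallest positive double with an ``underflow``
    flag.
    """
    if correction not in (None, "none", "bh"):
        raise ValueError("correction must be None or 'bh'")
    if len(quants_a) != len(quants_b):
        raise ValueError("group quant lists must align")
    results: list[DMRResult] = []
    for qa, qb in zip(quants_a, quants_b):
        if qa is None or qb is None:
            continue
        res = _dmr_from_quants(qa, qb)
        table = ContingencyTable2x2(qa.n_meth, qa.n_unmeth, qb.n_meth, qb.n_unmeth)
        try:
            stat, p = chisq_2x2(table, yates=yates)
        except ZeroMarginError:
            res.flags = ("undefined_test",)
            results.append(res)
            continue
        if p == 0.0:
            p = _TINY
            res.flags = res.flags + ("underflow",)
        res.statistic, res.p_raw = stat, p
        results.append(res)
    tested = [r for r in results if r.p_raw is not None]
    if correction == "bh" and tested:
        adj = bh_adjust([r.p_raw for r in tested])
        for r, a in zip(tested, adj):
            r.p_adj = float(a)
    for r in tested:
        p_eff = r.p_adj if correction == "bh" else r.p_raw
        r.passes = p_eff < alpha and r.abs_diff >= min_abs_diff
    return results


def call_dmrs_replicates(
    region_ids: Sequence[str],
    pcts_by_cell_a: Sequence[Sequence[float | None]],
    pcts_by_cell_b: Sequence[Sequence[float | None]],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> list[DMRResult]:
    """t-test DMR calling on per-cell percentages, BH across tested regions.

    ``pcts_by_cell_a[i]`` holds group-A per-cell percentages for region i
    (None where a cell lacked sufficient coverage). Regions with fewer than
    two quantified cells in either group, or a degenerate t-statistic, are
    excluded from testing (and from the BH family).
    """
    if not (len(region_ids) == len(pcts_by_cell_a) == len(pcts_by_cell_b)):
        raise ValueError("inputs must align")
    results: list[DMRResult] = []
    for rid, pa, pb in zip(region_ids, pcts_by_cell_a, pcts_by_cell_b):
        a = [x for x in pa if x is not None]
        b = [x for x in pb if x is not None]
        if len(a) < 2 or len(b) < 2:
            continue
        res = DMRResult(
            region_id=rid,
            pct_a=float(np.mean(a)),
            pct_b=float(np.mean(b)),
        )
        t = ttest_groups(a, b, equal_var=equal_var)
        if t is None:
            res.flags = ("degenerate_test",)
            results.append(res)
            continue
        res.statistic, res.p_raw = t
        results.append(res)
    tested = [r for r in results if r.p_raw is not None]
    if tested:
        adj = bh_adjust([r.p_raw for r in tested])
        for r, a in zip(tested, adj):
            r.p_adj = float(a)
            r.passes = r.p_adj < alpha
    return results


def venn_partition(
    classes_a: Mapping[object, str],
    classes_b: Mapping[object, str],
    dmr_results: Mapping[object, DMRResult] | None = None,
    class_labels: Sequence[str] = ("hyper", "hypo"),
    universe: set | None = None,
) -> dict[str, VennPartition]:
    """Partition per-group tile classifications into common/exclusive sets.

    ``classes_a`` and ``classes_b`` map tile identifiers (over the same tile
    universe) to class labels; tiles unquantified in a group may be absent
    from its mapping but must exist in the shared universe (pass
    ``universe`` to enforce this). The significant exclusive counts apply
    the DMR filter (minimum absolute change and p-value) carried by
    ``dmr_results``.
    """
    if universe is not None:
        stray = (set(classes_a) | set(classes_b)) - universe
        if stray:
            raise ValueError(
                f"classified tiles outside the shared universe: {sorted(map(str, stray))[:5]}"
            )
    if dmr_results is None:
        dmr_results = {}
    significant = {k for k, r in dmr_results.items() if r.passes}
    out: dict[str, VennPartition] = {}
    for label in class_labels:
        set_a = {k for k, v in classes_a.items() if v == label}
        set_b = {k for k, v in classes_b.items() if v == label}
        out[label] = VennPartition.from_sets(label, set_a, set_b, significant)
    return out


def panel_analysis(
    features: Sequence[Feature] | AnnotationTrack,
    libs_a: Sequence[MethylomeLibrary],
    libs_b: Sequence[MethylomeLibrary],
    index: GenomeIndex | None = None,
    alpha: float = 0.05,
    m_override: int | None = None,
    min_cg_obs: int = 1,
    group_names: tuple[str, str] = ("NS", "S"),
) -> pd.DataFrame:
    """Targeted gene/CGI panel comparison between two pooled groups.

    Per feature: pooled methylation percent per group, percent of genomic
    CGs observed per group, chi-square p, and BH FDR over the panel. The BH
    family size defaults to the number of features testable in both groups
    and can be overridden with ``m_override`` when the panel is a reported
    subset of a larger family. Features unquantified in a group, or with a
    zero table margin, are reported with null p and excluded from the
    family.
    """
    if isinstance(features, AnnotationTrack):
        features = list(features)
    rows = []
    for f in features:
        qa = quantitate((f.chrom, f.start, f.end), libs_a, min_cg_obs, index, f.label)
        qb = quantitate((f.chrom, f.start, f.end), libs_b, min_cg_obs, index, f.label)
        row = {
            "feature": f.label,
            "chrom": f.chrom,
            "start": f.start,
            "end": f.end,
            "oe": f.oe_ratio,
            f"pct_{group_names[0]}": None if qa is None else qa.pct,
            f"pct_{group_names[1]}": None if qb is None else qb.pct,
            f"read_cgs_{group_names[0]}": None if qa is None else qa.pct_read_cgs,
            f"read_cgs_{group_names[1]}": None if qb is None else qb.pct_read_cgs,
            "statistic": None,
            "p": None,
            "flags": "",
        }
        if qa is not None and qb is not None:
            row["difference"] = abs(qa.pct - qb.pct)
            try:
                stat, p = chisq_2x2(
                    ContingencyTable2x2(qa.n_meth, qa.n_unmeth, qb.n_meth, qb.n_unmeth)
                )
                if p == 0.0:
                    p = _TINY
                    row["flags"] = "underflow"
                row["statistic"], row["p"] = stat, p
            except ZeroMarginError:
                row["flags"] = "undefined_test"
        else:
            row["difference"] = None
            row["flags"] = "insufficient_coverage"
        rows.append(row)
    df = pd.DataFrame(rows)
    tested = df.index[df["p"].notna()]
    df["fdr"] = np.nan
    df["significant"] = False
    if len(tested):
        m = m_override if m_override is not None else len(tested)
        adj = bh_adjust(df.loc[tested, "p"].to_numpy(), m=m)
        df.loc[tested, "fdr"] = adj
        df.loc[tested, "significant"] = adj < alpha
    return df


def export_gene_lists(
    dmr_results: Sequence[DMRResult],
    gene_track: AnnotationTrack,
    out_dir: str | Path,
    group_names: tuple[str, str] = ("NS", "S"),
) -> dict[str, Path]:
    """Write plain-text gene symbol lists for significant DMRs per direction.

    A passing DMR contributes every gene its interval overlaps to the
    ``hyper_in_<A>`` list when group A is the more methylated, otherwise to
    ``hyper_in_<B>``. DMRs need genomic coordinates (chrom/start/end) to be
    overlapped; region-id strings of the form ``chrom:start-end[...]`` are
    parsed as a fallback.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lists: dict[str, list[str]] = {g: [] for g in group_names}
    for r in dmr_results:
        if not r.passes:
            continue
        chrom, start, end = r.chrom, r.start, r.end
        if chrom is None:
            try:
                chrom, span = r.region_id.split(":")[:2]
                start, end = (int(x) for x in span.split("-"))
            except (ValueError, IndexError):
                continue
        direction = group_names[0] if r.pct_a > r.pct_b else group_names[1]
        for f in gene_track.on_chrom(chrom):
            if f.start < end and start < f.end:
                lists[direction].append(f.label)
    paths: dict[str, Path] = {}
    for g, symbols in lists.items():
        path = out_dir / f"hyper_in_{g}.txt"
        path.write_text("".join(s + "\n" for s in sorted(set(symbols))))
        paths[g] = path
    return paths
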