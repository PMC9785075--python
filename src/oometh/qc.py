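"""Somatic-contamination quality control for single-cell oocyte libraries.

Oocytes carry an unusual methylation signature that somatic cells lack, and
the three filters here each exploit one facet of it:

1. context inversion — true oocytes show substantial non-CG (CH)
   methylation (around 5%); somatic DNA has almost none, so a low CH level
   (below 2.5% by default) marks likely contamination;
2. exemplar region — oocyte methylomes contain large contiguous
   demethylated regions; methylation above 10% over a declared exemplar
   region indicates somatic admixture;
3. ChrX CGI methylation — the X chromosome is reactivated and demethylated
   in the female germline, so oocyte ChrX CpG islands are nearly
   unmethylated, whereas female somatic cells average ~50% (one active,
   one inactive X). ChrX CGI methylation above 30% fails the filter; the
   same quantity over the largest autosome's CGIs is reported alongside as
   a control.

A filter with no informative coverage is inconclusive, not failed; a
library is discarded when at least one filter fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.vq import kmeans2

from .io import AnnotationTrack, GenomeIndex, MethylomeLibrary

__all__ = [
    "QCThresholds",
    "QCResult",
    "context_methylation",
    "flag_context_inversion",
    "region_methylation",
    "cgi_chrom_methylation",
    "qc_classify",
    "qc_study",
    "context_split_2means",
]

FILTER_NAMES = ("context_inversion", "ref_region", "chrx_cgi")


@dataclass
class QCThresholds:
    """Cutoffs for the three contamination filters.

    All percentages in [0, 100]. ``ref_region`` is the (chrom, start, end)
    of the exemplar demethylated region; it is data-dependent, so there is
    no hard-coded default. ``control_chrom`` defaults to the largest
    autosome at classification time.
    """

    ch_meth_min_pct: float = 2.5
    ref_region: tuple[str, int, int] | None = None
    ref_region_max_pct: float = 10.0
    chrx_cgi_max_pct: float = 30.0
    x_chrom: str = "chrX"
    control_chrom: str | None = None

    def __post_init__(self) -> None:
        for name in ("ch_meth_min_pct", "ref_region_max_pct", "chrx_cgi_max_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be within [0, 100], got {v}")


@dataclass
class QCResult:
    """Per-library QC measurements and keep/discard decision."""

    library_id: str
    cg_pct: float | None
    ch_pct: float | None
    ref_region_pct: float | None
    chrx_cgi_pct: float | None
    control_cgi_pct: float | None
    failed_filters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        unknown = set(self.failed_filters) - set(FILTER_NAMES)
        if unknown:
            raise ValueError(f"unknown filters {sorted(unknown)}")

    @property
    def decision(self) -> str:
        return "discard" if self.failed_filters else "keep"

    def to_record(self) -> dict:
        return {
            "library_id": self.library_id,
            "cg_pct": self.cg_pct,
            "ch_pct": self.ch_pct,
            "ref_region_pct": self.ref_region_pct,
            "chrx_cgi_pct": self.chrx_cgi_pct,
            "control_cgi_pct": self.control_cgi_pct,
            "failed_filters": ",".join(self.failed_filters),
            "decision": self.decision,
        }


def _pooled_pct(n_meth: int, total: int) -> float | None:
    if total == 0:
        return None
    return 100.0 * n_meth / total


def context_methylation(lib: MethylomeLibrary) -> tuple[float | None, float | None]:
    """Overall call-weighted methylation percent in CG and CH contexts.

    A context without calls yields None, making the dependent filter
    inapplicable rather than failed.
    """
    out = []
    for context in ("CG", "CH"):
        calls = lib.context(context)
        n_meth = sum(int(c.n_meth.sum()) for c in calls.values())
        total = n_meth + sum(int(c.n_unmeth.sum()) for c in calls.values())
        out.append(_pooled_pct(n_meth, total))
    return out[0], out[1]


def flag_context_inversion(
    cg_pct: float | None, ch_pct: float | None, thresholds: QCThresholds
) -> bool:
    """True when CH methylation falls strictly below the oocyte minimum."""
    if cg_pct is None or ch_pct is None:
        raise ValueError("context percentages must be non-null")
    return ch_pct < thresholds.ch_meth_min_pct


def region_methylation(
    lib: MethylomeLibrary, region: tuple[str, int, int]
) -> float | None:
    """Call-weighted CG methylation percent over one region; None if uncovered."""
    chrom, start, end = region
    if start >= end:
        raise ValueError(f"invalid region {chrom}:{start}-{end}")
    cc = lib.calls.get(chrom)
    if cc is None or len(cc) == 0:
        return None
    lo, hi = np.searchsorted(cc.pos, [start, end])
    if hi == lo:
        return None
    n_meth = int(cc.n_meth[lo:hi].sum())
    return _pooled_pct(n_meth, n_meth + int(cc.n_unmeth[lo:hi].sum()))


def cgi_chrom_methylation(
    lib: MethylomeLibrary, cgi_track: AnnotationTrack, chrom: str
) -> float | None:
    """Call-weighted percent pooled over every CGI interval on ``chrom``."""
    feats = cgi_track.on_chrom(chrom)
    if not feats:
        raise ValueError(f"CGI track has no feature on {chrom}")
    cc = lib.calls.get(chrom)
    if cc is None or len(cc) == 0:
        return None
    n_meth = n_total = 0
    for f in feats:
        lo, hi = np.searchsorted(cc.pos, [f.start, f.end])
        n_meth += int(cc.n_meth[lo:hi].sum())
        n_total += int(cc.n_meth[lo:hi].sum() + cc.n_unmeth[lo:hi].sum())
    return _pooled_pct(n_meth, n_total)


def qc_classify(
    lib: MethylomeLibrary,
    cgi_track: AnnotationTrack | None,
    thresholds: QCThresholds,
    index: GenomeIndex | None = None,
) -> QCResult:
    """Apply all three filters to one library and produce the decision.

    All filters are always evaluated (so the report is complete); any
    filter whose input is null is inconclusive and never fails. A library
    with zero CG calls cannot be assessed at all and raises.
    """
    if lib.n_calls("CG") == 0:
        raise ValueError(f"{lib.library_id}: no CG calls; cannot run QC")
    cg_pct, ch_pct = context_methylation(lib)
    failed: list[str] = []
    if ch_pct is not None and flag_context_inversion(cg_pct, ch_pct, thresholds):
        failed.append("context_inversion")

    ref_pct = None
    if thresholds.ref_region is not None:
        ref_pct = region_methylation(lib, thresholds.ref_region)
        if ref_pct is not None and ref_pct > thresholds.ref_region_max_pct:
            failed.append("ref_region")

    chrx_pct = control_pct = None
    if cgi_track is not None:
        x = thresholds.x_chrom
        if cgi_track.on_chrom(x):
            chrx_pct = cgi_chrom_methylation(lib, cgi_track, x)
            if chrx_pct is not None and chrx_pct > thresholds.chrx_cgi_max_pct:
                failed.append("chrx_cgi")
        control = thresholds.control_chrom
        if control is None and index is not None:
            control = index.largest_autosome()
        if control is not None and cgi_track.on_chrom(control):
            control_pct = cgi_chrom_methylation(lib, cgi_track, control)

    return QCResult(
        library_id=lib.library_id,
        cg_pct=cg_pct,
        ch_pct=ch_pct,
        ref_region_pct=ref_pct,
        chrx_cgi_pct=chrx_pct,
        control_cgi_pct=control_pct,
        failed_filters=tuple(failed),
    )


def qc_study(
    libs: Iterable[MethylomeLibrary],
    cgi_track: AnnotationTrack | None,
    thresholds: QCThresholds,
    index: GenomeIndex | None = None,
) -> pd.DataFrame:
    """QC every library of a study; one report row per library."""
    return pd.DataFrame(
        [qc_classify(lib, cgi_track, thresholds, index).to_record() for lib in libs]
    )


def context_split_2means(
    results: Sequence[QCResult], seed: int = 0
) -> dict[str, bool]:
    """Alternative contamination split: 2-means on (cg_pct, ch_pct).

    Mirrors the by-eye separation of libraries into two context-methylation
    groups with an explicit, reproducible rule: the cluster with the lower
    mean CH (and correspondingly higher CG) methylation is labelled
    contaminated. Returns library_id -> contaminated flag for libraries with
    both context percentages available.
    """
    usable = [r for r in results if r.cg_pct is not None and r.ch_pct is not None]
    if len(usable) < 2:
        return {r.library_id: False for r in usable}
    X = np.array([[r.cg_pct, r.ch_pct] for r in usable])
    centroids, labels = kmeans2(X, 2, minit="++", seed=seed)
    contaminated_cluster = int(np.argmin(centroids[:, 1]))
    return {
        r.library_id: bool(lab == contaminated_cluster)
        for r, lab in zip(usable, labels)
    }
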