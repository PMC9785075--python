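"""Self-contained synthetic single-cell oocyte methylome study.

Emulates, at toy scale, the structure of a 45-library bovine oocyte study:
15 non-stimulated (NS) and 30 hormone-stimulated (S) single-cell libraries
from 3 donors, over a 3-chromosome genome (a large control autosome, an
autosome carrying a contiguous demethylated exemplar region and the
imprinted-feature panel, and a chrX with CpG islands).

The true oocyte methylome follows a two-state (methylated/unmethylated)
Markov chain along CG positions; each domain draws its methylation level
from a beta distribution around the state mean, producing the bimodal
landscape with a global mean near 52% and hyper (>75%) / hypo (<25%)
500-CG-tile fractions near 25.5% / 18.75%. Oocytes carry ~5% non-CG (CH)
methylation; somatic cells ~0.5% CH, ~50% ChrX CGI methylation, and a
uniformly methylated background — the three signatures the QC filters look
for. Contamination is modelled at the call level: each sequencing call of a
contaminated library is drawn from the somatic truth with the configured
mixture probability.

Per-cell sparsity: every CG is observed independently with ``capture_rate``;
an observed CG receives ``1 + Poisson(lambda)`` calls, methylated counts
binomial in the true level. Coverage files are written in the Bismark
dialect with counts split across the two strands, so reading them back
exercises strand folding. All outputs are byte-reproducible from
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    AnnotationTrack,
    ChromCalls,
    Feature,
    GenomeIndex,
    MethylomeLibrary,
)

__all__ = [
    "PanelEffect",
    "SimulationConfig",
    "SyntheticGenome",
    "CellTruth",
    "Study",
    "DEFAULT_PANEL",
    "simulate_genome",
    "simulate_cell_truth",
    "simulate_library",
    "simulate_contaminated",
    "simulate_study",
    "write_study",
]


@dataclass(frozen=True)
class PanelEffect:
    """A targeted panel feature with its true group methylation levels.

    ``pct_ns == pct_s`` makes the feature a null; otherwise the difference
    is the injected group effect. ``oe`` is the CpG observed/expected ratio
    label carried by CGI probes.
    """

    kind: str  # "gene" | "cgi"
    label: str
    pct_ns: float
    pct_s: float
    oe: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "cgi"):
            raise ValueError("kind must be 'gene' or 'cgi'")
        for v in (self.pct_ns, self.pct_s):
            if not 0.0 <= v <= 100.0:
                raise ValueError("panel percentages must be within [0, 100]")

    @property
    def delta(self) -> float:
        return abs(self.pct_ns - self.pct_s)


# Effect sizes mirror the reported imprinted-panel group percentages; the
# null features are loci reported as not differentially methylated
# (H19 and the APEG3/TSSC4 CGIs unmethylated in both groups, PEG3 and
# SNRPN methylated in both).
DEFAULT_PANEL: tuple[PanelEffect, ...] = (
    PanelEffect("gene", "APEG3", 29.62963, 56.06027),
    PanelEffect("gene", "MEG3", 23.323172, 32.191566),
    PanelEffect("gene", "MEG9", 46.951218, 76.15186),
    PanelEffect("gene", "TSSC4", 81.801994, 52.26771),
    PanelEffect("gene", "H19", 2.0, 2.0),
    PanelEffect("gene", "PEG3", 85.0, 85.0),
    PanelEffect("gene", "SNRPN", 90.0, 90.0),
    PanelEffect("cgi", "MEST_PEG1_CGI", 97.06, 77.37, oe=0.66),
    PanelEffect("cgi", "IGF2R_CGI_1", 97.94, 88.54, oe=0.85),
    PanelEffect("cgi", "IGF2R_CGI_2", 97.37, 65.52, oe=1.07),
    PanelEffect("cgi", "GNAS_SCG6_CGI", 97.30, 81.26, oe=0.75),
    PanelEffect("cgi", "KvDMR1_ICR_CGI", 100.0, 58.57, oe=0.87),
    PanelEffect("cgi", "IGF2_CGI_1", 2.63, 10.92, oe=0.60),
    PanelEffect("cgi", "IGF2_CGI_2", 44.91, 5.43, oe=0.81),
    PanelEffect("cgi", "APEG3_CGI", 1.0, 1.0, oe=0.7),
    PanelEffect("cgi", "TSSC4_CGI", 2.0, 2.0, oe=0.9),
    PanelEffect("cgi", "H19_CGI", 1.5, 1.5, oe=0.8),
)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults define the study conditions.

    Percentages are in [0, 100], probabilities in [0, 1]. The two-state
    methylation chain is parameterised by the mean domain length in CGs per
    state and the per-state beta (mean percent, concentration); these
    defaults were calibrated once so that the clean oocyte truth yields a
    global CpG methylation mean near 52% and hyper/hypo 500-CG-tile
    fractions near 25.5% / 18.75% (``expected_*`` record the calibrated
    expectations; they are bookkeeping, not inputs to the process).
    """

    seed: int = 0
    # genome
    chrom_names: tuple[str, ...] = ("chr1", "chr5", "chrX")
    chrom_length_bp: int = 3_000_000
    cg_density: float = 0.02
    n_cgi_per_chrom: int = 20
    cgi_length_bp: int = 2_000
    cgi_cg_spacing: int = 12
    exemplar_region: tuple[str, int, int] = ("chr5", 2_100_000, 2_700_000)
    gene_length_bp: int = 15_000
    panel_chrom: str = "chr5"
    panel_start_bp: int = 100_000
    panel_gap_bp: int = 20_000
    # study design
    n_donors: int = 3
    ns_per_donor: tuple[int, ...] = (6, 4, 5)
    s_per_donor: tuple[int, ...] = (9, 6, 15)
    contaminated_library_fraction: float = 17 / 45
    somatic_mixture_fraction: float = 0.5
    # oocyte methylation landscape (calibrated, see class docstring)
    mean_domain_cg_m: float = 900.0
    mean_domain_cg_u: float = 900.0
    m_state_fraction: float = 0.70
    hyper_state_mean: float = 76.0
    hypo_state_mean: float = 20.0
    beta_conc_m: float = 4.0
    beta_conc_u: float = 22.4
    oocyte_global_target: float = 52.0
    expected_hyper_tile_frac: float = 0.255
    expected_hypo_tile_frac: float = 0.1875
    exemplar_meth_oocyte: float = 1.0
    cgi_meth_oocyte: float = 2.0
    chrx_cgi_meth_oocyte: float = 1.0
    ch_meth_oocyte: float = 5.0
    # somatic contaminant profile
    somatic_level_mean: float = 75.0
    somatic_level_conc: float = 30.0
    cgi_meth_somatic: float = 5.0
    chrx_cgi_meth_somatic: float = 50.0
    ch_meth_somatic: float = 0.5
    # capture model
    capture_rate: float = 0.05
    depth_extra_poisson: float = 0.3
    n_ch_sites: int = 100_000
    # targeted panel
    panel_effects: tuple[PanelEffect, ...] = DEFAULT_PANEL

    def __post_init__(self) -> None:
        if self.cg_density <= 0 or self.cg_density > 0.5:
            raise ValueError("cg_density must be in (0, 0.5]")
        for name in ("capture_rate", "contaminated_library_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0, 1]")
        if not 0.0 <= self.somatic_mixture_fraction <= 1.0:
            raise ValueError("somatic_mixture_fraction must be within [0, 1]")
        if not 0.0 < self.m_state_fraction < 1.0:
            raise ValueError("m_state_fraction must be within (0, 1)")
        if len(self.ns_per_donor) != self.n_donors or len(self.s_per_donor) != self.n_donors:
            raise ValueError("per-donor library counts must match n_donors")
        if self.exemplar_region[0] not in self.chrom_names:
            raise ValueError("exemplar_region chromosome not in chrom_names")

    @property
    def n_libraries(self) -> int:
        return sum(self.ns_per_donor) + sum(self.s_per_donor)


@dataclass
class SyntheticGenome:
    """Generated genome, annotation tracks, and CG backbone."""

    sequences: dict[str, str]
    index: GenomeIndex
    cgi_track: AnnotationTrack
    gene_track: AnnotationTrack
    panel_track: AnnotationTrack
    panel_features: dict[str, Feature]
    exemplar_region: tuple[str, int, int]
    ch_sites: dict[str, np.ndarray]

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.sequences):
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass
class CellTruth:
    """True per-CG methylation probabilities of one cell type and group."""

    cell_type: str
    group: str
    p_meth: dict[str, np.ndarray]  # aligned to SyntheticGenome.index
    ch_rate: float
    state: dict[str, np.ndarray]  # 1 = M domain, 0 = U domain per CG


@dataclass
class Study:
    """A simulated study: libraries plus ground truth for every property test."""

    config: SimulationConfig
    genome: SyntheticGenome
    libraries: list[MethylomeLibrary]
    truths: dict[tuple[str, str], CellTruth]
    manifest: pd.DataFrame

    def contaminated_ids(self) -> set[str]:
        m = self.manifest
        return set(m.loc[m["contaminated"], "library_id"])

    def libraries_by_group(self, group: str) -> list[MethylomeLibrary]:
        return [lib for lib in self.libraries if lib.group == group]


def _enforce_spacing(pos: np.ndarray, min_gap: int = 2) -> np.ndarray:
    """Greedily drop positions closer than ``min_gap`` to their predecessor."""
    if len(pos) == 0:
        return pos
    keep = [int(pos[0])]
    for p in pos[1:]:
        if p - keep[-1] >= min_gap:
            keep.append(int(p))
    return np.asarray(keep, dtype=np.int64)


def _plant_cg_sequence(length: int, cg_positions: np.ndarray, rng: np.random.Generator) -> str:
    """Random sequence whose CG dinucleotides are exactly ``cg_positions``."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    arr = bases[rng.integers(0, 4, size=length)]
    # destroy accidental CGs (turning the G into an A cannot create a new CG)
    acc = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    arr[np.flatnonzero(acc) + 1] = ord("A")
    arr[cg_positions] = ord("C")
    arr[cg_positions + 1] = ord("G")
    return arr.tobytes().decode("ascii")


def simulate_genome(config: SimulationConfig, rng: np.random.Generator | None = None) -> SyntheticGenome:
    """Generate sequences, the CG index, CGI/gene/panel tracks and CH sites.

    Background CGs are planted at ``cg_density`` per bp; CGI intervals are
    CG-dense (one CG every ``cgi_cg_spacing`` bp). The imprinted panel lives
    on ``panel_chrom`` upstream of the exemplar demethylated region; panel
    CGIs are also CGIs, so they join the CGI track.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.chrom_length_bp
    ex_chrom, ex_start, ex_end = config.exemplar_region
    if not (0 <= ex_start < ex_end <= L):
        raise ValueError("exemplar region outside chromosome")

    # panel layout: packed intervals on panel_chrom, clear of the exemplar
    panel_features: dict[str, Feature] = {}
    cursor = config.panel_start_bp
    for eff in config.panel_effects:
        span = config.gene_length_bp if eff.kind == "gene" else config.cgi_length_bp
        feat = Feature(config.panel_chrom, cursor, cursor + span, eff.label, eff.oe)
        panel_features[eff.label] = feat
        cursor += span + config.panel_gap_bp
    if cursor > ex_start:
        raise ValueError("panel does not fit upstream of the exemplar region")

    sequences: dict[str, str] = {}
    positions: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    ch_candidates: dict[str, np.ndarray] = {}
    cgi_feats: list[Feature] = []

    for chrom in config.chrom_names:
        # CG-dense intervals: generic CGIs on a jittered grid, plus panel CGIs
        dense: list[tuple[int, int, str | None]] = []
        step = L // config.n_cgi_per_chrom
        for i in range(config.n_cgi_per_chrom):
            start = i * step + int(rng.integers(0, max(1, step - config.cgi_length_bp)))
            end = start + config.cgi_length_bp
            dense.append((start, end, None))
        blocked: list[tuple[int, int]] = []
        if chrom == config.panel_chrom:
            for f in panel_features.values():
                blocked.append((f.start - 5_000, f.end + 5_000))
            for eff in config.panel_effects:
                if eff.kind == "cgi":
                    f = panel_features[eff.label]
                    dense.append((f.start, f.end, eff.label))
        dense = [
            (s, e, lab)
            for s, e, lab in dense
            if lab is not None or not any(s < be and bs < e for bs, be in blocked)
        ]
        dense.sort()
        for j, (s, e, lab) in enumerate(d for d in dense if d[2] is None):
            cgi_feats.append(Feature(chrom, s, e, f"cgi_{chrom}_{j:03d}"))

        bg = np.flatnonzero(rng.random(L - 2) < config.cg_density)
        in_dense = np.zeros(L - 2, dtype=bool)
        for s, e, _ in dense:
            in_dense[s:e] = True
        bg = bg[~in_dense[bg]]
        dense_pos = []
        for s, e, _ in dense:
            grid = np.arange(s + 2, e - 2, config.cgi_cg_spacing, dtype=np.int64)
            dense_pos.append(grid + rng.integers(0, 3, size=len(grid)))
        pos = np.unique(np.concatenate([bg] + dense_pos))
        pos = _enforce_spacing(pos)
        if len(pos) == 0:
            raise ValueError(f"{chrom}: no CG positions at density {config.cg_density}")
        positions[chrom] = pos
        lengths[chrom] = L
        seq = _plant_cg_sequence(L, pos, rng)
        sequences[chrom] = seq
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_c = arr == ord("C")
        is_c[pos] = False  # exclude the C of each CG: those are CpG context
        ch_candidates[chrom] = np.flatnonzero(is_c)

    # genome-wide CH site panel, shared by all cells
    n_per_chrom = max(1, config.n_ch_sites // len(config.chrom_names))
    ch_sites = {
        chrom: np.sort(
            rng.choice(cand, size=min(n_per_chrom, len(cand)), replace=False)
        )
        for chrom, cand in ch_candidates.items()
    }

    index = GenomeIndex(positions=positions, lengths=lengths)
    for f in cgi_feats:
        pos = positions[f.chrom]
        if np.searchsorted(pos, f.end) - np.searchsorted(pos, f.start) < 5:
            raise RuntimeError(f"CGI {f.label} holds too few CGs")  # construction bug

    panel_cgis = [
        panel_features[e.label] for e in config.panel_effects if e.kind == "cgi"
    ]
    gene_feats = [
        panel_features[e.label] for e in config.panel_effects if e.kind == "gene"
    ]
    return SyntheticGenome(
        sequences=sequences,
        index=index,
        cgi_track=AnnotationTrack("cgi", cgi_feats + panel_cgis),
        gene_track=AnnotationTrack("genes", gene_feats),
        panel_track=AnnotationTrack("panel", list(panel_features.values())),
        panel_features=panel_features,
        exemplar_region=config.exemplar_region,
        ch_sites=ch_sites,
    )


def _beta_params(mean_pct: float, conc: float) -> tuple[float, float]:
    mu = min(max(mean_pct / 100.0, 1e-6), 1 - 1e-6)
    return mu * conc, (1 - mu) * conc


def _domain_states(n: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Alternating M/U run labels (1/0) over ``n`` CG positions.

    Geometric run lengths; the per-state means are scaled so the stationary
    CG fraction in the M state equals ``m_state_fraction`` while the overall
    domain-length scale stays at the configured means.
    """
    pi_m = config.m_state_fraction
    mean_m = config.mean_domain_cg_m * (pi_m / 0.5)
    mean_u = config.mean_domain_cg_u * ((1.0 - pi_m) / 0.5)
    state = int(rng.random() < pi_m)
    out = np.empty(n, dtype=np.uint8)
    i = 0
    while i < n:
        mean_len = mean_m if state else mean_u
        run = int(rng.geometric(min(1.0, 1.0 / mean_len)))
        out[i : i + run] = state
        i += run
        state = 1 - state
    return out


def _mask_in_features(pos: np.ndarray, feats: Iterable[Feature]) -> np.ndarray:
    mask = np.zeros(len(pos), dtype=bool)
    for f in feats:
        lo, hi = np.searchsorted(pos, [f.start, f.end])
        mask[lo:hi] = True
    return mask


def simulate_cell_truth(
    genome: SyntheticGenome,
    cell_type: str,
    group: str,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> CellTruth:
    """Draw the true methylome of one cell type for one treatment group.

    Oocytes get the bimodal domain landscape with CGI, exemplar-region and
    (group-dependent) panel overrides; somatic cells get a uniformly high
    background with ~50% ChrX CGI methylation and no exemplar override.
    """
    if cell_type not in ("oocyte", "somatic"):
        raise ValueError("cell_type must be 'oocyte' or 'somatic'")
    if group not in ("NS", "S"):
        raise ValueError("group must be 'NS' or 'S'")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p_meth: dict[str, np.ndarray] = {}
    states: dict[str, np.ndarray] = {}
    ex_chrom, ex_start, ex_end = genome.exemplar_region
    for chrom in genome.index.chroms:
        pos = genome.index.positions[chrom]
        n = len(pos)
        state = _domain_states(n, config, rng)
        p = np.empty(n, dtype=float)
        # one beta level per run
        boundaries = np.flatnonzero(np.diff(state.astype(np.int8)) != 0) + 1
        run_starts = np.concatenate([[0], boundaries])
        run_ends = np.concatenate([boundaries, [n]])
        for s, e in zip(run_starts, run_ends):
            if cell_type == "somatic":
                a, b = _beta_params(config.somatic_level_mean, config.somatic_level_conc)
            elif state[s]:
                a, b = _beta_params(config.hyper_state_mean, config.beta_conc_m)
            else:
                a, b = _beta_params(config.hypo_state_mean, config.beta_conc_u)
            p[s:e] = rng.beta(a, b)
        # CGI overrides (panel CGIs handled with the panel below for oocytes)
        panel_labels = {f.label for f in genome.panel_track}
        generic_cgis = [
            f
            for f in genome.cgi_track.on_chrom(chrom)
            if f.label not in panel_labels
        ]
        is_x = chrom in genome.index.allosomes
        if cell_type == "oocyte":
            cgi_level = (
                config.chrx_cgi_meth_oocyte if is_x else config.cgi_meth_oocyte
            )
        else:
            cgi_level = (
                config.chrx_cgi_meth_somatic if is_x else config.cgi_meth_somatic
            )
        p[_mask_in_features(pos, generic_cgis)] = cgi_level / 100.0
        if cell_type == "oocyte":
            if chrom == ex_chrom:
                lo, hi = np.searchsorted(pos, [ex_start, ex_end])
                p[lo:hi] = config.exemplar_meth_oocyte / 100.0
            for eff in config.panel_effects:
                f = genome.panel_features[eff.label]
                if f.chrom != chrom:
                    continue
                level = eff.pct_ns if group == "NS" else eff.pct_s
                lo, hi = np.searchsorted(pos, [f.start, f.end])
                p[lo:hi] = level / 100.0
        p_meth[chrom] = p
        states[chrom] = state
    ch_rate = (
        config.ch_meth_oocyte if cell_type == "oocyte" else config.ch_meth_somatic
    ) / 100.0
    return CellTruth(cell_type, group, p_meth, ch_rate, states)


def _draw_context(
    pos: np.ndarray,
    p_true: np.ndarray | float,
    config: SimulationConfig,
    rng: np.random.Generator,
    mixture: float = 0.0,
    p_som: np.ndarray | float | None = None,
    depth_one: bool = False,
) -> ChromCalls | None:
    obs = rng.random(len(pos)) < config.capture_rate
    idx = np.flatnonzero(obs)
    if len(idx) == 0:
        return None
    if depth_one:
        depth = np.ones(len(idx), dtype=np.int64)
    else:
        depth = 1 + rng.poisson(config.depth_extra_poisson, size=len(idx))
    p_oo = p_true[idx] if isinstance(p_true, np.ndarray) else p_true
    if mixture > 0.0:
        ps = p_som[idx] if isinstance(p_som, np.ndarray) else p_som
        d_som = rng.binomial(depth, mixture)
        meth = rng.binomial(depth - d_som, p_oo) + rng.binomial(d_som, ps)
    else:
        meth = rng.binomial(depth, p_oo)
    return ChromCalls(pos=pos[idx], n_meth=meth, n_unmeth=depth - meth)


def simulate_library(
    genome: SyntheticGenome,
    truth: CellTruth,
    config: SimulationConfig,
    library_id: str,
    rng: np.random.Generator | None = None,
    donor_id: str = "",
    somatic_truth: CellTruth | None = None,
    mixture: float = 0.0,
) -> MethylomeLibrary:
    """Sample one single-cell library (CG and CH contexts) from a truth.

    With ``mixture`` > 0 each call is drawn from ``somatic_truth`` with that
    probability, modelling call-level contamination of a pooled PBAT
    library.
    """
    if mixture > 0.0 and somatic_truth is None:
        raise ValueError("mixture > 0 requires a somatic truth")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    calls: dict[str, ChromCalls] = {}
    ch_calls: dict[str, ChromCalls] = {}
    for chrom in genome.index.chroms:
        cc = _draw_context(
            genome.index.positions[chrom],
            truth.p_meth[chrom],
            config,
            rng,
            mixture=mixture,
            p_som=None if somatic_truth is None else somatic_truth.p_meth[chrom],
        )
        if cc is not None:
            calls[chrom] = cc
        ch_rate = truth.ch_rate
        if mixture > 0.0:
            ch_rate = (1 - mixture) * truth.ch_rate + mixture * somatic_truth.ch_rate
        ch = _draw_context(
            genome.ch_sites[chrom], ch_rate, config, rng, depth_one=True
        )
        if ch is not None:
            ch_calls[chrom] = ch
    return MethylomeLibrary(
        library_id=library_id,
        donor_id=donor_id,
        group=truth.group,
        calls=calls,
        ch_calls=ch_calls,
    )


def simulate_contaminated(
    genome: SyntheticGenome,
    oocyte_truth: CellTruth,
    somatic_truth: CellTruth,
    fraction: float,
    config: SimulationConfig,
    library_id: str,
    rng: np.random.Generator | None = None,
    donor_id: str = "",
) -> MethylomeLibrary:
    """Sample a library whose calls mix oocyte and somatic truths."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be within [0, 1]")
    return simulate_library(
        genome,
        oocyte_truth,
        config,
        library_id,
        rng=rng,
        donor_id=donor_id,
        somatic_truth=somatic_truth,
        mixture=fraction,
    )


def simulate_study(
    config: SimulationConfig,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> Study:
    """Simulate the full study: genome, truths, 45 libraries, manifest.

    A ``contaminated_library_fraction`` share of libraries (rounded) is
    contaminated at ``somatic_mixture_fraction``, chosen uniformly across
    the study. When ``out_dir`` is given the on-disk tree (FASTA, BEDs,
    per-library coverage files, manifest) is written as well.
    """
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    genome_ss, oocyte_ss, somatic_ss, design_ss = ss.spawn(4)

    genome = simulate_genome(config, np.random.default_rng(genome_ss))
    # NS and S oocytes share one base landscape (same animals); reusing the
    # seed sequence replays the identical domain draw, so the two group
    # truths differ only at the panel overrides.
    truths = {
        ("oocyte", "NS"): simulate_cell_truth(
            genome, "oocyte", "NS", config, np.random.default_rng(oocyte_ss)
        ),
        ("oocyte", "S"): simulate_cell_truth(
            genome, "oocyte", "S", config, np.random.default_rng(oocyte_ss)
        ),
        ("somatic", "NS"): simulate_cell_truth(
            genome, "somatic", "NS", config, np.random.default_rng(somatic_ss)
        ),
    }
    # the somatic contaminant profile is treatment-independent
    truths[("somatic", "S")] = replace(truths[("somatic", "NS")], group="S")

    lib_ids: list[tuple[str, str, str]] = []  # (library_id, donor, group)
    for d in range(config.n_donors):
        donor = f"donor{d + 1}"
        for i in range(config.ns_per_donor[d]):
            lib_ids.append((f"NS_{donor}_{i + 1:02d}", donor, "NS"))
        for i in range(config.s_per_donor[d]):
            lib_ids.append((f"S_{donor}_{i + 1:02d}", donor, "S"))

    n_cont = int(round(config.contaminated_library_fraction * len(lib_ids)))
    design_rng = np.random.default_rng(design_ss)
    cont_idx = set(
        design_rng.choice(len(lib_ids), size=n_cont, replace=False).tolist()
    )

    lib_streams = ss.spawn(len(lib_ids))
    libraries: list[MethylomeLibrary] = []
    rows = []
    for k, (lib_id, donor, group) in enumerate(lib_ids):
        rng = np.random.default_rng(lib_streams[k])
        contaminated = k in cont_idx
        mixture = config.somatic_mixture_fraction if contaminated else 0.0
        lib = simulate_library(
            genome,
            truths[("oocyte", group)],
            config,
            lib_id,
            rng=rng,
            donor_id=donor,
            somatic_truth=truths[("somatic", group)] if contaminated else None,
            mixture=mixture,
        )
        libraries.append(lib)
        rows.append(
            {
                "library_id": lib_id,
                "donor_id": donor,
                "group": group,
                "contaminated": contaminated,
                "mixture_fraction": mixture,
            }
        )
    manifest = pd.DataFrame(rows)
    study = Study(config, genome, libraries, truths, manifest)
    if out_dir is not None:
        write_study(study, out_dir, seed=seed)
    return study


def _write_library_coverage(
    lib: MethylomeLibrary,
    index: GenomeIndex,
    cov_path: Path,
    ch_path: Path,
    rng: np.random.Generator,
) -> None:
    """Write Bismark-dialect files, splitting CG counts across strands."""
    with open(cov_path, "w") as fh:
        for chrom in sorted(lib.calls):
            cc = lib.calls[chrom]
            total = cc.n_meth + cc.n_unmeth
            d_plus = rng.binomial(total, 0.5)
            m_plus = rng.hypergeometric(
                np.maximum(cc.n_meth, 0), np.maximum(cc.n_unmeth, 0), d_plus
            )
            d_minus = total - d_plus
            m_minus = cc.n_meth - m_plus
            rows = []
            for pos, m, d in (
                (cc.pos, m_plus, d_plus),
                (cc.pos + 1, m_minus, d_minus),
            ):
                keep = d > 0
                rows.append(
                    np.column_stack([pos[keep], m[keep], d[keep] - m[keep]])
                )
            merged = np.concatenate(rows)
            merged = merged[np.argsort(merged[:, 0], kind="stable")]
            for p, m, u in merged:
                pct = 100.0 * m / (m + u)
                fh.write(f"{chrom}\t{p + 1}\t{p + 1}\t{pct:.6g}\t{m}\t{u}\n")
    from .io import write_coverage

    write_coverage(lib.ch_calls, ch_path)


def write_study(study: Study, out_dir: str | Path, seed: int | None = None) -> Path:
    """Write the study directory tree (text formats only)."""
    out = Path(out_dir)
    (out / "coverage").mkdir(parents=True, exist_ok=True)
    study.genome.write_fasta(out / "genome.fa")
    study.genome.cgi_track.to_bed(out / "cgi.bed")
    study.genome.gene_track.to_bed(out / "genes.bed")
    study.genome.panel_track.to_bed(out / "panel.bed")
    ex_chrom, ex_start, ex_end = study.genome.exemplar_region
    (out / "exemplar.bed").write_text(
        f"{ex_chrom}\t{ex_start}\t{ex_end}\texemplar_demethylated\n"
    )
    if seed is None:
        seed = study.config.seed
    ss = np.random.SeedSequence([seed, 7_919])  # independent strand-split stream
    strand_rngs = ss.spawn(len(study.libraries))
    for lib, child in zip(study.libraries, strand_rngs):
        _write_library_coverage(
            lib,
            study.genome.index,
            out / "coverage" / f"{lib.library_id}.CpG.cov",
            out / "coverage" / f"{lib.library_id}.CHH.cov",
            np.random.default_rng(child),
        )
    study.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return out
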