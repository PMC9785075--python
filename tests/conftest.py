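import numpy as np
import pytest

from oometh.io import ChromCalls, MethylomeLibrary
from oometh.simulate import PanelEffect, SimulationConfig, simulate_study

# A reduced-scale configuration for fast unit tests: same structure as the
# default study (3 chromosomes incl. chrX, exemplar region, full panel) but a
# ~4x smaller genome and higher capture so per-library statistics stay stable.
SMALL_SIM_KWARGS = dict(
    chrom_length_bp=800_000,
    exemplar_region=("chr5", 550_000, 700_000),
    panel_start_bp=20_000,
    panel_gap_bp=4_000,
    gene_length_bp=6_000,
    cgi_length_bp=1_200,
    n_cgi_per_chrom=8,
    n_ch_sites=30_000,
    capture_rate=0.1,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(**SMALL_SIM_KWARGS)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config, seed=11)


@pytest.fixture(scope="session")
def clean_small_study():
    cfg = SimulationConfig(contaminated_library_fraction=0.0, **SMALL_SIM_KWARGS)
    return simulate_study(cfg, seed=13)


def make_library(records, library_id="lib", group="NS", context="CG", ch_records=None):
    """Build a MethylomeLibrary from (chrom, pos, n_meth, n_unmeth) tuples."""

    def to_calls(recs):
        by_chrom = {}
        for chrom, pos, m, u in recs:
            by_chrom.setdefault(chrom, []).append((pos, m, u))
        return {
            chrom: ChromCalls(
                pos=np.array([r[0] for r in sorted(rows)]),
                n_meth=np.array([r[1] for r in sorted(rows)]),
                n_unmeth=np.array([r[2] for r in sorted(rows)]),
            )
            for chrom, rows in by_chrom.items()
        }

    return MethylomeLibrary(
        library_id=library_id,
        group=group,
        calls=to_calls(records) if context == "CG" else {},
        ch_calls=to_calls(ch_records) if ch_records else {},
    )
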