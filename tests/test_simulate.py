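import filecmp

import numpy as np
import pytest

from oometh.io import read_coverage
from oometh.qc import cgi_chrom_methylation, context_methylation
from oometh.simulate import (
    CellTruth,
    PanelEffect,
    SimulationConfig,
    simulate_cell_truth,
    simulate_contaminated,
    simulate_genome,
    simulate_library,
    simulate_study,
    write_study,
)
from conftest import SMALL_SIM_KWARGS


class TestSimulationConfig:
    def test_zero_cg_density_rejected(self):
        with pytest.raises(ValueError, match="cg_density"):
            SimulationConfig(cg_density=0.0)

    def test_probabilities_validated(self):
        with pytest.raises(ValueError):
            SimulationConfig(capture_rate=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(somatic_mixture_fraction=-0.1)

    def test_default_study_counts(self):
        cfg = SimulationConfig()
        assert sum(cfg.ns_per_donor) == 15
        assert sum(cfg.s_per_donor) == 30
        assert cfg.n_libraries == 45

    def test_panel_percent_validation(self):
        with pytest.raises(ValueError):
            PanelEffect("gene", "X", 120.0, 50.0)


class TestSimulateGenome:
    def test_same_seed_identical_fasta(self, small_config, tmp_path):
        g1 = simulate_genome(small_config, np.random.default_rng(4))
        g2 = simulate_genome(small_config, np.random.default_rng(4))
        assert g1.sequences == g2.sequences

    def test_index_matches_planted_cg_positions(self, small_study, tmp_path):
        genome = small_study.genome
        genome.write_fasta(tmp_path / "g.fa")
        from oometh.io import build_genome_index

        rebuilt = build_genome_index(tmp_path / "g.fa")
        for chrom in genome.index.chroms:
            np.testing.assert_array_equal(
                rebuilt.positions[chrom], genome.index.positions[chrom]
            )

    def test_cgis_are_cg_dense(self, small_study):
        genome = small_study.genome
        for f in genome.cgi_track:
            pos = genome.index.positions[f.chrom]
            n = np.searchsorted(pos, f.end) - np.searchsorted(pos, f.start)
            assert n >= 5

    def test_panel_fits_upstream_of_exemplar(self, small_study):
        _, ex_start, _ = small_study.genome.exemplar_region
        for f in small_study.genome.panel_track:
            assert f.end <= ex_start


class TestCellTruth:
    def test_oocyte_truth_mean_near_target(self):
        # full-scale genome: the small test genome has too few domains for
        # the +-2-point calibration band to be meaningful
        cfg = SimulationConfig()
        means = []
        for seed in range(4):
            genome = simulate_genome(cfg, np.random.default_rng(seed))
            truth = simulate_cell_truth(
                genome, "oocyte", "NS", cfg, np.random.default_rng(seed + 50)
            )
            allp = np.concatenate(list(truth.p_meth.values()))
            means.append(100 * allp.mean())
        assert np.mean(means) == pytest.approx(cfg.oocyte_global_target, abs=2.0)

    def test_somatic_chrx_cgis_near_half(self, small_study):
        truth = small_study.truths[("somatic", "NS")]
        genome = small_study.genome
        pos = genome.index.positions["chrX"]
        vals = []
        for f in genome.cgi_track.on_chrom("chrX"):
            lo, hi = np.searchsorted(pos, [f.start, f.end])
            vals.append(truth.p_meth["chrX"][lo:hi].mean())
        assert 100 * np.mean(vals) == pytest.approx(50.0, abs=2.0)

    def test_full_persistence_gives_single_domain_per_chromosome(self, small_config):
        from dataclasses import replace

        cfg = replace(small_config, mean_domain_cg_m=1e12, mean_domain_cg_u=1e12)
        genome = simulate_genome(cfg, np.random.default_rng(0))
        truth = simulate_cell_truth(genome, "oocyte", "NS", cfg, np.random.default_rng(1))
        for chrom, state in truth.state.items():
            assert len(np.unique(state)) == 1

    def test_group_truths_differ_only_at_panel(self, small_study):
        ns = small_study.truths[("oocyte", "NS")]
        s = small_study.truths[("oocyte", "S")]
        genome = small_study.genome
        for chrom in genome.index.chroms:
            diff = np.flatnonzero(ns.p_meth[chrom] != s.p_meth[chrom])
            pos = genome.index.positions[chrom][diff]
            for p in pos:
                assert any(
                    f.start <= p < f.end for f in genome.panel_track.on_chrom(chrom)
                )


class TestSimulateLibrary:
    def test_full_capture_fully_methylated_truth(self, small_study):
        genome = small_study.genome
        from dataclasses import replace

        cfg = replace(small_study.config, capture_rate=1.0, depth_extra_poisson=0.0)
        truth = CellTruth(
            "oocyte",
            "NS",
            {c: np.ones(len(p)) for c, p in genome.index.positions.items()},
            0.05,
            {c: np.ones(len(p), dtype=np.uint8) for c, p in genome.index.positions.items()},
        )
        lib = simulate_library(genome, truth, cfg, "x", np.random.default_rng(0))
        for chrom, cc in lib.calls.items():
            assert len(cc) == len(genome.index.positions[chrom])
            assert (cc.n_meth == 1).all() and (cc.n_unmeth == 0).all()

    def test_capture_rate_observed_fraction(self, small_study):
        genome = small_study.genome
        from dataclasses import replace

        cfg = replace(small_study.config, capture_rate=0.3)
        truth = small_study.truths[("oocyte", "NS")]
        lib = simulate_library(genome, truth, cfg, "x", np.random.default_rng(1))
        n_obs = sum(len(cc) for cc in lib.calls.values())
        n_total = genome.index.n_cg()
        frac = n_obs / n_total
        assert frac == pytest.approx(0.3, abs=3 * np.sqrt(0.3 * 0.7 / n_total))

    def test_mixture_midpoint_on_chrx_cgis(self, small_study, small_config):
        genome = small_study.genome
        chrx_vals = []
        for k in range(6):
            lib = simulate_contaminated(
                genome,
                small_study.truths[("oocyte", "NS")],
                small_study.truths[("somatic", "NS")],
                0.5,
                small_config,
                f"mix{k}",
                np.random.default_rng(300 + k),
            )
            chrx_vals.append(cgi_chrom_methylation(lib, genome.cgi_track, "chrX"))
        assert np.mean(chrx_vals) == pytest.approx(25.0, abs=5.0)

    def test_full_mixture_is_somatic_profile(self, small_study, small_config):
        genome = small_study.genome
        ch_vals, chrx_vals = [], []
        for k in range(6):
            lib = simulate_contaminated(
                genome,
                small_study.truths[("oocyte", "NS")],
                small_study.truths[("somatic", "NS")],
                1.0,
                small_config,
                f"som{k}",
                np.random.default_rng(700 + k),
            )
            ch_vals.append(context_methylation(lib)[1])
            chrx_vals.append(cgi_chrom_methylation(lib, genome.cgi_track, "chrX"))
        assert np.mean(ch_vals) < 1.0
        assert np.mean(chrx_vals) == pytest.approx(50.0, abs=5.0)

    def test_oocyte_ch_level(self, clean_small_study):
        _, ch = context_methylation(clean_small_study.libraries[0])
        assert ch == pytest.approx(5.0, abs=1.0)


class TestSimulateStudy:
    def test_default_counts_and_manifest(self, small_study):
        assert len(small_study.libraries) == 45
        m = small_study.manifest
        assert len(m) == 45
        assert m.groupby("group").size().to_dict() == {"NS": 15, "S": 30}
        assert m["contaminated"].sum() == 17
        assert set(m.loc[m["contaminated"], "mixture_fraction"]) == {0.5}

    def test_rerun_same_seed_reproduces_manifest_and_calls(self, small_config):
        s1 = simulate_study(small_config, seed=21)
        s2 = simulate_study(small_config, seed=21)
        assert s1.manifest.equals(s2.manifest)
        for a, b in zip(s1.libraries, s2.libraries):
            for chrom in a.calls:
                np.testing.assert_array_equal(a.calls[chrom].pos, b.calls[chrom].pos)
                np.testing.assert_array_equal(a.calls[chrom].n_meth, b.calls[chrom].n_meth)

    def test_written_tree_is_byte_reproducible(self, tmp_path):
        cfg = SimulationConfig(
            **{**SMALL_SIM_KWARGS, "chrom_length_bp": 400_000,
               "exemplar_region": ("chr5", 300_000, 380_000)}
        )
        simulate_study(cfg, seed=3, out_dir=tmp_path / "a")
        simulate_study(cfg, seed=3, out_dir=tmp_path / "b")
        mismatch = []
        for rel in ["genome.fa", "cgi.bed", "manifest.tsv"]:
            if not filecmp.cmp(tmp_path / "a" / rel, tmp_path / "b" / rel, shallow=False):
                mismatch.append(rel)
        cov_a = sorted((tmp_path / "a" / "coverage").iterdir())
        cov_b = sorted((tmp_path / "b" / "coverage").iterdir())
        assert [p.name for p in cov_a] == [p.name for p in cov_b]
        for pa, pb in zip(cov_a, cov_b):
            if not filecmp.cmp(pa, pb, shallow=False):
                mismatch.append(pa.name)
        assert mismatch == []

    def test_coverage_files_round_trip_through_strand_folding(self, tmp_path):
        cfg = SimulationConfig(
            **{**SMALL_SIM_KWARGS, "chrom_length_bp": 400_000,
               "exemplar_region": ("chr5", 300_000, 380_000)}
        )
        study = simulate_study(cfg, seed=5, out_dir=tmp_path / "s")
        lib = study.libraries[3]
        path = tmp_path / "s" / "coverage" / f"{lib.library_id}.CpG.cov"
        folded = read_coverage(path, index=study.genome.index)
        assert set(folded) == set(lib.calls)
        for chrom, cc in lib.calls.items():
            np.testing.assert_array_equal(folded[chrom].pos, cc.pos)
            np.testing.assert_array_equal(folded[chrom].n_meth, cc.n_meth)
            np.testing.assert_array_equal(folded[chrom].n_unmeth, cc.n_unmeth)
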