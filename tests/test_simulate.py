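"""Generator determinism, statistical structure and truth consistency."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from atacnet.annotation import GeneModel
from atacnet.intervals import GenomicInterval, IntervalSet, intersect
from atacnet.motifs import fixture_library, reverse_complement
from atacnet.simulate import (
    PlacementError,
    SimulationConfig,
    _stage_rngs,
    generate_dataset,
    generate_expression,
    generate_genome,
    implant_motifs,
    write_dataset,
)


class TestConfig:
    def test_rates_validated(self):
        with pytest.raises(ValueError):
            SimulationConfig(implant_rate=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(peak_width_range=(0, 100))

    def test_impossible_gene_density_named(self):
        with pytest.raises(PlacementError, match="genes"):
            SimulationConfig(n_genes=10_000)

    def test_impossible_peak_density_named(self):
        with pytest.raises(PlacementError, match="peak"):
            SimulationConfig(n_shared_peaks=10_000)

    def test_single_replicate_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="atacnet.simulate"):
            SimulationConfig(replicates_per_condition=1)
        assert any("duplicates" in r.message for r in caplog.records)


class TestGenome:
    def test_no_genes_still_generates_genome(self):
        cfg = SimulationConfig(n_genes=0, n_shared_peaks=10,
                               n_unique_peaks_per_condition=0, seed=5)
        genome, genes = generate_genome(cfg)
        assert genes == []
        assert len(genome["chr1"]) == cfg.chrom_length

    def test_base_composition_uniform(self):
        cfg = SimulationConfig(n_chromosomes=1, chrom_length=1_000_000, n_genes=0,
                               n_shared_peaks=10, n_unique_peaks_per_condition=0, seed=6)
        genome, _ = generate_genome(cfg)
        seq = genome["chr1"]
        n = len(seq)
        sd = np.sqrt(0.25 * 0.75 / n)
        for base in "ACGT":
            assert abs(seq.count(base) / n - 0.25) < 3 * sd

    def test_gene_models_valid_and_spaced(self):
        cfg = SimulationConfig(seed=7)
        _, genes = generate_genome(cfg)
        assert len(genes) == cfg.n_genes
        for g in genes:
            assert len(g.exons) >= 2
            assert g.exons[0].start == g.body.start
            assert max(e.end for e in g.exons) == g.body.end
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for gs in by_chrom.values():
            gs.sort(key=lambda g: g.body.start)
            for a, b in zip(gs, gs[1:]):
                assert b.body.start - a.body.end >= cfg.min_gene_spacing


class TestPeaksAndCounts:
    def test_replicate_bed_contents(self, dataset):
        cfg = dataset.config
        for s in dataset.samples:
            peaks = dataset.sample_peaks[s.sample_id]
            assert len(peaks) == cfg.n_shared_peaks + cfg.n_unique_peaks_per_condition

    def test_unique_peaks_absent_from_other_condition(self, dataset):
        cfg = dataset.config
        ua = dataset.true_peaks(cfg.condition_a)
        for s in dataset.samples:
            if s.condition == cfg.condition_b:
                assert intersect(ua, dataset.sample_peaks[s.sample_id]) == []

    def test_truth_flags_mutually_exclusive(self, dataset):
        truth = dataset.truth_peaks
        assert truth["peak_id"].is_unique
        assert set(truth["condition"]) == {
            "shared", dataset.config.condition_a, dataset.config.condition_b
        }

    def test_nb_count_moments(self):
        cfg = SimulationConfig(n_shared_peaks=1000, n_unique_peaks_per_condition=0,
                               n_genes=0, n_super_enhancers=0, chrom_length=2_000_000,
                               n_chromosomes=2, seed=8)
        ds = generate_dataset(cfg)
        open_counts = ds.counts.counts.to_numpy().ravel().astype(float)
        mu, disp = cfg.nb_mean, cfg.nb_dispersion
        se = np.sqrt((mu + disp * mu**2) / open_counts.size)
        assert abs(open_counts.mean() - mu) < 3 * se

    def test_closed_counts_low(self, dataset):
        cfg = dataset.config
        ua_ids = dataset.truth_peaks.query("condition == @cfg.condition_a")["peak_id"]
        b_cols = [s.sample_id for s in dataset.samples if s.condition == cfg.condition_b]
        closed = dataset.counts.counts.loc[ua_ids, b_cols].to_numpy().astype(float)
        mu = cfg.closed_count_mean
        se = np.sqrt((mu + cfg.nb_dispersion * mu**2) / closed.size)
        assert abs(closed.mean() - mu) < 4 * se


class TestImplants:
    def test_rate_one_marks_every_unique_peak(self, pwms):
        cfg = SimulationConfig(implant_rate=1.0, seed=9)
        ds = generate_dataset(cfg)
        ua = ds.truth_peaks.query("condition == @cfg.condition_a")
        assert (ua["motif_id"] != "").all()

    def test_implanted_site_retrievable(self, dataset, pwms):
        truth = dataset.truth_peaks
        implanted = truth[truth["motif_id"] != ""]
        assert len(implanted) == round(
            dataset.config.implant_rate * dataset.config.n_unique_peaks_per_condition
        )
        for row in implanted.itertuples():
            pwm = pwms[row.motif_id]
            pos = row.start + int(row.implant_offset)
            found = dataset.genome[row.chrom][pos : pos + pwm.width]
            expected = pwm.consensus if row.implant_strand == "+" else reverse_complement(
                pwm.consensus
            )
            assert found == expected

    def test_rate_zero_leaves_genome_untouched(self):
        cfg = SimulationConfig(implant_rate=0.0, seed=10)
        rngs = _stage_rngs(cfg.seed)
        genome, genes = generate_genome(cfg, rngs["genome"], rngs["genes"])
        from atacnet.simulate import generate_peaks_and_counts

        _, _, _, truth = generate_peaks_and_counts(
            genome, genes, cfg, rngs["peaks"], rngs["jitter"], rngs["counts"]
        )
        lib = fixture_library()
        modified, truth2 = implant_motifs(genome, truth, list(lib.values()), cfg,
                                          rngs["implant"])
        assert modified == genome
        assert (truth2["motif_id"] == "").all()

    def test_too_wide_pwm_skipped_with_warning(self, caplog):
        import logging

        cfg = SimulationConfig(peak_width_range=(40, 48), implant_rate=1.0,
                               boundary_jitter=20, seed=11)
        # width-11 PWM cannot fit: 48 < 11 + 2 * 20 (jitter-safe margin)
        wide = fixture_library()["EBOX_ASCL1"]
        with caplog.at_level(logging.WARNING, logger="atacnet.simulate"):
            ds = generate_dataset(cfg, implant_pwms=[wide])
        assert (ds.truth_peaks["motif_id"] == "").all()
        assert any("too wide" in r.message for r in caplog.records)


class TestExpression:
    def test_flagged_genes_significant_up(self, dataset):
        expr = {r.gene_id: r for r in dataset.expression}
        for g in dataset.flagged_genes:
            assert expr[g].padj < 0.05
            assert expr[g].log2fc > 0
        for r in dataset.expression:
            if r.gene_id not in dataset.flagged_genes:
                assert r.padj >= 0.05

    def test_coupled_fraction_zero_means_no_upregulation(self):
        cfg = SimulationConfig(coupled_fraction=0.0, seed=12)
        ds = generate_dataset(cfg)
        assert ds.flagged_genes == set()
        assert all(r.padj >= 0.05 for r in ds.expression)

    def test_truncated_normal_mean(self):
        cfg = SimulationConfig(seed=13)
        rng = np.random.default_rng(99)
        genes = [
            GeneModel(f"g{i}", "chr1", "+",
                      GenomicInterval("chr1", i * 10_000, i * 10_000 + 2_000),
                      (GenomicInterval("chr1", i * 10_000, i * 10_000 + 500),
                       GenomicInterval("chr1", i * 10_000 + 1_500, i * 10_000 + 2_000)))
            for i in range(500)
        ]
        flagged = {g.gene_id for g in genes}
        records = generate_expression(genes, flagged, cfg, rng)
        lfcs = np.array([r.log2fc for r in records])
        a = -cfg.lfc_mean / cfg.lfc_sd
        expected = stats.truncnorm.mean(a, np.inf, loc=cfg.lfc_mean, scale=cfg.lfc_sd)
        expected_sd = stats.truncnorm.std(a, np.inf, loc=cfg.lfc_mean, scale=cfg.lfc_sd)
        assert abs(lfcs.mean() - expected) < 3 * expected_sd / np.sqrt(len(lfcs))


class TestH3K27acAndSE:
    def test_full_coverage_hits_every_unique_peak(self):
        cfg = SimulationConfig(h3k27ac_coverage=1.0, seed=14)
        ds = generate_dataset(cfg)
        ua = ds.true_peaks(cfg.condition_a)
        covered = {p.name for p, _, _ in intersect(ua, ds.h3k27ac)}
        assert covered == {iv.name for iv in ua}

    def test_no_marks_no_super_enhancers(self):
        cfg = SimulationConfig(h3k27ac_coverage=0.0, n_super_enhancers=0, seed=15)
        ds = generate_dataset(cfg)
        assert len(ds.h3k27ac) == 0
        assert len(ds.super_enhancers) == 0

    def test_every_se_has_three_constituents(self, dataset):
        for se in dataset.super_enhancers:
            members = [
                m for _, m, _ in intersect(
                    IntervalSet([se]), dataset.h3k27ac
                )
            ]
            assert len(members) >= 3

    def test_designed_se_hosts_are_flagged(self, dataset):
        designed = dataset.truth_se.query("designed")
        assert len(designed) == dataset.config.n_super_enhancers
        assert set(designed["gene_id"]) <= dataset.flagged_genes


class TestDeterminismAndOutput:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=21)
        d1 = tmp_path / "run1"
        d2 = tmp_path / "run2"
        p1 = write_dataset(generate_dataset(cfg), d1)
        p2 = write_dataset(generate_dataset(SimulationConfig(seed=21)), d2)
        assert set(p1) == set(p2)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seed_differs(self, tmp_path):
        a = generate_dataset(SimulationConfig(seed=22))
        b = generate_dataset(SimulationConfig(seed=23))
        assert a.genome["chr1"] != b.genome["chr1"]

    def test_written_files_parse_back(self, tmp_path, dataset):
        from atacnet.annotation import read_gene_models_bed12
        from atacnet.expression import read_expression_table
        from atacnet.intervals import read_bed
        from atacnet.simulate import read_fasta

        paths = write_dataset(dataset, tmp_path)
        genome = read_fasta(paths["genome"])
        assert genome == dataset.genome
        genes = read_gene_models_bed12(paths["genes"])
        assert len(genes) == len(dataset.genes)
        expr = read_expression_table(paths["expression"])
        assert len(expr) == len(dataset.expression)
        sid = dataset.samples[0].sample_id
        peaks = read_bed(paths[f"peaks_{sid}"])
        assert len(peaks) == len(dataset.sample_peaks[sid])
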