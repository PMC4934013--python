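"""Tests for the synthetic data generator."""

import numpy as np
import pandas as pd
import pytest

from riboscope.io import write_fasta
from riboscope.models import index_by_transcript
from riboscope.synthetic import (
    PREFIX_LENGTH,
    SimulationConfig,
    simulate_annotation,
    simulate_footprints,
    simulate_ribotag,
    simulate_rnaseq_counts,
)


class TestConfigValidation:
    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            SimulationConfig(n_genes=5, cds_length_range=(900, 300))

    def test_bad_proportion_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=5, frac_uaug_genes=1.5)

    def test_too_few_cell_types_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=5, n_cell_types=1)

    def test_split_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=5, cds_read_fraction=(0.5, 0.5, 0.5))

    def test_mixture_weights_must_sum_to_one(self):
        bad = {ct: ((0.5, 0.0, 1.0),) for ct in SimulationConfig(n_genes=1).cell_types}
        with pytest.raises(ValueError, match="mixture"):
            SimulationConfig(n_genes=5, te_log2_distribution=bad)


class TestSimulateAnnotation:
    def test_no_uaug_when_fraction_zero(self):
        config = SimulationConfig(n_genes=30, frac_uaug_genes=0.0, seed=3)
        models, truth = simulate_annotation(config)
        for m in models:
            assert "ATG" not in m.utr5_sequence
        assert not truth.genes["has_uaug"].any()

    def test_pure_gc_utr5_at_boundary_range(self):
        config = SimulationConfig(
            n_genes=20, frac_uaug_genes=0.0, utr5_gc_range=(1.0, 1.0), seed=4
        )
        models, _ = simulate_annotation(config)
        for m in models:
            assert set(m.utr5_sequence) <= {"G", "C"}

    def test_uaug_flags_consistent_with_sequence(self, small_dataset):
        models, truth = small_dataset
        by_gene = {m.gene_id: m for m in models}
        for gene, flagged in truth.genes["has_uaug"].items():
            has = "ATG" in by_gene[gene].utr5_sequence
            assert has == flagged

    def test_utr5_gc_within_configured_range(self, small_config, small_dataset):
        lo, hi = small_config.utr5_gc_range
        models, _ = small_dataset
        for m in models:
            seq = m.utr5_sequence
            gc = (seq.count("G") + seq.count("C")) / len(seq)
            assert lo - 1e-9 <= gc <= hi + 1e-9

    def test_cds_structure(self, small_dataset):
        models, _ = small_dataset
        for m in models:
            cds = m.cds_sequence
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG")

    def test_regions_tile_transcript(self, small_dataset):
        models, _ = small_dataset
        for m in models:
            (u5s, u5e), (cs, ce), (u3s, u3e) = m.utr5, m.cds, m.utr3
            assert (u5s, u5e, cs, ce, u3s, u3e) == (0, cs, u5e, u3s, ce, m.length)

    def test_truth_keys_match_annotation(self, small_dataset):
        models, truth = small_dataset
        gene_ids = {m.gene_id for m in models}
        assert gene_ids == set(truth.genes.index)
        assert gene_ids == set(truth.fpkm.index)

    def test_same_seed_byte_identical_fasta(self, tmp_path):
        config = SimulationConfig(n_genes=15, seed=11)
        paths = []
        for tag in ("a", "b"):
            models, _ = simulate_annotation(config)
            p = tmp_path / f"{tag}.fasta"
            write_fasta({m.transcript_id: m.sequence for m in models}, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_top_flags_only_on_repressed_genes(self, small_dataset):
        _, truth = small_dataset
        shift = truth.genes["log2_te_treated"] - truth.genes["log2_te_untreated"]
        assert (shift[truth.genes["is_top"]] != 0).all()
        assert (shift[~truth.genes["is_top"]] == 0).all()


class TestSimulateFootprints:
    def test_empty_models_rejected(self, small_config, small_dataset):
        _, truth = small_dataset
        with pytest.raises(ValueError, match="empty"):
            simulate_footprints([], truth, small_config)

    def test_read_length_conservation(self, small_config, small_footprints):
        reads, _ = small_footprints
        for r in reads[:500]:
            assert len(r.sequence) == small_config.read_length
            assert len(r.quality) == len(r.sequence)

    def test_read_structure_prefix_footprint_tail(self, small_config, small_dataset,
                                                  small_footprints):
        models, _ = small_dataset
        by_tid = index_by_transcript(models)
        reads, alignments = small_footprints
        for r, row in zip(reads[:200], alignments.head(200).itertuples(index=False)):
            m = by_tid[row.transcript_id]
            footprint = m.sequence[row.five_prime_pos : row.five_prime_pos + row.length]
            assert r.sequence[PREFIX_LENGTH : PREFIX_LENGTH + row.length] == footprint
            tail = r.sequence[PREFIX_LENGTH + row.length :]
            assert tail == "A" * len(tail)

    def test_full_periodicity_forces_frame_zero(self, small_dataset):
        models, truth = small_dataset
        config = SimulationConfig(n_genes=40, seed=7, periodicity_strength=1.0)
        _, aln = simulate_footprints(models, truth, config, depth=3000, with_reads=False)
        by_tid = index_by_transcript(models)
        starts = aln["transcript_id"].map(lambda t: by_tid[t].cds_start)
        ends = aln["transcript_id"].map(lambda t: by_tid[t].cds_end)
        in_cds = (aln["five_prime_pos"] >= starts) & (aln["five_prime_pos"] < ends)
        offsets = (aln["five_prime_pos"] - starts)[in_cds]
        assert (offsets % 3 == 0).all()

    def test_frame_composition_limit(self):
        # frame-0 fraction tends to p + (1-p)/3; Monte-Carlo at 1e5 reads, 1%
        p = 0.6
        config = SimulationConfig(n_genes=100, seed=21, periodicity_strength=p)
        models, truth = simulate_annotation(config)
        _, aln = simulate_footprints(models, truth, config, depth=120_000, with_reads=False)
        by_tid = index_by_transcript(models)
        starts = aln["transcript_id"].map(lambda t: by_tid[t].cds_start)
        ends = aln["transcript_id"].map(lambda t: by_tid[t].cds_end)
        in_cds = (aln["five_prime_pos"] >= starts) & (aln["five_prime_pos"] < ends)
        offsets = (aln["five_prime_pos"] - starts)[in_cds]
        frac0 = (offsets % 3 == 0).mean()
        assert abs(frac0 - (p + (1 - p) / 3)) < 0.01

    def test_top_repression_quarters_mean_counts(self):
        # law of the generator: the TOP/non-TOP count ratio between treated
        # and untreated conditions equals 2**top_repression_log2 (the global
        # normalizer cancels in the double ratio)
        config = SimulationConfig(
            n_genes=10_000, seed=5, top_gene_fraction=0.2, top_repression_log2=-2.0
        )
        models, truth = simulate_annotation(config)
        depth = 400_000
        counts = {}
        for cond in ("untreated", "treated"):
            _, aln = simulate_footprints(models, truth, config, cond, depth, with_reads=False)
            counts[cond] = aln["gene_id"].value_counts().reindex(truth.genes.index).fillna(0)
        is_top = truth.genes["is_top"]
        double_ratio = (
            counts["treated"][is_top].mean() / counts["untreated"][is_top].mean()
        ) / (
            counts["treated"][~is_top].mean() / counts["untreated"][~is_top].mean()
        )
        assert double_ratio == pytest.approx(0.25, rel=0.1)

    def test_region_split_recovered_at_depth(self):
        from riboscope.qc import gene_body_distribution

        config = SimulationConfig(n_genes=200, seed=9)
        models, truth = simulate_annotation(config)
        _, aln = simulate_footprints(models, truth, config, depth=1_000_000, with_reads=False)
        fractions = gene_body_distribution(aln, models)
        for region, target in zip(("utr5", "cds", "utr3"), config.cds_read_fraction):
            assert abs(fractions[region] - target) < 0.02

    def test_determinism(self, small_config, small_dataset):
        models, truth = small_dataset
        _, a = simulate_footprints(models, truth, small_config, depth=2000, with_reads=False)
        _, b = simulate_footprints(models, truth, small_config, depth=2000, with_reads=False)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateRnaseq:
    def test_scaling_factor_recovered_by_size_factors(self, small_config, small_dataset):
        from riboscope.quantify import size_factors

        models, truth = small_dataset
        table = simulate_rnaseq_counts(
            models, truth, small_config, depth=200_000, n_samples=2, lib_scales=[1.0, 2.0]
        )
        sf = size_factors(table.region("cds"))
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0, rel=0.05)

    def test_zero_fpkm_gene_yields_zero_counts(self, small_config, small_dataset):
        models, truth = small_dataset
        truth2 = type(truth)(genes=truth.genes.copy(), fpkm=truth.fpkm.copy())
        dead = models[0].gene_id
        truth2.fpkm.loc[dead] = 0.0
        table = simulate_rnaseq_counts(models, truth2, small_config, depth=100_000)
        assert table.gene_totals().loc[dead].sum() == 0

    def test_fixed_seed_identical_table(self, small_config, small_dataset):
        models, truth = small_dataset
        a = simulate_rnaseq_counts(models, truth, small_config, depth=20_000)
        b = simulate_rnaseq_counts(models, truth, small_config, depth=20_000)
        pd.testing.assert_frame_equal(a.counts, b.counts)


class TestSimulateRibotag:
    def test_neutral_enrichment_keeps_means_equal(self, small_config, small_dataset):
        models, truth = small_dataset
        ip, hom = simulate_ribotag(
            models, truth, small_config, enrichment=1.0, depletion=1.0, depth=400_000
        )
        ratio = ip.gene_totals().mean(axis=1) / hom.gene_totals().mean(axis=1)
        assert ratio.median() == pytest.approx(1.0, abs=0.05)

    def test_enrichment_recovered(self, small_config, small_dataset):
        from riboscope.quantify import ribotag_enrichment_score

        models, truth = small_dataset
        ip, hom = simulate_ribotag(models, truth, small_config, enrichment=4.0, depth=400_000)
        scores = ribotag_enrichment_score(ip, hom)
        target = small_config.cell_types[small_config.ribotag_target_cell_type]
        target_genes = truth.genes.index[truth.genes["cell_type"] == target]
        assert scores[scores.index.isin(target_genes)].median() == pytest.approx(4.0, rel=0.15)

    def test_absent_target_cell_type_rejected(self, small_config, small_dataset):
        models, truth = small_dataset
        target = small_config.cell_types[small_config.ribotag_target_cell_type]
        genes = truth.genes.copy()
        genes.loc[genes["cell_type"] == target, "cell_type"] = "astrocyte"
        truth2 = type(truth)(genes=genes, fpkm=truth.fpkm)
        with pytest.raises(ValueError, match="absent"):
            simulate_ribotag(models, truth2, small_config)
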