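"""Ground-truth fidelity and determinism of the synthetic-data generator."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import pytest

from tescope.annotation import annotation_frame, filter_redundancy, parse_rm_out
from tescope.divergence import read_alignment_pairs
from tescope.normalization import read_counts_table, read_gene_sets
from tescope.quantify import (
    aggregate_profile,
    assign_reads_to_te,
    filter_alignments,
    read_alignment_tsv,
)
from tescope.simulate import (
    FamilySpec,
    GroundTruth,
    SimulationConfig,
    TreatmentSpec,
    _apportion,
    simulate_expression,
    simulate_te_copies,
    write_copy_bundle,
    write_expression_bundle,
)


class TestConfigValidation:
    def test_saturating_rates_rejected(self):
        with pytest.raises(ValueError, match="saturat"):
            FamilySpec("x", "LTR/ERV1", 1, 100, 0.45, 0.2)

    def test_class_shares_must_leave_read_budget(self):
        shares = {s: {"DNA": 0.5, "LINE": 0.3, "SINE": 0.1, "LTR": 0.2, "Unclear": 0.1}
                  for s in SimulationConfig().stages}
        with pytest.raises(ValueError, match="sum"):
            SimulationConfig(stage_class_shares=shares)

    def test_ltr_mix_must_sum_to_one(self):
        mix = {s: {"ERV1": 0.5} for s in SimulationConfig().stages}
        with pytest.raises(ValueError, match="mix"):
            SimulationConfig(stage_ltr_mix=mix)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            simulate_expression(SimulationConfig(replicates=1))

    def test_excessive_treatment_fold_rejected(self):
        trt = TreatmentSpec(ltr_fold_change=50.0)
        with pytest.raises(ValueError, match="fold"):
            trt.treated_class_shares()


class TestApportion:
    def test_exact_when_shares_are_integral(self):
        assert _apportion(1000, [0.25, 0.25, 0.5]).tolist() == [250, 250, 500]

    def test_sums_to_total_with_awkward_shares(self, rng):
        for _ in range(50):
            weights = rng.uniform(0.01, 1.0, size=int(rng.integers(2, 8)))
            total = int(rng.integers(0, 5000))
            parts = _apportion(total, weights)
            assert parts.sum() == total and (parts >= 0).all()


class TestCopySimulation:
    def test_zero_rates_give_identical_copies(self):
        config = SimulationConfig(
            seed=3, families=(FamilySpec("flat", "LTR/ERV1", 4, 500, 0.0, 0.0),)
        )
        copies = simulate_te_copies(config)
        for entry_id, copy_seq, cons_seq in copies.pairs:
            assert copy_seq == cons_seq
        assert all(c.realized_transitions == c.realized_transversions == 0 for c in copies.copies)

    def test_same_seed_reproduces_byte_identical_outputs(self, tmp_path):
        config = SimulationConfig(seed=7, reads_per_sample=1000)
        for run in ("a", "b"):
            copies = simulate_te_copies(config)
            bundle = simulate_expression(config, copies)
            write_copy_bundle(copies, tmp_path / run)
            write_expression_bundle(bundle, tmp_path / run)
        files_a = sorted((tmp_path / "a").rglob("*"))
        for file_a in files_a:
            if file_a.is_file():
                file_b = tmp_path / "b" / file_a.relative_to(tmp_path / "a")
                assert file_a.read_bytes() == file_b.read_bytes(), file_a.name

    def test_annotations_match_copy_coordinates(self, noise_free_copies):
        for ann, copy in zip(noise_free_copies.annotations, noise_free_copies.copies):
            assert (ann.contig_id, ann.start, ann.end) == (copy.contig_id, copy.start, copy.end)
            contig = noise_free_copies.contigs[ann.contig_id]
            assert contig[ann.start : ann.end] == copy.sequence


class TestEmittedFilesRoundTrip:
    def test_bundle_files_reload_cleanly(self, tmp_path, noise_free_copies, noise_free_bundle):
        write_copy_bundle(noise_free_copies, tmp_path)
        write_expression_bundle(noise_free_bundle, tmp_path)

        assert parse_rm_out(tmp_path / "annotations.out") == noise_free_copies.annotations
        pairs = read_alignment_pairs(tmp_path / "pairs.fasta")
        assert pairs == noise_free_copies.pairs

        counts, lengths = read_counts_table(tmp_path / "gene_counts.tsv")
        assert np.allclose(counts, noise_free_bundle.gene_counts, rtol=1e-9)
        assert lengths.tolist() == noise_free_bundle.gene_lengths.tolist()

        sets = read_gene_sets(tmp_path / "gene_sets.txt")
        assert sets == noise_free_bundle.gene_sets

        sample = noise_free_bundle.sample_sheet["sample"].iloc[0]
        table = read_alignment_tsv(tmp_path / "alignments" / f"{sample}.tsv")
        pd.testing.assert_frame_equal(table, noise_free_bundle.alignments[sample])

        truth = GroundTruth.from_json(tmp_path / "ground_truth.json")
        assert truth.samples == noise_free_bundle.truth.samples

    def test_ground_truth_is_json_serialisable(self, tmp_path, noise_free_bundle):
        noise_free_bundle.truth.to_json(tmp_path / "gt.json")
        data = json.loads((tmp_path / "gt.json").read_text())
        assert data["orthologues_constant"] is True
        assert set(data) == {"samples", "genes", "copies", "orthologues_constant"}


class TestEndToEndIdentity:
    def test_noise_free_pipeline_recovers_configured_percentages(
        self, noise_free_config, noise_free_copies, noise_free_bundle
    ):
        """Quantifying noise-free reads reproduces the configured stage x class
        share matrix exactly (integer read counts, exact percentages)."""
        ann = annotation_frame(filter_redundancy(noise_free_copies.annotations))
        for sample, table in noise_free_bundle.alignments.items():
            kept = filter_alignments(table)
            counts = assign_reads_to_te(kept, ann)
            prof = aggregate_profile(counts, ann, total_mapped_reads=len(kept), sample_id=sample)
            truth = noise_free_bundle.truth.samples[sample]["class_shares"]
            total = prof.total_mapped_reads
            for cls, share in truth.items():
                assert prof.counts[cls] == round(share * total)
                assert prof.percentages[cls] == pytest.approx(100.0 * share, rel=1e-12)
            assert sum(prof.ltr_percentages.values()) == pytest.approx(
                prof.percentages["LTR"], abs=1e-9
            )

    def test_orthologue_constancy_and_depth_recovery(self):
        config = SimulationConfig(
            seed=21,
            reads_per_sample=1000,
            dispersion=0.0,
            depth_multipliers={"zygote_r1": 1.0, "zygote_r2": 2.0},
        )
        bundle = simulate_expression(config)
        counts = bundle.gene_counts[["zygote_r1", "zygote_r2"]]
        rates = counts.div(bundle.gene_lengths, axis=0)
        from tescope.normalization import ortholog_scaling

        orth = bundle.gene_sets["single_copy_orthologues"]
        factors, _ = ortholog_scaling(rates, orth)
        assert factors["zygote_r1"] / factors["zygote_r2"] == pytest.approx(2.0, abs=1e-6)
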