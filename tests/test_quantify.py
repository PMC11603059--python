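"""Read filtering, read-to-TE assignment and percent-of-mapped-reads profiles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tescope.annotation import annotation_frame, filter_redundancy
from tescope.quantify import (
    ReadAlignment,
    aggregate_profile,
    alignment_frame,
    assign_reads_to_te,
    filter_alignments,
    profile_frame,
    read_sam,
)
from tescope.simulate import write_sam

from conftest import random_annotation
from test_annotation import _ann


def _read(read_id, contig, start, end, read_length=100, aligned=None, matches=None):
    aligned = (end - start) if aligned is None else aligned
    matches = aligned if matches is None else matches
    return ReadAlignment(read_id, contig, start, end, read_length, aligned, matches)


class TestFilterAlignments:
    @pytest.mark.parametrize(
        "aligned, matches, kept",
        [
            (79, 79, False),  # 0.79 aligned fraction, just below the cutoff
            (80, 68, True),  # both ratios exactly at / above 0.80
            (80, 63, False),  # identity 0.7875 below the cutoff
            (100, 80, True),
        ],
    )
    def test_cutoffs_are_inclusive(self, aligned, matches, kept):
        aln = _read("r1", "c1", 0, aligned, read_length=100, aligned=aligned, matches=matches)
        out = filter_alignments([aln])
        assert (len(out) == 1) == kept

    def test_empty_input(self):
        assert filter_alignments([]).empty

    def test_multimapped_read_reduced_to_best_record(self):
        records = [
            _read("r1", "c1", 0, 100, matches=85),
            _read("r1", "c2", 0, 100, matches=95),
            _read("r1", "c3", 0, 100, matches=95),  # tie -> earlier record wins
            _read("r2", "c1", 0, 100, matches=90),
        ]
        out = filter_alignments(records)
        assert len(out) == 2
        r1 = out[out["read_id"] == "r1"].iloc[0]
        assert (r1["contig_id"], r1["matches"]) == ("c2", 95)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.2])
    def test_invalid_fraction_rejected(self, bad):
        with pytest.raises(ValueError, match="fraction"):
            filter_alignments([], length_fraction=bad)


class TestAssignment:
    def _two_entry_frame(self):
        return annotation_frame([_ann("c1", 100, 600, score=10), _ann("c1", 700, 900, score=10)])

    def test_fully_contained_read_counts(self):
        ann = self._two_entry_frame()
        counts = assign_reads_to_te([_read("r1", "c1", 150, 250)], ann)
        assert counts.tolist() == [1, 0]

    def test_half_overlap_boundary_counts(self):
        ann = self._two_entry_frame()
        # overlap 50 of 100 aligned bases = 0.5, inclusive cutoff
        counts = assign_reads_to_te([_read("r1", "c1", 550, 650)], ann)
        assert counts.tolist() == [1, 0]
        counts = assign_reads_to_te([_read("r1", "c1", 551, 651)], ann)
        assert counts.tolist() == [0, 0]  # 49/100 < 0.5

    def test_read_on_te_free_contig_unassigned(self):
        ann = self._two_entry_frame()
        counts = assign_reads_to_te([_read("r1", "cX", 0, 100)], ann)
        assert counts.sum() == 0

    def test_overlapping_annotations_rejected(self):
        ann = annotation_frame([_ann("c1", 100, 300, score=5), _ann("c1", 200, 400, score=4)])
        with pytest.raises(ValueError, match="overlap"):
            assign_reads_to_te([_read("r1", "c1", 0, 100)], ann)

    def test_matches_brute_force_scan(self, rng):
        anns = filter_redundancy(
            [random_annotation(rng, f"c{int(rng.integers(0, 4))}") for _ in range(40)],
            min_length=30,
        )
        ann = annotation_frame(anns)
        reads = []
        for i in range(200):
            start = int(rng.integers(0, 2300))
            length = int(rng.integers(20, 150))
            reads.append(_read(f"r{i}", f"c{int(rng.integers(0, 5))}", start, start + length,
                               read_length=length))
        counts = assign_reads_to_te(reads, ann)
        expected = np.zeros(len(ann), dtype=int)
        for read in reads:
            best, best_frac = None, -1.0
            for pos, row in enumerate(ann.itertuples()):
                if row.contig_id != read.contig_id:
                    continue
                overlap = min(read.aln_end, row.end) - max(read.aln_start, row.start)
                frac = overlap / (read.aln_end - read.aln_start)
                if frac > best_frac + 1e-12:
                    best, best_frac = pos, frac
            if best is not None and best_frac >= 0.5:
                expected[best] += 1
        assert counts.tolist() == expected.tolist()


class TestAggregate:
    def _profile(self, counts_by_class, total):
        anns = []
        entry_counts = []
        for i, (class_family, n) in enumerate(counts_by_class):
            anns.append(_ann(f"c{i}", 0, 200, score=10, class_family=class_family))
            entry_counts.append(n)
        ann = annotation_frame(anns)
        return aggregate_profile(pd.Series(entry_counts, index=ann.index), ann, total)

    def test_hand_worked_percentages(self):
        prof = self._profile(
            [("LTR/ERV1", 30), ("LTR/Gypsy", 20), ("LINE/L2", 30)], total=1000
        )
        assert prof.percentages["LTR"] == pytest.approx(5.0)
        assert prof.percentages["LINE"] == pytest.approx(3.0)
        assert prof.ltr_percentages["ERV1"] == pytest.approx(3.0)
        assert prof.ltr_percentages["Gypsy"] == pytest.approx(2.0)

    def test_no_te_reads_all_zero(self):
        prof = self._profile([("LTR/ERV1", 0)], total=1000)
        assert all(v == 0 for v in prof.percentages.values())

    def test_single_class(self):
        prof = self._profile([("SINE/tRNA", 7)], total=70)
        assert prof.percentages["SINE"] == pytest.approx(10.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="total_mapped_reads"):
            self._profile([("LTR/ERV1", 0)], total=0)

    def test_percentages_invariant_under_uniform_scaling(self):
        base = self._profile([("LTR/ERV1", 30), ("LINE/L2", 50)], total=1000)
        scaled = self._profile([("LTR/ERV1", 300), ("LINE/L2", 500)], total=10000)
        assert base.percentages == scaled.percentages
        assert base.ltr_percentages == scaled.ltr_percentages

    def test_ltr_superfamily_percentages_sum_to_class(self):
        prof = self._profile(
            [("LTR/ERV1", 13), ("LTR/Gypsy", 29), ("LTR/DIRS", 8), ("LTR/ERVK", 3)], total=977
        )
        assert sum(prof.ltr_percentages.values()) == pytest.approx(
            prof.percentages["LTR"], abs=1e-9
        )

    def test_tidy_frame_schema(self):
        prof = self._profile([("LTR/ERV1", 30)], total=100)
        df = profile_frame([prof])
        assert set(df["level"]) == {"te_class", "ltr_superfamily"}
        assert df[df["level"] == "te_class"]["percent"].sum() == pytest.approx(30.0)


class TestNoiseFreeRecovery:
    def test_generating_counts_recovered_exactly(self, noise_free_copies, noise_free_bundle):
        """Reads generated from an entry must come back to that entry, 1:1."""
        ann = annotation_frame(filter_redundancy(noise_free_copies.annotations))
        sample = "gastrula_r1"
        table = noise_free_bundle.alignments[sample]
        kept = filter_alignments(table)
        assert len(kept) == len(table)  # simulator emits filter-clean reads
        counts = assign_reads_to_te(kept, ann)
        # every TE read sits fully inside its source copy, so totals match
        background = (table["contig_id"] == "contig_background").sum()
        assert counts.sum() == len(table) - background


class TestSamIO:
    def test_sam_round_trip_matches_table(self, tmp_path, noise_free_bundle, noise_free_copies):
        sample = "zygote_r1"
        table = noise_free_bundle.alignments[sample].head(50)
        lengths = {name: len(seq) for name, seq in noise_free_copies.contigs.items()}
        path = tmp_path / "reads.sam"
        write_sam(table, lengths, path)
        back = read_sam(path)
        pd.testing.assert_frame_equal(
            back, alignment_frame(table).astype(back.dtypes.to_dict())
        )
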