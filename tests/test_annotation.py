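"""RepeatMasker parsing, TE taxonomy and redundancy filtering."""

from __future__ import annotations

import io
import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tescope.annotation import (
    RepeatMaskerParseError,
    TEAnnotation,
    annotation_frame,
    classify_te,
    filter_redundancy,
    parse_rm_out,
    write_bed,
    write_rm_out,
)

from conftest import random_annotation

HEADER = (
    "   SW  perc perc perc  query      position in query           matching       repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat         class/family\n"
    "\n"
)

EXAMPLE_ROW = "463 1.3 0.6 1.7 contig_1 101 600 (400) + DR0001 LTR/ERV1 1 500 (0) 1\n"


class TestParse:
    def test_example_row_converts_coordinates(self):
        (ann,) = parse_rm_out(HEADER + EXAMPLE_ROW)
        assert ann.contig_id == "contig_1"
        assert (ann.start, ann.end) == (100, 600)  # 1-based inclusive -> 0-based half-open
        assert ann.sw_score == 463
        assert ann.repeat_class_family == "LTR/ERV1"
        assert ann.strand == "+"
        assert (ann.repeat_start, ann.repeat_end, ann.repeat_left) == (1, 500, 0)
        assert ann.rm_id == 1 and not ann.overlap_flag
        assert ann.match_length == 500

    def test_c_strand_reverses_repeat_columns_and_star_sets_flag(self):
        row = "310 10.0 0.0 0.0 ctg 51 150 (20) C rep2 LINE/L2 (5) 300 201 7 *\n"
        (ann,) = parse_rm_out(row)
        assert ann.strand == "-"
        assert (ann.repeat_left, ann.repeat_end, ann.repeat_start) == (-5, 300, 201)
        assert ann.overlap_flag and ann.rm_id == 7

    def test_header_only_gives_empty_collection(self):
        assert parse_rm_out(HEADER) == []

    @pytest.mark.parametrize(
        "row, line_no",
        [
            ("abc 1.3 0.6 1.7 contig_1 101 600 (400) + R LTR/ERV1 1 500 (0) 1", 4),
            ("463 1.3 0.6 1.7 contig_1 101 600 (400) + R", 4),
            ("463 1.3 0.6 1.7 contig_1 600 101 (400) + R LTR/ERV1 1 500 (0) 1", 4),
        ],
        ids=["non-numeric-score-column", "too-few-fields", "inverted-interval"],
    )
    def test_malformed_rows_raise_with_line_number(self, row, line_no):
        with pytest.raises(RepeatMaskerParseError, match=f"line {line_no}"):
            parse_rm_out(HEADER + row)

    def test_accepts_stream_and_path(self, tmp_path):
        path = tmp_path / "hits.out"
        path.write_text(HEADER + EXAMPLE_ROW)
        assert parse_rm_out(path) == parse_rm_out(io.StringIO(HEADER + EXAMPLE_ROW))


class TestClassify:
    @pytest.mark.parametrize(
        "label, te_class, superfamily",
        [
            ("LTR/Gypsy", "LTR", "Gypsy"),
            ("LTR/Gypsy?", "LTR", "Gypsy"),
            ("ltr/pao", "LTR", "Pao"),
            ("LTR/ERV1", "LTR", "ERV1"),
            ("LTR/ERVK", "LTR", "LTR_other"),
            ("LTR", "LTR", "LTR_other"),
            ("Unknown", "Unclear", None),
            ("Unspecified", "Unclear", None),
            ("Retroposon", "Unclear", None),
            ("DNA/hAT-Charlie", "DNA", None),
            ("DNA?", "DNA", None),
            ("RC/Helitron", "DNA", None),
            ("LINE/L2", "LINE", None),
            ("SINE/tRNA-V", "SINE", None),
            ("Simple_repeat", "NotTE", None),
            ("Low_complexity", "NotTE", None),
            ("Satellite/centr", "NotTE", None),
            ("rRNA", "NotTE", None),
            ("ARTEFACT", "NotTE", None),
        ],
    )
    def test_label_taxonomy(self, label, te_class, superfamily):
        cls = classify_te(label)
        assert (cls.te_class, cls.ltr_superfamily) == (te_class, superfamily)

    @given(st.text(max_size=30))
    @settings(max_examples=200, derandomize=True)
    def test_total_and_deterministic(self, label):
        first = classify_te(label)
        assert classify_te(label) == first
        assert first.te_class in ("DNA", "LINE", "SINE", "LTR", "Unclear", "NotTE")
        assert (first.te_class == "LTR") == (first.ltr_superfamily is not None)


def _brute_force_filter(annotations, min_length=80):
    """Exhaustive oracle: transitive overlap clusters + direct keep rule."""
    te = [
        (ann, i)
        for i, ann in enumerate(annotations)
        if classify_te(ann.repeat_class_family).is_te
    ]
    n = len(te)
    adjacent = [[False] * n for _ in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        a, b = te[i][0], te[j][0]
        if a.contig_id == b.contig_id and a.start < b.end and b.start < a.end:
            adjacent[i][j] = adjacent[j][i] = True
    # transitive closure by repeated sweeps
    cluster = list(range(n))
    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(range(n), 2):
            if adjacent[i][j] and cluster[i] != cluster[j]:
                low = min(cluster[i], cluster[j])
                cluster[i] = cluster[j] = low
                changed = True
                for k in range(n):
                    if cluster[k] in (cluster[i], cluster[j]):
                        cluster[k] = low
    kept = []
    for label in sorted(set(cluster)):
        members = [te[i] for i in range(n) if cluster[i] == label]
        best = min(
            members,
            key=lambda pair: (-pair[0].sw_score, -pair[0].match_length, pair[0].start, pair[1]),
        )[0]
        if best.match_length > min_length:
            kept.append(best)
    kept.sort(key=lambda ann: (ann.contig_id, ann.start))
    return kept


class TestFilterRedundancy:
    def test_higher_score_survives_overlap(self):
        a = _ann("c1", 100, 300, score=500)
        b = _ann("c1", 200, 400, score=300)
        assert filter_redundancy([a, b], min_length=80) == [a]

    def test_exact_80bp_match_is_removed(self):
        ann = _ann("c1", 0, 80, score=999)
        assert filter_redundancy([ann], min_length=80) == []
        assert filter_redundancy([_ann("c1", 0, 81, score=999)], min_length=80) != []

    def test_empty_input(self):
        assert filter_redundancy([]) == []

    def test_not_te_entries_dropped_before_clustering(self):
        te = _ann("c1", 100, 300, score=100)
        simple = _ann("c1", 150, 350, score=900, class_family="Simple_repeat")
        # the higher-scoring simple repeat must not displace the TE
        assert filter_redundancy([te, simple]) == [te]

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        for _ in range(200):
            n_contigs = int(rng.integers(1, 4))
            anns = []
            for c in range(n_contigs):
                for _ in range(int(rng.integers(0, 13))):
                    anns.append(random_annotation(rng, f"c{c}"))
            assert filter_redundancy(anns) == _brute_force_filter(anns)

    def test_output_invariants(self, rng):
        anns = [random_annotation(rng, f"c{int(rng.integers(0, 3))}") for _ in range(60)]
        out = filter_redundancy(anns)
        assert all(ann in anns for ann in out)  # subset of input
        assert all(ann.match_length > 80 for ann in out)
        by_contig: dict[str, list] = {}
        for ann in out:
            by_contig.setdefault(ann.contig_id, []).append(ann)
        for entries in by_contig.values():
            entries.sort(key=lambda a: a.start)
            for left, right in zip(entries, entries[1:]):
                assert left.end <= right.start  # no residual overlap


class TestRoundTrip:
    def test_out_dialect_round_trip(self, rng, tmp_path):
        anns = [random_annotation(rng, f"c{i % 5}") for i in range(40)]
        path = tmp_path / "filtered.out"
        write_rm_out(anns, path)
        assert parse_rm_out(path) == anns

    def test_bed_export_is_zero_based_half_open(self, tmp_path):
        ann = _ann("c1", 100, 300, score=42)
        path = tmp_path / "out.bed"
        write_bed([ann], path)
        assert path.read_text() == "c1\t100\t300\trep\t42\t+\n"

    def test_frame_has_classification_columns(self):
        df = annotation_frame([_ann("c1", 0, 200, score=10, class_family="LTR/Gypsy")])
        assert df.loc[0, "te_class"] == "LTR"
        assert df.loc[0, "ltr_superfamily"] == "Gypsy"


def _ann(contig, start, end, score, class_family="LTR/ERV1"):
    return TEAnnotation(
        contig_id=contig,
        start=start,
        end=end,
        strand="+",
        sw_score=score,
        pct_divergence=1.0,
        pct_deleted=0.0,
        pct_inserted=0.0,
        repeat_name="rep",
        repeat_class_family=class_family,
        repeat_start=1,
        repeat_end=end - start,
        repeat_left=0,
        rm_id=1,
    )
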