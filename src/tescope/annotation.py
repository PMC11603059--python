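"""RepeatMasker ``.out`` annotations: parsing, TE taxonomy, redundancy filtering.

RepeatMasker reports every repeat hit on an assembly as one whitespace-delimited
row (Smith–Waterman score, divergence, query interval, repeat name and
class/family, consensus interval).  For transcriptome assemblies the raw table
is highly redundant: overlapping hits of related models pile up on the same
contig.  This module parses the table, maps the free-text ``class/family``
labels onto the five working TE classes (DNA, LINE, SINE, LTR, Unclear — plus
NotTE for simple repeats and other non-TE annotation), and reduces redundancy
by keeping, per cluster of mutually overlapping hits, the single best-scoring
entry longer than a minimum match length.

Coordinates are 1-based inclusive in ``.out`` files (the RepeatMasker
convention) and 0-based half-open everywhere in memory.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd

__all__ = [
    "TEAnnotation",
    "TEClassification",
    "TE_CLASSES",
    "LTR_SUPERFAMILIES",
    "RepeatMaskerParseError",
    "parse_rm_out",
    "classify_te",
    "filter_redundancy",
    "annotation_frame",
    "write_rm_out",
    "write_table",
    "write_bed",
]

#: Working TE classes, in the plotting order used for read-share profiles.
TE_CLASSES = ("DNA", "LINE", "SINE", "LTR", "Unclear")

#: Recognised LTR superfamilies; anything else under ``LTR/`` is ``LTR_other``.
LTR_SUPERFAMILIES = ("Copia", "DIRS", "ERV1", "ERV2", "Gypsy", "Pao", "Ngaro", "LTR_other")

# RepeatMasker categories that are repeats but not transposable elements.
_NOT_TE_PREFIXES = frozenset(
    {
        "simple_repeat",
        "low_complexity",
        "satellite",
        "rrna",
        "trna",
        "snrna",
        "scrna",
        "srprna",
        "artefact",
    }
)

_LTR_TOKENS = {name.lower(): name for name in LTR_SUPERFAMILIES if name != "LTR_other"}


class RepeatMaskerParseError(ValueError):
    """Raised for malformed ``.out`` rows; carries the 1-based line number."""


@dataclass(frozen=True)
class TEClassification:
    """A repeat label resolved to (TE class, LTR superfamily).

    ``ltr_superfamily`` is ``None`` unless ``te_class == "LTR"``.
    """

    te_class: str
    ltr_superfamily: str | None = None

    def __post_init__(self) -> None:
        if (self.te_class == "LTR") != (self.ltr_superfamily is not None):
            raise ValueError("ltr_superfamily must be set exactly when te_class is LTR")

    @property
    def is_te(self) -> bool:
        return self.te_class != "NotTE"


@dataclass(frozen=True)
class TEAnnotation:
    """One RepeatMasker hit: a repeat-model match on an assembly contig.

    ``start``/``end`` are 0-based half-open contig coordinates.  Consensus
    coordinates keep the file's orientation convention; the "left" remainder
    columns, printed in parentheses by RepeatMasker, are stored as negative
    integers so they cannot be confused with real positions.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    sw_score: int
    pct_divergence: float
    pct_deleted: float
    pct_inserted: float
    repeat_name: str
    repeat_class_family: str
    repeat_start: int
    repeat_end: int
    repeat_left: int
    rm_id: int
    overlap_flag: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.sw_score < 0:
            raise ValueError("sw_score must be non-negative")
        if not 0.0 <= self.pct_divergence <= 100.0:
            raise ValueError("pct_divergence must lie in [0, 100]")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def match_length(self) -> int:
        """Length of the match on the contig, in bp."""
        return self.end - self.start

    @property
    def classification(self) -> TEClassification:
        return classify_te(self.repeat_class_family)


def classify_te(repeat_class_family: str) -> TEClassification:
    """Map a RepeatMasker ``class/family`` label to the working TE taxonomy.

    The prefix before ``/`` (case-insensitive, trailing ``?`` stripped) decides
    the class: DNA and RC (rolling-circle Helitrons) are DNA transposons; LINE,
    SINE and LTR map to themselves; simple repeats, low-complexity runs,
    satellites, structural RNAs and artefacts are NotTE; everything else —
    including ``Unknown`` — is Unclear.  For LTR elements the suffix resolves
    the superfamily (Copia, DIRS, ERV1, ERV2, Gypsy, Pao, Ngaro), defaulting to
    ``LTR_other``.  Total: every string classifies.
    """
    text = (repeat_class_family or "").strip()
    prefix, _, suffix = text.partition("/")
    key = prefix.strip().rstrip("?").lower()
    if key in _NOT_TE_PREFIXES:
        return TEClassification("NotTE")
    if key in ("dna", "rc"):
        return TEClassification("DNA")
    if key == "line":
        return TEClassification("LINE")
    if key == "sine":
        return TEClassification("SINE")
    if key == "ltr":
        token = suffix.strip().rstrip("?").lower()
        superfamily = _LTR_TOKENS.get(token) or _LTR_TOKENS.get(token.split("-")[0])
        return TEClassification("LTR", superfamily or "LTR_other")
    return TEClassification("Unclear")


def _parse_position(token: str) -> tuple[int, bool]:
    """Parse a coordinate token; ``(x)`` remainders come back negative."""
    if token.startswith("(") and token.endswith(")"):
        return -int(token[1:-1]), True
    return int(token), False


_HEADER_FIRST_TOKENS = {"sw", "score", "bp"}


def parse_rm_out(source: str | Path | TextIO) -> list[TEAnnotation]:
    """Parse a RepeatMasker ``.out`` table into :class:`TEAnnotation` records.

    Accepts a path, a raw string containing the table, or an open text stream.
    The standard three-line header is optional; blank lines are skipped.  File
    coordinates (1-based inclusive) are converted to 0-based half-open; a
    ``C``-strand row has its consensus columns read in reversed order; a
    trailing ``*`` sets ``overlap_flag``.

    Raises :class:`RepeatMaskerParseError` (naming the 1-based line number) for
    rows with fewer than 14 fields, non-numeric scores or coordinates, or an
    empty/negative query interval.
    """
    if isinstance(source, Path):
        stream: TextIO = source.open()
    elif isinstance(source, str):
        if "\n" not in source and Path(source).is_file():
            stream = open(source)
        else:
            stream = io.StringIO(source)
    else:
        stream = source

    annotations: list[TEAnnotation] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        if fields[0].lower() in _HEADER_FIRST_TOKENS and not fields[0].isdigit():
            continue  # header line
        if len(fields) < 14:
            raise RepeatMaskerParseError(
                f"line {lineno}: expected >= 14 whitespace-separated fields, got {len(fields)}"
            )
        try:
            annotations.append(_parse_row(fields, lineno))
        except RepeatMaskerParseError:
            raise
        except (ValueError, IndexError) as exc:
            raise RepeatMaskerParseError(f"line {lineno}: {exc}") from exc
    return annotations


def _parse_row(fields: Sequence[str], lineno: int) -> TEAnnotation:
    sw_score = int(fields[0])
    pct_div, pct_del, pct_ins = (float(f) for f in fields[1:4])
    contig_id = fields[4]
    q_begin = int(fields[5])
    q_end = int(fields[6])
    _parse_position(fields[7])  # query "(left)" — validated, not stored
    strand_token = fields[8]
    if strand_token in ("+",):
        strand = "+"
    elif strand_token in ("C", "-"):
        strand = "-"
    else:
        raise ValueError(f"unrecognised strand {strand_token!r}")
    repeat_name = fields[9]
    repeat_class_family = fields[10]
    if strand == "+":
        repeat_start, _ = _parse_position(fields[11])
        repeat_end, _ = _parse_position(fields[12])
        repeat_left, _ = _parse_position(fields[13])
    else:  # C strand prints (left) end begin
        repeat_left, _ = _parse_position(fields[11])
        repeat_end, _ = _parse_position(fields[12])
        repeat_start, _ = _parse_position(fields[13])

    overlap_flag = False
    rm_id = 0
    if len(fields) >= 15:
        tail = list(fields[14:])
        if tail and tail[-1] == "*":
            overlap_flag = True
            tail = tail[:-1]
        if tail:
            rm_id = int(tail[0])

    start = q_begin - 1
    end = q_end
    if end <= start:
        raise RepeatMaskerParseError(
            f"line {lineno}: query interval end ({q_end}) <= start ({q_begin})"
        )
    return TEAnnotation(
        contig_id=contig_id,
        start=start,
        end=end,
        strand=strand,
        sw_score=sw_score,
        pct_divergence=pct_div,
        pct_deleted=pct_del,
        pct_inserted=pct_ins,
        repeat_name=repeat_name,
        repeat_class_family=repeat_class_family,
        repeat_start=repeat_start,
        repeat_end=repeat_end,
        repeat_left=repeat_left,
        rm_id=rm_id,
        overlap_flag=overlap_flag,
    )


def filter_redundancy(
    annotations: Iterable[TEAnnotation],
    min_length: int = 80,
    *,
    drop_not_te: bool = True,
) -> list[TEAnnotation]:
    """Reduce overlapping RepeatMasker hits to one representative per locus.

    Three steps, in order: (1) drop entries not classified as TEs;
    (2) per contig, group entries whose intervals overlap by at least one base
    (transitive closure) and keep exactly one per group — the highest
    Smith–Waterman score, ties broken by longer match, then smaller start, then
    input order; (3) drop survivors whose match length is not strictly greater
    than ``min_length`` (default 80 bp).  Output is sorted by (contig, start)
    and is guaranteed overlap-free within each contig.
    """
    indexed = [
        (ann, idx)
        for idx, ann in enumerate(annotations)
        if not (drop_not_te and not classify_te(ann.repeat_class_family).is_te)
    ]

    by_contig: dict[str, list[tuple[TEAnnotation, int]]] = {}
    for ann, idx in indexed:
        by_contig.setdefault(ann.contig_id, []).append((ann, idx))

    survivors: list[TEAnnotation] = []
    for entries in by_contig.values():
        entries.sort(key=lambda pair: (pair[0].start, pair[0].end, pair[1]))
        cluster: list[tuple[TEAnnotation, int]] = []
        cluster_end = -1
        for ann, idx in entries:
            if cluster and ann.start < cluster_end:
                cluster.append((ann, idx))
                cluster_end = max(cluster_end, ann.end)
            else:
                if cluster:
                    survivors.append(_best_of_cluster(cluster))
                cluster = [(ann, idx)]
                cluster_end = ann.end
        if cluster:
            survivors.append(_best_of_cluster(cluster))

    survivors = [ann for ann in survivors if ann.match_length > min_length]
    survivors.sort(key=lambda ann: (ann.contig_id, ann.start))
    return survivors


def _best_of_cluster(cluster: list[tuple[TEAnnotation, int]]) -> TEAnnotation:
    return min(
        cluster,
        key=lambda pair: (-pair[0].sw_score, -pair[0].match_length, pair[0].start, pair[1]),
    )[0]


def annotation_frame(annotations: Iterable[TEAnnotation]) -> pd.DataFrame:
    """Tabulate annotations, adding ``te_class`` / ``ltr_superfamily`` columns."""
    rows = []
    for ann in annotations:
        cls = classify_te(ann.repeat_class_family)
        rows.append(
            {
                "contig_id": ann.contig_id,
                "start": ann.start,
                "end": ann.end,
                "strand": ann.strand,
                "sw_score": ann.sw_score,
                "pct_divergence": ann.pct_divergence,
                "pct_deleted": ann.pct_deleted,
                "pct_inserted": ann.pct_inserted,
                "repeat_name": ann.repeat_name,
                "repeat_class_family": ann.repeat_class_family,
                "repeat_start": ann.repeat_start,
                "repeat_end": ann.repeat_end,
                "repeat_left": ann.repeat_left,
                "rm_id": ann.rm_id,
                "overlap_flag": ann.overlap_flag,
                "te_class": cls.te_class,
                "ltr_superfamily": cls.ltr_superfamily or "NA",
            }
        )
    columns = [
        "contig_id",
        "start",
        "end",
        "strand",
        "sw_score",
        "pct_divergence",
        "pct_deleted",
        "pct_inserted",
        "repeat_name",
        "repeat_class_family",
        "repeat_start",
        "repeat_end",
        "repeat_left",
        "rm_id",
        "overlap_flag",
        "te_class",
        "ltr_superfamily",
    ]
    return pd.DataFrame(rows, columns=columns)


def _format_position(value: int) -> str:
    return f"({-value})" if value < 0 else str(value)


def write_rm_out(annotations: Iterable[TEAnnotation], path: str | Path | TextIO) -> None:
    """Write annotations back in the ``.out`` dialect accepted by :func:`parse_rm_out`.

    The query "(left)" remainder is not retained in memory and is written as
    ``(0)``; all retained fields round-trip exactly.
    """
    own = isinstance(path, (str, Path))
    stream = open(path, "w") if own else path
    try:
        for ann in annotations:
            if ann.strand == "+":
                rpt = (str(ann.repeat_start), str(ann.repeat_end), _format_position(ann.repeat_left))
                strand = "+"
            else:
                rpt = (_format_position(ann.repeat_left), str(ann.repeat_end), str(ann.repeat_start))
                strand = "C"
            cols = [
                str(ann.sw_score),
                f"{ann.pct_divergence:.1f}",
                f"{ann.pct_deleted:.1f}",
                f"{ann.pct_inserted:.1f}",
                ann.contig_id,
                str(ann.start + 1),
                str(ann.end),
                "(0)",
                strand,
                ann.repeat_name,
                ann.repeat_class_family,
                *rpt,
                str(ann.rm_id),
            ]
            if ann.overlap_flag:
                cols.append("*")
            stream.write(" ".join(cols) + "\n")
    finally:
        if own:
            stream.close()


def write_table(annotations: Iterable[TEAnnotation], path: str | Path) -> None:
    """Write the annotated table as TSV with an explicit column header."""
    annotation_frame(annotations).to_csv(path, sep="\t", index=False)


def write_bed(annotations: Iterable[TEAnnotation], path: str | Path) -> None:
    """Export annotations as BED6 (0-based half-open; name=repeat, score=SW)."""
    own = isinstance(path, (str, Path))
    stream = open(path, "w") if own else path
    try:
        for ann in annotations:
            stream.write(
                f"{ann.contig_id}\t{ann.start}\t{ann.end}\t{ann.repeat_name}\t{ann.sw_score}\t{ann.strand}\n"
            )
    finally:
        if own:
            stream.close()
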