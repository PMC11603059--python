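"""Assign RNA-seq reads to TE loci and build per-sample read-share profiles.

The quantification follows a mapping-based definition of TE transcriptional
activity: reads are first screened with the same cutoffs the read mapper used
(aligned fraction of the read >= 0.80 and identity over the aligned part
>= 0.80), each read is then attributed to at most one redundancy-filtered TE
entry by interval overlap, and per-class totals are expressed as percentages of
all reads mapped to the assembly in that sample, which makes profiles
comparable across developmental stages and treatment arms.

Alignments travel either as :class:`ReadAlignment` records, as a 7-column
table (``read_id  contig_id  aln_start  aln_end  read_length  aligned_bases
matches``), or as SAM via :mod:`pysam`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import LTR_SUPERFAMILIES, TE_CLASSES, TEAnnotation, annotation_frame

__all__ = [
    "ReadAlignment",
    "TETypeProfile",
    "ALIGNMENT_COLUMNS",
    "alignment_frame",
    "read_alignment_tsv",
    "write_alignment_tsv",
    "read_sam",
    "filter_alignments",
    "assign_reads_to_te",
    "aggregate_profile",
    "profile_frame",
]

ALIGNMENT_COLUMNS = (
    "read_id",
    "contig_id",
    "aln_start",
    "aln_end",
    "read_length",
    "aligned_bases",
    "matches",
)


@dataclass(frozen=True)
class ReadAlignment:
    """One read-to-contig alignment (0-based half-open contig interval)."""

    read_id: str
    contig_id: str
    aln_start: int
    aln_end: int
    read_length: int
    aligned_bases: int
    matches: int

    def __post_init__(self) -> None:
        if not 0 < self.aligned_bases <= self.read_length:
            raise ValueError("aligned_bases must lie in (0, read_length]")
        if self.matches > self.aligned_bases or self.matches < 0:
            raise ValueError("matches must lie in [0, aligned_bases]")
        if self.aln_end - self.aln_start < 1:
            raise ValueError("alignment interval must span >= 1 base")


def alignment_frame(alignments: Iterable[ReadAlignment] | pd.DataFrame) -> pd.DataFrame:
    """Coerce alignments to the canonical 7-column table."""
    if isinstance(alignments, pd.DataFrame):
        missing = set(ALIGNMENT_COLUMNS) - set(alignments.columns)
        if missing:
            raise ValueError(f"alignment table lacks columns: {sorted(missing)}")
        return alignments.loc[:, list(ALIGNMENT_COLUMNS)].reset_index(drop=True)
    return pd.DataFrame(
        [
            (a.read_id, a.contig_id, a.aln_start, a.aln_end, a.read_length, a.aligned_bases, a.matches)
            for a in alignments
        ],
        columns=list(ALIGNMENT_COLUMNS),
    )


def read_alignment_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return alignment_frame(df)


def write_alignment_tsv(alignments: Iterable[ReadAlignment] | pd.DataFrame, path: str | Path) -> None:
    alignment_frame(alignments).to_csv(path, sep="\t", index=False)


def read_sam(path: str | Path) -> pd.DataFrame:
    """Load mapped records from a SAM file into the canonical alignment table.

    ``aligned_bases`` is the aligned query length (CIGAR M/=/X); ``matches``
    subtracts the mismatch component of the ``NM`` tag (NM minus inserted and
    deleted bases).  Unmapped and secondary records are skipped.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as handle:
        for rec in handle:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            aligned = rec.query_alignment_length
            read_length = rec.query_length or rec.infer_read_length() or aligned
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            indel = sum(length for op, length in (rec.cigartuples or []) if op in (1, 2))
            mismatches = max(int(nm) - indel, 0)
            matches = max(aligned - mismatches, 0)
            rows.append(
                (
                    rec.query_name,
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    read_length,
                    aligned,
                    matches,
                )
            )
    return pd.DataFrame(rows, columns=list(ALIGNMENT_COLUMNS))


def filter_alignments(
    alignments: Iterable[ReadAlignment] | pd.DataFrame,
    length_fraction: float = 0.80,
    similarity_fraction: float = 0.80,
) -> pd.DataFrame:
    """Apply the mapper-style length/identity cutoffs and de-multimap reads.

    Keeps alignments with ``aligned_bases / read_length >= length_fraction``
    and ``matches / aligned_bases >= similarity_fraction`` (both inclusive),
    then reduces each multi-mapped read to its single best surviving record
    (most matched bases; ties go to the first record in input order).
    """
    for name, value in (("length_fraction", length_fraction), ("similarity_fraction", similarity_fraction)):
        if not 0.0 < value <= 1.0:
            raise ValueError(f"{name} must lie in (0, 1], got {value}")
    df = alignment_frame(alignments)
    keep = (df["aligned_bases"] / df["read_length"] >= length_fraction) & (
        df["matches"] / df["aligned_bases"] >= similarity_fraction
    )
    df = df.loc[keep]
    if df.empty:
        return df.reset_index(drop=True)
    # stable sort on -matches keeps input order among ties; first per read wins
    df = df.sort_values("matches", ascending=False, kind="stable")
    df = df.loc[~df["read_id"].duplicated(keep="first")]
    return df.sort_index().reset_index(drop=True)


def _contig_intervals(
    annotations: Sequence[TEAnnotation] | pd.DataFrame,
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per contig: (starts, ends, entry indices) sorted by start, overlap-checked."""
    if isinstance(annotations, pd.DataFrame):
        ann = annotations
    else:
        ann = annotation_frame(annotations)
    out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for contig, sub in ann.groupby("contig_id", sort=False):
        order = np.argsort(sub["start"].to_numpy(), kind="stable")
        starts = sub["start"].to_numpy()[order]
        ends = sub["end"].to_numpy()[order]
        idx = sub.index.to_numpy()[order]
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(
                f"annotations on contig {contig!r} overlap; run filter_redundancy first"
            )
        out[contig] = (starts, ends, idx)
    return out


def assign_reads_to_te(
    alignments: Iterable[ReadAlignment] | pd.DataFrame,
    annotations: Sequence[TEAnnotation] | pd.DataFrame,
    min_overlap_fraction: float = 0.5,
) -> pd.Series:
    """Count reads per TE entry by interval overlap.

    A read counts toward the entry covering at least ``min_overlap_fraction``
    of its aligned interval; because redundancy-filtered entries never overlap,
    at most one entry can reach a fraction > 0.5, and exact ties (possible only
    at 0.5) go to the leftmost entry.  Reads reaching no entry stay unassigned
    (they still contribute to a sample's mapped-read total downstream).

    Returns a Series of read counts indexed like the annotation table (list
    position when a list of :class:`TEAnnotation` is given); unassigned reads
    are not represented.
    """
    if not 0.0 < min_overlap_fraction <= 1.0:
        raise ValueError("min_overlap_fraction must lie in (0, 1]")
    df = alignment_frame(alignments)
    if isinstance(annotations, pd.DataFrame):
        ann = annotations
    else:
        ann = annotation_frame(annotations)
    intervals = _contig_intervals(ann)

    counts = np.zeros(len(ann), dtype=np.int64)
    index_pos = {label: pos for pos, label in enumerate(ann.index)}
    for contig, sub in df.groupby("contig_id", sort=False):
        if contig not in intervals:
            continue
        starts, ends, labels = intervals[contig]
        s = sub["aln_start"].to_numpy()
        e = sub["aln_end"].to_numpy()
        lo = np.searchsorted(ends, s, side="right")
        hi = np.searchsorted(starts, e, side="left")
        span = (e - s).astype(float)
        for i in range(len(sub)):
            best_label = None
            best_frac = -1.0
            for j in range(lo[i], hi[i]):
                overlap = min(e[i], ends[j]) - max(s[i], starts[j])
                frac = overlap / span[i]
                if frac > best_frac + 1e-12:
                    best_frac = frac
                    best_label = labels[j]
            if best_label is not None and best_frac >= min_overlap_fraction:
                counts[index_pos[best_label]] += 1
    return pd.Series(counts, index=ann.index, name="reads")


@dataclass
class TETypeProfile:
    """Per-sample TE read counts and percentages of total mapped reads."""

    sample_id: str
    total_mapped_reads: int
    counts: Mapping[str, int]
    ltr_counts: Mapping[str, int]

    @property
    def percentages(self) -> dict[str, float]:
        return {k: 100.0 * v / self.total_mapped_reads for k, v in self.counts.items()}

    @property
    def ltr_percentages(self) -> dict[str, float]:
        return {k: 100.0 * v / self.total_mapped_reads for k, v in self.ltr_counts.items()}


def aggregate_profile(
    entry_counts: pd.Series,
    annotations: Sequence[TEAnnotation] | pd.DataFrame,
    total_mapped_reads: int,
    sample_id: str = "sample",
) -> TETypeProfile:
    """Sum per-entry read counts into TE-class and LTR-superfamily totals.

    Percentages are taken over ``total_mapped_reads`` — all reads mapped to
    the assembly in the sample — not over TE-assigned reads only.
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    if isinstance(annotations, pd.DataFrame):
        ann = annotations
    else:
        ann = annotation_frame(annotations)
    assigned = int(entry_counts.sum())
    if assigned > total_mapped_reads:
        raise ValueError(
            f"assigned reads ({assigned}) exceed total_mapped_reads ({total_mapped_reads})"
        )
    counts = {cls: 0 for cls in TE_CLASSES}
    ltr_counts = {sf: 0 for sf in LTR_SUPERFAMILIES}
    te_class = ann["te_class"]
    superfamily = ann["ltr_superfamily"]
    for label, n in entry_counts.items():
        if n == 0:
            continue
        cls = te_class.loc[label]
        if cls == "NotTE":
            raise ValueError("NotTE entries must not carry read counts")
        counts[cls] += int(n)
        if cls == "LTR":
            ltr_counts[superfamily.loc[label]] += int(n)
    return TETypeProfile(
        sample_id=sample_id,
        total_mapped_reads=int(total_mapped_reads),
        counts=counts,
        ltr_counts=ltr_counts,
    )


def profile_frame(profiles: Iterable[TETypeProfile]) -> pd.DataFrame:
    """Tidy table of profiles: one row per (sample, level, group)."""
    rows = []
    for prof in profiles:
        for cls in TE_CLASSES:
            rows.append(
                {
                    "sample": prof.sample_id,
                    "level": "te_class",
                    "group": cls,
                    "count": prof.counts.get(cls, 0),
                    "percent": 100.0 * prof.counts.get(cls, 0) / prof.total_mapped_reads,
                    "total_mapped_reads": prof.total_mapped_reads,
                }
            )
        for sf in LTR_SUPERFAMILIES:
            rows.append(
                {
                    "sample": prof.sample_id,
                    "level": "ltr_superfamily",
                    "group": sf,
                    "count": prof.ltr_counts.get(sf, 0),
                    "percent": 100.0 * prof.ltr_counts.get(sf, 0) / prof.total_mapped_reads,
                    "total_mapped_reads": prof.total_mapped_reads,
                }
            )
    return pd.DataFrame(rows)
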