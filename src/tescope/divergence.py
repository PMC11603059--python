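"""Kimura two-parameter divergence of TE copies and repeat landscapes.

A TE copy's divergence from its family consensus is a proxy for the age of the
insertion: young, potentially active copies sit near 0, ancient fossils far
right.  Divergence is corrected for multiple hits with Kimura's two-parameter
model, which distinguishes transitions (A<->G, C<->T; proportion ``p`` of
aligned sites) from transversions (proportion ``q``)::

    K = -1/2 * ln((1 - 2p - q) * sqrt(1 - 2q))

A "repeat landscape" bins copies by 100*K (percent divergence, default 1%
bins over [0, 50)) and sums a per-copy weight — aligned bp by RepeatMasker
convention, or assigned read counts when the landscape should describe the
*expressed* TE fraction.  Copies past the model's domain (saturated) are
counted and excluded; copies past the last bin land in an explicit overflow
bucket, so total weight is always conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log, sqrt
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubstitutionCounts",
    "KimuraRecord",
    "LandscapeBins",
    "SaturationError",
    "count_substitutions",
    "kimura_k2p",
    "kimura_from_counts",
    "build_landscape",
    "read_alignment_pairs",
    "write_alignment_pairs",
]


class SaturationError(ValueError):
    """K2P domain violation: divergence too high for the correction to exist."""


@dataclass(frozen=True)
class SubstitutionCounts:
    """Substitution tally over the ungapped, unambiguous columns of a pair."""

    aligned_sites: int
    transitions: int
    transversions: int

    def __post_init__(self) -> None:
        if self.aligned_sites <= 0:
            raise ValueError("aligned_sites must be positive")
        if self.transitions + self.transversions > self.aligned_sites:
            raise ValueError("substitutions cannot exceed aligned sites")

    @property
    def p(self) -> float:
        """Transition proportion."""
        return self.transitions / self.aligned_sites

    @property
    def q(self) -> float:
        """Transversion proportion."""
        return self.transversions / self.aligned_sites


_VALID = frozenset(b"ACGT")
_TRANSITION_PAIRS = frozenset({(65, 71), (71, 65), (67, 84), (84, 67)})  # A<->G, C<->T


def count_substitutions(copy_sequence: str, consensus_sequence: str) -> SubstitutionCounts:
    """Count transitions/transversions between two aligned, equal-length strings.

    Columns with a gap (``-``), an ``N``, or any non-ACGT symbol on either side
    are excluded from ``aligned_sites``.  Raises on length mismatch or if no
    unambiguous column remains.
    """
    if len(copy_sequence) != len(consensus_sequence):
        raise ValueError(
            f"aligned sequences differ in length ({len(copy_sequence)} vs {len(consensus_sequence)})"
        )
    a = np.frombuffer(copy_sequence.upper().encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(consensus_sequence.upper().encode("ascii"), dtype=np.uint8)
    valid_codes = np.array(sorted(_VALID), dtype=np.uint8)
    ok = np.isin(a, valid_codes) & np.isin(b, valid_codes)
    aligned = int(ok.sum())
    if aligned == 0:
        raise ValueError("no unambiguous aligned columns")
    diff = ok & (a != b)
    # transition iff both bases are purines or both pyrimidines
    purine = lambda x: (x == 65) | (x == 71)  # noqa: E731  A or G
    transitions = int((diff & (purine(a) == purine(b))).sum())
    transversions = int(diff.sum()) - transitions
    return SubstitutionCounts(aligned, transitions, transversions)


def kimura_k2p(p: float, q: float) -> float:
    """Kimura two-parameter distance for transition/transversion proportions.

    Requires ``1 - 2p - q > 0`` and ``1 - 2q > 0``; otherwise the observed
    divergence is saturated and :class:`SaturationError` is raised.
    """
    if p < 0 or q < 0:
        raise ValueError("p and q must be non-negative")
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"K2P undefined for p={p:.4g}, q={q:.4g} (saturated)")
    return -0.5 * log(w1 * sqrt(w2))


def kimura_from_counts(counts: SubstitutionCounts) -> float:
    """K2P distance straight from a substitution tally."""
    return kimura_k2p(counts.p, counts.q)


@dataclass(frozen=True)
class KimuraRecord:
    """One TE copy's divergence, with the weight it contributes to a landscape."""

    entry_id: str
    K: float
    weight: float
    te_class: str = "LTR"
    ltr_superfamily: str | None = None

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("K must be non-negative")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")


@dataclass
class LandscapeBins:
    """Binned divergence landscape: ``bins`` has one row per (bin, group)."""

    bin_width: float
    bins: pd.DataFrame  # columns: bin_lo, bin_hi, group, weight, percent
    overflow: pd.DataFrame  # columns: group, weight
    total_weight: float
    normalization: str = "raw"

    def pivot(self) -> pd.DataFrame:
        """Groups as columns, divergence bins as rows — ready for stacked plots."""
        return self.bins.pivot_table(
            index=["bin_lo", "bin_hi"], columns="group", values="weight", fill_value=0.0
        )


def build_landscape(
    records: Iterable[KimuraRecord],
    bin_width: float = 1.0,
    group_by: str = "ltr_superfamily",
    normalization: str = "raw",
    max_divergence: float = 50.0,
) -> LandscapeBins:
    """Bin per-copy K2P divergences (as percent, 100*K) into a landscape table.

    ``group_by`` is ``"te_class"`` or ``"ltr_superfamily"``; ``normalization``
    is ``"raw"`` (summed weights) or ``"percent_of_total"``.  Records at or
    past ``max_divergence`` percent go to the per-group overflow table rather
    than being dropped, so bin totals plus overflow conserve total weight.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if group_by not in ("te_class", "ltr_superfamily"):
        raise ValueError("group_by must be 'te_class' or 'ltr_superfamily'")
    if normalization not in ("raw", "percent_of_total"):
        raise ValueError("normalization must be 'raw' or 'percent_of_total'")
    records = list(records)
    if not records:
        raise ValueError("no records to bin (all saturated or empty input)")

    edges = np.arange(0.0, max_divergence + bin_width / 2, bin_width)
    n_bins = len(edges) - 1
    groups = sorted(
        {
            (rec.ltr_superfamily or "NA") if group_by == "ltr_superfamily" else rec.te_class
            for rec in records
        }
    )
    weight = {g: np.zeros(n_bins) for g in groups}
    overflow = {g: 0.0 for g in groups}
    for rec in records:
        g = (rec.ltr_superfamily or "NA") if group_by == "ltr_superfamily" else rec.te_class
        div = 100.0 * rec.K
        if div >= max_divergence:
            overflow[g] += rec.weight
            continue
        weight[g][int(div // bin_width)] += rec.weight

    total = float(sum(rec.weight for rec in records))
    rows = []
    for g in groups:
        for i in range(n_bins):
            w = weight[g][i]
            rows.append(
                {
                    "bin_lo": edges[i],
                    "bin_hi": edges[i + 1],
                    "group": g,
                    "weight": w if normalization == "raw" else (100.0 * w / total if total else 0.0),
                    "percent": 100.0 * w / total if total else 0.0,
                }
            )
    bins = pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "group", "weight", "percent"])
    over = pd.DataFrame(
        [{"group": g, "weight": overflow[g]} for g in groups], columns=["group", "weight"]
    )
    return LandscapeBins(
        bin_width=bin_width,
        bins=bins,
        overflow=over,
        total_weight=total,
        normalization=normalization,
    )


def read_alignment_pairs(path: str | Path) -> list[tuple[str, str, str]]:
    """Read copy/consensus pairs from an aligned multi-FASTA.

    Records come in consecutive pairs ``<entry_id>|copy`` then
    ``<entry_id>|consensus`` (equal-length, gapped alignment strings).
    Returns ``(entry_id, copy_seq, consensus_seq)`` triples.
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2:
        raise ValueError("aligned-pair FASTA must contain an even number of records")
    pairs = []
    for copy_rec, cons_rec in zip(records[0::2], records[1::2]):
        copy_id, _, copy_role = copy_rec.id.rpartition("|")
        cons_id, _, cons_role = cons_rec.id.rpartition("|")
        if copy_role != "copy" or cons_role != "consensus" or copy_id != cons_id:
            raise ValueError(
                f"malformed pair: {copy_rec.id!r} / {cons_rec.id!r} "
                "(expected '<id>|copy' followed by '<id>|consensus')"
            )
        pairs.append((copy_id, str(copy_rec.seq), str(cons_rec.seq)))
    return pairs


def write_alignment_pairs(pairs: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    """Write ``(entry_id, copy_seq, consensus_seq)`` triples as aligned FASTA."""
    with open(path, "w") as handle:
        for entry_id, copy_seq, cons_seq in pairs:
            handle.write(f">{entry_id}|copy\n{copy_seq}\n>{entry_id}|consensus\n{cons_seq}\n")
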