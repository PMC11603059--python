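"""TPM expression with cross-sample scaling anchored on single-copy orthologues.

Raw TPM makes columns comparable only under the assumption that total
transcriptional output is constant, which fails badly across early embryonic
stages (maternal load, ZGA).  The normalisation used here instead anchors each
sample on the cumulative TPM of a set of single-copy orthologous genes assumed
to be uniformly expressed: each sample j gets a multiplicative factor

    s_j = R / C_j,   C_j = sum of orthologue TPM in sample j,

with R the across-sample mean of the C_j (configurable to a named reference
sample).  After scaling, the orthologue set has identical cumulative
expression in every sample, while within-sample gene ratios are untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneSet",
    "compute_tpm",
    "ortholog_scaling",
    "family_mean_expression",
    "read_gene_sets",
    "write_gene_sets",
    "read_counts_table",
]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers (e.g. NuRD, KRAB_like_family)."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} contains duplicate members")

    def present_in(self, genes: Iterable[str]) -> tuple[str, ...]:
        """Members found in ``genes``; warns (never silently drops) on misses."""
        available = set(genes)
        present = tuple(m for m in self.members if m in available)
        missing = [m for m in self.members if m not in available]
        if missing:
            warnings.warn(
                f"gene set {self.name!r}: {len(missing)} member(s) absent from the "
                f"expression matrix: {missing[:10]}",
                stacklevel=3,
            )
        return present


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from a gene x sample count matrix.

    ``rate_g = count_g / length_g``; ``tpm_g = 1e6 * rate_g / sum(rates)`` per
    sample, so every column sums to one million.  Effective length is the
    transcript length (no fragment-length correction).
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:10]
        raise ValueError(f"missing transcript lengths for genes: {missing}")
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    if (counts < 0).to_numpy().any():
        raise ValueError("counts must be non-negative")
    col_sums = counts.sum(axis=0)
    dead = list(col_sums.index[col_sums == 0])
    if dead:
        raise ValueError(f"sample(s) with all-zero counts: {dead}")
    rates = counts.div(lengths, axis=0)
    return rates.div(rates.sum(axis=0), axis=1) * 1e6


def ortholog_scaling(
    tpm: pd.DataFrame,
    orthologues: GeneSet | Iterable[str],
    reference: str = "mean",
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-sample scaling factors from cumulative orthologue expression.

    ``reference="mean"`` anchors on the across-sample arithmetic mean of the
    cumulative orthologue TPM; naming a sample anchors on that sample instead.
    Returns ``(scaling_factors, scaled_tpm)``.
    """
    if isinstance(orthologues, GeneSet):
        members = orthologues.present_in(tpm.index)
        set_name = orthologues.name
    else:
        members = tuple(m for m in orthologues if m in tpm.index)
        set_name = "orthologues"
    if not members:
        raise ValueError(f"no members of {set_name!r} are present in the matrix")
    cumulative = tpm.loc[list(members)].sum(axis=0)
    zero = list(cumulative.index[cumulative == 0])
    if zero:
        raise ValueError(f"cumulative orthologue TPM is zero in sample(s): {zero}")
    if reference == "mean":
        ref_value = float(cumulative.mean())
    else:
        if reference not in cumulative.index:
            raise ValueError(f"reference sample {reference!r} not in matrix")
        ref_value = float(cumulative.loc[reference])
    factors = ref_value / cumulative
    factors.name = "scaling_factor"
    return factors, tpm.mul(factors, axis=1)


def family_mean_expression(
    scaled_tpm: pd.DataFrame, family: GeneSet | Iterable[str]
) -> pd.Series:
    """Unweighted per-sample mean of a gene family's scaled TPM values.

    Multi-gene families (KRAB-like ZNFs, FiNZ ZNFs) are reported as the plain
    average over member genes, one value per sample.
    """
    if isinstance(family, GeneSet):
        members = family.present_in(scaled_tpm.index)
        name = family.name
    else:
        members = tuple(m for m in family if m in scaled_tpm.index)
        name = "family"
    if not members:
        raise ValueError(f"gene family {name!r} has no members in the matrix")
    result = scaled_tpm.loc[list(members)].mean(axis=0)
    result.name = name
    return result


def read_gene_sets(path: str | Path) -> dict[str, GeneSet]:
    """Read gene sets from a text file: ``>set_name`` headers, one gene per line."""
    sets: dict[str, GeneSet] = {}
    name: str | None = None
    members: list[str] = []
    with open(path) as handle:
        for raw in handle:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                if name is not None:
                    sets[name] = GeneSet(name, tuple(members))
                name = line[1:].strip()
                members = []
            else:
                if name is None:
                    raise ValueError("gene identifier before any '>set_name' header")
                members.append(line)
    if name is not None:
        sets[name] = GeneSet(name, tuple(members))
    return sets


def write_gene_sets(sets: Mapping[str, GeneSet] | Sequence[GeneSet], path: str | Path) -> None:
    items = sets.values() if isinstance(sets, Mapping) else sets
    with open(path, "w") as handle:
        for gene_set in items:
            handle.write(f">{gene_set.name}\n")
            for member in gene_set.members:
                handle.write(member + "\n")


def read_counts_table(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a gene count TSV (columns: gene, length, then one per sample)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "length"):
        if col not in df.columns:
            raise ValueError(f"counts table lacks required column {col!r}")
    df = df.set_index("gene")
    lengths = df.pop("length")
    return df, lengths
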