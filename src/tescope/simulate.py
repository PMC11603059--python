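"""Seed-reproducible synthetic inputs with the structure the pipeline assumes.

Real inputs for this kind of analysis are SRA runs mapped to a de novo
transcriptome — heavy, proprietary-tool-shaped, and useless for unit testing.
This module fabricates the whole input bundle instead, with known ground
truth at every level:

* **TE copies** diverged from a random consensus by i.i.d. per-site
  substitutions at a chosen transition rate ``p`` and transversion rate ``q``
  (expected K2P distance known in closed form), embedded in contigs with
  non-repetitive flanks and described by a RepeatMasker-style ``.out`` table.
* **Read alignments** per sample: TE-derived reads drawn from stage-specific
  TE-class activity shares (a maternal 1-cell peak, a trough at zygotic genome
  activation, a post-ZGA rebound with ERV1-dominated LTR activity), the rest
  placed on a non-repetitive background contig.  A treatment contrast
  multiplies the LTR share in the drug arm, emulating DNA-demethylation-driven
  derepression, with 3 replicates per arm.
* **Gene counts** for silencing-machinery gene sets whose expression tracks a
  chosen TE-class trajectory with a programmed Pearson correlation, a
  constant-expression single-copy-orthologue set, and uncorrelated background
  genes.  A per-sample depth multiplier scales every count.

With ``dispersion = 0`` the generator is noise-free: read counts are exact
largest-remainder apportionments of the configured shares and gene counts are
exact expected values, so downstream recovery tests can assert equality rather
than closeness.  All outputs are a pure function of the configuration
(including its seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import TEAnnotation, classify_te, write_rm_out
from .divergence import kimura_k2p, write_alignment_pairs
from .normalization import GeneSet, write_gene_sets
from .quantify import ALIGNMENT_COLUMNS

__all__ = [
    "FamilySpec",
    "TreatmentSpec",
    "GeneModelSpec",
    "SimulationConfig",
    "SimulatedCopy",
    "TECopySet",
    "ExpressionBundle",
    "GroundTruth",
    "simulate_te_copies",
    "simulate_expression",
    "write_copy_bundle",
    "write_expression_bundle",
    "write_sam",
    "DEFAULT_STAGES",
]

DEFAULT_STAGES = ("zygote", "blastula", "gastrula", "somitogenesis", "pharyngula", "larva")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = {65: 71, 71: 65, 67: 84, 84: 67}  # A<->G, C<->T
_TRANSVERSIONS = {65: (67, 84), 71: (67, 84), 67: (65, 71), 84: (65, 71)}


@dataclass(frozen=True)
class FamilySpec:
    """One simulated TE family: copy number, consensus length, substitution rates.

    ``transition_rate`` / ``transversion_rate`` are per-site probabilities that
    a copy site carries a transition / transversion relative to the consensus;
    the expected K2P distance of the family's copies is their closed form.
    """

    name: str
    class_family: str
    n_copies: int
    consensus_length: int
    transition_rate: float
    transversion_rate: float

    def __post_init__(self) -> None:
        if self.n_copies < 1 or self.consensus_length < 1:
            raise ValueError("n_copies and consensus_length must be positive")
        p, q = self.transition_rate, self.transversion_rate
        if p < 0 or q < 0:
            raise ValueError("substitution rates must be non-negative")
        if 2 * p + q >= 1 or 2 * q >= 1:
            raise ValueError("rates too high: expected divergence saturates the K2P model")

    @property
    def expected_K(self) -> float:
        return kimura_k2p(self.transition_rate, self.transversion_rate)


def _default_families() -> tuple[FamilySpec, ...]:
    return (
        FamilySpec("ERV1-sim", "LTR/ERV1", 8, 3000, 0.020, 0.010),
        FamilySpec("ERV2-sim", "LTR/ERV2", 5, 2500, 0.030, 0.015),
        FamilySpec("Gypsy-sim", "LTR/Gypsy", 6, 4000, 0.080, 0.040),
        FamilySpec("Copia-sim", "LTR/Copia", 4, 3000, 0.060, 0.030),
        FamilySpec("DIRS-sim", "LTR/DIRS", 4, 3500, 0.050, 0.025),
        FamilySpec("Pao-sim", "LTR/Pao", 4, 3000, 0.070, 0.035),
        FamilySpec("Ngaro-sim", "LTR/Ngaro", 3, 2500, 0.060, 0.030),
        FamilySpec("LTRX-sim", "LTR/Unknown", 3, 2000, 0.100, 0.050),
        FamilySpec("hAT-sim", "DNA/hAT-Charlie", 8, 2000, 0.100, 0.050),
        FamilySpec("Tc1-sim", "DNA/TcMar-Tc1", 6, 1600, 0.120, 0.060),
        FamilySpec("L2-sim", "LINE/L2", 8, 3000, 0.090, 0.045),
        FamilySpec("SINE-sim", "SINE/tRNA-V", 6, 300, 0.080, 0.040),
        FamilySpec("UnkRep-sim", "Unknown", 5, 1000, 0.100, 0.050),
    )


# Stage-specific fraction of all mapped reads attributed to each TE class:
# strong maternal signal at the 1-cell stage, a trough as maternal transcripts
# are cleared around ZGA (blastula), then a rebound through larva.
def _default_stage_class_shares() -> dict[str, dict[str, float]]:
    return {
        "zygote": {"DNA": 0.050, "LINE": 0.030, "SINE": 0.008, "LTR": 0.050, "Unclear": 0.012},
        "blastula": {"DNA": 0.015, "LINE": 0.008, "SINE": 0.003, "LTR": 0.012, "Unclear": 0.004},
        "gastrula": {"DNA": 0.035, "LINE": 0.022, "SINE": 0.006, "LTR": 0.048, "Unclear": 0.009},
        "somitogenesis": {"DNA": 0.032, "LINE": 0.020, "SINE": 0.006, "LTR": 0.045, "Unclear": 0.009},
        "pharyngula": {"DNA": 0.030, "LINE": 0.018, "SINE": 0.005, "LTR": 0.040, "Unclear": 0.008},
        "larva": {"DNA": 0.028, "LINE": 0.017, "SINE": 0.005, "LTR": 0.038, "Unclear": 0.007},
    }


_EARLY_MIX = {
    "ERV1": 0.25, "ERV2": 0.10, "Gypsy": 0.25, "Copia": 0.10,
    "DIRS": 0.10, "Pao": 0.10, "Ngaro": 0.05, "LTR_other": 0.05,
}
_LATE_MIX = {
    "ERV1": 0.45, "ERV2": 0.12, "Gypsy": 0.15, "Copia": 0.07,
    "DIRS": 0.07, "Pao": 0.06, "Ngaro": 0.04, "LTR_other": 0.04,
}


def _default_stage_ltr_mix() -> dict[str, dict[str, float]]:
    return {
        "zygote": dict(_EARLY_MIX),
        "blastula": dict(_EARLY_MIX),
        "gastrula": dict(_LATE_MIX),
        "somitogenesis": dict(_LATE_MIX),
        "pharyngula": dict(_LATE_MIX),
        "larva": dict(_LATE_MIX),
    }


@dataclass(frozen=True)
class TreatmentSpec:
    """Control-vs-demethylation contrast at a single time point (3 reps/arm)."""

    control_label: str = "DMSO"
    treated_label: str = "5Aza"
    timepoint: str = "12hpf"
    ltr_fold_change: float = 3.0
    superfamily_multipliers: Mapping[str, float] = field(default_factory=dict)
    gene_fold_change: float = 1.5
    control_class_shares: Mapping[str, float] = field(
        default_factory=lambda: {
            "DNA": 0.030, "LINE": 0.020, "SINE": 0.005, "LTR": 0.040, "Unclear": 0.008
        }
    )
    ltr_mix: Mapping[str, float] = field(default_factory=lambda: dict(_LATE_MIX))

    def treated_class_shares(self) -> dict[str, float]:
        shares = dict(self.control_class_shares)
        shares["LTR"] = shares["LTR"] * self.ltr_fold_change
        if sum(shares.values()) >= 1.0:
            raise ValueError("treated TE shares exceed the read budget; lower the fold change")
        return shares

    def treated_ltr_mix(self) -> dict[str, float]:
        mix = {k: v * self.superfamily_multipliers.get(k, 1.0) for k, v in self.ltr_mix.items()}
        total = sum(mix.values())
        return {k: v / total for k, v in mix.items()}


@dataclass(frozen=True)
class GeneModelSpec:
    """Gene-set sizes and their programmed correlation to a TE trajectory.

    ``rho`` maps a set name to the Pearson correlation its members' expression
    should have, across stages, with the target TE class share; background and
    orthologue genes are uncorrelated (orthologues are exactly constant).
    ``n_orthologues`` is a desk-scale stand-in for a genome-wide single-copy
    orthologue catalogue.
    """

    n_heterochromatin: int = 10
    n_nurd: int = 15
    n_trim33: int = 1
    n_krab_like: int = 8
    n_finz: int = 10
    n_orthologues: int = 200
    n_background: int = 400
    rho: Mapping[str, float] = field(
        default_factory=lambda: {
            "heterochromatin": 0.95,
            "NuRD": 0.95,
            "trim33": 0.90,
            "KRAB_like": 0.90,
            "FiNZ": 0.10,
            "background": 0.0,
        }
    )
    target_class: str = "LTR"
    noise_scale: float = 0.25  # relative amplitude of the stage-level variation

    def set_sizes(self) -> dict[str, int]:
        return {
            "heterochromatin": self.n_heterochromatin,
            "NuRD": self.n_nurd,
            "trim33": self.n_trim33,
            "KRAB_like": self.n_krab_like,
            "FiNZ": self.n_finz,
            "single_copy_orthologues": self.n_orthologues,
            "background": self.n_background,
        }


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic study; every output is a pure
    function of this object (the seed included)."""

    seed: int = 0
    families: tuple[FamilySpec, ...] = field(default_factory=_default_families)
    stages: tuple[str, ...] = DEFAULT_STAGES
    stage_class_shares: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_stage_class_shares
    )
    stage_ltr_mix: Mapping[str, Mapping[str, float]] = field(default_factory=_default_stage_ltr_mix)
    replicates: int = 3
    reads_per_sample: int = 20000
    read_length: int = 100
    dispersion: float = 0.05
    depth_multipliers: Mapping[str, float] = field(default_factory=dict)
    flank_length: int = 200
    background_contig_length: int = 5000
    treatment: TreatmentSpec = field(default_factory=TreatmentSpec)
    genes: GeneModelSpec = field(default_factory=GeneModelSpec)

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        for stage in self.stages:
            shares = self.stage_class_shares.get(stage)
            if shares is None:
                raise ValueError(f"no class shares configured for stage {stage!r}")
            if any(v < 0 for v in shares.values()) or sum(shares.values()) >= 1.0:
                raise ValueError(f"stage {stage!r}: class shares must be >= 0 and sum to < 1")
            mix = self.stage_ltr_mix.get(stage)
            if mix is None or abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"stage {stage!r}: LTR superfamily mix must sum to 1")

    def family_by_superfamily(self) -> dict[str, list[FamilySpec]]:
        out: dict[str, list[FamilySpec]] = {}
        for fam in self.families:
            cls = classify_te(fam.class_family)
            key = cls.ltr_superfamily if cls.te_class == "LTR" else cls.te_class
            out.setdefault(key, []).append(fam)
        return out


@dataclass(frozen=True)
class SimulatedCopy:
    entry_id: str
    family: str
    te_class: str
    ltr_superfamily: str | None
    contig_id: str
    start: int
    end: int
    sequence: str
    expected_K: float
    realized_transitions: int
    realized_transversions: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TECopySet:
    """Simulated TE copies plus everything the annotation stage consumes."""

    config: SimulationConfig
    consensus: dict[str, str]
    copies: list[SimulatedCopy]
    contigs: dict[str, str]
    annotations: list[TEAnnotation]
    pairs: list[tuple[str, str, str]]
    background_contig: str

    def copies_by_group(self) -> dict[str, list[SimulatedCopy]]:
        """Copies keyed by LTR superfamily name or (for non-LTR) TE class."""
        out: dict[str, list[SimulatedCopy]] = {}
        for copy in self.copies:
            key = copy.ltr_superfamily if copy.te_class == "LTR" else copy.te_class
            out.setdefault(key, []).append(copy)
        return out


@dataclass
class GroundTruth:
    """Everything needed to score recovery: serialised next to the outputs."""

    samples: dict[str, dict]
    genes: dict[str, dict]
    copies: dict[str, dict]
    orthologues_constant: bool = True

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(dataclasses.asdict(self), handle, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as handle:
            data = json.load(handle)
        return cls(**data)


@dataclass
class ExpressionBundle:
    """Per-sample read alignments, the gene count matrix, and ground truth."""

    config: SimulationConfig
    alignments: dict[str, pd.DataFrame]
    gene_counts: pd.DataFrame
    gene_lengths: pd.Series
    gene_sets: dict[str, GeneSet]
    sample_sheet: pd.DataFrame
    truth: GroundTruth


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, consensus: np.ndarray, p: float, q: float) -> tuple[np.ndarray, int, int]:
    """Apply i.i.d. per-site substitutions; returns (copy, transitions, transversions)."""
    u = rng.random(consensus.size)
    copy = consensus.copy()
    ts_mask = u < p
    tv_mask = (u >= p) & (u < p + q)
    for code, partner in _TRANSITION.items():
        copy[ts_mask & (consensus == code)] = partner
    if tv_mask.any():
        pick = rng.integers(0, 2, size=int(tv_mask.sum()))
        idx = np.flatnonzero(tv_mask)
        for j, site in enumerate(idx):
            copy[site] = _TRANSVERSIONS[consensus[site]][pick[j]]
    return copy, int(ts_mask.sum()), int(tv_mask.sum())


def simulate_te_copies(config: SimulationConfig) -> TECopySet:
    """Generate consensus sequences, diverged copies, contigs and annotations.

    Each copy sits on its own contig between random non-repetitive flanks, and
    is reported as one RepeatMasker-style row with the correct coordinates and
    class/family label.  Deterministic for a given configuration.
    """
    rng = np.random.default_rng([config.seed, 0])
    consensus: dict[str, str] = {}
    copies: list[SimulatedCopy] = []
    contigs: dict[str, str] = {}
    annotations: list[TEAnnotation] = []
    pairs: list[tuple[str, str, str]] = []

    contig_no = 0
    for fam in config.families:
        cons = _random_sequence(rng, fam.consensus_length)
        consensus[fam.name] = cons.tobytes().decode("ascii")
        cls = classify_te(fam.class_family)
        for i in range(fam.n_copies):
            copy_arr, n_ts, n_tv = _mutate(rng, cons, fam.transition_rate, fam.transversion_rate)
            contig_no += 1
            contig_id = f"contig_{contig_no:04d}"
            flank5 = _random_sequence(rng, config.flank_length)
            flank3 = _random_sequence(rng, config.flank_length)
            contigs[contig_id] = (
                flank5.tobytes().decode("ascii")
                + copy_arr.tobytes().decode("ascii")
                + flank3.tobytes().decode("ascii")
            )
            start = config.flank_length
            end = start + fam.consensus_length
            # "<repeat_name>#<rm_id>" is the cross-file entry key: the pairs
            # FASTA and the .out table can be joined on it downstream.
            entry_id = f"{fam.name}#{contig_no}"
            copy_seq = copy_arr.tobytes().decode("ascii")
            realized_div = 100.0 * (n_ts + n_tv) / fam.consensus_length
            annotations.append(
                TEAnnotation(
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    strand="+",
                    sw_score=max(1, 2 * (fam.consensus_length - n_ts - n_tv)),
                    pct_divergence=round(min(realized_div, 100.0), 1),
                    pct_deleted=0.0,
                    pct_inserted=0.0,
                    repeat_name=fam.name,
                    repeat_class_family=fam.class_family,
                    repeat_start=1,
                    repeat_end=fam.consensus_length,
                    repeat_left=0,
                    rm_id=contig_no,
                )
            )
            pairs.append((entry_id, copy_seq, consensus[fam.name]))
            copies.append(
                SimulatedCopy(
                    entry_id=entry_id,
                    family=fam.name,
                    te_class=cls.te_class,
                    ltr_superfamily=cls.ltr_superfamily,
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    sequence=copy_seq,
                    expected_K=fam.expected_K,
                    realized_transitions=n_ts,
                    realized_transversions=n_tv,
                )
            )

    background = "contig_background"
    contigs[background] = _random_sequence(rng, config.background_contig_length).tobytes().decode("ascii")
    return TECopySet(
        config=config,
        consensus=consensus,
        copies=copies,
        contigs=contigs,
        annotations=annotations,
        pairs=pairs,
        background_contig=background,
    )


def _apportion(total: int, weights: Sequence[float]) -> np.ndarray:
    """Split ``total`` into integers proportional to ``weights``.

    Largest-remainder rounding: exact when ``weight/sum*total`` is integral,
    deterministic (ties to the lowest index) otherwise.
    """
    w = np.asarray(weights, dtype=float)
    if total < 0:
        raise ValueError("total must be non-negative")
    if w.sum() <= 0 or total == 0:
        return np.zeros(w.size, dtype=np.int64)
    shares = w / w.sum() * total
    base = np.floor(shares + 1e-9).astype(np.int64)
    remainder = total - int(base.sum())
    if remainder > 0:
        order = np.argsort(-(shares - base), kind="stable")
        base[order[:remainder]] += 1
    return base


def _nb_jitter(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Gamma-Poisson (negative binomial) draw around ``mean``."""
    if mean <= 0:
        return 0
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return int(rng.poisson(lam))


def _sample_plan(config: SimulationConfig, condition: str) -> list[dict]:
    plan = []
    if condition == "development":
        for stage in config.stages:
            for rep in range(1, config.replicates + 1):
                plan.append(
                    {
                        "sample": f"{stage}_r{rep}",
                        "stage": stage,
                        "condition": "development",
                        "replicate": rep,
                        "class_shares": dict(config.stage_class_shares[stage]),
                        "ltr_mix": dict(config.stage_ltr_mix[stage]),
                    }
                )
    elif condition == "treatment":
        trt = config.treatment
        arms = (
            (trt.control_label, dict(trt.control_class_shares), dict(trt.ltr_mix)),
            (trt.treated_label, trt.treated_class_shares(), trt.treated_ltr_mix()),
        )
        for label, shares, mix in arms:
            for rep in range(1, config.replicates + 1):
                plan.append(
                    {
                        "sample": f"{label}_r{rep}",
                        "stage": trt.timepoint,
                        "condition": label,
                        "replicate": rep,
                        "class_shares": shares,
                        "ltr_mix": mix,
                    }
                )
    else:
        raise ValueError("condition must be 'development' or 'treatment'")
    for entry in plan:
        entry["depth"] = float(config.depth_multipliers.get(entry["sample"], 1.0))
    return plan


def _simulate_sample_reads(
    rng: np.random.Generator,
    config: SimulationConfig,
    copy_set: TECopySet,
    plan: dict,
) -> pd.DataFrame:
    """One sample's alignment table: TE reads per configured class shares,
    the remainder on the background contig."""
    groups = copy_set.copies_by_group()
    n_total = int(round(config.reads_per_sample * plan["depth"]))
    shares = plan["class_shares"]
    classes = list(shares)
    noise_free = config.dispersion == 0.0

    if noise_free:
        weights = [shares[c] for c in classes] + [1.0 - sum(shares.values())]
        counts = _apportion(n_total, weights)
        class_counts = dict(zip(classes, counts[:-1]))
        background_count = int(counts[-1])
    else:
        class_counts = {
            c: _nb_jitter(rng, shares[c] * n_total, config.dispersion) for c in classes
        }
        background_count = _nb_jitter(
            rng, (1.0 - sum(shares.values())) * n_total, config.dispersion
        )

    rows_contig: list[np.ndarray] = []
    rows_start: list[np.ndarray] = []
    rows_len: list[np.ndarray] = []

    def _place(copies: list[SimulatedCopy], n: int) -> None:
        per_copy = _apportion(n, [c.length for c in copies])
        for copy, k in zip(copies, per_copy):
            if k == 0:
                continue
            rl = min(config.read_length, copy.length)
            if noise_free:
                starts = np.full(int(k), copy.start, dtype=np.int64)
            else:
                starts = copy.start + rng.integers(0, copy.length - rl + 1, size=int(k))
            rows_contig.append(np.full(int(k), copy.contig_id, dtype=object))
            rows_start.append(starts)
            rows_len.append(np.full(int(k), rl, dtype=np.int64))

    for cls in classes:
        n_cls = int(class_counts[cls])
        if n_cls == 0:
            continue
        if cls == "LTR":
            mix = plan["ltr_mix"]
            superfamilies = list(mix)
            if noise_free:
                sf_counts = _apportion(n_cls, [mix[s] for s in superfamilies])
            else:
                sf_counts = rng.multinomial(n_cls, np.array([mix[s] for s in superfamilies]))
            for sf, n_sf in zip(superfamilies, sf_counts):
                if n_sf and sf in groups:
                    _place(groups[sf], int(n_sf))
        else:
            if cls in groups:
                _place(groups[cls], n_cls)

    if background_count:
        rl = min(config.read_length, config.background_contig_length)
        if noise_free:
            starts = np.full(background_count, 0, dtype=np.int64)
        else:
            starts = rng.integers(
                0, config.background_contig_length - rl + 1, size=background_count
            )
        rows_contig.append(np.full(background_count, copy_set.background_contig, dtype=object))
        rows_start.append(starts)
        rows_len.append(np.full(background_count, rl, dtype=np.int64))

    contig = np.concatenate(rows_contig) if rows_contig else np.array([], dtype=object)
    start = np.concatenate(rows_start) if rows_start else np.array([], dtype=np.int64)
    length = np.concatenate(rows_len) if rows_len else np.array([], dtype=np.int64)
    n = contig.size
    return pd.DataFrame(
        {
            "read_id": [f"{plan['sample']}_read{i + 1}" for i in range(n)],
            "contig_id": contig,
            "aln_start": start,
            "aln_end": start + length,
            "read_length": length,
            "aligned_bases": length,
            "matches": length,
        },
        columns=list(ALIGNMENT_COLUMNS),
    )


def _gene_catalogue(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Fixed per-gene attributes: id, set, programmed rho, base level, length."""
    spec = config.genes
    rows = []
    prefixes = {
        "heterochromatin": "hc",
        "NuRD": "nurd",
        "trim33": "trim33",
        "KRAB_like": "krab",
        "FiNZ": "finz",
        "single_copy_orthologues": "orth",
        "background": "bg",
    }
    for set_name, size in spec.set_sizes().items():
        rho = 0.0 if set_name == "single_copy_orthologues" else float(
            spec.rho.get(set_name, 0.0)
        )
        for i in range(size):
            gene = prefixes[set_name] if size == 1 else f"{prefixes[set_name]}_{i + 1:04d}"
            rows.append(
                {
                    "gene": gene,
                    "set": set_name,
                    "rho": rho,
                    "base": float(rng.uniform(50.0, 500.0)),
                    "length": int(rng.integers(500, 3001)),
                }
            )
    return pd.DataFrame(rows).set_index("gene")


def simulate_expression(
    config: SimulationConfig,
    copy_set: TECopySet | None = None,
    condition: str = "development",
) -> ExpressionBundle:
    """Generate per-sample read alignments and a gene count matrix.

    Silencing-gene expression across stages is ``base * (1 + v * x)`` with
    ``x = rho * z + sqrt(1 - rho^2) * eps``, where ``z`` is the standardised
    target-TE-class trajectory and ``eps`` is i.i.d. standard normal per gene
    and stage — so the programmed Pearson correlation to the TE trajectory is
    ``rho``.  Orthologues are exactly constant; every count is scaled by the
    sample's depth multiplier; with positive ``dispersion`` counts get
    gamma-Poisson (negative binomial) noise.
    """
    if config.replicates < 2:
        raise ValueError("need at least 2 replicates per stage/arm (ANOVA requires them)")
    if copy_set is None:
        copy_set = simulate_te_copies(config)
    rng = np.random.default_rng([config.seed, 1])
    plan = _sample_plan(config, condition)
    catalogue = _gene_catalogue(config, rng)
    spec = config.genes

    # Stage-level latent trajectory of the target TE class, standardised.
    stage_labels = list(dict.fromkeys(entry["stage"] for entry in plan))
    if condition == "development":
        target = np.array(
            [config.stage_class_shares[s][spec.target_class] for s in stage_labels]
        )
    else:
        target = np.array(
            [entry["class_shares"][spec.target_class] for entry in plan]
        )[:: config.replicates]
        stage_labels = [entry["condition"] for entry in plan][:: config.replicates]
    if target.std() > 0:
        z = (target - target.mean()) / target.std()
    else:
        z = np.zeros_like(target)

    # Per-gene, per-stage-group expected expression levels.
    n_groups = len(stage_labels)
    eps = rng.standard_normal((len(catalogue), n_groups))
    rho = catalogue["rho"].to_numpy()[:, None]
    x = rho * z[None, :] + np.sqrt(1.0 - rho**2) * eps
    level = catalogue["base"].to_numpy()[:, None] * np.clip(
        1.0 + spec.noise_scale * x, 1e-6, None
    )
    is_orth = (catalogue["set"] == "single_copy_orthologues").to_numpy()
    level[is_orth] = catalogue["base"].to_numpy()[is_orth, None]
    if condition == "treatment":
        silencing = catalogue["set"].isin(
            ["heterochromatin", "NuRD", "trim33", "KRAB_like", "FiNZ"]
        ).to_numpy()
        treated_col = [i for i, lab in enumerate(stage_labels) if lab == config.treatment.treated_label]
        for col in treated_col:
            level[silencing, col] *= config.treatment.gene_fold_change

    group_index = {lab: i for i, lab in enumerate(stage_labels)}
    lengths = catalogue["length"].astype(float)
    alignments: dict[str, pd.DataFrame] = {}
    counts_cols: dict[str, np.ndarray] = {}
    truth_samples: dict[str, dict] = {}
    for entry in plan:
        sample = entry["sample"]
        alignments[sample] = _simulate_sample_reads(rng, config, copy_set, entry)
        group = entry["stage"] if condition == "development" else entry["condition"]
        mean_counts = (
            level[:, group_index[group]] * lengths.to_numpy() / 1000.0 * entry["depth"]
        )
        if config.dispersion == 0.0:
            col = mean_counts  # exact expected values; float on purpose
        else:
            col = np.array(
                [_nb_jitter(rng, m, config.dispersion) for m in mean_counts], dtype=float
            )
        counts_cols[sample] = col
        truth_samples[sample] = {
            "stage": entry["stage"],
            "condition": entry["condition"],
            "replicate": entry["replicate"],
            "depth": entry["depth"],
            "class_shares": entry["class_shares"],
            "ltr_mix": entry["ltr_mix"],
        }

    gene_counts = pd.DataFrame(counts_cols, index=catalogue.index)
    sample_sheet = pd.DataFrame(
        [
            {
                "sample": e["sample"],
                "stage": e["stage"],
                "condition": e["condition"],
                "replicate": e["replicate"],
            }
            for e in plan
        ]
    )
    gene_sets = {
        name: GeneSet(name, tuple(catalogue.index[catalogue["set"] == name]))
        for name in spec.set_sizes()
    }
    truth = GroundTruth(
        samples=truth_samples,
        genes={
            gene: {"set": row["set"], "rho": row["rho"], "base": row["base"], "length": row["length"]}
            for gene, row in catalogue.iterrows()
        },
        copies={
            c.entry_id: {
                "family": c.family,
                "te_class": c.te_class,
                "ltr_superfamily": c.ltr_superfamily,
                "expected_K": c.expected_K,
                "realized_transitions": c.realized_transitions,
                "realized_transversions": c.realized_transversions,
                "length": c.length,
            }
            for c in copy_set.copies
        },
    )
    return ExpressionBundle(
        config=config,
        alignments=alignments,
        gene_counts=gene_counts,
        gene_lengths=catalogue["length"].rename("length"),
        gene_sets=gene_sets,
        sample_sheet=sample_sheet,
        truth=truth,
    )


def write_sam(alignment_table: pd.DataFrame, contig_lengths: Mapping[str, int], path: str | Path) -> None:
    """Write the alignment table as headered SAM (full-match CIGAR, NM from mismatches)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": int(length)} for name, length in contig_lengths.items()],
    }
    ref_ids = {name: i for i, name in enumerate(contig_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in alignment_table.itertuples(index=False):
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = row.read_id
            rec.reference_id = ref_ids[row.contig_id]
            rec.reference_start = int(row.aln_start)
            rec.mapping_quality = 60
            rec.cigartuples = [(0, int(row.aligned_bases))]
            rec.query_sequence = "N" * int(row.aligned_bases)
            rec.set_tag("NM", int(row.aligned_bases - row.matches))
            out.write(rec)


def write_copy_bundle(copy_set: TECopySet, outdir: str | Path) -> dict[str, Path]:
    """Write consensus/contig FASTA, the ``.out`` table and aligned pairs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "consensus": outdir / "consensus.fasta",
        "contigs": outdir / "contigs.fasta",
        "annotations": outdir / "annotations.out",
        "pairs": outdir / "pairs.fasta",
    }
    _write_fasta(copy_set.consensus, paths["consensus"])
    _write_fasta(copy_set.contigs, paths["contigs"])
    write_rm_out(copy_set.annotations, paths["annotations"])
    write_alignment_pairs(copy_set.pairs, paths["pairs"])
    return paths


def write_expression_bundle(bundle: ExpressionBundle, outdir: str | Path) -> dict[str, Path]:
    """Write alignments, counts, sample sheet, gene sets and ground truth."""
    outdir = Path(outdir)
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sample, table in bundle.alignments.items():
        path = aln_dir / f"{sample}.tsv"
        table.to_csv(path, sep="\t", index=False)
        paths[f"alignments/{sample}"] = path

    counts = bundle.gene_counts.copy()
    counts.insert(0, "length", bundle.gene_lengths)
    counts.index.name = "gene"
    paths["gene_counts"] = outdir / "gene_counts.tsv"
    counts.to_csv(paths["gene_counts"], sep="\t", float_format="%.10g")

    paths["samples"] = outdir / "samples.tsv"
    bundle.sample_sheet.to_csv(paths["samples"], sep="\t", index=False)

    paths["gene_sets"] = outdir / "gene_sets.txt"
    write_gene_sets(bundle.gene_sets, paths["gene_sets"])

    paths["ground_truth"] = outdir / "ground_truth.json"
    bundle.truth.to_json(paths["ground_truth"])
    return paths


def _write_fasta(sequences: Mapping[str, str], path: Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
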