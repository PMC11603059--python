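"""End-to-end orchestration: filter -> quantify -> landscape -> normalise -> stats.

The pipeline consumes an input bundle (RepeatMasker ``.out`` table, per-sample
alignment tables, a gene count matrix, gene-set lists, a sample sheet — the
layout :func:`tescope.simulate.write_copy_bundle` /
:func:`tescope.simulate.write_expression_bundle` produce) and writes tidy TSV
tables plus a run manifest.  Outputs are a pure function of the inputs and the
configuration: rerunning with the same manifest yields byte-identical tables.

Stage functions are importable individually; :func:`run_pipeline` chains them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .annotation import (
    LTR_SUPERFAMILIES,
    TE_CLASSES,
    classify_te,
    filter_redundancy,
    parse_rm_out,
    write_bed,
    write_rm_out,
    write_table,
)
from .divergence import (
    KimuraRecord,
    SaturationError,
    build_landscape,
    count_substitutions,
    kimura_from_counts,
    read_alignment_pairs,
)
from .normalization import (
    compute_tpm,
    family_mean_expression,
    ortholog_scaling,
    read_counts_table,
    read_gene_sets,
)
from .quantify import (
    aggregate_profile,
    assign_reads_to_te,
    filter_alignments,
    profile_frame,
    read_alignment_tsv,
)
from .stats import (
    correlation_frame,
    correlation_panel,
    mean_sem,
    null_correlation_control,
    one_way_anova,
)

__all__ = ["RunConfig", "run_pipeline", "make_report"]

logger = logging.getLogger("tescope")

_FLOAT_FORMAT = "%.10g"

#: Gene sets whose members are "genes of interest" for correlations/ANOVA.
INTEREST_SETS = ("heterochromatin", "NuRD", "trim33")
FAMILY_SETS = ("KRAB_like", "FiNZ")
ORTHOLOGUE_SET = "single_copy_orthologues"
BACKGROUND_SET = "background"


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run.

    Filter and mapping defaults follow the study design this pipeline mirrors:
    redundancy length cutoff 80 bp (strict), mapper length and similarity
    fractions 0.80, read-to-entry overlap fraction 0.5.
    """

    input_dir: str | Path
    output_dir: str | Path
    min_length: int = 80
    length_fraction: float = 0.80
    similarity_fraction: float = 0.80
    min_overlap_fraction: float = 0.5
    bin_width: float = 1.0
    alpha: float = 0.05
    n_random: int = 100
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle)
        return cls(**data)

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["input_dir"] = str(self.input_dir)
        data["output_dir"] = str(self.output_dir)
        return data

    # -- bundle paths -----------------------------------------------------
    def _input(self, name: str) -> Path:
        path = Path(self.input_dir) / name
        if not path.exists():
            raise FileNotFoundError(f"required input missing: {path}")
        return path

    def _output(self, name: str) -> Path:
        out = Path(self.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        return out / name

    def _stage_output(self, name: str) -> Path:
        path = Path(self.output_dir) / name
        if not path.exists():
            raise FileNotFoundError(
                f"stage output missing: {path} (run the earlier pipeline stage first)"
            )
        return path


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FORMAT)


def stage_filter(config: RunConfig) -> pd.DataFrame:
    """Parse and redundancy-filter the RepeatMasker table; write .out/TSV/BED."""
    annotations = parse_rm_out(config._input("annotations.out"))
    filtered = filter_redundancy(annotations, min_length=config.min_length)
    if not filtered:
        raise ValueError("no TE entries survive filtering")
    write_rm_out(filtered, config._output("filtered.out"))
    write_table(filtered, config._output("filtered.tsv"))
    write_bed(filtered, config._output("filtered.bed"))
    logger.info("filter: %d/%d entries retained", len(filtered), len(annotations))
    from .annotation import annotation_frame

    return annotation_frame(filtered)


def stage_quantify(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample read assignment and TE-class/LTR-superfamily profiles.

    Returns (tidy profile table, per-entry read count table).
    """
    ann = pd.read_csv(config._stage_output("filtered.tsv"), sep="\t")
    samples = pd.read_csv(config._input("samples.tsv"), sep="\t")
    profiles = []
    entry_counts = pd.DataFrame(index=ann.index)
    for sample in samples["sample"]:
        table = read_alignment_tsv(config._input(f"alignments/{sample}.tsv"))
        kept = filter_alignments(table, config.length_fraction, config.similarity_fraction)
        counts = assign_reads_to_te(kept, ann, config.min_overlap_fraction)
        profiles.append(aggregate_profile(counts, ann, total_mapped_reads=len(kept), sample_id=sample))
        entry_counts[sample] = counts
    tidy = profile_frame(profiles)
    _write_tsv(tidy, config._output("te_profiles.tsv"))
    entry_table = ann[
        ["contig_id", "start", "end", "repeat_name", "repeat_class_family", "rm_id", "te_class", "ltr_superfamily"]
    ].copy()
    entry_table["entry_id"] = ann["repeat_name"] + "#" + ann["rm_id"].astype(str)
    entry_table = pd.concat([entry_table, entry_counts], axis=1)
    _write_tsv(entry_table, config._output("entry_counts.tsv"))
    return tidy, entry_table


def stage_landscape(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Kimura-divergence landscapes of the LTR fraction, bp- and read-weighted.

    Copy/consensus pairs come from ``pairs.fasta``; entry ids of the form
    ``<repeat_name>#<rm_id>`` are joined with the quantified entry table so
    the read-weighted landscape describes the *expressed* LTR copies.
    Saturated copies are counted and excluded; the overflow bucket keeps
    weight conservation explicit.
    """
    pairs = read_alignment_pairs(config._input("pairs.fasta"))
    entry_table = pd.read_csv(config._stage_output("entry_counts.tsv"), sep="\t")
    meta_cols = (
        "contig_id",
        "start",
        "end",
        "repeat_name",
        "repeat_class_family",
        "rm_id",
        "te_class",
        "ltr_superfamily",
        "entry_id",
    )
    sample_cols = [c for c in entry_table.columns if c not in meta_cols]
    reads_by_entry = dict(
        zip(entry_table["entry_id"], entry_table[sample_cols].sum(axis=1))
    )
    class_by_name = dict(zip(entry_table["repeat_name"], entry_table["repeat_class_family"]))

    records_bp: list[KimuraRecord] = []
    records_reads: list[KimuraRecord] = []
    saturated = 0
    for entry_id, copy_seq, cons_seq in pairs:
        family = entry_id.rsplit("#", 1)[0]
        cls = classify_te(class_by_name.get(family, family))
        if cls.te_class != "LTR":
            continue
        counts = count_substitutions(copy_seq, cons_seq)
        try:
            K = kimura_from_counts(counts)
        except SaturationError:
            saturated += 1
            continue
        records_bp.append(
            KimuraRecord(entry_id, K, float(counts.aligned_sites), cls.te_class, cls.ltr_superfamily)
        )
        records_reads.append(
            KimuraRecord(entry_id, K, float(reads_by_entry.get(entry_id, 0.0)), cls.te_class, cls.ltr_superfamily)
        )
    if saturated:
        logger.warning("landscape: %d saturated copies excluded", saturated)
    out: dict[str, pd.DataFrame] = {}
    for label, records in (("bp", records_bp), ("reads", records_reads)):
        scape = build_landscape(records, bin_width=config.bin_width, group_by="ltr_superfamily")
        _write_tsv(scape.bins, config._output(f"landscape_{label}.tsv"))
        _write_tsv(scape.overflow, config._output(f"landscape_{label}_overflow.tsv"))
        out[label] = scape.bins
    summary = pd.DataFrame(
        [{"saturated_copies": saturated, "ltr_copies_binned": len(records_bp)}]
    )
    _write_tsv(summary, config._output("landscape_summary.tsv"))
    return out


def stage_normalize(config: RunConfig) -> dict[str, pd.DataFrame]:
    """TPM, orthologue-anchored scaling, and per-family mean expression."""
    counts, lengths = read_counts_table(config._input("gene_counts.tsv"))
    gene_sets = read_gene_sets(config._input("gene_sets.txt"))
    if ORTHOLOGUE_SET not in gene_sets:
        raise ValueError(f"gene_sets.txt must define the {ORTHOLOGUE_SET!r} set")
    tpm = compute_tpm(counts, lengths)
    factors, scaled = ortholog_scaling(tpm, gene_sets[ORTHOLOGUE_SET])
    _write_tsv(tpm.rename_axis("gene"), config._output("tpm.tsv"), index=True)
    _write_tsv(scaled.rename_axis("gene"), config._output("scaled_tpm.tsv"), index=True)
    _write_tsv(
        factors.rename_axis("sample").reset_index(), config._output("scaling_factors.tsv")
    )
    family_rows = {}
    for name in FAMILY_SETS + INTEREST_SETS:
        if name in gene_sets and gene_sets[name].members:
            family_rows[name] = family_mean_expression(scaled, gene_sets[name])
    family_means = pd.DataFrame(family_rows).T.rename_axis("gene_set")
    _write_tsv(family_means, config._output("family_means.tsv"), index=True)
    return {"tpm": tpm, "scaled_tpm": scaled, "family_means": family_means}


def _group_means(values: pd.DataFrame, sample_to_group: Mapping[str, str]) -> pd.DataFrame:
    """Average columns (samples) into their stage/condition groups, preserving order."""
    groups = list(dict.fromkeys(sample_to_group[s] for s in values.columns))
    out = {}
    for g in groups:
        cols = [s for s in values.columns if sample_to_group[s] == g]
        out[g] = values[cols].mean(axis=1)
    return pd.DataFrame(out)


def stage_stats(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Correlation panel with a random-gene null (staged designs) and one-way
    ANOVA with star annotations plus mean ± SEM summaries (two-arm designs)."""
    samples = pd.read_csv(config._input("samples.tsv"), sep="\t")
    tidy = pd.read_csv(config._stage_output("te_profiles.tsv"), sep="\t")
    scaled = pd.read_csv(config._stage_output("scaled_tpm.tsv"), sep="\t").set_index("gene")
    family_means = pd.read_csv(config._stage_output("family_means.tsv"), sep="\t").set_index("gene_set")
    gene_sets = read_gene_sets(config._input("gene_sets.txt"))

    class_percent = tidy[tidy["level"] == "te_class"].pivot(
        index="group", columns="sample", values="percent"
    )[samples["sample"]]
    ltr_percent = tidy[tidy["level"] == "ltr_superfamily"].pivot(
        index="group", columns="sample", values="percent"
    )[samples["sample"]]

    conditions = list(dict.fromkeys(samples["condition"]))
    results: dict[str, pd.DataFrame] = {}

    if len(conditions) == 1:
        # staged design: correlate per-stage means (TE classes x genes of interest)
        sample_to_stage = dict(zip(samples["sample"], samples["stage"]))
        te_traj = _group_means(class_percent, sample_to_stage)
        te_traj.loc["TE_total"] = te_traj.loc[list(TE_CLASSES)].sum(axis=0)
        gene_traj = _group_means(scaled, sample_to_stage)
        family_traj = _group_means(family_means, sample_to_stage)

        interest_genes = [
            m
            for name in INTEREST_SETS
            if name in gene_sets
            for m in gene_sets[name].members
            if m in gene_traj.index
        ]
        family_rows = [name for name in FAMILY_SETS if name in family_traj.index]
        targets = pd.concat([gene_traj.loc[interest_genes], family_traj.loc[family_rows]])
        panel = correlation_panel(
            te_traj, targets, pairs=None, alpha=config.alpha
        )
        corr = correlation_frame(panel)
        _write_tsv(corr, config._output("correlations.tsv"))
        results["correlations"] = corr

        exclude = {
            m
            for name in (*INTEREST_SETS, *FAMILY_SETS, ORTHOLOGUE_SET)
            if name in gene_sets
            for m in gene_sets[name].members
        }
        null = null_correlation_control(
            te_traj,
            gene_traj,
            n_random=config.n_random,
            seed=config.seed,
            exclude=exclude,
            alpha=config.alpha,
        )
        null_df = pd.DataFrame([dataclasses.asdict(null)])
        _write_tsv(null_df, config._output("null_control.tsv"))
        results["null_control"] = null_df
    else:
        # two-arm contrast: ANOVA per TE class / LTR superfamily / gene set mean
        sample_groups = {
            cond: list(samples.loc[samples["condition"] == cond, "sample"]) for cond in conditions
        }
        anova_rows = []
        summary_rows = []

        def _add(level: str, name: str, values: pd.Series) -> None:
            groups = [values[cols].to_numpy() for cols in sample_groups.values()]
            try:
                res = one_way_anova(groups)
                f_val, p_val, stars = res.F, res.p_value, res.stars
            except ValueError:
                f_val, p_val, stars = float("nan"), float("nan"), ""
            anova_rows.append(
                {"level": level, "name": name, "F": f_val, "p_value": p_val, "stars": stars}
            )
            for cond, cols in sample_groups.items():
                summ = mean_sem(values[cols].to_numpy())
                summary_rows.append(
                    {
                        "level": level,
                        "name": name,
                        "condition": cond,
                        "mean": summ.mean,
                        "sem": summ.sem,
                        "n": summ.n,
                    }
                )

        for cls in TE_CLASSES:
            _add("te_class_percent", cls, class_percent.loc[cls])
        for sf in LTR_SUPERFAMILIES:
            _add("ltr_superfamily_percent", sf, ltr_percent.loc[sf])
        for name in family_means.index:
            _add("gene_set_mean_tpm", name, family_means.loc[name])
        anova = pd.DataFrame(anova_rows)
        summary = pd.DataFrame(summary_rows)
        _write_tsv(anova, config._output("anova.tsv"))
        _write_tsv(summary, config._output("replicate_summary.tsv"))
        results["anova"] = anova
        results["replicate_summary"] = summary
    return results


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage in order and write the run manifest; returns output dir."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    stage_filter(config)
    stage_quantify(config)
    stage_landscape(config)
    stage_normalize(config)
    stage_stats(config)
    make_report(config)

    input_dir = Path(config.input_dir)
    checksums = {
        str(p.relative_to(input_dir)): _sha256(p)
        for p in sorted(input_dir.rglob("*"))
        if p.is_file()
    }
    parameters = config.to_dict()
    # the output location is where the bundle lands, not a parameter of it:
    # runs into different directories must stay byte-identical
    parameters.pop("output_dir")
    manifest = {
        "tool": "tescope",
        "version": __version__,
        "parameters": parameters,
        "input_checksums": checksums,
    }
    manifest_path = config._output("manifest.json")
    with open(manifest_path, "w") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
    return Path(config.output_dir)


def make_report(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Figure-ready tables from the stage outputs.

    Stacked-bar matrices of TE-class and LTR-superfamily percentages per
    sample, the landscape table, family expression, and (depending on design)
    the correlation bar table or the ANOVA star table.
    """
    report_dir = Path(config.output_dir) / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    tidy = pd.read_csv(config._stage_output("te_profiles.tsv"), sep="\t")
    out: dict[str, pd.DataFrame] = {}

    class_matrix = tidy[tidy["level"] == "te_class"].pivot(
        index="sample", columns="group", values="percent"
    )
    ltr_matrix = tidy[tidy["level"] == "ltr_superfamily"].pivot(
        index="sample", columns="group", values="percent"
    )
    _write_tsv(class_matrix, report_dir / "te_class_percent.tsv", index=True)
    _write_tsv(ltr_matrix, report_dir / "ltr_superfamily_percent.tsv", index=True)
    out["te_class_percent"] = class_matrix
    out["ltr_superfamily_percent"] = ltr_matrix

    for label in ("bp", "reads"):
        scape = pd.read_csv(config._stage_output(f"landscape_{label}.tsv"), sep="\t")
        if scape["weight"].sum() == 0:
            logger.warning("landscape (%s-weighted) has zero total weight", label)
        _write_tsv(scape, report_dir / f"landscape_{label}.tsv")
        out[f"landscape_{label}"] = scape

    family = pd.read_csv(config._stage_output("family_means.tsv"), sep="\t")
    _write_tsv(family, report_dir / "family_expression.tsv")
    out["family_expression"] = family

    for name in ("correlations", "null_control", "anova", "replicate_summary"):
        path = Path(config.output_dir) / f"{name}.tsv"
        if path.exists():
            table = pd.read_csv(path, sep="\t")
            _write_tsv(table, report_dir / f"{name}.tsv")
            out[name] = table
    return out
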