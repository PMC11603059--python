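# Methods

## Scope and model of the data

`tescope` analyses TE transcription from three inputs: a RepeatMasker `.out`
annotation of a transcriptome assembly, read alignments of RNA-seq samples
against that assembly, and a gene × sample count matrix with transcript
lengths and gene-set lists.  It does not run RepeatMasker, trim reads, map
reads or assemble transcriptomes; those upstream steps are assumed done (or
are replaced by the synthetic generator).  Coordinates are 1-based inclusive
in files (the RepeatMasker convention) and 0-based half-open in memory.

## Annotation filtering

RepeatMasker output on assembled transcripts is redundant: overlapping hits
of related repeat models stack on the same contig.  Redundancy is reduced in
three ordered steps: (1) entries whose class is not a transposable element
(simple repeats, low-complexity runs, satellites, structural RNAs,
artefacts) are removed; (2) entries on the same contig whose intervals share
at least one base are clustered by transitive closure and exactly one entry
per cluster is kept — the highest Smith–Waterman score, with ties broken by
longer match, then smaller start, then input order; (3) survivors with match
length ≤ 80 bp are removed (the cutoff is strict: an 80-bp match is
discarded).  Scoring competition is per overlap cluster, not per contig — a
contig carrying two non-overlapping TEs legitimately keeps both.  The match
length tested is the length on the contig, not on the consensus.  Overlap is
defined as ≥ 1 shared base.  These choices (cluster scope, step order,
overlap definition) are interface-level decisions where the procedure itself
admits variants; the defaults maximise retained signal and are checked
against an exhaustive oracle in the test suite.

Label taxonomy: the prefix before `/` decides the class (case-insensitive,
trailing `?` stripped); `RC`/Helitron rolling-circle elements are counted as
DNA transposons; anything unrecognised — including `Unknown` — is `Unclear`,
which is deliberately a *TE* category (it mirrors treating unclassified
repeat models as putative TEs) while the non-TE list above is excluded from
every profile.  For LTR elements the suffix resolves the superfamily; the
seven named superfamilies are kept and everything else becomes `LTR_other`.

## Read assignment and profiles

Alignments are screened with the same cutoffs a read mapper would apply:
aligned fraction of the read ≥ 0.80 and identity over the aligned part
≥ 0.80, both inclusive.  Multi-mapped reads are reduced to their single best
surviving record (most matched bases, ties to input order) — a deliberate,
simple stand-in for a mapper's placement policy.  A read then counts toward
the unique filtered TE entry covering at least half of its aligned interval
(filtered entries never overlap, so at most one entry can exceed 0.5; exact
0.5 ties go to the leftmost entry).  Counting is unstranded.  Per-class and
per-superfamily totals are expressed as percentages of *all* reads mapped to
the assembly in that sample, which makes profiles comparable across samples
with different TE loads.  An alternative reading — counting whole-transcript
reads per TE-containing contig — is not the default because a transcript can
contain both TE and non-TE sequence; interval overlap measures the TE
contribution directly.

## Kimura landscapes

Copy-versus-consensus alignments (aligned-FASTA pairs of equal length) are
reduced to transition/transversion proportions over the ungapped,
unambiguous columns; the Kimura two-parameter distance
`K = −½ ln((1 − 2p − q)·√(1 − 2q))` corrects for multiple hits while
distinguishing the two substitution types.  Copies outside the model's
domain (`1 − 2p − q ≤ 0` or `1 − 2q ≤ 0`) are *saturated*: they are counted,
reported, and excluded from bins rather than silently dropped.  Landscapes
bin `100·K` into `[0,1), [1,2), … [49,50)` percent bins (width
configurable); anything at or past 50% goes to an explicit per-group
overflow bucket so total weight is conserved exactly.  Two weightings are
emitted: aligned bp per copy (the RepeatMasker convention) and assigned read
counts (describing the *expressed* TE fraction); CpG-adjusted divergence is
not applied.

## Expression normalisation

TPM is computed with transcript length as the effective length (no
fragment-length model): `tpm_g = 10⁶ · (count_g/len_g) / Σ_h (count_h/len_h)`.
Raw TPM columns are comparable only if total transcriptional output is
constant, which fails across early development (maternal load, ZGA).  Each
sample is therefore rescaled by `s_j = R / C_j`, where `C_j` is the
cumulative TPM of a single-copy-orthologue set assumed uniformly expressed
and `R` is the across-sample mean of the `C_j` (configurable to a named
reference sample — the mean is the default because no reference sample is
canonical).  After scaling, the orthologue set has identical cumulative
expression everywhere and within-sample ratios are untouched; applied to
length-normalised counts instead of TPM, the same machinery recovers
injected sequencing-depth multipliers exactly, which is how the test suite
validates it.  Replicates are scaled independently and summarised (mean ±
SEM) afterwards.  Multi-gene families (KRAB-like and FiNZ ZNFs) are reported
as the unweighted mean of member scaled TPMs per sample.  Gene-set members
absent from the matrix are reported with a warning, never silently dropped.

## Statistics

Pearson `r` with the two-sided t test on `t = r√(n−2)/√(1−r²)` links
TE-type trajectories to genes of interest across per-stage replicate means
(n = 6 stages by default; per-replicate mode is available simply by not
averaging).  Significance for correlation bars is two-sided p < 0.05; no
multiple-testing correction is applied, since the battery's honesty is
instead demonstrated by an empirical null: `n_random` genes drawn uniformly
without replacement (seeded, deterministic) are correlated with the same
trajectories, and the fraction flagged significant is reported — for truly
unrelated genes it sits at the α level, which the calibration tests verify
at n_random = 1000.  The default n_random is 100 (the null-set size is a
free parameter of the design; it is configurable).  One-way fixed-effects
ANOVA handles the two-arm treatment contrast, run on percentages of mapped
reads (the plotted quantity); stars use strict thresholds (`*` < 0.05,
`**` < 0.01, `***` < 0.001).  Zero within-group variance with a real
between-group difference yields F = ∞, p = 0; fully constant data is an
error.  All statistics are checked to ≥ 9 decimal digits against independent
implementations (scipy) and naive formula evaluations.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
sequencing physics:

* **Copies** diverge from a random consensus by i.i.d. per-site
  substitutions — transition with probability `p`, transversion (uniform
  over the two options) with probability `q` — so the expected K2P distance
  is the closed form of `(p, q)`.  No indels, no rate heterogeneity, no CpG
  hypermutability: the simplest model matching the estimator.  Each copy
  sits on its own contig between 200-bp random flanks.
* **Reads** are interval-level alignment records placed fully inside copies
  (no base qualities, which the pipeline never uses).  Stage-specific
  class shares define the six-stage developmental design: a maternal peak at
  the 1-cell stage (16% of mapped reads TE-derived), a trough at ZGA
  (~4%), and a rebound (~9–12%) with an ERV1-dominated LTR mix from
  gastrula onward.  The treatment design multiplies the LTR share by 3 in
  the drug arm (3 replicates per arm at one timepoint).  These defaults are
  qualitative mirrors of the biological narrative; all numbers are
  configuration values, chosen once as plausible for embryonic zebrafish
  data.
* **Genes**: expression across stage groups is `base · (1 + 0.25·x)` with
  `x = ρ·z + √(1−ρ²)·ε`, `z` the standardised target-TE-class trajectory and
  `ε` i.i.d. standard normal — so the programmed Pearson correlation to the
  TE trajectory is `ρ` and, because the model is linear-Gaussian, the null
  calibration of the correlation test is exact.  Default ρ: 0.95 for
  heterochromatin and NuRD genes, 0.90 for trim33 and KRAB-like, 0.10 for
  FiNZ (kept low so the *family mean*, whose averaging over members shrinks
  noise and inflates correlation, stays below the significance threshold —
  matching the narrative that FiNZ tracking is not statistically supported),
  0 for background.  Orthologues are exactly constant.  Per-sample depth
  multipliers scale every count.
* **Noise**: counts receive gamma-Poisson (negative binomial) jitter with
  dispersion 0.05 by default.  With `dispersion = 0` the generator is exact:
  read counts are largest-remainder apportionments of the configured shares
  (integral whenever `share × reads_per_sample` is integral, as the defaults
  are) and gene counts are exact expected values — recovery tests can then
  assert equality, not closeness.

Everything is a pure function of the configuration object, including its
seed; ground truth (per-copy expected K, per-sample shares, per-gene ρ,
depth multipliers) is serialised beside the outputs.

What passing tests on this generator do **not** show: robustness to indels
and alignment error, to mapper-specific multi-mapping policies, to
fragment-length effects on effective lengths, or to biological violations of
the orthologue-constancy assumption.  Those belong to the upstream tools and
to study design, not to this pipeline.

## Numerical and operational choices

Comparisons at cutoffs are inclusive (`≥`) throughout.  Read-to-entry
assignment breaks exact overlap ties (only possible at fraction 0.5) toward
the smaller start.  Landscape bins use half-open intervals `[lo, lo+w)`.
TPM columns sum to 10⁶ to ~1e-10 relative; scaling is idempotent to 1e-9.
All tables are written with a fixed float format (`%.10g`) and sorted,
deterministic ordering, so a rerun with the same inputs and parameters is
byte-identical; the run manifest records the tool version, every parameter
and the SHA-256 of every input, and deliberately omits output paths and
timestamps.  Test and acceptance problem sizes (5,000-read noise-free
samples, 100 × 10-kb copies for divergence recovery, 200 seeded runs for
derepression power, 10,000 simulations for ANOVA calibration) were chosen as
the smallest scales at which the checked properties are sharp.

## Known limitations

* The redundancy filter keeps one entry per overlap cluster; nested distinct
  elements (a genuine TE inside another) are collapsed to the better hit.
* Read assignment is single-placement; EM-style multi-mapping reallocation
  is out of scope.
* The `.align` RepeatMasker dialect is not parsed; copy/consensus pairs are
  exchanged as aligned FASTA.
* The K2P estimator ignores indels (gap columns are excluded), so divergence
  of indel-rich copies is underestimated relative to alignment-aware models.
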