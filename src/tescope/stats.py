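"""Correlation and ANOVA battery linking TE activity to silencing-gene expression.

Three instruments, matching how co-regulation is usually argued from staged
bulk RNA-seq: (i) Pearson correlation of a TE-type trajectory against each gene
of interest across stages, with a two-sided t test on ``r``; (ii) the same
correlations against randomly drawn background genes as an empirical null
control — if the battery is honest, about ``alpha`` of random genes come out
"significant"; (iii) one-way ANOVA for treated-vs-control contrasts with the
conventional star code (* p<0.05, ** p<0.01, *** p<0.001, strict thresholds)
and mean ± SEM replicate summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

__all__ = [
    "CorrelationResult",
    "AnovaResult",
    "ReplicateSummary",
    "NullControlSummary",
    "pearson",
    "correlation_panel",
    "null_correlation_control",
    "one_way_anova",
    "mean_sem",
    "stars_for_p",
    "correlation_frame",
]


@dataclass(frozen=True)
class CorrelationResult:
    x_label: str
    y_label: str
    n: int
    r: float
    t_stat: float
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class AnovaResult:
    group_sizes: tuple[int, ...]
    F: float
    df_between: int
    df_within: int
    p_value: float

    @property
    def stars(self) -> str:
        return stars_for_p(self.p_value)


@dataclass(frozen=True)
class ReplicateSummary:
    mean: float
    sem: float
    n: int


@dataclass(frozen=True)
class NullControlSummary:
    """Distribution of correlations between TE trajectories and random genes."""

    n_random: int
    n_tests: int
    mean_r: float
    sd_r: float
    fraction_significant: float
    alpha: float
    seed: int


def stars_for_p(p_value: float) -> str:
    """Significance stars; thresholds are strict (p = 0.05 earns none)."""
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def pearson(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.05,
    x_label: str = "x",
    y_label: str = "y",
) -> CorrelationResult:
    """Pearson correlation with a two-sided t test (n - 2 df).

    ``r = sum((x - x̄)(y - ȳ)) / sqrt(sum((x - x̄)²) sum((y - ȳ)²))`` and
    ``t = r sqrt(n - 2) / sqrt(1 - r²)``.  Requires n >= 3 and non-constant
    vectors; perfectly collinear input returns p = 0.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = xa.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("zero variance: correlation undefined for a constant vector")
    r = float(dx @ dy) / sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if 1.0 - r * r <= 0.0:
        t_stat = np.inf if r > 0 else -np.inf
        p_value = 0.0
    else:
        t_stat = r * sqrt((n - 2) / (1.0 - r * r))
        p_value = float(2.0 * _scipy_stats.t.sf(abs(t_stat), df=n - 2))
    return CorrelationResult(x_label, y_label, n, r, float(t_stat), p_value, alpha)


def correlation_panel(
    te_profiles: pd.DataFrame,
    gene_expression: pd.DataFrame,
    pairs: Iterable[tuple[str, str]] | None = None,
    alpha: float = 0.05,
) -> list[CorrelationResult]:
    """Correlate TE-type trajectories (or genes) with genes across shared samples.

    Both frames carry variables on rows and samples on columns; the sample
    labels must agree exactly and in order.  ``pairs`` lists (x, y) labels — x
    is looked up among TE profiles first, then genes; y among genes.  With no
    explicit pairs, every TE profile is paired with every gene.
    """
    if list(te_profiles.columns) != list(gene_expression.columns):
        raise ValueError(
            "sample labels of TE profiles and gene expression differ: "
            f"{list(te_profiles.columns)} vs {list(gene_expression.columns)}"
        )
    if pairs is None:
        pairs = [(te, gene) for te in te_profiles.index for gene in gene_expression.index]
    results = []
    for x_label, y_label in pairs:
        if x_label in te_profiles.index:
            x = te_profiles.loc[x_label]
        elif x_label in gene_expression.index:
            x = gene_expression.loc[x_label]
        else:
            raise KeyError(f"unknown x label {x_label!r}")
        if y_label not in gene_expression.index:
            raise KeyError(f"unknown gene {y_label!r}")
        y = gene_expression.loc[y_label]
        results.append(pearson(x, y, alpha=alpha, x_label=x_label, y_label=y_label))
    return results


def correlation_frame(results: Iterable[CorrelationResult]) -> pd.DataFrame:
    """Tidy table of correlation results (the data behind correlation bar charts)."""
    return pd.DataFrame(
        [
            {
                "x": res.x_label,
                "y": res.y_label,
                "n": res.n,
                "r": res.r,
                "t_stat": res.t_stat,
                "p_value": res.p_value,
                "significant": res.significant,
                "bar_colour": "blue" if res.significant else "orange",
            }
            for res in results
        ]
    )


def null_correlation_control(
    te_profiles: pd.DataFrame,
    gene_expression: pd.DataFrame,
    n_random: int,
    seed: int,
    exclude: Iterable[str] = (),
    alpha: float = 0.05,
) -> NullControlSummary:
    """Empirical null: correlate TE trajectories with randomly drawn genes.

    Samples ``n_random`` genes uniformly without replacement (excluding the
    genes of interest), correlates each with every TE trajectory, and
    summarises the r distribution and the fraction significant at ``alpha``.
    Deterministic for a given seed.
    """
    if n_random <= 0:
        raise ValueError("n_random must be positive")
    pool = [g for g in gene_expression.index if g not in set(exclude)]
    if len(pool) < n_random:
        raise ValueError(
            f"only {len(pool)} candidate genes available for a null of size {n_random}"
        )
    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(np.asarray(pool, dtype=object), size=n_random, replace=False))
    results = correlation_panel(
        te_profiles,
        gene_expression.loc[chosen],
        pairs=[(te, gene) for te in te_profiles.index for gene in chosen],
        alpha=alpha,
    )
    r_values = np.array([res.r for res in results])
    return NullControlSummary(
        n_random=n_random,
        n_tests=len(results),
        mean_r=float(r_values.mean()),
        sd_r=float(r_values.std(ddof=1)) if len(r_values) > 1 else 0.0,
        fraction_significant=float(np.mean([res.significant for res in results])),
        alpha=alpha,
        seed=seed,
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA across k groups.

    ``F = MS_between / MS_within`` with (k - 1, N - k) degrees of freedom.
    Each group needs >= 2 values.  Zero within-group variance with a real
    between-group difference yields F = inf (p = 0); all-identical data is an
    error (no variance to test).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.ndim != 1 or a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    sizes = tuple(int(a.size) for a in arrays)
    n_total = sum(sizes)
    k = len(arrays)
    grand = sum(float(a.sum()) for a in arrays) / n_total
    ss_between = sum(a.size * (float(a.mean()) - grand) ** 2 for a in arrays)
    ss_within = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        if ms_between == 0.0:
            raise ValueError("all observations identical: ANOVA undefined")
        return AnovaResult(sizes, float("inf"), df_between, df_within, 0.0)
    F = ms_between / ms_within
    p_value = float(_scipy_stats.f.sf(F, df_between, df_within))
    return AnovaResult(sizes, float(F), df_between, df_within, p_value)


def mean_sem(values: Sequence[float]) -> ReplicateSummary:
    """Mean and standard error (sample SD over sqrt(n)); needs n >= 2."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values for a SEM")
    return ReplicateSummary(
        mean=float(arr.mean()),
        sem=float(arr.std(ddof=1) / sqrt(arr.size)),
        n=int(arr.size),
    )
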