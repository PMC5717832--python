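"""Carrier-level 2x2 statistics and a permutation gene-burden test.

Carrier-level comparisons use the classical 2x2 machinery: the sample
odds ratio ad/bc, the Woolf (log-normal) confidence interval
``exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))``, and the two-sided
Fisher exact test (point-probability method).  Unexposed counts are
group size minus carriers, since the screen reports carrier frequencies.

Gene-level burden testing aggregates rare-variant allele counts per
pool; because the pool — not the individual — is the unit of sequencing
and the exchangeable unit under the null, significance comes from
permuting case/control labels over pools (stratified by stage when both
stages are present), with the add-one ``(r + 1) / (n_perm + 1)``
convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, norm

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "BurdenResult",
    "odds_ratio",
    "woolf_ci",
    "fisher_exact_two_sided",
    "compute_association",
    "gene_burden_test",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Carrier counts: a/b exposed/unexposed cases, c/d exposed/unexposed
    controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero table")

    @classmethod
    def from_carriers(cls, case_carriers: int, n_cases: int,
                      control_carriers: int, n_controls: int) -> "ContingencyTable":
        return cls(case_carriers, n_cases - case_carriers,
                   control_carriers, n_controls - control_carriers)

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def _as_table(table) -> ContingencyTable:
    if isinstance(table, ContingencyTable):
        return table
    return ContingencyTable(*table)


def odds_ratio(table) -> float:
    """Sample odds ratio (a*d)/(b*c).

    Zero off-diagonal cells (b or c) give ``inf``; a zero numerator cell
    gives 0.0.  Callers wanting a finite interval in those cases should
    use :func:`woolf_ci`, which applies the Haldane correction.
    """
    t = _as_table(table)
    if t.b == 0 or t.c == 0:
        return float("inf")
    return (t.a * t.d) / (t.b * t.c)


def woolf_ci(table, level: float = 0.95) -> tuple[float, float]:
    """Woolf confidence interval for the odds ratio.

    With any zero cell, 0.5 is added to every cell (Haldane-Anscombe)
    and the interval is computed on the corrected table.
    """
    t = _as_table(table)
    cells = np.array(t.as_tuple(), dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    a, b, c, d = cells
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(0.5 + level / 2)
    return float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities not
    exceeding that of the observed table)."""
    t = _as_table(table)
    return float(fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")[1])


@dataclass(frozen=True)
class AssociationResult:
    table: ContingencyTable
    or_point: float
    ci_low: float
    ci_high: float
    level: float
    p_two_sided: float
    method: str = "sample-OR/Woolf-CI/Fisher-exact"
    zero_cell_corrected: bool = False


def compute_association(table, level: float = 0.95) -> AssociationResult:
    """Odds ratio, Woolf CI, and Fisher exact p for one 2x2 table."""
    t = _as_table(table)
    lo, hi = woolf_ci(t, level)
    return AssociationResult(
        table=t,
        or_point=odds_ratio(t),
        ci_low=lo,
        ci_high=hi,
        level=level,
        p_two_sided=fisher_exact_two_sided(t),
        zero_cell_corrected=0 in t.as_tuple(),
    )


@dataclass(frozen=True)
class BurdenResult:
    statistic: float  # case allele rate minus control allele rate
    p_value: float
    n_perm: int
    case_rate: float
    control_rate: float


def gene_burden_test(
    pool_counts: Mapping[str, int] | pd.Series,
    pool_labels: Mapping[str, str],
    pool_two_n: Mapping[str, int],
    n_perm: int = 1000,
    seed: int | None = 0,
    pool_stages: Mapping[str, int] | None = None,
) -> BurdenResult:
    """One-sided permutation burden test on pooled allele counts.

    ``pool_counts`` holds the summed rare-variant allele count of the
    gene per pool (every sequenced pool, zeros included);
    ``pool_labels`` maps pool id to ``"case"``/``"control"``.  The
    statistic is the rare-allele rate per chromosome in case pools minus
    control pools; the p-value is the one-sided (enrichment) permutation
    tail over pool-label reassignments, stratified by ``pool_stages``
    when given, with p = (r + 1) / (n_perm + 1).
    """
    pools = sorted(pool_labels)
    counts = np.array([pool_counts.get(p, 0) for p in pools], dtype=float)
    two_n = np.array([pool_two_n[p] for p in pools], dtype=float)
    is_case = np.array([pool_labels[p] == "case" for p in pools])
    if is_case.sum() < 2 or (~is_case).sum() < 2:
        raise ValueError("need at least 2 pools per group")
    strata = (
        np.array([pool_stages[p] for p in pools])
        if pool_stages is not None
        else np.zeros(len(pools), dtype=int)
    )

    def rate_diff(case_mask: np.ndarray) -> float:
        return counts[case_mask].sum() / two_n[case_mask].sum() - counts[
            ~case_mask
        ].sum() / two_n[~case_mask].sum()

    observed = rate_diff(is_case)
    rng = np.random.default_rng(seed)
    # all permuted label masks at once: within each stratum, shuffle the
    # observed labels independently per permutation
    masks = np.tile(is_case, (n_perm, 1))
    for idx in (np.flatnonzero(strata == s) for s in np.unique(strata)):
        order = np.argsort(rng.random((n_perm, len(idx))), axis=1)
        masks[:, idx] = is_case[idx][order]
    case_cnt = masks @ counts
    case_chrom = masks @ two_n
    ctrl_cnt = counts.sum() - case_cnt
    ctrl_chrom = two_n.sum() - case_chrom
    perm_stats = case_cnt / case_chrom - ctrl_cnt / ctrl_chrom
    exceed = int((perm_stats >= observed - 1e-12).sum())
    p = (exceed + 1) / (n_perm + 1)
    return BurdenResult(
        statistic=float(observed),
        p_value=float(p),
        n_perm=n_perm,
        case_rate=float(counts[is_case].sum() / two_n[is_case].sum()),
        control_rate=float(counts[~is_case].sum() / two_n[~is_case].sum()),
    )
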