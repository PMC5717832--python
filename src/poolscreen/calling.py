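"""Pooled allele-count calling, variant discovery, and coverage QC.

Genotypes in a DNA pool of N individuals are observed only through read
counts.  With ``c`` alt alleles among the pool's ``2N`` chromosomes and a
per-base miscall rate ``e`` (spread evenly over the three non-reference
bases), the alt-read fraction is

    p_c = (c/2N)(1 - e) + (1 - c/2N)(e/3)

and the alt-read count is Binomial(depth, p_c).  The caller reports the
maximum-likelihood allele count (uniform prior over 0..2N, ties broken
toward the smaller count, which is conservative for rare variants) and a
quality equal to the log10 likelihood ratio of the best count against
zero.  Joint cross-pool modelling of the kind done by dedicated pooled
callers is deliberately not attempted; the per-pool MAP count is the
quantity every downstream stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

__all__ = [
    "AlleleCountCall",
    "CoverageReport",
    "CallMetrics",
    "estimate_pool_allele_count",
    "call_allele_counts",
    "discover_variants",
    "coverage_qc",
    "evaluate_calls",
]

DEFAULT_MIN_QUALITY = 2.0
DEFAULT_MIN_DEPTH_PER_INDIVIDUAL = 10.0


@dataclass(frozen=True)
class AlleleCountCall:
    estimated_count: int
    quality: float
    margin: float
    depth: int
    alt_count: int
    two_n: int


def _alt_fraction(c: np.ndarray, two_n: int, error_rate: float) -> np.ndarray:
    f = c / two_n
    return f * (1.0 - error_rate) + (1.0 - f) * (error_rate / 3.0)


def _map_counts(
    depth: np.ndarray, alt: np.ndarray, two_n: int, error_rate: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised MAP allele count for one 2N.

    Returns (best count, quality, margin): quality is the log10 LR of
    the best count against zero, margin the log10 LR of the best count
    against the runner-up — a confidence in the count's *resolution*,
    not just the variant's presence.
    """
    c_grid = np.arange(two_n + 1)
    p = _alt_fraction(c_grid, two_n, error_rate)
    p = np.clip(p, 1e-300, 1.0)
    ll = binom.logpmf(alt[:, None], depth[:, None], p[None, :])
    best = np.argmax(ll, axis=1)  # first max = smallest count on ties
    rows = np.arange(len(alt))
    best_ll = ll[rows, best]
    qual = (best_ll - ll[:, 0]) / np.log(10.0)
    masked = ll.copy()
    masked[rows, best] = -np.inf
    margin = (best_ll - masked.max(axis=1)) / np.log(10.0)
    return best, qual, margin


def estimate_pool_allele_count(
    depth: int, alt_count: int, pool_2n: int, error_rate: float = 0.005
) -> AlleleCountCall:
    """MAP allele count for a single (pool, site) observation."""
    if pool_2n <= 0:
        raise ValueError("pool_2n must be positive")
    if depth < 0 or not (0 <= alt_count <= depth):
        raise ValueError("require depth >= 0 and 0 <= alt_count <= depth")
    best, qual, margin = _map_counts(
        np.array([depth]), np.array([alt_count]), pool_2n, error_rate
    )
    return AlleleCountCall(
        estimated_count=int(best[0]),
        quality=float(qual[0]),
        margin=float(margin[0]),
        depth=depth,
        alt_count=alt_count,
        two_n=pool_2n,
    )


def call_allele_counts(
    read_counts: pd.DataFrame,
    pool_sizes: dict[str, int],
    error_rate: float = 0.005,
) -> pd.DataFrame:
    """Estimate allele counts for every row of a read-count table.

    ``read_counts`` needs columns pool_id, site, depth, alt_count;
    ``pool_sizes`` maps pool_id -> number of individuals.  Returns the
    input with ``est_count`` and ``quality`` columns appended.
    """
    missing = set(read_counts["pool_id"]) - set(pool_sizes)
    if missing:
        raise KeyError(f"pools without a size entry: {sorted(missing)[:5]}")
    out = read_counts.copy()
    out["est_count"] = 0
    out["quality"] = 0.0
    out["margin"] = 0.0
    for pool_id, idx in out.groupby("pool_id", sort=False).groups.items():
        two_n = 2 * pool_sizes[pool_id]
        depth = out.loc[idx, "depth"].to_numpy(dtype=np.int64)
        alt = out.loc[idx, "alt_count"].to_numpy(dtype=np.int64)
        best, qual, margin = _map_counts(depth, alt, two_n, error_rate)
        out.loc[idx, "est_count"] = best
        out.loc[idx, "quality"] = qual
        out.loc[idx, "margin"] = margin
    return out


def discover_variants(
    calls: pd.DataFrame,
    pool_sizes: dict[str, int],
    min_quality: float = DEFAULT_MIN_QUALITY,
    min_depth_per_individual: float = DEFAULT_MIN_DEPTH_PER_INDIVIDUAL,
) -> pd.DataFrame:
    """Aggregate per-pool calls into a cohort variant table.

    A site is a variant iff at least one pool shows an estimated count
    >= 1 with quality >= ``min_quality`` at a depth of at least
    ``min_depth_per_individual`` per pool member.  The cohort allele
    count AC sums estimated counts over all pools passing the depth QC
    at that site (a nonzero count contributes only when its quality
    clears ``min_quality`` — sub-threshold blips do not inflate AC),
    AN sums their chromosomes, and AF = AC/AN.

    Returns a frame indexed by site with AC, AN, AF, n_positive_pools,
    and the list of variant-positive pools (with their counts).
    """
    if calls.empty:
        return pd.DataFrame(
            columns=["site", "AC", "AN", "AF", "n_positive_pools", "positive_pools"]
        ).set_index("site")
    df = calls.copy()
    sizes = df["pool_id"].map(pool_sizes)
    df["two_n"] = 2 * sizes
    df["depth_ok"] = df["depth"] >= min_depth_per_individual * sizes
    df["is_positive"] = (
        (df["est_count"] >= 1) & (df["quality"] >= min_quality) & df["depth_ok"]
    )
    qc = df[df["depth_ok"]].copy()
    qc["counted"] = np.where(qc["quality"] >= min_quality, qc["est_count"], 0)
    ac = qc.groupby("site")["counted"].sum()
    an = qc.groupby("site")["two_n"].sum()
    pos = df[df["is_positive"]]
    if pos.empty:
        return pd.DataFrame(
            columns=["site", "AC", "AN", "AF", "n_positive_pools", "positive_pools"]
        ).set_index("site")
    pos_pools = pos.groupby("site").apply(
        lambda g: list(zip(g["pool_id"], g["est_count"])), include_groups=False
    )
    variant_sites = pos_pools.index
    table = pd.DataFrame(
        {
            "AC": ac.reindex(variant_sites).astype(int),
            "AN": an.reindex(variant_sites).astype(int),
            "n_positive_pools": pos_pools.str.len(),
            "positive_pools": pos_pools,
        }
    )
    table["AF"] = table["AC"] / table["AN"]
    table.index.name = "site"
    return table[["AC", "AN", "AF", "n_positive_pools", "positive_pools"]]


@dataclass
class CoverageReport:
    """Per-pool covered fractions and systematically low-coverage exons."""

    per_pool_fraction: pd.Series
    exon_median_depth: pd.DataFrame  # exon_id x pool_id
    flagged_exons: list[str]
    threshold_per_individual: float


def coverage_qc(
    read_counts: pd.DataFrame,
    pool_sizes: dict[str, int],
    site_exons: pd.Series | None = None,
    per_individual_threshold: float = DEFAULT_MIN_DEPTH_PER_INDIVIDUAL,
    flag_pool_fraction: float = 0.9,
) -> CoverageReport:
    """Coverage QC over a depth table.

    Per pool, reports the fraction of sites with depth at least
    ``per_individual_threshold`` x pool size (e.g. 200x for pools of 20
    at the default 10x per individual).  When ``site_exons`` maps site ->
    exon_id, exons whose median depth falls below that threshold in at
    least ``flag_pool_fraction`` of pools are flagged.
    """
    if (read_counts["depth"] < 0).any():
        raise ValueError("depths must be non-negative")
    df = read_counts.copy()
    thresh = df["pool_id"].map(lambda p: per_individual_threshold * pool_sizes[p])
    df["covered"] = df["depth"] >= thresh
    per_pool = df.groupby("pool_id")["covered"].mean()
    per_pool.name = "fraction_covered"

    flagged: list[str] = []
    exon_median = pd.DataFrame()
    if site_exons is not None:
        df["exon_id"] = df["site"].map(site_exons)
        exon_median = df.pivot_table(
            index="exon_id", columns="pool_id", values="depth", aggfunc="median"
        )
        below = exon_median.lt(
            pd.Series({p: per_individual_threshold * n for p, n in pool_sizes.items()}),
            axis=1,
        )
        frac_below = below.mean(axis=1)
        flagged = sorted(frac_below.index[frac_below >= flag_pool_fraction])
    return CoverageReport(
        per_pool_fraction=per_pool,
        exon_median_depth=exon_median,
        flagged_exons=flagged,
        threshold_per_individual=per_individual_threshold,
    )


@dataclass(frozen=True)
class CallMetrics:
    n_true: int
    n_called: int
    n_overlap: int
    sensitivity: float
    fn_rate: float
    fp_rate: float


def evaluate_calls(called_sites, true_sites) -> CallMetrics:
    """Compare a called variant set against simulation truth.

    FN rate = missed true variants / true variants; FP rate =
    called-but-absent / called.  Accepts any iterables of site keys
    (a discover_variants table's index works directly).
    """
    called = set(called_sites)
    truth = set(true_sites)
    overlap = called & truth
    n_true, n_called = len(truth), len(called)
    fn = (n_true - len(overlap)) / n_true if n_true else 0.0
    fp = (n_called - len(overlap)) / n_called if n_called else 0.0
    return CallMetrics(
        n_true=n_true,
        n_called=n_called,
        n_overlap=len(overlap),
        sensitivity=1.0 - fn,
        fn_rate=fn,
        fp_rate=fp,
    )
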