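"""Parsimonious carrier decoding across orthogonal pool stages.

A rare variant observed in pooled data is visible only as per-pool
allele counts.  Because every individual was sequenced in one pool per
stage and stage-3 pools overlap stage-1/2 pools in at most one or two
members, the pattern of variant-positive pools constrains — often
uniquely — which individuals carry the variant.  "Parsimonious" is
operationalised as: minimise the number of carrier individuals first,
then the total allele count; all minimal assignments that reproduce
every confident pool count exactly are reported, so ties surface as
ambiguity rather than being silently resolved.

Confidently-negative pools (adequate depth, estimated count 0) are hard
constraints: their members cannot carry the variant.  Low-coverage
negative pools are ignored, mirroring how real screens explain
expected-versus-observed discrepancies by missing coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CarrierSolution",
    "ConsistencyResult",
    "decode_carriers",
    "check_stage_consistency",
    "summarize_partial_attributes",
]


@dataclass
class CarrierSolution:
    """All minimal carrier assignments for one variant.

    ``solutions`` is a list of ``{individual_id: copies}`` dicts; status
    is ``unique`` (exactly one minimal solution), ``ambiguous`` (several)
    or ``discrepant`` (no assignment reproduces the pool counts).
    """

    site: str | None
    solutions: list[dict[str, int]]
    status: str

    @property
    def n_solutions(self) -> int:
        return len(self.solutions)

    @property
    def candidate_carriers(self) -> set[str]:
        """Union of carriers over all minimal solutions."""
        return {i for sol in self.solutions for i in sol}


def decode_carriers(
    positive_pools: Mapping[str, int],
    membership: Mapping[str, Iterable[str]],
    negative_pools: Iterable[str] = (),
    site: str | None = None,
    max_copies: int = 2,
) -> CarrierSolution:
    """Find all minimum-cardinality carrier assignments.

    ``positive_pools`` maps variant-positive pool ids (across all
    stages) to their estimated allele counts; ``membership`` maps every
    referenced pool id to its member ids; ``negative_pools`` lists pools
    confidently negative at this site.  An assignment gives each
    candidate 0..``max_copies`` alleles such that every positive pool's
    implied count equals its estimated count and no confidently-negative
    pool member carries an allele.  The search is exact (depth-first
    with residual-capacity and objective bounds) over the union of
    members of positive pools.
    """
    for pid in list(positive_pools) + list(negative_pools):
        if pid not in membership:
            raise KeyError(f"pool {pid} absent from membership index")
    if any(c < 1 for c in positive_pools.values()):
        raise ValueError("positive pools must have count >= 1")

    excluded = {m for pid in negative_pools for m in membership[pid]}
    candidates = sorted(
        {m for pid in positive_pools for m in membership[pid]} - excluded
    )
    pool_ids = sorted(positive_pools)
    residual = [positive_pools[p] for p in pool_ids]
    member_pools: dict[str, list[int]] = {m: [] for m in candidates}
    for k, pid in enumerate(pool_ids):
        for m in membership[pid]:
            if m in member_pools:
                member_pools[m].append(k)
    # capacity[k] = max alleles still assignable to pool k from unprocessed candidates
    capacity = [0] * len(pool_ids)
    for m in candidates:
        for k in member_pools[m]:
            capacity[k] += max_copies

    best: list[tuple[int, int]] = [(len(candidates) + 1, 10 ** 9)]
    solutions: list[dict[str, int]] = []

    def dfs(idx: int, carriers: int, total: int, current: dict[str, int]) -> None:
        obj = (carriers, total)
        if obj > best[0]:
            return
        if any(r > c for r, c in zip(residual, capacity)):
            return
        if idx == len(candidates):
            if any(residual):
                return
            if obj < best[0]:
                best[0] = obj
                solutions.clear()
            solutions.append(dict(current))
            return
        m = candidates[idx]
        pools_m = member_pools[m]
        for k in pools_m:
            capacity[k] -= max_copies
        cap = min((residual[k] for k in pools_m), default=0)
        for x in range(0, min(max_copies, cap) + 1):
            if x:
                for k in pools_m:
                    residual[k] -= x
                current[m] = x
            dfs(idx + 1, carriers + (x > 0), total + x, current)
            if x:
                for k in pools_m:
                    residual[k] += x
                del current[m]
        for k in pools_m:
            capacity[k] += max_copies

    dfs(0, 0, 0, {})
    status = (
        "discrepant"
        if not solutions
        else ("unique" if len(solutions) == 1 else "ambiguous")
    )
    return CarrierSolution(site=site, solutions=solutions, status=status)


@dataclass
class ConsistencyResult:
    status: str  # consistent | discrepant | unresolvable
    expected: tuple[int, int]  # feasible [lo, hi] stage-3 allele total
    observed: int


def check_stage_consistency(
    stage12_pools: Mapping[str, int],
    stage3_pools: Mapping[str, int],
    membership: Mapping[str, Iterable[str]],
    sequenced_ids: set[str],
    low_coverage_pools: Iterable[str] = (),
    site: str | None = None,
    max_copies: int = 2,
) -> ConsistencyResult:
    """Expected-versus-observed allele-count consistency across stages.

    Under any stage-1/2-consistent carrier assignment, the alleles
    attributable to individuals re-sequenced in stage 3 form a feasible
    interval: each stage-1/2 positive pool with count ``c`` over members
    ``M`` can place between ``max(0, c - max_copies*|M \\ S|)`` and
    ``min(c, max_copies*|M & S|)`` alleles on the re-sequenced subset
    ``S``.  The observed stage-3 total must fall in the sum of these
    intervals to be consistent.  If it does not and any relevant
    stage-1/2 pool had low coverage at the site, the case is
    ``unresolvable`` (missing data can explain it) rather than
    ``discrepant``.
    """
    low_cov = set(low_coverage_pools)
    lo = hi = 0
    for pid, c in stage12_pools.items():
        if pid not in membership:
            raise KeyError(f"pool {pid} absent from membership index")
        members = set(membership[pid])
        in_s = len(members & sequenced_ids)
        out_s = len(members) - in_s
        lo += max(0, c - max_copies * out_s)
        hi += min(c, max_copies * in_s)
    observed = sum(stage3_pools.values())
    if lo <= observed <= hi:
        status = "consistent"
    elif low_cov & (set(stage12_pools) | set(stage3_pools)) or (
        not stage12_pools and low_cov
    ):
        status = "unresolvable"
    else:
        status = "discrepant"
    return ConsistencyResult(status=status, expected=(lo, hi), observed=observed)


def summarize_partial_attributes(
    solution: CarrierSolution,
    phenotypes: pd.DataFrame,
    attribute: str,
) -> set:
    """Attribute values over all candidate carriers.

    Even when the carrier is ambiguous, a singleton value set identifies
    the attribute (e.g. the age at diagnosis) without identifying the
    individual.  ``phenotypes`` must carry an ``id`` column or be
    indexed by id.
    """
    if solution.status == "discrepant":
        raise ValueError("no carrier solutions to summarise")
    pheno = phenotypes.set_index("id") if "id" in phenotypes.columns else phenotypes
    if attribute not in pheno.columns:
        raise KeyError(f"unknown attribute {attribute!r}")
    values = set()
    for ind in solution.candidate_carriers:
        if ind not in pheno.index:
            raise KeyError(f"individual {ind} absent from phenotype table")
        values.add(pheno.loc[ind, attribute])
    return values
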