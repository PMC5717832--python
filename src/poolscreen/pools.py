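"""Phenotype-homogeneous and orthogonal DNA-pool designs.

Stages 1 and 2 of a pooled screen partition cases and controls into
stratum-pure pools (all members share case/control status and, where
requested, onset group).  Stage 3 re-pools a subset of already-sequenced
individuals *orthogonally*: any stage-3 pool shares at most
``max_overlap`` members with any earlier pool, so that the intersection
pattern of variant-positive pools pinpoints the carriers of rare
variants (group testing).
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Pool",
    "PoolDesign",
    "InfeasibleDesignError",
    "design_stratified_pools",
    "design_orthogonal_pools",
    "max_pairwise_overlap",
]


class InfeasibleDesignError(RuntimeError):
    """Raised when no pool assignment can satisfy the overlap constraints."""


@dataclass(frozen=True)
class Pool:
    pool_id: str
    stage: int
    stratum: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"pool {self.pool_id} has duplicate members")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def two_n(self) -> int:
        """Number of chromosomes in the pool."""
        return 2 * len(self.members)


@dataclass
class PoolDesign:
    pools: list[Pool] = field(default_factory=list)

    def __post_init__(self) -> None:
        # within one stage, pools partition their individuals
        seen: dict[tuple[int, str], str] = {}
        for pool in self.pools:
            for m in pool.members:
                key = (pool.stage, m)
                if key in seen:
                    raise ValueError(
                        f"individual {m} in both {seen[key]} and {pool.pool_id} "
                        f"(stage {pool.stage})"
                    )
                seen[key] = pool.pool_id

    def __len__(self) -> int:
        return len(self.pools)

    @property
    def individuals(self) -> set[str]:
        return {m for p in self.pools for m in p.members}

    def membership(self) -> dict[str, str]:
        """individual id -> pool id; requires each individual to be in a
        single pool across the whole design (true for one-stage designs
        and for the disjoint stage-1/2 union)."""
        out: dict[str, str] = {}
        for p in self.pools:
            for m in p.members:
                if m in out:
                    raise ValueError(f"individual {m} is in more than one pool")
                out[m] = p.pool_id
        return out

    def pool_map(self) -> dict[str, Pool]:
        return {p.pool_id: p for p in self.pools}

    def pool_sizes(self) -> dict[str, int]:
        return {p.pool_id: p.size for p in self.pools}


def design_stratified_pools(
    individuals,
    pool_size: int,
    strata: dict[str, str] | None = None,
    stage: int = 1,
    seed: int = 0,
    prefix: str | None = None,
) -> PoolDesign:
    """Partition individuals into stratum-pure pools of ``pool_size``.

    ``individuals`` is an iterable of ids; ``strata`` maps id -> stratum
    label (a single implicit stratum when omitted).  Within each stratum
    the ids are canonically sorted, shuffled under ``seed``, and chunked;
    the final pool of a stratum may be smaller (a warning is emitted).
    The number of pools per stratum is ``ceil(stratum size / pool_size)``.
    """
    if pool_size < 2:
        raise ValueError("pool_size must be >= 2")
    ids = list(individuals)
    if strata is None:
        strata = {i: "all" for i in ids}
    by_stratum: dict[str, list[str]] = defaultdict(list)
    for i in ids:
        by_stratum[strata[i]].append(i)
    rng = np.random.default_rng(seed)
    pools: list[Pool] = []
    tag = prefix if prefix is not None else f"S{stage}"
    for stratum in sorted(by_stratum):
        members = sorted(by_stratum[stratum])
        if not members:
            continue
        order = rng.permutation(len(members))
        shuffled = [members[k] for k in order]
        n_pools = math.ceil(len(shuffled) / pool_size)
        for k in range(n_pools):
            chunk = tuple(shuffled[k * pool_size : (k + 1) * pool_size])
            if len(chunk) < pool_size:
                warnings.warn(
                    f"stratum {stratum!r}: final pool has {len(chunk)} members "
                    f"(pool size {pool_size})",
                    stacklevel=2,
                )
            pools.append(
                Pool(
                    pool_id=f"{tag}_{stratum}_{k + 1:03d}",
                    stage=stage,
                    stratum=stratum,
                    members=chunk,
                )
            )
    return PoolDesign(pools)


def _greedy_fill(
    groups: list[tuple[str, list[str]]],
    n_new: int,
    pool_size: int,
    max_overlap: int,
    rng: np.random.Generator,
    max_backtrack: int,
) -> list[list[str]] | None:
    """Assign members to ``n_new`` pools with per-base-pool quota
    ``max_overlap`` and capacity ``pool_size``, transversal-first:
    largest base-pool groups are dealt first, each member to the most
    open admissible pool.  Depth-first backtracking (bounded by
    ``max_backtrack`` steps) covers the rare dead ends."""
    members: list[str] = []
    group_of: list[int] = []
    for g, (_, mem) in enumerate(groups):
        mem = list(mem)
        rng.shuffle(mem)
        for m in mem:
            members.append(m)
            group_of.append(g)
    capacity = [pool_size] * n_new
    quota = [[max_overlap] * n_new for _ in range(len(groups))]
    assignment: list[int] = []
    # stack of candidate lists per position
    stack: list[list[int]] = []
    steps = 0

    def candidates(pos: int) -> list[int]:
        g = group_of[pos]
        cands = [
            j for j in range(n_new) if capacity[j] > 0 and quota[g][j] > 0
        ]
        cands.sort(key=lambda j: (-capacity[j], j))
        return cands

    pos = 0
    stack.append(candidates(0))
    while True:
        if pos == len(members):
            out: list[list[str]] = [[] for _ in range(n_new)]
            for k, j in enumerate(assignment):
                out[j].append(members[k])
            return out
        if not stack[pos]:
            # backtrack
            steps += 1
            if steps > max_backtrack or pos == 0:
                return None
            pos -= 1
            j = assignment.pop()
            capacity[j] += 1
            quota[group_of[pos]][j] += 1
            continue
        j = stack[pos].pop(0)
        assignment.append(j)
        capacity[j] -= 1
        quota[group_of[pos]][j] -= 1
        pos += 1
        if pos < len(members):
            if len(stack) > pos:
                stack[pos] = candidates(pos)
            else:
                stack.append(candidates(pos))
        else:
            stack.append([])


def design_orthogonal_pools(
    base_design: PoolDesign,
    subset_ids,
    pool_size: int,
    max_overlap: int = 1,
    stage: int = 3,
    strata: dict[str, str] | None = None,
    seed: int = 0,
    max_backtrack: int = 10_000,
    max_restarts: int = 5,
    prefix: str = "S3",
) -> PoolDesign:
    """Re-pool ``subset_ids`` so every new pool shares at most
    ``max_overlap`` members with every pool of ``base_design``.

    When ``strata`` is given the construction runs independently per
    stratum (e.g. to keep stage-3 pools homogeneous by onset group);
    by default stratum purity is not enforced.  The returned design is
    verified against :func:`max_pairwise_overlap` before being returned.

    Raises :class:`InfeasibleDesignError` when a base pool contributes
    more members than ``max_overlap`` times the number of new pools, or
    when the bounded backtracking search exhausts its restarts.
    """
    if max_overlap < 1:
        raise ValueError("max_overlap must be >= 1")
    if pool_size < 2:
        raise ValueError("pool_size must be >= 2")
    subset = sorted(set(subset_ids))
    base_members = base_design.individuals
    outside = [i for i in subset if i not in base_members]
    if outside:
        raise ValueError(f"subset ids not in base design: {outside[:5]}")
    membership = base_design.membership()

    strata = strata if strata is not None else {i: "all" for i in subset}
    by_stratum: dict[str, list[str]] = defaultdict(list)
    for i in subset:
        by_stratum[strata[i]].append(i)

    pools: list[Pool] = []
    for stratum in sorted(by_stratum):
        ids = by_stratum[stratum]
        n_new = math.ceil(len(ids) / pool_size)
        grouped: dict[str, list[str]] = defaultdict(list)
        for i in ids:
            grouped[membership[i]].append(i)
        for base_id, mem in grouped.items():
            if len(mem) > max_overlap * n_new:
                raise InfeasibleDesignError(
                    f"base pool {base_id} contributes {len(mem)} subset members "
                    f"but only {max_overlap} x {n_new} new pools are available"
                )
        groups = sorted(grouped.items(), key=lambda kv: (-len(kv[1]), kv[0]))
        filled = None
        for attempt in range(max_restarts + 1):
            rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
            filled = _greedy_fill(
                [(k, list(v)) for k, v in groups],
                n_new,
                pool_size,
                max_overlap,
                rng,
                max_backtrack,
            )
            if filled is not None:
                break
        if filled is None:
            raise InfeasibleDesignError(
                f"no overlap-{max_overlap} design found for stratum {stratum!r} "
                f"after {max_restarts + 1} attempts"
            )
        for k, mem in enumerate(filled):
            if mem:
                pools.append(
                    Pool(
                        pool_id=f"{prefix}_{stratum}_{k + 1:03d}",
                        stage=stage,
                        stratum=stratum,
                        members=tuple(sorted(mem)),
                    )
                )
    design = PoolDesign(pools)
    achieved = max_pairwise_overlap(base_design, design)
    if achieved > max_overlap:
        raise InfeasibleDesignError(
            f"constructed design violates overlap bound: {achieved} > {max_overlap}"
        )
    return design


def max_pairwise_overlap(design_a: PoolDesign, design_b: PoolDesign) -> int:
    """Largest |intersection| over all pool pairs (one from each design);
    0 when the designs share no individuals."""
    pool_a = design_a.membership()
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for pool in design_b.pools:
        for m in pool.members:
            a = pool_a.get(m)
            if a is not None:
                counts[(a, pool.pool_id)] += 1
    return max(counts.values(), default=0)
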