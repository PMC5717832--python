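"""Carrier decoding: forced intersections, ambiguity, consistency."""

import numpy as np
import pandas as pd
import pytest

from poolscreen.decoding import (
    check_stage_consistency,
    decode_carriers,
    summarize_partial_attributes,
)


def _pheno(ages):
    rows = []
    for ind, age in ages.items():
        rows.append(
            {
                "id": ind,
                "status": "case" if age is not None else "control",
                "age_at_diagnosis": age,
            }
        )
    return pd.DataFrame(rows)


def test_singleton_forced_by_intersection():
    membership = {
        "P7": [f"a{i}" for i in range(19)] + ["i42"],
        "Q3": [f"b{i}" for i in range(23)] + ["i42"],
    }
    sol = decode_carriers({"P7": 1, "Q3": 1}, membership)
    assert sol.status == "unique"
    assert sol.solutions == [{"i42": 1}]


def test_two_carriers_from_disjoint_stage3_intersections():
    membership = {
        "P1": ["i5", "i9"] + [f"a{i}" for i in range(18)],
        "Q1": ["i5"] + [f"b{i}" for i in range(23)],
        "Q2": ["i9"] + [f"c{i}" for i in range(23)],
    }
    sol = decode_carriers({"P1": 2, "Q1": 1, "Q2": 1}, membership)
    assert sol.status == "unique"
    assert sol.solutions == [{"i5": 1, "i9": 1}]


def test_discrepant_when_unsatisfiable():
    # stage-1 pool positive but the member resequenced in stage 3 sits in
    # a confidently negative pool
    membership = {"P1": ["x1"], "Q1": ["x1", "y1"]}
    sol = decode_carriers({"P1": 1}, membership, negative_pools=["Q1"])
    assert sol.status == "discrepant"
    assert sol.solutions == []


def test_homozygote_preferred_over_two_hets_and_ties_are_ambiguous():
    # one pool with count 2 and a second pool pinning the carrier: the
    # 1-carrier homozygous solution beats two hets
    membership = {"P1": ["a", "b", "c"], "Q1": ["a", "z"]}
    sol = decode_carriers({"P1": 2, "Q1": 2}, membership)
    assert sol.status == "unique"
    assert sol.solutions == [{"a": 2}]
    # without the pinning pool, hom-a / hom-b / hom-c tie: ambiguous
    tie = decode_carriers({"P1": 2}, {"P1": ["a", "b", "c"]})
    assert tie.status == "ambiguous"
    assert tie.n_solutions == 3
    assert all(list(s.values()) == [2] for s in tie.solutions)


def test_unknown_pool_raises():
    with pytest.raises(KeyError):
        decode_carriers({"nope": 1}, {"P1": ["a"]})


def _exhaustive_oracle(positive, membership, max_copies=2):
    """Enumerate every assignment over candidate individuals."""
    candidates = sorted({m for p in positive for m in membership[p]})
    n = len(candidates)
    pools = sorted(positive)
    mat = np.array(
        [[m in set(membership[p]) for m in candidates] for p in pools], dtype=np.int64
    )
    req = np.array([positive[p] for p in pools])
    grid = (
        np.arange((max_copies + 1) ** n)[:, None]
        // (max_copies + 1) ** np.arange(n)
    ) % (max_copies + 1)
    ok = (grid @ mat.T == req).all(axis=1)
    feas = grid[ok]
    if not len(feas):
        return []
    carriers = (feas > 0).sum(axis=1)
    totals = feas.sum(axis=1)
    order = np.lexsort((totals, carriers))
    best_c, best_t = carriers[order[0]], totals[order[0]]
    minimal = feas[(carriers == best_c) & (totals == best_t)]
    return sorted(
        tuple((candidates[j], int(x)) for j, x in enumerate(row) if x)
        for row in minimal
    )


def test_decoder_matches_exhaustive_enumeration_small():
    rng = np.random.default_rng(42)
    people = [f"i{k}" for k in range(9)]
    for trial in range(30):
        n_pools = rng.integers(1, 4)
        membership = {}
        for p in range(n_pools):
            size = rng.integers(1, 6)
            membership[f"P{p}"] = list(rng.choice(people, size=size, replace=False))
        positive = {p: int(rng.integers(1, 4)) for p in membership}
        sol = decode_carriers(positive, membership)
        oracle = _exhaustive_oracle(positive, membership)
        got = sorted(tuple(sorted(s.items())) for s in sol.solutions)
        assert got == oracle, f"trial {trial}: {positive} {membership}"


def _feasible_assignments(positive, membership, max_copies=2):
    """All assignments over candidates that reproduce every pool count."""
    candidates = sorted({m for p in positive for m in membership[p]})
    pools = sorted(positive)
    mat = np.array(
        [[m in set(membership[p]) for m in candidates] for p in pools], dtype=np.int64
    )
    req = np.array([positive[p] for p in pools])
    n = len(candidates)
    grid = (
        np.arange((max_copies + 1) ** n)[:, None]
        // (max_copies + 1) ** np.arange(n)
    ) % (max_copies + 1)
    ok = (grid @ mat.T == req).all(axis=1)
    return {
        tuple((candidates[j], int(x)) for j, x in enumerate(row) if x)
        for row in grid[ok]
    }


def test_extra_consistent_pool_only_prunes_feasible_assignments():
    """A positive pool consistent with the planted carriers never adds
    feasible assignments (over the shared candidates) and never rules
    out the planted assignment itself."""
    rng = np.random.default_rng(7)
    people = [f"i{k}" for k in range(9)]
    checked = 0
    for trial in range(40):
        planted = {
            str(m): 1 for m in rng.choice(people, size=2, replace=False)
        }
        pools = {
            f"P{p}": [str(m) for m in rng.choice(people, size=5, replace=False)]
            for p in range(3)
        }
        positive = {
            p: sum(planted.get(m, 0) for m in mem) for p, mem in pools.items()
        }
        positive = {p: c for p, c in positive.items() if c > 0}
        if len(positive) < 2:
            continue
        items = sorted(positive)
        partial = {p: positive[p] for p in items[:-1]}
        before = _feasible_assignments(partial, pools)
        after = _feasible_assignments(positive, pools)
        partial_candidates = {m for p in partial for m in pools[p]}
        projected = {
            tuple((m, x) for m, x in sol if m in partial_candidates) for sol in after
        }
        assert projected <= before
        full_truth = tuple(
            sorted((m, x) for m, x in planted.items() if any(m in pools[p] for p in positive))
        )
        assert full_truth in {tuple(sorted(s)) for s in after}
        checked += 1
    assert checked >= 10


def test_consistency_singleton_resequenced():
    membership = {"P1": ["a", "b"], "Q1": ["a", "z"]}
    res = check_stage_consistency({"P1": 1}, {"Q1": 1}, membership, {"a", "b", "z"})
    assert res.status == "consistent"
    assert res.expected == (1, 1)
    assert res.observed == 1


def test_consistency_low_coverage_is_unresolvable():
    membership = {"P1": ["a", "b"], "Q1": ["a", "z"]}
    res = check_stage_consistency(
        {"P1": 1}, {}, membership, {"a", "b", "z"}, low_coverage_pools={"P1"}
    )
    # expected one allele in stage 3, none observed, but the stage-1 pool
    # was poorly covered: flagged, not declared contradictory
    assert res.status == "unresolvable"


def test_consistency_observed_outside_feasible_set():
    membership = {"P1": ["a", "b"], "Q1": ["a", "z"]}
    # only "a" resequenced; P1 holds 1 allele on {a, b}: feasible {0, 1}
    res = check_stage_consistency({"P1": 1}, {"Q1": 2}, membership, {"a", "z"})
    assert res.expected == (0, 1)
    assert res.status == "discrepant"


def test_partial_attributes():
    pheno = _pheno({"u1": 14.0, "v1": 33.0, "v2": 33.0, "w1": 29.0, "w2": 51.0})
    unique = decode_carriers({"P": 1}, {"P": ["u1"]})
    assert summarize_partial_attributes(unique, pheno, "age_at_diagnosis") == {14.0}
    same_age = decode_carriers({"P": 1}, {"P": ["v1", "v2"]})
    assert same_age.status == "ambiguous"
    assert summarize_partial_attributes(same_age, pheno, "age_at_diagnosis") == {33.0}
    spread = decode_carriers({"P": 1}, {"P": ["w1", "w2"]})
    assert summarize_partial_attributes(spread, pheno, "age_at_diagnosis") == {29.0, 51.0}
    with pytest.raises(KeyError):
        summarize_partial_attributes(unique, pheno, "shoe_size")
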