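"""End-to-end pipeline: simulate -> design -> call -> decode -> associate.

Mirrors the three-stage design of a pooled case-control screen: two
independent sub-cohorts are sequenced in stratum-pure pools (stage 1,
pools of 20; stage 2, pools of 24), then a subset of the cases is
re-sequenced in orthogonal stage-3 pools to validate rare variants and
identify their carriers.  Every stage writes a TSV artifact and the run
manifest records seeds and output hashes, so a rerun with the same
configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as psio
from .calling import call_allele_counts, coverage_qc, discover_variants
from .classify import apply_rare_filter, tally_carriers
from .cohort import Cohort, CohortConfig, generate_cohort, simulate_pool_read_counts
from .decoding import check_stage_consistency, decode_carriers
from .pools import PoolDesign, design_orthogonal_pools, design_stratified_pools
from .stats import ContingencyTable, compute_association, gene_burden_test

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration for a simulated end-to-end run.

    Stage-1 and stage-2 sub-cohort sizes must sum to the cohort sizes in
    ``cohort``.  ``stage3_n_early``/``stage3_n_late`` select the cases
    re-sequenced orthogonally in stage 3.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    stage1_cases: int = 1880
    stage1_controls: int = 1840
    stage1_pool_size: int = 20
    stage2_pool_size: int = 24
    stage3_pool_size: int = 24
    stage3_n_early: int = 1268
    stage3_n_late: int = 746
    max_overlap: int = 2
    min_quality: float = 2.0
    min_depth_per_individual: float = 10.0
    rare_af_threshold: float = 0.002
    decode_max_ac: int = 4
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage1_cases > self.cohort.n_cases:
            raise ValueError("stage1_cases exceeds cohort cases")
        if self.stage1_controls > self.cohort.n_controls:
            raise ValueError("stage1_controls exceeds cohort controls")
        for name in (
            "stage1_pool_size", "stage2_pool_size", "stage3_pool_size",
            "rare_af_threshold", "n_perm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def small(cls, seed: int = 0) -> "PipelineConfig":
        """A reduced-scale configuration for quick runs and tests."""
        return cls(
            cohort=CohortConfig(
                n_cases=400,
                n_controls=280,
                n_sites=400,
                n_pathogenic=6,
                seed=seed,
            ),
            stage1_cases=200,
            stage1_controls=160,
            stage3_pool_size=12,
            stage3_n_early=100,
            stage3_n_late=60,
            n_perm=200,
            seed=seed,
        )

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["cohort"]["af_model"] = dataclasses.asdict(self.cohort.af_model)
        d["cohort"]["coverage"] = dataclasses.asdict(self.cohort.coverage)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        from .cohort import AlleleFrequencyModel, CoverageModel

        d = yaml.safe_load(Path(path).read_text())
        cd = d.pop("cohort", {})
        af = AlleleFrequencyModel(**cd.pop("af_model", {}))
        cov_d = cd.pop("coverage", {})
        if "median_range" in cov_d:
            cov_d["median_range"] = tuple(cov_d["median_range"])
        cov = CoverageModel(**cov_d)
        return cls(cohort=CohortConfig(af_model=af, coverage=cov, **cd), **d)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full simulated screen; returns a dict of result frames.

    Writes eight artifacts under ``outdir``: phenotypes, pool manifest,
    read counts (stages 1-3 combined), variant calls (TSV + VCF),
    coverage report, carrier solutions, carrier tally, association
    table — plus a manifest of seeds and file hashes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    seeds = {
        name: int(ss.generate_state(1)[0] % (2 ** 31))
        for name, ss in zip(
            ["design", "reads1", "reads2", "reads3", "burden"], root.spawn(5)
        )
    }

    with _stage("simulate"):
        cohort = generate_cohort(cfg.cohort)
        psio.write_phenotypes(cohort.individuals, outdir / "phenotypes.tsv")

    with _stage("design"):
        ind = cohort.individuals
        cases = ind.loc[ind["status"] == "case", "id"].tolist()
        controls = ind.loc[ind["status"] == "control", "id"].tolist()
        s1_ids = cases[: cfg.stage1_cases] + controls[: cfg.stage1_controls]
        s2_ids = cases[cfg.stage1_cases :] + controls[cfg.stage1_controls :]
        strata = dict(
            zip(ind["id"], np.where(ind["status"] == "case", "case_" + ind["onset_group"], "control"))
        )
        design1 = design_stratified_pools(
            s1_ids, cfg.stage1_pool_size, {i: strata[i] for i in s1_ids},
            stage=1, seed=seeds["design"], prefix="S1",
        )
        design2 = design_stratified_pools(
            s2_ids, cfg.stage2_pool_size, {i: strata[i] for i in s2_ids},
            stage=2, seed=seeds["design"] + 1, prefix="S2",
        )
        base = PoolDesign(design1.pools + design2.pools)
        case_ind = ind[ind["status"] == "case"]
        early_ids = case_ind.loc[case_ind["onset_group"] == "early", "id"].tolist()
        late_ids = case_ind.loc[case_ind["onset_group"] == "late", "id"].tolist()
        subset = early_ids[: cfg.stage3_n_early] + late_ids[: cfg.stage3_n_late]
        design3 = design_orthogonal_pools(
            base, subset, cfg.stage3_pool_size, cfg.max_overlap, seed=seeds["design"] + 2
        )
        manifest_design = PoolDesign(design1.pools + design2.pools + design3.pools)
        psio.write_pool_manifest(manifest_design, outdir / "pools.tsv")

    with _stage("sequence"):
        counts1 = simulate_pool_read_counts(design1.pools, cohort, rng=seeds["reads1"])
        counts2 = simulate_pool_read_counts(design2.pools, cohort, rng=seeds["reads2"])
        counts3 = simulate_pool_read_counts(design3.pools, cohort, rng=seeds["reads3"])
        counts = pd.concat([counts1, counts2, counts3], ignore_index=True)
        psio.write_read_counts(counts, outdir / "read_counts.tsv")

    with _stage("call"):
        sizes = {
            **design1.pool_sizes(), **design2.pool_sizes(), **design3.pool_sizes(),
        }
        stage_of = {p.pool_id: p.stage for p in manifest_design.pools}
        calls = call_allele_counts(counts, sizes, cfg.cohort.error_rate)
        calls12 = calls[calls["pool_id"].map(stage_of) < 3]
        calls3 = calls[calls["pool_id"].map(stage_of) == 3]
        table12 = discover_variants(
            calls12, sizes, cfg.min_quality, cfg.min_depth_per_individual
        )
        calls.to_csv(outdir / "calls.tsv", sep="\t", index=False)
        if len(table12):
            psio.write_variant_vcf(table12, calls12, outdir / "variants.vcf")

    with _stage("qc"):
        site_exons = cohort.variants.set_index("site")["exon_id"]
        report = coverage_qc(counts, sizes, site_exons, cfg.min_depth_per_individual)
        report.per_pool_fraction.to_frame().assign(
            flagged_exons=";".join(report.flagged_exons)
        ).to_csv(outdir / "coverage_qc.tsv", sep="\t")

    with _stage("decode"):
        membership = {p.pool_id: p.members for p in manifest_design.pools}
        sizes_map = sizes
        rare = table12[table12["AC"] <= cfg.decode_max_ac]
        pos3 = (
            discover_variants(calls3, sizes, cfg.min_quality, cfg.min_depth_per_individual)
            if len(calls3)
            else pd.DataFrame()
        )
        rows = []
        solutions = {}
        for site in rare.index:
            positive = dict(rare.loc[site, "positive_pools"])
            if len(pos3) and site in pos3.index:
                positive.update(dict(pos3.loc[site, "positive_pools"]))
            site_calls = calls[calls["site"] == site]
            confident_neg = [
                r["pool_id"]
                for _, r in site_calls.iterrows()
                if r["est_count"] == 0
                and r["depth"] >= cfg.min_depth_per_individual * sizes_map[r["pool_id"]]
            ]
            sol = decode_carriers(positive, membership, confident_neg, site=site)
            solutions[site] = sol
            stage12_pos = {
                p: c for p, c in positive.items() if stage_of[p] < 3
            }
            stage3_pos = {p: c for p, c in positive.items() if stage_of[p] == 3}
            cons = check_stage_consistency(
                stage12_pos, stage3_pos, membership, set(subset), site=site
            )
            rows.append(
                {
                    "site": site,
                    "status": sol.status,
                    "n_solutions": sol.n_solutions,
                    "carriers": ";".join(
                        "|".join(f"{i}:{x}" for i, x in sorted(s.items()))
                        for s in sol.solutions[:20]
                    ),
                    "consistency": cons.status,
                    "expected_lo": cons.expected[0],
                    "expected_hi": cons.expected[1],
                    "observed_stage3": cons.observed,
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "carriers.tsv", sep="\t", index=False)

    with _stage("classify"):
        truth = cohort.variants.set_index("site")
        pathogenic_sites = truth.index[truth["pathogenic"]]
        carrier_map = {}
        for site in pathogenic_sites:
            if site in solutions and solutions[site].status == "unique":
                carrier_map[site] = sorted(solutions[site].solutions[0])
            else:
                rows_idx = np.flatnonzero(
                    cohort.genotypes[:, truth.index.get_loc(site)] > 0
                )
                carrier_map[site] = cohort.individuals["id"].iloc[rows_idx].tolist()
        tally = tally_carriers(carrier_map, cohort.individuals)
        pd.DataFrame(
            [
                {
                    "group": g,
                    "carriers": getattr(tally, g),
                    "denominator": getattr(tally, f"n_{g}"),
                }
                for g in ("cases", "early", "late", "controls")
            ]
        ).to_csv(outdir / "carrier_tally.tsv", sep="\t", index=False)

    with _stage("associate"):
        assoc_rows = []
        t = ContingencyTable.from_carriers(
            tally.cases, tally.n_cases, tally.controls, tally.n_controls
        )
        res = compute_association(t)
        assoc_rows.append(
            {
                "test": "pathogenic_carriers_case_vs_control",
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                "or": round(res.or_point, 2),
                "ci_low": round(res.ci_low, 2),
                "ci_high": round(res.ci_high, 2),
                "p": res.p_two_sided,
                "method": res.method,
            }
        )
        # gene burden per gene on stage-1/2 pooled counts
        pool_labels = {
            p.pool_id: ("case" if p.stratum.startswith("case") else "control")
            for p in base.pools
        }
        pool_two_n = {p.pool_id: p.two_n for p in base.pools}
        pool_stage = {p.pool_id: p.stage for p in base.pools}
        rare_tab = apply_rare_filter(
            table12.reset_index().assign(population_af=lambda d: d["AF"]),
            cfg.rare_af_threshold,
        ).set_index("site")
        missense_like = truth["func_class"].isin(["missense", "inframe_indel"])
        for gene, gene_truth in truth[missense_like].groupby("gene"):
            gene_sites = [s for s in gene_truth.index if s in rare_tab.index]
            if not gene_sites:
                continue
            gcalls = calls12[
                calls12["site"].isin(gene_sites)
                & (calls12["quality"] >= cfg.min_quality)
            ]
            per_pool = gcalls.groupby("pool_id")["est_count"].sum().to_dict()
            try:
                burden = gene_burden_test(
                    per_pool, pool_labels, pool_two_n,
                    n_perm=cfg.n_perm, seed=seeds["burden"], pool_stages=pool_stage,
                )
            except ValueError:
                continue
            assoc_rows.append(
                {
                    "test": f"burden_{gene}",
                    "a": "", "b": "", "c": "", "d": "",
                    "or": "",
                    "ci_low": "", "ci_high": "",
                    "p": burden.p_value,
                    "method": f"pool-permutation,n_perm={burden.n_perm}",
                }
            )
        pd.DataFrame(assoc_rows).to_csv(outdir / "association.tsv", sep="\t", index=False)

    files = [
        "phenotypes.tsv", "pools.tsv", "read_counts.tsv", "calls.tsv",
        "coverage_qc.tsv", "carriers.tsv", "carrier_tally.tsv", "association.tsv",
    ]
    if (outdir / "variants.vcf").exists():
        files.append("variants.vcf")
    psio.write_manifest(outdir, files, {"root": cfg.seed, **seeds})
    return {
        "cohort": cohort,
        "designs": (design1, design2, design3),
        "variant_table": table12,
        "solutions": solutions,
        "tally": tally,
    }
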