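"""Functional classification, rarity filters, and carrier tallies.

The screen's analysis groups coding variants into protein-truncating
variants (nonsense, canonical splice site, frameshift) and the
missense group (missense SNVs plus in-frame indels), applies strict
minor-allele-frequency filters (default 0.2% for gene-level tests,
0.05% for candidate-deleterious flagging), and tallies distinct carrier
individuals by onset subgroup (early onset = diagnosed before 40).

Three registry fixtures ship with the package, transcribing the
screen's reported mutation lists: protein-truncating variants in MODY
genes (``ptv``), GCK missense/in-frame variants (``gck_missense``), and
previously reported pathogenic missense variants in HNF1A/HNF4A/ABCC8/
INS (``reported_missense``).  ACMG 5-tier labels are input data, not
re-derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "classify_functional",
    "apply_rare_filter",
    "flag_candidate_deleterious",
    "tally_carriers",
    "tally_registry_counts",
    "load_registry",
    "CarrierTally",
]

EARLY_ONSET_CUTOFF = 40.0

#: consequence string -> functional class; in-frame indels join the
#: missense group, frameshifts and splice-site changes are truncating.
_CONSEQUENCE_MAP = {
    "synonymous": "synonymous",
    "synonymous_snv": "synonymous",
    "synonymous_variant": "synonymous",
    "missense": "missense",
    "missense_snv": "missense",
    "missense_variant": "missense",
    "nonsynonymous_snv": "missense",
    "nonframeshift_deletion": "missense",
    "nonframeshift_insertion": "missense",
    "nonframeshift_substitution": "missense",
    "inframe_deletion": "missense",
    "inframe_insertion": "missense",
    "inframe_indel": "missense",
    "stopgain": "PTV",
    "stop_gained": "PTV",
    "nonsense": "PTV",
    "frameshift": "PTV",
    "frameshift_deletion": "PTV",
    "frameshift_insertion": "PTV",
    "frameshift_variant": "PTV",
    "splice": "PTV",
    "splicing": "PTV",
    "splice_site": "PTV",
    "splice_acceptor_variant": "PTV",
    "splice_donor_variant": "PTV",
    "ptv": "PTV",
}


def classify_functional(consequence: str) -> str:
    """Map a consequence string to synonymous / missense / PTV.

    In-frame (non-frameshift) indels map to the missense group.  An
    unrecognised consequence returns ``"unclassified"`` — never silently
    dropped.
    """
    if not consequence or not str(consequence).strip():
        raise ValueError("consequence string required")
    key = str(consequence).strip().lower().replace(" ", "_").replace("-", "_")
    return _CONSEQUENCE_MAP.get(key, "unclassified")


def apply_rare_filter(
    variants: pd.DataFrame,
    af_threshold: float = 0.002,
    af_column: str = "population_af",
) -> pd.DataFrame:
    """Keep variants with minor allele frequency strictly below threshold.

    Missing AF is treated as unobserved (AF 0, kept) — matching how
    absent-from-reference-database entries are handled.  ``af_column``
    selects which frequency the filter uses (population or cohort).
    """
    if af_column not in variants.columns:
        raise KeyError(f"no column {af_column!r} in variant table")
    af = pd.to_numeric(variants[af_column], errors="coerce").fillna(0.0)
    return variants[af < af_threshold]


def flag_candidate_deleterious(
    variants: pd.DataFrame,
    af_threshold: float = 0.0005,
    af_column: str = "population_af",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Candidate-deleterious missense filter.

    Kept iff PolyPhen2 is not benign AND SIFT calls it deleterious AND
    the population minor allele frequency is below ``af_threshold``.
    The expected side condition — MutationTaster disease_causing and
    scaled CADD > 20 — is verified on the kept set; records failing it
    are returned in the second frame for review rather than silently
    accepted or dropped.
    """
    for col in ("polyphen2", "sift"):
        if col not in variants.columns:
            raise KeyError(f"no column {col!r} in variant table")
    af = pd.to_numeric(variants[af_column], errors="coerce").fillna(0.0)
    kept = variants[
        (variants["polyphen2"] != "benign")
        & (variants["sift"] == "deleterious")
        & (af < af_threshold)
    ]
    cadd = pd.to_numeric(kept.get("cadd_scaled"), errors="coerce")
    side_ok = (kept.get("mutationtaster") == "disease_causing") & (cadd > 20)
    return kept, kept[~side_ok.fillna(False)]


@dataclass(frozen=True)
class CarrierTally:
    """Distinct-carrier counts by subgroup with their denominators."""

    cases: int
    early: int
    late: int
    controls: int
    n_cases: int | None = None
    n_early: int | None = None
    n_late: int | None = None
    n_controls: int | None = None

    @property
    def total(self) -> int:
        return self.cases + self.controls

    def frequency(self, group: str) -> float:
        count = getattr(self, group)
        denom = getattr(self, f"n_{group}")
        if denom is None:
            raise ValueError(f"no denominator recorded for {group!r}")
        return count / denom


def tally_carriers(
    carriers: Mapping[str, Iterable[str]],
    phenotypes: pd.DataFrame,
    onset_cutoff: float = EARLY_ONSET_CUTOFF,
) -> CarrierTally:
    """Count distinct carrier individuals by onset subgroup.

    ``carriers`` maps variant site -> iterable of carrier individual
    ids; an individual carrying several registry variants counts once.
    Diagnosis at exactly the cutoff counts as late onset.
    """
    pheno = phenotypes.set_index("id") if "id" in phenotypes.columns else phenotypes
    distinct: set[str] = set()
    for ids in carriers.values():
        distinct.update(ids)
    unknown = distinct - set(pheno.index)
    if unknown:
        raise KeyError(f"carrier ids absent from phenotype table: {sorted(unknown)[:5]}")
    cases = early = late = controls = 0
    for ind in distinct:
        row = pheno.loc[ind]
        if row["status"] == "control":
            controls += 1
        else:
            cases += 1
            if float(row["age_at_diagnosis"]) < onset_cutoff:
                early += 1
            else:
                late += 1
    n_cases = int((pheno["status"] == "case").sum())
    case_ages = pheno.loc[pheno["status"] == "case", "age_at_diagnosis"].astype(float)
    n_early = int((case_ages < onset_cutoff).sum())
    return CarrierTally(
        cases=cases,
        early=early,
        late=late,
        controls=controls,
        n_cases=n_cases,
        n_early=n_early,
        n_late=n_cases - n_early,
        n_controls=int((pheno["status"] == "control").sum()),
    )


def tally_registry_counts(registry: pd.DataFrame) -> CarrierTally:
    """Sum a registry fixture's per-variant carrier-count columns.

    Registry fixtures record one carrier per count (each variant's
    carriers are distinct individuals), so column sums are distinct-
    carrier tallies.
    """
    cases = int(registry["cases"].sum())
    early = int(registry["early_onset"].sum())
    return CarrierTally(
        cases=cases,
        early=early,
        late=cases - early,
        controls=int(registry["controls"].sum()),
    )


_REGISTRY_FILES = {
    "ptv": "table1_ptv_registry.tsv",
    "gck_missense": "table2_gck_missense.tsv",
    "reported_missense": "table3_reported_missense.tsv",
}


def load_registry(name: str) -> pd.DataFrame:
    """Load a packaged registry fixture (``ptv``, ``gck_missense`` or
    ``reported_missense``)."""
    if name not in _REGISTRY_FILES:
        raise KeyError(f"unknown registry {name!r}; choose from {sorted(_REGISTRY_FILES)}")
    ref = resources.files("poolscreen.data") / _REGISTRY_FILES[name]
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"prior_mody_report": "string"})
    return df
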