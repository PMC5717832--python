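import numpy as np
import pandas as pd
import pytest

from poolscreen.cohort import Cohort, CohortConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_manual_cohort(genotypes: np.ndarray, n_cases: int | None = None) -> Cohort:
    """Build a cohort directly from a genotype matrix (rows=individuals)."""
    n, m = genotypes.shape
    n_cases = n if n_cases is None else n_cases
    ids = [f"I{k:03d}" for k in range(n)]
    status = ["case"] * n_cases + ["control"] * (n - n_cases)
    ages = [30.0 if s == "case" else np.nan for s in status]
    individuals = pd.DataFrame(
        {
            "id": ids,
            "status": status,
            "age_at_diagnosis": ages,
            "onset_group": ["early" if s == "case" else "control" for s in status],
        }
    )
    variants = pd.DataFrame(
        {
            "site": [f"target1:{1000 + j}:A:G" for j in range(m)],
            "chrom": "target1",
            "pos": np.arange(1000, 1000 + m),
            "ref": "A",
            "alt": "G",
            "gene": "GCK",
            "exon_id": "GCK_ex1",
            "low_coverage": False,
            "func_class": "missense",
            "true_af": 0.001,
            "pathogenic": False,
            "effect_or": 1.0,
        }
    )
    cfg = CohortConfig(n_cases=max(n_cases, 1), n_controls=max(n - n_cases, 1))
    return Cohort(
        individuals=individuals,
        variants=variants,
        genotypes=genotypes.astype(np.int8),
        config=cfg,
    )
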