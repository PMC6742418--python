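import warnings

import numpy as np
import pytest

from mistloo.types import CohortData, RegionData, VariantRecord

# quadrature warnings from the chi-square-mixture tail are expected noise
warnings.filterwarnings("ignore", message=".*maximum number of subdivisions.*")
warnings.filterwarnings("ignore", message=".*probably divergent.*")


CLASSES = ["missense", "nonframeshift_indel", "frameshift", "nonsense",
           "splicing"]
CLASS_PROBS = [0.80, 0.04, 0.06, 0.05, 0.05]


def random_region(rng: np.random.Generator, n_samples: int, n_variants: int,
                  maf_lo: float = 1e-4, maf_hi: float = 0.01,
                  gene: str = "GENE") -> RegionData:
    """A null region with the generator's rare-variant structure."""
    maf = np.exp(rng.uniform(np.log(maf_lo), np.log(maf_hi), n_variants))
    G = rng.binomial(2, maf, (n_samples, n_variants)).astype(float)
    pos = np.sort(rng.choice(10 ** 6, n_variants, replace=False)) + 1
    variants = [
        VariantRecord("1", int(p), "A", "C", gene,
                      str(rng.choice(CLASSES, p=CLASS_PROBS)),
                      float(rng.uniform(0, 30)))
        for p in pos
    ]
    return RegionData(gene=gene, variants=variants, G=G)


def balanced_cohort(n_cases: int, n_controls: int) -> CohortData:
    n = n_cases + n_controls
    return CohortData(
        sample_ids=[f"s{i}" for i in range(n)],
        y=np.concatenate([np.ones(n_cases), np.zeros(n_controls)]),
        X=np.ones((n, 1)),
    )


@pytest.fixture(scope="session")
def small_cohort() -> CohortData:
    """130 cases / 270 controls, intercept-only covariates."""
    return balanced_cohort(130, 270)


@pytest.fixture(scope="session")
def worked_example():
    from mistloo.simdata import make_worked_example

    return make_worked_example(seed=0)
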