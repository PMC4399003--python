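import numpy as np
import pytest

from haph import CohortSimConfig, simulate_cohort
from haph.io_formats import GenotypeMatrix, VariantRecord


@pytest.fixture
def small_matrix() -> GenotypeMatrix:
    """Four samples, three variants; v1+v2 share carriers (cis pair)."""
    gts = {
        "v1": [1, 1, 0, 0],
        "v2": [1, 1, 0, 0],
        "v3": [0, 1, 2, -1],
    }
    records = [
        VariantRecord("1", 100, "G", "A", np.array(gts["v1"]), gene="GENEA",
                      var_class="nonsynonymous SNV"),
        VariantRecord("1", 112, "G", "A", np.array(gts["v2"]), gene="GENEA",
                      var_class="nonsynonymous SNV"),
        VariantRecord("2", 500, "C", "T", np.array(gts["v3"]), gene="GENEB",
                      var_class="nonsynonymous SNV"),
    ]
    return GenotypeMatrix(samples=["S1", "S2", "S3", "S4"], records=records)


@pytest.fixture(scope="session")
def demo_cohort():
    """A deterministic 5v5 cohort with a planted causal haplotype."""
    cfg = CohortSimConfig(
        n_affected=5,
        n_unaffected=5,
        penetrance=0.9,
        phenocopy=0.0,
        background_variants=100,
        seed=11,
    )
    return simulate_cohort(cfg)
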