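import numpy as np
import pytest

from bayesr import simdata


def make_panel(dosage, chrom=None, pos=None, maf=None, annotation=None,
               breed=None, sex=None, iid=None):
    """Hand-built GenotypePanel with sensible metadata defaults."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if maf is None:
        p = dosage.mean(axis=0) / 2.0
        maf = np.minimum(p, 1.0 - p)
    return simdata.GenotypePanel(
        dosage=dosage,
        chrom=np.ones(m, dtype=np.int64) if chrom is None else chrom,
        pos=np.arange(1, m + 1) if pos is None else pos,
        variant_id=np.array([f"v{j}" for j in range(m)], dtype=object),
        maf=np.asarray(maf, dtype=np.float64),
        annotation=np.full(m, "OTHER", dtype=object) if annotation is None
        else np.asarray(annotation, dtype=object),
        breed=np.full(n, "A", dtype=object) if breed is None else breed,
        sex=np.full(n, "F", dtype=object) if sex is None else sex,
        iid=np.array([f"i{j}" for j in range(n)], dtype=object) if iid is None else iid,
    )


@pytest.fixture(scope="session")
def small_hap_panel():
    return simdata.simulate_panel({"A": 15, "B": 15}, 120, n_chromosomes=2,
                                  divergence=0.1, seed=42)


@pytest.fixture(scope="session")
def small_geno_panel(small_hap_panel):
    return simdata.genotypes_from_haplotypes(small_hap_panel)
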