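import numpy as np
import pytest

import depgenes as dg


@pytest.fixture(scope="session")
def preweight():
    return dg.load_default_preweight()


@pytest.fixture(scope="session")
def uniform_preweight():
    return dg.PreWeightVector.uniform()


@pytest.fixture
def toy_matrix():
    """Five genes with hand-set scores across the seven sources."""
    scores = np.array(
        [
            [4.0, 0.0, 0.0, 6.0, 3.0, 0.0, 0.0],  # GENEA: strong
            [4.0, 0.0, 0.0, 6.0, 3.0, 0.0, 0.0],  # GENEB: ties GENEA
            [0.0, 2.0, 1.0, 0.0, 0.0, 0.0, 0.0],  # GENEC
            [0.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0],  # GENED
            [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],  # GENEE: no evidence
        ]
    )
    return dg.EvidenceMatrix(("GENEA", "GENEB", "GENEC", "GENED", "GENEE"), scores)


@pytest.fixture(scope="session")
def synthetic_bundle():
    """One deterministic synthetic dataset shared by read-only tests."""
    cfg = dg.SyntheticConfig(seed=7)
    evidence, truth = dg.generate_evidence(cfg)
    core = dg.sample_core_genes(truth)
    snps, coords = dg.generate_gwa(truth)
    gwa = dg.map_snps_to_genes(snps, coords)
    tissue = dg.generate_tissue_matrix(truth)
    return {
        "cfg": cfg,
        "evidence": evidence,
        "truth": truth,
        "core": core,
        "snps": snps,
        "coords": coords,
        "gwa": gwa,
        "tissue": tissue,
    }
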