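import numpy as np
import pytest

from retroproteo import synthetic_data as sd


@pytest.fixture()
def small_family():
    """A 12-locus family of 200-residue proteins at the default divergence."""
    cfg = sd.GeneratorConfig(seed=42, n_loci=12, protein_length=200)
    loci, consensus, ledger = sd.generate_locus_family(cfg)
    return loci, consensus, ledger


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
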