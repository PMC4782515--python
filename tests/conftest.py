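import pandas as pd
import pytest

import motifrecruit as mr


@pytest.fixture(scope="session")
def default_dataset() -> mr.SyntheticDataset:
    """The shipped default synthetic dataset (seed 42, noise-free)."""
    return mr.generate_dataset(mr.SimConfig())


@pytest.fixture(scope="session")
def default_presence(default_dataset):
    """Consensus-scan presence table over both species' promoters."""
    ds = default_dataset
    p3 = mr.extract_promoters(ds.genome_c3, ds.genes_c3)
    p4 = mr.extract_promoters(ds.genome_c4, ds.genes_c4)
    occ3, pres3 = mr.scan_promoters(p3, ds.motifs)
    occ4, pres4 = mr.scan_promoters(p4, ds.motifs)
    presence = pd.concat([pres3, pres4], axis=1)
    return {"p3": p3, "p4": p4, "occ3": occ3, "occ4": occ4, "presence": presence}
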