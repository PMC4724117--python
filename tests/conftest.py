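import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dupfates import Dataset, GeneRecord, ParalogPair, generate_dataset, paper_like_config

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def tiny_dataset() -> Dataset:
    """Hand-written 5-gene / 4-pair / 3-tissue dataset."""
    genes = {
        "g1": GeneRecord("g1", go_bp=frozenset({"P1", "P2", "P3"}),
                         go_mf=frozenset({"F1", "F2"}), go_cc=frozenset({"C1"}),
                         expression=np.array([1.0, 2.0, 3.0]),
                         essential=True, disease=False,
                         pfam_domain_count=2, age_rank=1),
        "g2": GeneRecord("g2", go_bp=frozenset({"P2", "P3", "P4"}),
                         go_mf=frozenset({"F1", "F2"}), go_cc=frozenset({"C1", "C2"}),
                         expression=np.array([2.0, 4.0, 6.0]),
                         essential=False, disease=True,
                         pfam_domain_count=1, age_rank=3),
        "g3": GeneRecord("g3", go_bp=frozenset({"P5"}),
                         expression=np.array([3.0, 2.0, 1.0]),
                         essential=False, disease=False, age_rank=12),
        "g4": GeneRecord("g4", go_cc=frozenset({"C3"}),
                         essential=True, disease=True,
                         pfam_domain_count=4, age_rank=15),
        "g5": GeneRecord("g5"),
    }
    pairs = [
        ParalogPair("g1", "g2", origin="SSD", dn=0.05, ds=0.2, identity_pct=80.0),
        ParalogPair("g1", "g3", origin="WGD", dn=0.25, ds=0.9, identity_pct=40.0),
        ParalogPair("g3", "g4", origin="WGD", dn=0.73, ds=2.5, identity_pct=55.0),
        ParalogPair("g4", "g5", origin="SSD", dn=0.1, ds=0.5, identity_pct=62.0),
    ]
    from dupfates import OrthologRate
    rates = [
        OrthologRate("g1", "mouse", dn=0.1, ds=0.5),
        OrthologRate("g2", "mouse", dn=0.08, ds=3.0),
        OrthologRate("g3", "mouse", dn=0.1, ds=0.0),
        OrthologRate("g5", "chimp", dn=0.01, ds=0.04),
    ]
    return Dataset(genes=genes, pairs=pairs, ortholog_rates=rates,
                   tissue_names=["liver", "kidney", "testis"]).validate()


@pytest.fixture(scope="session")
def recovery_dataset():
    """Shared mid-sized synthetic dataset for parameter-recovery checks."""
    cfg = paper_like_config(n_pairs_ssd=2000, n_pairs_wgd=2000, seed=11)
    return cfg, generate_dataset(cfg)
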