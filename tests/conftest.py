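import pytest

from panforge.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small clade reused across modules: 6 genomes, modest family counts,
    a few implanted transfers."""
    cfg = SimulationConfig(
        n_genomes=6,
        n_core_families=25,
        n_root_accessory=30,
        gain_rate=20.0,
        loss_rate=30.0,
        hgt_rate=1.0,
        seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_families(small_dataset):
    """FamilySet built from the small dataset's ground truth."""
    from panforge.orthology import FamilySet

    ds = small_dataset
    genomes = sorted({r.genome for r in ds.records})
    return FamilySet.from_memberships(ds.truth.family_membership, genomes)
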