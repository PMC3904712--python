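import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def family_table_path():
    from hsfkit.registry import packaged_family_table

    return packaged_family_table()


@pytest.fixture(scope="session")
def standin_protein():
    """Synthetic stand-in protein matching the published TaHsfA2b
    summary statistics (413 aa, 45.6 kDa, pI 4.99)."""
    from pathlib import Path

    import hsfkit
    from hsfkit.io import read_fasta

    path = Path(hsfkit.__file__).parent / "data" / "tahsfa2b_synthetic_standin.faa"
    return read_fasta(path, alphabet="protein")[0]


@pytest.fixture(scope="session")
def small_family():
    from hsfkit.simulate import FamilySimParams, simulate_family

    params = FamilySimParams(
        n_subfamilies=3, members_per_subfamily=2, labels=("A1", "B1", "C1")
    )
    return simulate_family(params, seed=11)


@pytest.fixture(scope="session")
def reference_set(small_family):
    from hsfkit.domains import ReferenceDomain, ReferenceDomainSet

    refs = [
        ReferenceDomain(rid, region[:96], label)
        for rid, region, label in small_family.references
    ]
    return ReferenceDomainSet(tuple(refs))
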