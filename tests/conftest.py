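import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "package",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture(scope="session")
def bundled_table():
    from aminochol import load_bundled_table1

    return load_bundled_table1()


@pytest.fixture(scope="session")
def property_records(bundled_table):
    from aminochol import build_property_table

    return build_property_table(bundled_table)


@pytest.fixture(scope="session")
def exp_eos():
    """Equation of state over the bundled experimental parameter set."""
    from aminochol import EpcSaft, load_bundled_params

    return EpcSaft(load_bundled_params("experimental"))


def record(records, amino_acid, m_aa, T, m_chcl):
    """Look up one derived record by its state-point key."""
    for r in records:
        if (
            r.system.amino_acid == amino_acid
            and abs(r.system.amino_acid_molality - m_aa) < 1e-9
            and r.T == T
            and abs(r.m_chcl - m_chcl) < 1e-9
        ):
            return r
    raise KeyError((amino_acid, m_aa, T, m_chcl))
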