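import pytest

from glysubsume import fixtures as fx

_FIXTURES = ("F1", "T1", "C1", "B1", "R1", "M1", "M2",
             "GAL", "GLCNAC", "O1", "O2", "NG")


@pytest.fixture(scope="session")
def glycans():
    """All shipped fixture structures, parsed once per session."""
    return {name: fx.load_fixture(name) for name in _FIXTURES}


@pytest.fixture(scope="session")
def texts():
    return {name: fx.fixture_text(name) for name in _FIXTURES}


def small_families(max_residues=6, n_variants=25, rng_seeds=(1, 2)):
    """Degraded families from seeds small enough for brute-force oracles."""
    out = []
    for seed_name in ("F1", "O1", "O2"):
        seed = fx.load_fixture(seed_name)
        if len(seed.residues) > max_residues:
            continue
        for rs in rng_seeds:
            out.append((seed_name, rs,
                        fx.generate_family(seed, n_variants, rs)))
    return out


@pytest.fixture(scope="session")
def families():
    return small_families()
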