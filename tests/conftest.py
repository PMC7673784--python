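import pytest

from retsbi import cells, synth
from retsbi.efield import RetinaFieldModel, solve_field


@pytest.fixture(scope="session")
def short_chirp():
    """A compressed chirp on a 2 kHz grid: (t, intensity, dt)."""
    spec = synth.ChirpSpec(sample_rate=2000.0).scaled(0.08)
    t, x = synth.make_chirp(spec)
    return t, x, 1.0 / spec.sample_rate


@pytest.fixture(scope="session")
def field_solution():
    """Single-disk DC field at the published tissue parameters (1 uA)."""
    return solve_field(RetinaFieldModel(), 1e-6, 0.0)


@pytest.fixture(scope="session")
def selectivity_toys():
    return cells.make_selectivity_toys()


@pytest.fixture()
def bc_swc(tmp_path):
    from retsbi.morphology import write_swc

    morph = synth.bc_like_morphology(seed=3, n_nodes=120)
    path = tmp_path / "bc_like.swc"
    write_swc(morph, path)
    return path, morph
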