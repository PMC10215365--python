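import numpy as np
import pytest

from plasmidlattice import CellType, Lattice, SimulationParams, SiteState


class ScriptedRNG:
    """Deterministic stand-in for RandomState: replays a scripted draw list."""

    def __init__(self, draws):
        self.draws = list(draws)
        self.used = 0

    def random_sample(self):
        u = self.draws[self.used]
        self.used += 1
        return u


@pytest.fixture
def scripted_rng():
    return ScriptedRNG


@pytest.fixture
def small_params():
    """Parameter factory for desk-scale grids."""

    def make(**overrides):
        defaults = dict(
            edge=20,
            n_donors=5,
            n_recipients=5,
            n_cull_events=3,
            b=0.4,
            c=0.1,
            gamma_max=1.0,
            adaptation_time=70,
            seed=0,
        )
        defaults.update(overrides)
        return SimulationParams(**defaults)

    return make


def place(lattice: Lattice, x, y, cell_type, cost=0.0, countdown=0):
    lattice.set_state(x, y, SiteState(CellType(cell_type), cost, countdown))


@pytest.fixture
def placer():
    return place
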