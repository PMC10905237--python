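import numpy as np
import pytest

from mpnull.records import PopulationRecord


@pytest.fixture
def make_record():
    """Factory for valid population records with overridable fields."""

    def _make(**kw):
        base = dict(
            species_name="Synthea exempli",
            population_id="pop1",
            clade="bird",
            technique="microsatellite",
            mating_system="monogamous",
            n_broods=50,
            mean_brood_size=3.6,
            mean_n_sires=1.3,
            prop_mp=0.2,
        )
        base.update(kw)
        return PopulationRecord(**base)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)
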