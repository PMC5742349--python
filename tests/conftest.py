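import pytest

from sweetsuite import synthetic


@pytest.fixture(scope="session")
def templates():
    return synthetic.make_templates(n_units=2, seed=1)


@pytest.fixture(scope="session")
def zero_noise_family(templates):
    """One 7-TMH family of 5 identical sequences (no noise, no injections)."""
    scenario = synthetic.EvolutionScenario(
        n_families=1,
        seqs_per_family=5,
        architecture_per_family=(7,),
        substitution_rate=0.0,
        seed=0,
    )
    return synthetic.generate(scenario, templates)


@pytest.fixture(scope="session")
def two_family_records(templates):
    """Two diverged 7-TMH families, 10 members each, mild noise."""
    scenario = synthetic.EvolutionScenario(
        n_families=2,
        seqs_per_family=10,
        architecture_per_family=(7, 7),
        substitution_rate=0.1,
        seed=42,
    )
    return synthetic.generate(scenario, templates)
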