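import pytest

from pinetviz import GeneratorSpec, full_subnetwork, generate_dataset, toy6


@pytest.fixture(scope="session")
def toy():
    return toy6()


@pytest.fixture(scope="session")
def toy_expr():
    return toy6(with_expression=True)


@pytest.fixture()
def toy_full(toy):
    return full_subnetwork(toy)


@pytest.fixture(scope="session")
def random_dataset():
    """Factory for small random datasets keyed by seed."""

    def make(seed, n=30, orgs=2, edge_p=0.12, cross_p=0.05):
        proportions = [1.0 / orgs] * orgs
        proportions[-1] = 1.0 - sum(proportions[:-1])
        spec = GeneratorSpec(
            n_proteins=n,
            organisms=[(f"ORG{i + 1}", p) for i, p in enumerate(proportions)],
            edge_probability=edge_p,
            cross_organism_probability=cross_p,
            seed=seed,
        )
        return generate_dataset(spec)

    return make
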