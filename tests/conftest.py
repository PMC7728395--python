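import pytest

from httscan import simulate


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A tiny simulated study bundle shared across integration tests."""
    specs = [
        simulate.TeSpec(unit_id="te_h1", mode="horizontal", donor="sp1",
                        recipient="sp4", t_ht_my=1.0, beta=0.3),
        simulate.TeSpec(unit_id="te_v1", mode="vertical", beta=0.5),
    ]
    config = simulate.SimConfig(
        species_tree="(((sp1:4,sp2:4):3,sp3:7):3,(sp4:5,sp5:5):5);",
        n_genes=25,
        codons_per_gene=300,
        codons_per_te=400,
        te_specs=specs,
        seed=42,
    )
    outdir = tmp_path_factory.mktemp("study") / "sim"
    simulate.generate_study(config, outdir)
    return config, outdir
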