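import pytest

from hipnet.catalog import PPIObservation
from hipnet.simulate import FixtureSpec, generate_all


def make_obs(
    gene,
    study="S1",
    species="Mice",
    tissue="",
    htt_length="",
    method="",
    confirmed=True,
    obs_id=None,
):
    """Terse builder for confirmed interaction observations."""
    return PPIObservation(
        obs_id=obs_id or f"{gene}-{study}-{species}-{tissue}",
        gene_symbol_human=gene,
        gene_symbol_source=gene,
        study_id=study,
        model_species=species,
        tissue=tissue,
        htt_length=htt_length,
        detection_method=method,
        interaction_confirmed=confirmed,
    )


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """One full synthetic input set shared across the session."""
    out = tmp_path_factory.mktemp("fixtures")
    spec = FixtureSpec(seed=20, n_genes=40, n_studies=6)
    result = generate_all(spec, out)
    result["dir"] = out
    result["fixture_spec"] = spec
    return result
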