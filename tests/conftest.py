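import numpy as np
import pytest

from mirtarsnp.pipeline import PipelineConfig
from mirtarsnp.rna_struct import EnergyModel
from mirtarsnp.synthetic_data import SimConfig, simulate_inputs


@pytest.fixture(scope="session")
def turner():
    return EnergyModel.turner()


@pytest.fixture(scope="session")
def unit_model():
    return EnergyModel.unit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


SMALL_SIM = dict(
    n_transcripts=6,
    n_switch_sites=4,
    n_disruptive=3,
    n_benign_site=20,
    n_hairpin_flank=2,
    n_neutral=4,
    n_lead_site=1,
    n_decoy_site=2,
    n_decoy_neutral=2,
    n_insig_site=2,
)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A reduced synthetic bundle shared by the integration-level tests."""
    out = tmp_path_factory.mktemp("bundle")
    return simulate_inputs(SimConfig(seed=7, **SMALL_SIM), out)


def bundle_config(bundle, **overrides) -> PipelineConfig:
    base = dict(
        gwas=str(bundle.files["gwas"]),
        ld=str(bundle.files["ld"]),
        targetome=[str(p) for p in bundle.files["targetome"]],
        utr_fasta=str(bundle.files["utr_fasta"]),
        mirna_fasta=str(bundle.files["mirna_fasta"]),
        variants=str(bundle.files["variants"]),
        eqtl=str(bundle.files["eqtl"]),
        conservation=str(bundle.files["conservation"]),
        seed=bundle.config.seed,
    )
    base.update(overrides)
    return PipelineConfig(**base)
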