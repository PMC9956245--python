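import pytest

from sympan.align import AlignmentParams, SubstitutionMatrix
from sympan.config import PipelineConfig
from sympan.pipeline import run_pipeline
from sympan.records import StrainPanel
from sympan.simulate import GroupSpec, PangenomeConfig, generate_pangenome


@pytest.fixture(scope="session")
def blosum62():
    return SubstitutionMatrix.blosum62()


@pytest.fixture(scope="session")
def params():
    return AlignmentParams()


@pytest.fixture(scope="session")
def permissive_params():
    """No E-value gate: every positive-scoring optimum is reported."""
    return AlignmentParams(evalue_threshold=1e18)


def make_panel(config: PangenomeConfig):
    proteomes, truth = generate_pangenome(config)
    panel = StrainPanel(
        proteomes=proteomes,
        metadata={s.strain_id: s for s in config.strain_infos()})
    return panel, truth


@pytest.fixture(scope="session")
def small_config():
    return PangenomeConfig(
        groups=(GroupSpec("Ia-Spp", "Ia", "Sp+", 2),
                GroupSpec("Ia-Spm", "Ia", "Sp-", 2),
                GroupSpec("Ic", "Ic", "none", 1)),
        n_universal_families=5, n_groupA_specific_core=3, n_lost_in_spplus=4,
        n_strain_specific_per_strain=2, seed=101)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return make_panel(small_config)


@pytest.fixture(scope="session")
def small_result(small_panel):
    panel, _ = small_panel
    return run_pipeline(panel, PipelineConfig())
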