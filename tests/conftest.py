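import numpy as np
import pytest

from iespipe.mapper import build_index
from iespipe.simulate import LengthModel, SimConfig, generate_genomes, simulate_reads


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulation with retention, errors and contamination,
    shared by mapper/retention/errors tests."""
    cfg = SimConfig(
        n_scaffolds=2,
        scaffold_len=8000,
        n_ies=20,
        coverage=60,
        retention_prob=0.3,
        error_rate=0.2,
        old_mac_fraction=0.1,
        parental_error_junctions=5,
        seed=7,
    )
    germline, somatic, annotation = generate_genomes(cfg)
    reads, truth = simulate_reads(cfg, (germline, somatic), annotation, sample="autogamous")
    parental_reads, parental_truth = simulate_reads(
        cfg, (germline, somatic), annotation, sample="parental"
    )
    index = build_index(germline, somatic, annotation)
    return {
        "cfg": cfg,
        "germline": germline,
        "somatic": somatic,
        "annotation": annotation,
        "reads": reads,
        "truth": truth,
        "parental_reads": parental_reads,
        "parental_truth": parental_truth,
        "index": index,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def default_model():
    return LengthModel()
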