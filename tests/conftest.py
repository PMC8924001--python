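import numpy as np
import pytest

from ribopes import (SimRiboParams, SimTranscriptomeParams, TranscriptModel,
                     models_by_id, simulate_ribo_counts, simulate_transcriptome)


@pytest.fixture(scope="session")
def toy_models():
    """Ten small hand-buildable transcripts for brute-force comparisons."""
    rng = np.random.default_rng(123)
    models = []
    for i in range(10):
        u5 = int(rng.integers(15, 40))
        ncod = int(rng.integers(30, 80))
        u3 = int(rng.integers(10, 50))
        seq = "".join(rng.choice(list("ACGT"), size=u5 + 3 * ncod + u3))
        models.append(TranscriptModel(
            transcript_id=f"T{i}", gene_id=f"G{i}", sequence=seq,
            cds_start=u5, cds_end=u5 + 3 * ncod))
    return models


@pytest.fixture(scope="session")
def small_simulation():
    """A modest planted-effect simulation shared across recovery tests."""
    tx_params = SimTranscriptomeParams(n_transcripts=150, pes_fraction=0.2, seed=42)
    models, truth = simulate_transcriptome(tx_params)
    ribo_params = SimRiboParams(te_effect_on_pes=4.0, depth_rpf=200_000,
                                depth_rna=200_000, seed=43)
    profiles, te_truth = simulate_ribo_counts(models, truth, ribo_params)
    return {
        "models": models, "by_id": models_by_id(models), "truth": truth,
        "profiles": profiles, "te_truth": te_truth, "params": ribo_params,
    }
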