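import numpy as np
import pytest

from icnet.pipeline import PipelineConfig, subject_session_patterns
from icnet.synthetic import StudyConfig, generate_subject_session


@pytest.fixture(scope="session")
def tiny_study() -> StudyConfig:
    """Smallest sensible study: 6 subjects, 6 ROIs, 40 encoding trials."""
    return StudyConfig(group_sizes=(2, 2, 2), n_rois=6, voxels_per_roi=30,
                       n_encoding_trials=40, n_retrieval_trials=40, seed=42)


@pytest.fixture(scope="session")
def tiny_encoding_session(tiny_study):
    """One generated subject-session (encoding runs) plus LS-S patterns."""
    cfg = PipelineConfig(study=tiny_study, phases=("encoding",))
    data = generate_subject_session(tiny_study, 0, "pre", "control",
                                    phases=("encoding",))
    patterns, meta, _ = subject_session_patterns(cfg, data["encoding"])
    return {"cfg": cfg, "runs": data["encoding"], "patterns": patterns,
            "meta": meta}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
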