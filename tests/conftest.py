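import numpy as np
import pytest

from propriomap.scoring import fit_normative_model, score_cohort
from propriomap.synthetic import (
    simulate_normative_cohort, simulate_study,
)
from propriomap.tracts import MaskVolume, build_template


@pytest.fixture(scope="session")
def study():
    """Default-scale synthetic study: 26 stroke, 7 controls, planted couplings."""
    return simulate_study(rng=np.random.default_rng(3))


@pytest.fixture(scope="session")
def norm_model():
    exams, _ = simulate_normative_cohort(200, rng=np.random.default_rng(17))
    return fit_normative_model(exams)


@pytest.fixture(scope="session")
def study_scores(study, norm_model):
    return score_cohort(study.exams, norm_model)


@pytest.fixture(scope="session")
def templates(study):
    vox = study.config.grid.voxel_size_mm
    out = {}
    for (tract, hemi), masks in study.control_tract_masks.items():
        out[(tract, hemi)] = build_template(
            [MaskVolume(m, vox) for m in masks],
            study.config.agreement_k,
            tract=tract,
            hemisphere=hemi,
        )
    return out
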