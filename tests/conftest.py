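import numpy as np
import pytest

import tissuedc as t


def featurize_cohort(cohort, cfg, gate=True):
    """Gate + summarize every sample; returns (matrix, labels)."""
    vecs = []
    for rec in cohort:
        events = rec.events
        if gate:
            events, _ = t.apply_debris_gates(events)
        vecs.append(t.summarize_sample(events, cfg, sample_id=rec.sample_id,
                                       label=rec.condition))
    return t.assemble_matrix(vecs)


@pytest.fixture(scope="session")
def mouse_cfg():
    return t.preset("mouse_colon")


@pytest.fixture(scope="session")
def paired_cohort():
    """16 matched healthy/tumour pairs at reduced event counts."""
    spec = t.CohortSpec(n_pairs=16, events_per_sample=(2000, 4000))
    return t.sample_cohort(spec, seed=42)


@pytest.fixture(scope="session")
def trained_model(paired_cohort, mouse_cfg):
    matrix, labels = featurize_cohort(paired_cohort, mouse_cfg)
    model = t.fit_pipeline(matrix, labels, seed=0)
    return model, matrix, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
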