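from types import SimpleNamespace

import pytest
from hypothesis import HealthCheck, settings

import babyfeed as bf
from babyfeed.config import VisitSlot

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def lexicon():
    return bf.load_lexicon()


def _pipeline(cfg, lexicon):
    registry, trajectories, notes = bf.simulate_corpus(cfg)
    observations = bf.extract_all(notes, lexicon)
    cohort = bf.build_cohort(registry, observations)
    statuses = bf.timepoint_table(cohort)
    return SimpleNamespace(
        cfg=cfg,
        registry=registry,
        trajectories={t.infant_id: t for t in trajectories},
        notes=notes,
        observations=observations,
        cohort=cohort,
        statuses=statuses,
    )


@pytest.fixture(scope="session")
def study_run(lexicon):
    """Full synthetic cohort at study scale, default conditions."""
    return _pipeline(bf.SimConfig(n_infants=8815, seed=11), lexicon)


@pytest.fixture(scope="session")
def closure_run(lexicon):
    """Fully documented, on-schedule corpus: ground truth is recoverable
    exactly at every target age."""
    slots = tuple(VisitSlot(a, 1.0, 0.0) for a in (7, 60, 122, 182))
    cfg = bf.SimConfig(
        n_infants=800, seed=5, undocumented_prob=0.0, visit_schedule=slots
    )
    return _pipeline(cfg, lexicon)
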