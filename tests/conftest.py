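import numpy as np
import pytest

from hrvaf.types import RRSegment


def random_segment(rng: np.random.Generator, *, n_min: int = 20,
                   n_max: int = 120, rhythm: str = "SR") -> RRSegment:
    """A random but structurally valid segment, with random removal gaps."""
    n = int(rng.integers(n_min, n_max + 1))
    kind = rng.integers(0, 3)
    if kind == 0:      # SR-like: small correlated wiggle
        rr = 800 + np.cumsum(rng.normal(0, 8, n)) * 0.3 + rng.normal(0, 12, n)
    elif kind == 1:    # AF-like: wide i.i.d.
        rr = rng.gamma(20.0, 35.0, n)
    else:              # mixture with occasional jumps
        rr = 700 + rng.normal(0, 30, n)
        jumps = rng.random(n) < 0.1
        rr[jumps] += rng.choice([-250, 250], size=int(jumps.sum()))
    rr = np.clip(rr, 250.0, 2990.0)
    adjacency = rng.random(n - 1) > 0.1  # ~10% removal gaps
    return RRSegment("rand", "test", 0, rhythm, rr, adjacency)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-parameter cohort shared across tests (seeded)."""
    from hrvaf import features, preprocessing, synthetic

    cfg = synthetic.GeneratorConfig(n_patients_per_class=10,
                                    recording_duration=300.0, seed=7)
    recordings, manifest = synthetic.generate_cohort(cfg)
    segments, qcs = preprocessing.segment_cohort(recordings)
    table, exclusions = features.build_feature_table(segments)
    return {"config": cfg, "recordings": recordings, "manifest": manifest,
            "segments": segments, "qcs": qcs, "table": table,
            "exclusions": exclusions}
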