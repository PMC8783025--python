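import numpy as np
import pytest

import valveseq as vs


@pytest.fixture(scope="session")
def small_parts():
    """2 spacers x 3 modifiers x 4 terminators of realistic sizes."""
    return vs.synthetic_part_set(2, 3, 4, seed=11)


@pytest.fixture(scope="session")
def flanks():
    rng = np.random.default_rng(301)
    bases = list("ACGT")
    return "".join(rng.choice(bases, 50)), "".join(rng.choice(bases, 40))


@pytest.fixture(scope="session")
def small_designs(small_parts, flanks):
    return vs.enumerate_designs(small_parts, flanks)


@pytest.fixture(scope="session")
def one_design(small_designs):
    return small_designs[0]


@pytest.fixture(scope="session")
def clean_pool(small_designs):
    """Error-free, truncation-free pool with known per-design true Te."""
    rng = np.random.default_rng(42)
    true_te = {d.id: float(rng.uniform(0.1, 0.9)) for d in small_designs}
    models = {d.id: vs.default_truth_model(d, true_te[d.id]) for d in small_designs}
    cfg = vs.SimulationConfig(substitution_rate=0.0, reads_per_design=120, seed=99)
    reads, truth = vs.simulate_pool(small_designs, models, cfg)
    return reads, truth, true_te


def measure_design(design, reads, terminator_margin=20):
    """Shared mini-pipeline: map -> filter -> profile for one design."""
    mapped = [
        m
        for m in (vs.map_read(r.id, r.sequence, design) for r in reads)
        if m is not None
    ]
    kept, log = vs.filter_reads(mapped, design, terminator_margin)
    profile = vs.build_depth_profile(kept, len(design.reference_sequence), design.id)
    return profile, kept, log
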