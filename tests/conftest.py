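import numpy as np
import pandas as pd
import pytest

from hicap import interactions as ia
from hicap import pairs as pr
from hicap.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def sim_small():
    """Desk-scale simulated dataset shared across test modules."""
    cfg = SimConfig(
        seed=42,
        genome_length=2_000_000,
        n_promoters=60,
        n_planted_loops=80,
        pairs_per_replicate=30_000,
        n_planted_pp=15,
        n_planted_ee=15,
    )
    return simulate_all(cfg)


@pytest.fixture(scope="session")
def sim_calls(sim_small):
    """Filtered pairs and called interactions for the shared dataset."""
    retained = {}
    valid = {}
    for rep, ends in sim_small.ends_by_replicate.items():
        paired, _ = pr.pair_ends(ends)
        deduped, _ = pr.dedupe(paired)
        classified = pr.classify(deduped, sim_small.fragmap)
        v = classified[classified["validity_class"] == "valid"].reset_index(drop=True)
        valid[rep] = v
        retained[rep], _ = pr.on_target_filter(v, sim_small.targets)
    counts = ia.count_support(retained, sim_small.targets)
    calls = ia.call_interactions(counts, sim_small.targets, min_support=3)
    dd = ia.call_dd(valid, calls, min_support=3)
    all_calls = pd.concat([calls, dd], ignore_index=True)
    return {
        "retained": retained,
        "valid": valid,
        "counts": counts,
        "calls": calls,
        "dd": dd,
        "all_calls": all_calls,
    }


@pytest.fixture
def toy_genome():
    rng = np.random.default_rng(0)
    return {
        "chrA": "".join(rng.choice(list("ACGT"), size=5000)),
        "chrB": "".join(rng.choice(list("ACGT"), size=3000)),
    }
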