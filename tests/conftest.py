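import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20220418)


@pytest.fixture
def small_sim_config():
    """A tiny library: 3 fragments, 30 clones, light coverage."""
    from snrcm.simulate import BGCSpec, SimulationConfig

    return SimulationConfig(
        n_fragments=3,
        fragment_len_bp=(70_000, 80_000),
        n_clones=30,
        pool_size=20,
        long_read_coverage=6.0,
        bgc_plan=[
            BGCSpec("lasso", 4_200, with_transporter=True),
            BGCSpec("terpene", 8_000),
            BGCSpec("NRPS-like", 58_000),
        ],
        seed=3,
    )


@pytest.fixture(scope="session")
def small_library():
    """Session-shared small simulated library with mined verdicts."""
    from snrcm.containment import BGCRegion, mine_regions
    from snrcm.simulate import (BGCSpec, SimulationConfig, build_fosmid_library,
                                generate_community, simulate_long_reads)

    cfg = SimulationConfig(
        n_fragments=3,
        fragment_len_bp=(70_000, 80_000),
        n_clones=30,
        pool_size=20,
        long_read_coverage=8.0,
        bgc_plan=[
            BGCSpec("lasso", 4_200, with_transporter=True),
            BGCSpec("terpene", 8_000),
            BGCSpec("NRPS-like", 58_000),
        ],
        seed=3,
    )
    community = generate_community(cfg)
    clones = build_fosmid_library(community, cfg)
    reads, truth = simulate_long_reads(clones, cfg)
    regions = [BGCRegion(b.bgc_id, b.fragment_id, b.start, b.end, b.class_label)
               for b in community.bgcs]
    verdicts = mine_regions(regions, community.fragments,
                            [(r.read_id, r.sequence) for r in reads])
    return {"config": cfg, "community": community, "clones": clones, "reads": reads,
            "read_truth": truth, "regions": regions, "verdicts": verdicts}
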