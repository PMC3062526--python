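import numpy as np
import pytest

from pph.config import PipelineConfig
from pph.pipeline import run_pipeline
from pph.synthetic import SimConfig


def make_config(**sim_kw) -> PipelineConfig:
    cfg = PipelineConfig()
    seed = sim_kw.pop("seed", 1)
    cfg.sim = SimConfig(rng_seed=seed, **sim_kw)
    return cfg.with_seed(seed)


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run on a default-conditions synthetic cell."""
    cfg = make_config(image_size_px=(128, 128), n_cycles=150, n_ccs=40, seed=1)
    cfg.randomization.n_shifts = 60   # enough for stable bands in sanity checks
    return run_pipeline(cfg)


def match_planted(res, max_dist_px=2.0, max_dframe=1):
    """Pair confirmed events with planted ground-truth events."""
    ccs = {c.id: c for c in res.truth.ccs_records}
    pairs = []
    for ev in res.events:
        for e in res.truth.event_records:
            if e.detection_frame is None:
                continue
            c = ccs[e.ccs_id]
            if (np.hypot(c.row - ev.position[0], c.col - ev.position[1])
                    <= max_dist_px
                    and abs(e.detection_frame - ev.detection_frame)
                    <= max_dframe):
                pairs.append((ev, e))
                break
    return pairs
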