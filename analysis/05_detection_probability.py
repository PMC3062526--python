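#!/usr/bin/env python
"""Probability of detecting protein recruitment at scission sites.

For each recruitment family, runs both detection strategies on a
simulated cell: the object strategy (segmented red object > 3 px with
> 8 s dwell inside a 3-px circle at the site, per frame in the 80 s
around scission) and the peak strategy (significant trace peak above
6 x tail noise).  A non-recruited control calibrates the false-positive
floor.

Writes results/detprob/profiles.csv and summary.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pph.config import PipelineConfig
from pph.pipeline import run_pipeline
from pph.synthetic import SimConfig

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "detprob"

FAMILIES = ["clathrin-like", "dynamin-like", "gak-like", "none"]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    prof_rows, summary = [], []
    for i, family in enumerate(FAMILIES):
        cfg = PipelineConfig()
        cfg.sim = SimConfig(image_size_px=(128, 128), n_cycles=200, n_ccs=60,
                            red_families=(family,), red_family_weights=(1.0,),
                            red_sum_mean=300.0, rng_seed=20 + i)
        cfg.randomization.n_shifts = 20
        res = run_pipeline(cfg.with_seed(20 + i))
        prof = res.detection_profile
        times = 4.0 * np.arange(-20, 21)
        for t, p in zip(times, prof.p_detect):
            prof_rows.append({"protein": family, "time_s": t, "p_detect": p})
        summary.append({"protein": family, "n_events": len(res.events),
                        "p_max": prof.p_max,
                        "peak_fraction": prof.peak_fraction})
        print(f"{family}: object-detection p_max = {prof.p_max:.2f}, "
              f"peak-detection fraction = {prof.peak_fraction:.2f} "
              f"({len(res.events)} events)")

    pd.DataFrame(prof_rows).to_csv(OUT / "profiles.csv", index=False)
    df = pd.DataFrame(summary).sort_values("p_max", ascending=False)
    df.to_csv(OUT / "summary.csv", index=False)
    print("ranking by object detection:",
          " > ".join(df["protein"].tolist()))


if __name__ == "__main__":
    main()
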