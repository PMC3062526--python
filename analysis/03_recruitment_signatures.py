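#!/usr/bin/env python
"""Recruitment signatures of three protein classes around scission.

Simulates one cell per recruitment family (dynamin-like transient,
clathrin-like slow build, GAK-like post-scission) plus a non-recruited
negative control, runs the full pipeline on each (randomization bands
from 200 coordinate shifts), and clusters the normalized signatures.

Writes results/signatures/signatures.csv (protein x 80 time points),
modules.csv, peaks.csv and terminal_sorting.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pph.config import PipelineConfig
from pph.pipeline import run_pipeline
from pph.quantification import INTERLACED_TIMES_S
from pph.signatures import cluster_signatures
from pph.synthetic import SimConfig

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "signatures"

FAMILIES = ["dynamin-like", "clathrin-like", "gak-like", "none"]


def run_family(family: str, seed: int):
    cfg = PipelineConfig()
    cfg.sim = SimConfig(image_size_px=(128, 128), n_cycles=200, n_ccs=60,
                        red_families=(family,), red_family_weights=(1.0,),
                        rng_seed=seed)
    cfg.randomization.n_shifts = 200
    return run_pipeline(cfg.with_seed(seed))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sig_rows, peak_rows, term_rows = [], [], []
    signatures = []
    for i, family in enumerate(FAMILIES):
        res = run_family(family, seed=10 + i)
        sig = res.signature
        sig.protein = family
        signatures.append(sig)
        for t, v in zip(INTERLACED_TIMES_S, sig.trace):
            sig_rows.append({"protein": family, "time_s": t, "signature": v})
        n_sig = sum(s for s, _ in res.peaks.values())
        peak_rows.append({
            "protein": family, "n_events": len(res.events),
            "peak_fraction": n_sig / max(len(res.events), 1),
            "signature_peak_time_s":
                float(INTERLACED_TIMES_S[np.nanargmax(sig.trace)]),
        })
        labels = [tc.label for tc in res.terminal.values()]
        term_rows.append({"protein": family,
                          "terminal": labels.count("terminal"),
                          "non_terminal": labels.count("non-terminal"),
                          "unsorted": labels.count("unsorted")})
        print(f"{family}: {len(res.events)} events, signature peak at "
              f"{peak_rows[-1]['signature_peak_time_s']:+.0f} s, "
              f"peak-significant fraction "
              f"{peak_rows[-1]['peak_fraction']:.2f}")

    pd.DataFrame(sig_rows).to_csv(OUT / "signatures.csv", index=False)
    pd.DataFrame(peak_rows).to_csv(OUT / "peaks.csv", index=False)
    pd.DataFrame(term_rows).to_csv(OUT / "terminal_sorting.csv", index=False)

    recruited = [s for s in signatures if s.protein != "none"]
    modules = cluster_signatures(recruited, cut_distance=0.2)
    pd.DataFrame([{"protein": p, "module": m}
                  for p, m in modules.modules.items()]
                 ).to_csv(OUT / "modules.csv", index=False)
    print(f"clustering: {modules.n_modules} modules among "
          f"{len(recruited)} recruited proteins, cophenetic r = "
          f"{modules.cophenetic_r:.2f}")


if __name__ == "__main__":
    main()
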