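#!/usr/bin/env python
"""Parameter-recovery summaries at reduced replicate count.

Runs the three replicated recovery studies (calving effects, dam-by-calf
interaction deviation, carcass-weight effects) with a handful of replicates
each and prints the mean recovered estimates next to the simulated truths.
The full 20-replicate runs, which produce the headline numbers, live in
scripts/acceptance.py.
"""

import sys
import time
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from mstnassoc.studies import (recovery_summary, run_calving_recovery,
                               run_carcass_recovery, run_null_calibration)

SEED = 2024
REPS = 5
OUT = Path(__file__).resolve().parents[1] / "results" / "recovery"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    tables = []

    base = run_calving_recovery(seed=SEED, n_replicates=REPS)
    s = recovery_summary(base, ["calf_het", "calf_hom", "dam_het", "dam_hom"])
    s.insert(0, "study", "calving")
    tables.append(s)
    print(f"[{time.time()-t0:.0f}s] calving effects\n{s.to_string(index=False)}",
          flush=True)

    inter = run_calving_recovery(seed=SEED, n_replicates=REPS, interaction=True,
                                 design=base["design"])
    s = recovery_summary(inter, ["interaction_dev"])
    s.insert(0, "study", "calving-interaction")
    tables.append(s)
    print(f"[{time.time()-t0:.0f}s] interaction deviation\n"
          f"{s.to_string(index=False)}", flush=True)

    for variant in ("Q204X", "nt821"):
        st = run_carcass_recovery(seed=SEED, variant=variant, n_replicates=REPS)
        s = recovery_summary(st, ["het", "hom"])
        s.insert(0, "study", f"carcass-{variant}")
        tables.append(s)
        print(f"[{time.time()-t0:.0f}s] carcass {variant}\n"
              f"{s.to_string(index=False)}", flush=True)

    nc = run_null_calibration(seed=SEED, n_replicates=200)
    print(f"[{time.time()-t0:.0f}s] null F-test rejection rate at alpha=0.05: "
          f"{nc['rejection_rate']:.3f} over {nc['n_replicates']} replicates")

    out = pd.concat(tables, ignore_index=True)
    out.to_csv(OUT / "recovery_summary.tsv", sep="\t", index=False)
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
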