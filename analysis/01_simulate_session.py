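"""Simulate the default study conditions: one 600 s patient session
(behavior + STN LFP) and one control session, and store them for the
downstream analyses.

Writes results/session/{pd_behavior.h5,pd_lfp.h5,control_behavior.h5}
and a CSV of the latent impairment state averaged into 7 s epochs.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from stnmes import io as sio
from stnmes.synth import GeneratorConfig, simulate_session

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    outdir = ROOT / "results" / "session"
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = GeneratorConfig()
    ss = np.random.SeedSequence(seed).generate_state(2)
    pd_s = simulate_session(cfg, group="PD", seed=int(ss[0]), subject_id="PD00")
    ct_s = simulate_session(cfg, group="control", seed=int(ss[1]), subject_id="CTRL",
                            with_lfp=False)

    sio.write_behavior_h5(pd_s.cursor, pd_s.target, outdir / "pd_behavior.h5")
    sio.write_lfp_h5(pd_s.lfp, outdir / "pd_lfp.h5")
    sio.write_behavior_h5(ct_s.cursor, ct_s.target, outdir / "control_behavior.h5")

    es = pd_s.epoch_latent(7.0)
    pd.DataFrame({"epoch_start": 7.0 * np.arange(es.size), "latent_mean": es}).to_csv(
        outdir / "pd_latent_7s.csv", index=False
    )

    print(f"simulated {cfg.duration:.0f} s sessions (seed {seed})")
    print(f"  latent: tau={cfg.tau} s, sd={pd_s.s.std():.3f} (target {cfg.latent_sd})")
    print(f"  band couplings w_true = {cfg.w_true}")
    print(f"  cursor occupies [{pd_s.cursor.x.min():.1f}, {pd_s.cursor.x.max():.1f}] "
          f"of the +/-{cfg.display_halfwidth:.0f} unit display")
    print(f"  wrote session files to {outdir}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
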