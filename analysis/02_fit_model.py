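"""MAP-fit the hybrid learner to every subject of the generated study and
score parameter recovery against the ground truth.

Reads results/study/, writes results/fits.csv and results/recovery.json.
Run analysis/01_generate_study.py first.
"""

import json
from pathlib import Path

import numpy as np

from twostep_social import PriorSpec, TaskConfig, exclusion_filter
from twostep_social.io import read_trials, sessions_from_trials, write_fits, read_fits
from twostep_social.pipeline import fit_cohort

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20250922


def main() -> None:
    import pandas as pd

    config = TaskConfig()
    trials = read_trials(ROOT / "study" / "trials.csv")
    sessions = sessions_from_trials(trials)
    included, report = exclusion_filter(sessions)
    print(f"exclusion: {len(included)}/{len(sessions)} subjects retained")

    kept = {sid: sessions[sid] for sid in sorted(included)}
    fits = fit_cohort(kept, PriorSpec(), config, seed=SEED, n_restarts=10)
    write_fits(fits, ROOT / "fits.csv")

    agents = pd.read_csv(ROOT / "study" / "agents.csv")
    agents["subject_id"] = agents["subject_id"].astype(str)
    fitted = read_fits(ROOT / "fits.csv")
    merged = agents.merge(fitted, on="subject_id", suffixes=("_true", "_hat"))
    recovery = {}
    for name in ("alpha", "beta", "lam", "w", "pi"):
        t = merged[f"{name}_true"].to_numpy()
        e = merged[f"{name}_hat"].to_numpy()
        recovery[name] = {
            "corr": float(np.corrcoef(t, e)[0, 1]) if np.std(t) > 0 else None,
            "bias": float(np.mean(e - t)),
            "rmse": float(np.sqrt(np.mean((e - t) ** 2))),
        }
    (ROOT / "recovery.json").write_text(json.dumps(recovery, indent=2) + "\n")
    print("recovery of w:", recovery["w"])
    print(f"mean fitted w: {fitted['w'].mean():.3f} "
          f"(true mean {agents['w'].mean():.3f})")


if __name__ == "__main__":
    main()
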