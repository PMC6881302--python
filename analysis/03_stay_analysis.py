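"""Model-agnostic stay/switch analysis of the generated study, plus the
two reference simulations (fully model-based and fully model-free cohorts)
that bracket its signatures.

A model-based cohort shows a previous-reward main effect only; a
model-free cohort adds a reward-by-same-state interaction.  Writes
results/stay_model.json, results/stay_table.csv and
results/stay_probabilities.csv.
"""

import json
from pathlib import Path

import numpy as np

from twostep_social import (
    AgentParameters,
    TaskConfig,
    build_stay_table,
    fit_stay_model,
    simulate_agent,
    stay_probability_table,
)
from twostep_social.io import read_trials, sessions_from_trials

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20250922
OPERATING = dict(alpha=0.5, beta=4.2416, lam=0.5, pi=0.15)


def reference_cohort(config, w, n=100):
    rng = np.random.default_rng(SEED + int(w))
    return {
        f"s{i:03d}": simulate_agent(
            AgentParameters(w=w, **OPERATING), config, rng, subject_id=f"s{i:03d}"
        )
        for i in range(n)
    }


def main() -> None:
    config = TaskConfig()
    sessions = sessions_from_trials(read_trials(ROOT / "study" / "trials.csv"))
    table = build_stay_table(sessions)
    table.to_csv(ROOT / "stay_table.csv", index=False, lineterminator="\n")
    result = fit_stay_model(table)
    (ROOT / "stay_model.json").write_text(
        json.dumps(result.to_dict(), indent=2) + "\n"
    )
    print("study cohort (mixed w):")
    print(result.coefficients.round(3).to_string())

    probs = stay_probability_table(sessions)
    probs.to_csv(ROOT / "stay_probabilities.csv", index=False, lineterminator="\n")

    for w, label in ((1.0, "model-based"), (0.0, "model-free")):
        ref = fit_stay_model(build_stay_table(reference_cohort(config, w)))
        print(f"\nreference {label} cohort (w={w:.0f}):")
        print(ref.coefficients.round(3).to_string())


if __name__ == "__main__":
    main()
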