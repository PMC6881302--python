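"""Generate the default synthetic study: 65 hybrid-learner agents, 150
two-step trials each, plus post-task liking ratings driven by the agents'
true final latent values.

Writes trials.csv, liking.csv and agents.csv (ground truth) under
results/study/.
"""

from pathlib import Path

import numpy as np

from twostep_social import CohortSpec, TaskConfig, generate_study
from twostep_social.io import write_trials

OUT = Path(__file__).resolve().parent.parent / "results" / "study"
SEED = 20250922


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = CohortSpec(seed=SEED)
    config = TaskConfig()
    trials, liking, agents = generate_study(spec, config)
    write_trials(trials, OUT / "trials.csv")
    liking.to_csv(OUT / "liking.csv", index=False, lineterminator="\n")
    agents.to_csv(OUT / "agents.csv", index=False, lineterminator="\n")
    print(f"{len(agents)} subjects, {len(trials)} trial rows -> {OUT}")
    print(f"true w: mean {agents['w'].mean():.3f}, "
          f"quartiles {np.percentile(agents['w'], [25, 75]).round(3)}")


if __name__ == "__main__":
    main()
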