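"""Regress post-task liking ratings on the fitted final model-free and
model-based advisor values, with moderation by the model-based weight w,
and report simple effects of model-free value at the 25th and 75th
percentiles of w.

Reads results/fits.csv and results/study/liking.csv; writes
results/attitude_model.json.  Run analysis scripts 01 and 02 first.
"""

import json
from pathlib import Path

import pandas as pd

from twostep_social import build_attitude_design, fit_liking_model, simple_effects
from twostep_social.io import fits_from_frame, read_fits

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    fits = fits_from_frame(read_fits(ROOT / "fits.csv"))
    liking = pd.read_csv(ROOT / "study" / "liking.csv")
    liking["subject_id"] = liking["subject_id"].astype(str)
    liking = liking[liking["subject_id"].isin(fits)]

    design = build_attitude_design(fits, liking)
    result = fit_liking_model(design)
    print("liking model:")
    print(result.coefficients.round(3).to_string())

    se25 = simple_effects(design, percentile=0.25)
    se75 = simple_effects(design, percentile=0.75)
    for label, se in (("25th", se25), ("75th", se75)):
        print(f"mf simple effect at {label} pct of w (w={se['center_w']:.2f}): "
              f"b={se['estimate']:.3f}, t={se['stat']:.2f}, p={se['p']:.4f}")

    payload = result.to_dict()
    payload["simple_effects"] = {
        "mf_at_w_p25": {k: v for k, v in se25.items() if k != "result"},
        "mf_at_w_p75": {k: v for k, v in se75.items() if k != "result"},
    }
    (ROOT / "attitude_model.json").write_text(json.dumps(payload, indent=2) + "\n")


if __name__ == "__main__":
    main()
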