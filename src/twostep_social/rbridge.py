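"""Bridge to R's lme4 for the hierarchical logistic stay model.

lme4's ``glmer`` (Laplace approximation to the marginal likelihood) is the
field-standard fitter for random-slope logistic regressions of this size
and is what this analysis lineage uses; no Python fitter in the stack
handles several hundred variance-component effects at acceptable speed.
The bridge writes the model table to a temporary CSV, runs a short R
script via ``Rscript`` and reads the coefficient table back as JSON.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
from pathlib import Path

import pandas as pd

__all__ = ["glmer_logistic", "rscript_available"]

_R_SCRIPT = r"""
suppressMessages({library(lme4); library(jsonlite)})
args <- commandArgs(trailingOnly = TRUE)
d <- read.csv(args[1], stringsAsFactors = FALSE)
d$subject_id <- factor(d$subject_id)
m <- glmer(
  stay ~ prev_reward_z + same_state + interaction +
    (1 | subject_id) + (0 + prev_reward_z | subject_id) +
    (0 + same_state | subject_id) + (0 + interaction | subject_id),
  data = d, family = binomial,
  control = glmerControl(optimizer = "bobyqa")
)
co <- summary(m)$coefficients
vc <- as.data.frame(VarCorr(m))
msgs <- unlist(m@optinfo$conv$lme4$messages)
failed <- any(grepl("failed to converge", msgs, fixed = TRUE))
out <- list(
  terms = rownames(co),
  estimate = unname(co[, "Estimate"]),
  se = unname(co[, "Std. Error"]),
  z = unname(co[, "z value"]),
  p = unname(co[, "Pr(>|z|)"]),
  re_names = vc$var1,
  re_vars = vc$vcov,
  converged = !failed,
  messages = if (is.null(msgs)) list() else as.list(msgs),
  singular = isSingular(m)
)
writeLines(toJSON(out, digits = 12, auto_unbox = TRUE), args[2])
"""

_TERM_NAMES = {"(Intercept)": "intercept"}


def rscript_available() -> bool:
    try:
        subprocess.run(
            ["Rscript", "--version"], capture_output=True, check=True, timeout=60
        )
        return True
    except Exception:  # noqa: BLE001
        return False


def glmer_logistic(table: pd.DataFrame, timeout: int = 600) -> dict:
    """Fit the stay GLMM with lme4 and return the parsed result dict.

    Raises on any R-side failure; callers route that to the documented
    fallback path.
    """
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        data_path = tmp / "stay_table.csv"
        script_path = tmp / "fit_glmer.R"
        out_path = tmp / "result.json"
        table.to_csv(data_path, index=False)
        script_path.write_text(_R_SCRIPT)
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script_path), str(data_path), str(out_path)],
            capture_output=True,
            text=True,
            timeout=timeout,
        )
        if proc.returncode != 0 or not out_path.exists():
            raise RuntimeError(
                f"glmer fit failed (exit {proc.returncode}): {proc.stderr[-2000:]}"
            )
        result = json.loads(out_path.read_text())
    result["terms"] = [_TERM_NAMES.get(t, t) for t in result["terms"]]
    return result
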