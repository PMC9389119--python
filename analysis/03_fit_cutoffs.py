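#!/usr/bin/env python
"""Fit per-feature decision cutoffs on the simulated model cohort.

For every continuous indicator: ROC curve, Youden-index cutoff, AUC with a
DeLong 95 % CI, and a univariate chi-square/Fisher screen of the
dichotomized call; significant indicators then enter a multivariable
logistic model.  These cutoffs are dataset-specific — the defaults used for
classification (SUVmax 7.02, TLG 12.53, hue 132.73, grade 3) are the
published ones and are carried as configuration, not refit.

Writes results/cutoffs_simulated.json.
"""

import json
from pathlib import Path

from click.testing import CliRunner

from lnfusion.cli import cli

ROOT = Path(__file__).resolve().parents[1]
FEATURES = ROOT / "results" / "features_simulated.csv"
OUT = ROOT / "results" / "cutoffs_simulated.json"


def main() -> None:
    if not FEATURES.exists():
        raise SystemExit("run analysis/02_quantify_features.py first")
    res = CliRunner().invoke(
        cli, ["fit", "--features", str(FEATURES), "--out", str(OUT)],
        catch_exceptions=False)
    assert res.exit_code == 0, res.output

    report = json.loads(OUT.read_text())
    print(f"{'feature':<14}{'cutoff':>10}{'AUC':>8}  95% CI")
    for name, block in sorted(report["features"].items(),
                              key=lambda kv: -kv[1]["auc"]):
        lo, hi = block["auc_ci95"]
        print(f"{name:<14}{block['cutoff']:>10.3f}{block['auc']:>8.3f}"
              f"  ({lo:.3f}, {hi:.3f})")
    if "multivariable" in report:
        mv = report["multivariable"]
        sig = [k for k, p in mv["p_values"].items()
               if k != "const" and p < 0.05]
        print(f"multivariable model converged={mv['converged']}; "
              f"independent predictors at p<0.05: {sig}")


if __name__ == "__main__":
    main()
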