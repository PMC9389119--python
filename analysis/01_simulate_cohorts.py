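#!/usr/bin/env python
"""Build the study cohorts.

Writes three cohorts:
  * the deterministic 154-node model-group fixture and 53-node
    validation-group fixture, whose features force the published confusion
    counts under the default cutoffs (tables only, no images); and
  * a sampled 154-node cohort drawn from the class-conditional feature
    distributions, with rendered elastogram stills, ROI masks and PET
    uptake grids for the quantification step.

Tables go to results/, image/volume artifacts to scratch/cohort_sim/.
"""

from pathlib import Path

from click.testing import CliRunner

from lnfusion.cli import cli
from lnfusion.cohort import make_model_fixture, make_validation_fixture

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 20240917


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    model = make_model_fixture()
    val = make_validation_fixture()
    model.to_csv(RESULTS / "fixture_model.csv", index=False)
    val.to_csv(RESULTS / "fixture_validation.csv", index=False)
    print(f"model fixture: {len(model)} nodes "
          f"({(model.true_class == 'malignant').sum()} malignant)")
    print(f"validation fixture: {len(val)} nodes "
          f"({(val.true_class == 'malignant').sum()} malignant)")

    sim_dir = SCRATCH / "cohort_sim"
    runner = CliRunner()
    res = runner.invoke(
        cli,
        ["simulate", "--n", "154", "--seed", str(SEED), "--image-size", "64",
         "--out", str(sim_dir)],
        catch_exceptions=False,
    )
    assert res.exit_code == 0, res.output
    print(f"sampled cohort with rendered images -> {sim_dir}")


if __name__ == "__main__":
    main()
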