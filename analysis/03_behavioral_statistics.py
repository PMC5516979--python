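#!/usr/bin/env python
"""Behavioral and parameter statistics on the fitted cohort.

Computes the stay-probability mixed ANOVA (outcome x transition x
condition), condition comparisons of performance (total points,
advantageous-choice probability) and of the five fitted parameters, the
regression of the model-free no-reward increment on gamma plus treatment,
and the ANCOVA adjusting for advantageous-choice probability.  Writes the
stats report under results/cohort/ and prints the headline numbers.
"""

import argparse
from pathlib import Path

import pandas as pd

from twostep.pipeline import analysis_tables, _stats_report_frame, _stats_report_text
from twostep.stats import exclude_perseverators
from twostep.task import default_task_config, read_trials

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dir", type=Path, default=ROOT / "results" / "cohort")
    args = ap.parse_args()

    config = default_task_config()
    trials = read_trials(args.dir / "trials.csv")
    retained, _ = exclude_perseverators(trials)
    fits = pd.read_csv(args.dir / "fits.csv", dtype={"subject_id": str, "condition": str})

    tables = analysis_tables(retained, fits, config)
    _stats_report_frame(tables).to_csv(args.dir / "stats_report.csv", index=False)
    (args.dir / "stats_report.txt").write_text(_stats_report_text(tables))

    anova = tables["stay_anova"].set_index("effect")
    three = anova.loc["condition * outcome * transition"]
    print(f"stay ANOVA three-way interaction: F(1,{int(three['df2'])}) = "
          f"{three['F']:.2f}, p = {three['p']:.4f}")
    ptest = tables["parameter_tests"].set_index("variable").loc["d_minus_mf"]
    print(f"model-free no-reward increment, control vs stress: "
          f"t({int(ptest['df'])}) = {ptest['t']:.2f}, p = {ptest['p']:.4g}")
    reg = tables["delta_regression"].set_index("predictor").loc["treatment"]
    print(f"treatment effect controlling gamma: B = {reg['B']:.3f} "
          f"(SE {reg['SE']:.3f}), p = {reg['p']:.4g}")
    print(f"full report -> {args.dir / 'stats_report.txt'}")


if __name__ == "__main__":
    main()
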