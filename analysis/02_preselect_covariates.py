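"""Univariate mixed-model screen of candidate signs and symptoms.

Keeps the top half of candidates (treatments always retained) and writes the
ranking to results/preselection.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from jdmjm import filter_history_complete, preselect_covariates, read_cohort, read_roster

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
parser.add_argument("--out", type=Path, default=Path("results/preselection.csv"))
args = parser.parse_args()

roster = read_roster(args.cohort_dir / "roster.yaml")
cohort = read_cohort(args.cohort_dir / "visits.csv", roster)
cohort, excl = filter_history_complete(cohort)
res = preselect_covariates(cohort)

args.out.parent.mkdir(parents=True, exist_ok=True)
pd.DataFrame([
    {"covariate": n, "max_abs_wald": w, "selected": n in res.selected}
    for n, w in sorted(res.ranking.items(), key=lambda kv: -kv[1])
]).to_csv(args.out, index=False)
print("selected:", ", ".join(res.selected))
print(f"excluded visits (incomplete history): {len(excl.dropped_visits)}")
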