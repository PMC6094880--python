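"""Generate the study cohort: 150 patients under the paper-like preset.

Writes the visit table, the covariate roster, and the generating-parameter
sidecar under results/cohort/.
"""

import argparse
from pathlib import Path

from jdmjm import CohortDesign, default_truth, simulate_cohort, write_roster

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--preset", default="paper_like")
parser.add_argument("--n-patients", type=int, default=150)
parser.add_argument("--seed", type=int, default=20180501)
parser.add_argument("--out", type=Path, default=Path("results/cohort"))
args = parser.parse_args()

truth = default_truth(args.preset)
design = CohortDesign(n_patients=args.n_patients, seed=args.seed)
cohort, latent = simulate_cohort(design, truth)

args.out.mkdir(parents=True, exist_ok=True)
cohort.df.drop(columns=["patient_index"]).to_csv(
    args.out / "visits.csv", index=False, na_rep="NA")
write_roster(truth.roster, args.out / "roster.yaml")
truth.to_json(args.out / "truth.json")

n_best = {c: int((latent.at_best[c]).sum()) for c in latent.at_best.columns}
print(f"{cohort.n_patients} patients, {len(cohort.df)} visits -> {args.out}")
print(f"visits at the best value: {n_best}")
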