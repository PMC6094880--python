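"""Sampler self-validation: Geweke joint-distribution test on a small model.

Writes the per-statistic z-table to results/geweke.csv; exits non-zero on
rejection.
"""

import argparse
import sys
from pathlib import Path

from jdmjm import geweke_test

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results/geweke.csv"))
args = parser.parse_args()

res = geweke_test(seed=args.seed)
args.out.parent.mkdir(parents=True, exist_ok=True)
res.table.sort_values("p").to_csv(args.out, index=False)
print(res.table.sort_values("p").head(8).to_string(index=False))
print(f"passed at level {res.alpha}: {res.passed}")
sys.exit(0 if res.passed else 1)
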