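"""Multi-trial rank sweep with the experiments driver.

Runs the full protocol (per-trial baseline re-estimation, shared derived
seeds across methods) on the three-group benchmark where two groups share a
subspace, and prints the aggregated per-group mean errors and the summary
report.  The same sweep is available from the shell:

    fairnmf sweep --input synthetic-2 --ranks 1-3 --trials 3 \
        --methods standard-mu,fairer-am --seed 0 --out results/sweep2
"""

import json

from fairnmf import ExperimentSpec, run_rank_sweep, summarize

spec = ExperimentSpec(
    source="synthetic-2",
    ranks=(1, 2, 3),
    trials=3,
    methods=("standard-mu", "fairer-am"),
    seed=0,
)
raw, agg, failures = run_rank_sweep(spec)
assert failures == 0

print(agg[["method", "rank", "group", "mean_error_pct", "mean_loss"]].to_string(index=False))
print()
report = summarize(raw)
print(json.dumps(report["methods"], indent=2))
print(
    "\nAt low rank, standard NMF spends its budget on the shared subspace of\n"
    "groups 1-2 and the orthogonal group 3 carries the highest loss; the\n"
    "min-max solver narrows that gap (smaller mean_max_loss / loss gap)."
)
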