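"""Step 3 — audit whether confidence selects against the second fold.

Builds nested confidence pools (All ⊇ Medium ⊇ Good ⊇ High from the
fraction of residues with pLDDT >= 70), reranks models by that fraction,
and writes under results/confidence/: census.tsv (per protein x pool x
conformation model counts and predicted flags), trendlines.tsv (label
fractions for All/Top10/Top1 selections within each pool) and
depletion_tests.json (exact one-sided binomial lower tails comparing
high-confidence identification counts to the all-models rate).
"""

import json
from pathlib import Path

import pandas as pd

from foldswitch_bench import benchmark, confidence
from foldswitch_bench.pipeline import load_predictions, run_assess, run_rerank

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "results" / "simulated"
OUT = ROOT / "results" / "confidence"


def main() -> None:
    per_protein = run_assess(SIM / "pairs.tsv", SIM / "models", OUT)
    pairs = benchmark.read_pair_table(SIM / "pairs.tsv")
    summaries = {
        pair.id: [
            confidence.summarize(p.model_id, p.plddt)
            for p in load_predictions(SIM / "models" / pair.id)
        ]
        for pair in pairs
    }
    run_rerank(per_protein, summaries, OUT)
    tests = json.loads((OUT / "depletion_tests.json").read_text())
    for conformation, t in tests.items():
        print(f"{conformation}: {t['k']} of {t['n']} proteins identified in the "
              f"High pool vs rate {t['p0']:.3f} overall -> one-sided p = {t['pvalue']:.3g}")
    if not tests:
        print("protein-level depletion test degenerate (each conformation was "
              "found for all or for none of the proteins); testing at model level")

    # model-level counterpart: is the fraction of Fold2-labelled models among
    # High-pool models depleted relative to the fraction among all models?
    census = pd.read_csv(OUT / "census.tsv", sep="\t")
    totals = census.groupby("pool").n_models.sum()
    for conformation in ("Fold1", "Fold2"):
        sub = census[census.conformation == conformation]
        k_all = int(sub[sub.pool == "All"].n_models.sum())
        k_high = int(sub[sub.pool == "High"].n_models.sum())
        n_all, n_high = int(totals["All"]), int(totals.get("High", 0))
        if n_high == 0 or not 0 < k_all < n_all:
            continue
        p = confidence.binom_lower(k_high, n_high, k_all / n_all)
        print(f"{conformation} models: {k_high}/{n_high} in the High pool vs "
              f"{k_all}/{n_all} overall -> one-sided p = {p:.3g}")


if __name__ == "__main__":
    main()
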