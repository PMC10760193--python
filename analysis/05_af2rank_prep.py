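"""Step 5 — template preparation and fold ranking on the simulated pairs.

For every pair from step 1: check eligibility (fragment coverage and gap
limits), write template-ready PDBs for both conformations (backbone + CB
only, glycine CB rebuilt, MSE/SEC standardized), and rank the two folds.
Ranking uses the composite score tm * ptm * (pLDDT / 100) computed from
each protein's most confident model: its TM-score against each
conformation (from step 2's assessments.tsv) and its mean pLDDT; the
simulator emits no pTM, so ptm is proxied by mean pLDDT / 100 here.
Outputs land under results/af2rank/ (eligibility.tsv, *_template.pdb,
verdicts.tsv).
"""

from pathlib import Path
from statistics import mean

import pandas as pd

from foldswitch_bench import af2rank, benchmark
from foldswitch_bench.pipeline import load_predictions
from foldswitch_bench.structio import write_structure

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "results" / "simulated"
ASSESS = ROOT / "results" / "assess"
OUT = ROOT / "results" / "af2rank"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pairs = benchmark.read_pair_table(SIM / "pairs.tsv")
    assessments = pd.read_csv(ASSESS / "assessments.tsv", sep="\t").set_index("model_id")

    eligibility_rows = ["id\tstatus\treasons"]
    verdicts = []
    for pair in pairs:
        ok, reasons = af2rank.eligibility(pair)
        eligibility_rows.append(
            f"{pair.id}\t{'include' if ok else 'exclude'}\t{';'.join(reasons)}"
        )
        if not ok:
            continue
        for tag, conf in (("a", pair.conf_a), ("b", pair.conf_b)):
            prepared = af2rank.prepare_template(conf)
            write_structure(prepared.template, OUT / f"{pair.id}_{tag}_template.pdb")

        preds = load_predictions(SIM / "models" / pair.id)
        best = max(preds, key=lambda p: mean(p.plddt))
        plddt = mean(best.plddt)
        row = assessments.loc[best.model_id]
        scores_a = af2rank.RankScores.from_raw(tm=row.tm1, ptm=plddt / 100, plddt=plddt)
        scores_b = af2rank.RankScores.from_raw(tm=row.tm2, ptm=plddt / 100, plddt=plddt)
        verdicts.append(af2rank.rank_folds(scores_a, scores_b, pair))

    (OUT / "eligibility.tsv").write_text("\n".join(eligibility_rows) + "\n")
    lines = ["pair_id\tverdict\tcorrect"]
    lines += [f"{v.pair_id}\t{v.verdict}\t{v.correct}" for v in verdicts]
    (OUT / "verdicts.tsv").write_text("\n".join(lines) + "\n")
    accuracy = af2rank.ground_state_accuracy(verdicts)
    print(f"templates and verdicts for {len(verdicts)} eligible pairs under {OUT}")
    print(f"ground-state ranking accuracy: {accuracy:.3f}")


if __name__ == "__main__":
    main()
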