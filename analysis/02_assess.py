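"""Step 2 — assess every simulated model against both conformations.

Reads results/simulated/ from step 1 and writes, under results/assess/:
assessments.tsv (per-model TM/RMSD against each conformation plus the
Fold1/Fold2/Other label), per_protein.tsv (dual-success flags) and
summary.json (label fractions and the dual-conformation success rate).
"""

import json
from pathlib import Path

from foldswitch_bench.pipeline import run_assess

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "results" / "simulated"
OUT = ROOT / "results" / "assess"


def main() -> None:
    per_protein = run_assess(SIM / "pairs.tsv", SIM / "models", OUT)
    summary = json.loads((OUT / "summary.json").read_text())
    print(f"assessed {sum(len(v) for v in per_protein.values())} models "
          f"of {summary['n_proteins']} proteins")
    print(f"success rate (both folds among defaults): {summary['success_rate']:.3f}")
    print(f"label fractions  Fold1 {summary['fraction_fold1']:.3f}  "
          f"Fold2 {summary['fraction_fold2']:.3f}  "
          f"Other {summary['fraction_other']:.3f}")


if __name__ == "__main__":
    main()
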