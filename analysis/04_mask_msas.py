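"""Step 4 — generate alanine-masked MSAs for a packed conformation.

Builds a packed beta-hairpin from the first simulated pair's sequence (the
extended simulated conformations themselves have no long-range contacts,
so a hairpin makes the contact-exclusion rule visible), synthesizes an
alignment for that sequence, and writes one masked a3m per 11-residue
window sliding over the fold-switching region (plus manifest.tsv) under
results/masked_msas/. Masked columns are the window itself and every
sequence-distant residue with a heavy atom within 4 A of the window.
"""

from pathlib import Path

from foldswitch_bench import benchmark, speach
from foldswitch_bench.synthetic import build_hairpin, synth_msa

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "results" / "simulated"
OUT = ROOT / "results" / "masked_msas"
MSA_DEPTH = 32
MSA_SEED = 7


def main() -> None:
    pair = benchmark.read_pair_table(SIM / "pairs.tsv")[0]
    structure = build_hairpin(pair.conf_b.sequence)
    msa = synth_msa(structure.sequence, MSA_DEPTH, seed=MSA_SEED)
    manifest = speach.generate_all(structure, msa, pair.region_b, OUT)
    n_contacts = sum(1 for m in manifest if int(m["n_masked"]) > 0)
    print(f"wrote {len(manifest)} masked MSAs for {pair.id} under {OUT}")
    print(f"{n_contacts} windows masked residues beyond the window itself (contacts)")


if __name__ == "__main__":
    main()
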