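"""Disk-facing workflow glue shared by the CLI and the analysis drivers.

The on-disk layout mirrors what a real benchmark consumes: a pair-table TSV
naming two experimental PDB files per protein, directories of predicted
models (one PDB per model, pLDDT in the B-factor column), and a3m MSAs.
The synthetic simulator writes exactly this layout, so the downstream
commands cannot tell fixtures from real inputs.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import benchmark, confidence, speach, synthetic
from .benchmark import Assessment, FoldSwitchPair, PredictionRecord
from .structio import RegionSpec, plddt_profile, read_structure, write_structure

log = logging.getLogger("foldswitch_bench")

__all__ = [
    "simulate_to_disk",
    "load_predictions",
    "run_assess",
    "run_rerank",
]


def simulate_to_disk(spec: synthetic.ScenarioSpec, out_dir: str | Path) -> Path:
    """Materialize a scenario as pair table + experimental PDBs + model dirs."""
    out_dir = Path(out_dir)
    (out_dir / "experimental").mkdir(parents=True, exist_ok=True)
    scn = synthetic.scenario(spec)
    rows = []
    truth_rows = []
    for prot in scn.proteins:
        pair = prot.pair
        pa = f"experimental/{pair.id}_a.pdb"
        pb = f"experimental/{pair.id}_b.pdb"
        write_structure(pair.conf_a, out_dir / pa)
        write_structure(pair.conf_b, out_dir / pb)
        rows.append(
            {
                "id": pair.id,
                "pdb_a": pa,
                "chain_a": pair.conf_a.chain,
                "region_a": str(pair.region_a),
                "pdb_b": pb,
                "chain_b": pair.conf_b.chain,
                "region_b": str(pair.region_b),
                "ground_state": pair.ground_state,
            }
        )
        model_dir = out_dir / "models" / pair.id
        model_dir.mkdir(parents=True, exist_ok=True)
        for pred, label in zip(prot.predictions, prot.true_labels):
            write_structure(pred.structure, model_dir / f"{pred.model_id}.pdb")
            truth_rows.append({"model_id": pred.model_id, "protein": pair.id, "true_label": label})
    benchmark.write_pair_table(rows, out_dir / "pairs.tsv")
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    log.info("simulated %d proteins x %d models under %s", spec.n_proteins, spec.n_models, out_dir)
    return out_dir / "pairs.tsv"


def load_predictions(models_dir: str | Path, method: str = "unknown") -> list[PredictionRecord]:
    """Read every model PDB in a directory (pLDDT from the B-factor column)."""
    models_dir = Path(models_dir)
    paths = sorted(models_dir.glob("*.pdb"))
    if not paths:
        raise FileNotFoundError(f"no model PDB files under {models_dir}")
    preds = []
    for p in paths:
        structure = read_structure(p, "A")
        preds.append(
            PredictionRecord(
                model_id=p.stem,
                method=method,
                structure=structure,
                plddt=tuple(plddt_profile(structure)),
            )
        )
    return preds


def _assess_protein(pair: FoldSwitchPair, preds: Sequence[PredictionRecord]) -> list[Assessment]:
    out = []
    for pred in preds:
        a = benchmark.assess(pred, pair)
        cat = confidence.category(confidence.confident_fraction(pred.plddt))
        out.append(
            Assessment(
                model_id=a.model_id, tm1=a.tm1, tm2=a.tm2, rmsd1=a.rmsd1,
                rmsd2=a.rmsd2, label=a.label, method=a.method, category=cat,
            )
        )
    return out


def run_assess(
    pair_table: str | Path, models_root: str | Path, out_dir: str | Path
) -> dict[str, list[Assessment]]:
    """Assess every model of every protein; write per-model and per-protein reports."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = benchmark.read_pair_table(pair_table)
    models_root = Path(models_root)
    per_protein: dict[str, list[Assessment]] = {}
    for pair in pairs:
        preds = load_predictions(models_root / pair.id)
        per_protein[pair.id] = _assess_protein(pair, preds)
        log.info("assessed %d models of %s", len(preds), pair.id)
    all_assessments = [a for rows in per_protein.values() for a in rows]
    benchmark.write_assessment_report(all_assessments, out_dir / "assessments.tsv")
    fractions = benchmark.label_fractions(all_assessments)
    summary = pd.DataFrame(
        [
            {
                "protein": pid,
                "n_models": len(rows),
                "dual_success": benchmark.dual_success(rows),
            }
            for pid, rows in per_protein.items()
        ]
    )
    summary.to_csv(out_dir / "per_protein.tsv", sep="\t", index=False)
    rate = benchmark.success_rate(per_protein)
    (out_dir / "summary.json").write_text(
        json.dumps(
            {
                "n_proteins": len(per_protein),
                "success_rate": rate,
                "fraction_fold1": fractions[0],
                "fraction_fold2": fractions[1],
                "fraction_other": fractions[2],
            },
            indent=2,
        )
    )
    return per_protein


def _pool_assessments(
    per_protein: Mapping[str, Sequence[Assessment]]
) -> dict[str, dict[str, list[Assessment]]]:
    """Assessments grouped pool -> protein using nested confidence pools."""
    thresholds = {"All": 0.0, **{k: v for k, v in confidence.CATEGORY_THRESHOLDS.items()}}
    joined: dict[str, dict[str, list[Assessment]]] = {p: defaultdict(list) for p in confidence.POOL_ORDER}
    # categories are ordered None < Medium < Good < High; a model enters every
    # pool whose threshold its confident fraction meets
    rank = {"None": 0, "Medium": 1, "Good": 2, "High": 3}
    for protein, rows in per_protein.items():
        for a in rows:
            level = rank.get(a.category, 0)
            joined["All"][protein].append(a)
            if level >= 1:
                joined["Medium"][protein].append(a)
            if level >= 2:
                joined["Good"][protein].append(a)
            if level >= 3:
                joined["High"][protein].append(a)
    return {pool: dict(by_prot) for pool, by_prot in joined.items()}


def run_rerank(
    per_protein: Mapping[str, Sequence[Assessment]],
    summaries: Mapping[str, Sequence[confidence.ConfidenceSummary]],
    out_dir: str | Path,
) -> pd.DataFrame:
    """Confidence pools, Top1/Top10/All label fractions, census, depletion tests.

    ``summaries`` maps protein -> per-model confidence summaries (joinable to
    the assessments by model_id).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pooled = _pool_assessments(per_protein)
    census_df = benchmark.census(pooled)
    census_df.to_csv(out_dir / "census.tsv", sep="\t", index=False)

    assessment_by_id = {
        a.model_id: a for rows in per_protein.values() for a in rows
    }
    trend_rows = []
    for protein, summ in summaries.items():
        ordered = confidence.rerank(summ)
        for top_name, k in (("All", None), ("Top10", 10), ("Top1", 1)):
            chosen = ordered if k is None else ordered[: min(k, len(ordered))]
            for pool_name, thr in (("All", 0.0), ("Medium", 0.7), ("Good", 0.8), ("High", 0.9)):
                in_pool = [m for m in chosen if m.confident_fraction >= thr]
                if not in_pool:
                    continue
                fr = benchmark.label_fractions([assessment_by_id[m.model_id] for m in in_pool])
                trend_rows.append(
                    {
                        "protein": protein,
                        "selection": top_name,
                        "pool": pool_name,
                        "n": len(in_pool),
                        "fraction_fold1": fr[0],
                        "fraction_fold2": fr[1],
                        "fraction_other": fr[2],
                    }
                )
    trend = pd.DataFrame(trend_rows)
    trend.to_csv(out_dir / "trendlines.tsv", sep="\t", index=False)

    # depletion of each conformation among high-confidence identifications
    n = len(per_protein)
    tests = {}
    flags = census_df.pivot_table(
        index=["conformation", "pool"], values="predicted", aggfunc="sum"
    )
    for conformation in ("Fold1", "Fold2"):
        try:
            k_all = int(flags.loc[(conformation, "All"), "predicted"])
            k_high = int(flags.loc[(conformation, "High"), "predicted"])
        except KeyError:
            continue
        if 0 < k_all < n:
            t = confidence.depletion_test(k_high, k_all, n)
            tests[conformation] = {"k": t.k, "n": t.n, "p0": t.p0, "pvalue": t.pvalue}
    (out_dir / "depletion_tests.json").write_text(json.dumps(tests, indent=2))
    return trend
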