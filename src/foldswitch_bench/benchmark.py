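"""Classification of predicted models against paired experimental conformations.

Each fold-switching protein has two experimentally determined conformations.
Fold1 is defined as the conformation a predictor's five default-mode models
favor (majority over regional TM-scores); Fold2 is the other. A prediction
is labelled Fold1 or Fold2 when its fold-switching-region TM-score against
that conformation exceeds 0.6 (ties broken by the larger TM), and Other when
neither exceeds 0.6. A protein counts as a success only when at least one
model captures each conformation — sampling one fold of a fold switcher is
not success.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .similarity import rmsd_backbone, tm_score
from .structio import RegionSpec, Structure, StructureError, read_structure

__all__ = [
    "TM_SUCCESS_THRESHOLD",
    "FoldSwitchPair",
    "PredictionRecord",
    "Assessment",
    "assign_label",
    "assess",
    "order_folds",
    "dual_success",
    "success_rate",
    "label_fractions",
    "census",
    "read_pair_table",
    "write_assessment_report",
]

TM_SUCCESS_THRESHOLD = 0.6
LABELS = ("Fold1", "Fold2", "Other")


@dataclass(frozen=True)
class FoldSwitchPair:
    """Two experimental conformations of one fold-switching protein."""

    id: str
    conf_a: Structure
    conf_b: Structure
    region_a: RegionSpec
    region_b: RegionSpec
    ground_state: str = "A"  # {A, B, both}
    fold1_is: str = "unset"  # {A, B, unset}

    def __post_init__(self) -> None:
        if self.ground_state not in ("A", "B", "both"):
            raise ValueError(f"invalid ground_state {self.ground_state!r}")
        if self.fold1_is not in ("A", "B", "unset"):
            raise ValueError(f"invalid fold1_is {self.fold1_is!r}")

    def fold1(self) -> tuple[Structure, RegionSpec]:
        which = "A" if self.fold1_is == "unset" else self.fold1_is
        return (self.conf_a, self.region_a) if which == "A" else (self.conf_b, self.region_b)

    def fold2(self) -> tuple[Structure, RegionSpec]:
        which = "A" if self.fold1_is == "unset" else self.fold1_is
        return (self.conf_b, self.region_b) if which == "A" else (self.conf_a, self.region_a)


@dataclass(frozen=True)
class PredictionRecord:
    model_id: str
    method: str
    structure: Structure
    plddt: tuple[float, ...]
    seed: int | None = None
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.plddt) != len(self.structure):
            raise ValueError(
                f"pLDDT length {len(self.plddt)} != residue count {len(self.structure)}"
            )


@dataclass(frozen=True)
class Assessment:
    model_id: str
    tm1: float
    tm2: float
    rmsd1: float
    rmsd2: float
    label: str
    method: str = ""
    category: str = ""

    def __post_init__(self) -> None:
        expected = assign_label(self.tm1, self.tm2)
        if self.label != expected:
            raise ValueError(
                f"label {self.label} inconsistent with TM-scores "
                f"({self.tm1}, {self.tm2}) -> {expected}"
            )


def assign_label(tm1: float, tm2: float, threshold: float = TM_SUCCESS_THRESHOLD) -> str:
    """Fold1/Fold2 when the corresponding TM exceeds the threshold (larger
    wins when both do, ties to Fold1); Other when neither exceeds it."""
    for v in (tm1, tm2):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"TM-score {v} outside [0, 1]")
    if tm1 <= threshold and tm2 <= threshold:
        return "Other"
    if tm1 > threshold and (tm2 <= threshold or tm1 >= tm2):
        return "Fold1"
    return "Fold2"


def assess(pred: PredictionRecord, pair: FoldSwitchPair) -> Assessment:
    """TM-scores and backbone RMSDs of one model against both conformations."""
    f1_struct, f1_region = pair.fold1()
    f2_struct, f2_region = pair.fold2()
    s1 = tm_score(pred.structure, f1_struct, f1_region)
    s2 = tm_score(pred.structure, f2_struct, f2_region)
    return Assessment(
        model_id=pred.model_id,
        tm1=s1.tm,
        tm2=s2.tm,
        rmsd1=s1.rmsd,
        rmsd2=s2.rmsd,
        label=assign_label(s1.tm, s2.tm),
        method=pred.method,
    )


def order_folds(defaults: Sequence[PredictionRecord], pair: FoldSwitchPair) -> str:
    """Which conformation is Fold1, by majority over five default-mode models.

    Each model votes for the conformation with the larger regional TM; exact
    ties count toward neither. If no conformation reaches three votes, the
    one with the larger mean TM wins.
    """
    if len(defaults) != 5:
        raise ValueError(f"exactly 5 default predictions required, got {len(defaults)}")
    wins = Counter()
    sums = {"A": 0.0, "B": 0.0}
    for pred in defaults:
        tma = tm_score(pred.structure, pair.conf_a, pair.region_a).tm
        tmb = tm_score(pred.structure, pair.conf_b, pair.region_b).tm
        if tma > tmb:
            wins["A"] += 1
        elif tmb > tma:
            wins["B"] += 1
        sums["A"] += tma
        sums["B"] += tmb
    if wins["A"] >= 3:
        return "A"
    if wins["B"] >= 3:
        return "B"
    return "A" if sums["A"] >= sums["B"] else "B"


def dual_success(assessments: Iterable[Assessment]) -> bool:
    """True iff the ensemble captured both conformations at least once."""
    labels = {a.label for a in assessments}
    return "Fold1" in labels and "Fold2" in labels


def success_rate(per_protein: Mapping[str, Sequence[Assessment]]) -> float:
    """Fraction of proteins whose ensembles capture both conformations."""
    if not per_protein:
        raise ValueError("empty protein map")
    n_success = sum(dual_success(a) for a in per_protein.values())
    return n_success / len(per_protein)


def label_fractions(assessments: Sequence[Assessment]) -> tuple[float, float, float]:
    """(fraction Fold1, fraction Fold2, fraction Other); sums to 1."""
    if not assessments:
        raise ValueError("no assessments to summarize")
    counts = Counter(a.label for a in assessments)
    n = len(assessments)
    return tuple(counts.get(label, 0) / n for label in LABELS)


def census(
    pools: Mapping[str, Mapping[str, Sequence[Assessment]]]
) -> pd.DataFrame:
    """Nij table: model counts per (conformation i, protein j, pool).

    ``pools`` maps pool name -> protein id -> assessments in that pool. A
    conformation counts as predicted within a pool when Nij >= 1.
    """
    records = []
    for pool_name, by_protein in pools.items():
        for protein_id, assessments in by_protein.items():
            counts = Counter(a.label for a in assessments)
            for label in LABELS:
                n = counts.get(label, 0)
                records.append(
                    {
                        "pool": pool_name,
                        "protein": protein_id,
                        "conformation": label,
                        "n_models": n,
                        "predicted": n >= 1,
                    }
                )
    return pd.DataFrame.from_records(
        records, columns=["pool", "protein", "conformation", "n_models", "predicted"]
    )


def read_pair_table(path: str | Path, base_dir: str | Path | None = None) -> list[FoldSwitchPair]:
    """Load fold-switch pairs from the TSV pair table.

    Columns: id, pdb_a, chain_a, region_a, pdb_b, chain_b, region_b,
    ground_state; regions written as "start-end"; structure paths resolved
    relative to ``base_dir`` (default: the table's directory).
    """
    path = Path(path)
    base = Path(base_dir) if base_dir is not None else path.parent
    pairs = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            conf_a = read_structure(base / row["pdb_a"], row["chain_a"])
            conf_b = read_structure(base / row["pdb_b"], row["chain_b"])
            pairs.append(
                FoldSwitchPair(
                    id=row["id"],
                    conf_a=conf_a,
                    conf_b=conf_b,
                    region_a=RegionSpec.parse(row["region_a"], row["chain_a"]),
                    region_b=RegionSpec.parse(row["region_b"], row["chain_b"]),
                    ground_state=row.get("ground_state", "A") or "A",
                )
            )
    if not pairs:
        raise ValueError(f"pair table {path} has no rows")
    return pairs


def write_pair_table(rows: Sequence[dict], path: str | Path) -> Path:
    fields = ["id", "pdb_a", "chain_a", "region_a", "pdb_b", "chain_b", "region_b", "ground_state"]
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields, delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)
    return path


def write_assessment_report(
    assessments: Sequence[Assessment], path: str | Path
) -> Path:
    df = pd.DataFrame(
        [
            {
                "model_id": a.model_id,
                "method": a.method,
                "tm1": a.tm1,
                "tm2": a.tm2,
                "rmsd1": a.rmsd1,
                "rmsd2": a.rmsd2,
                "label": a.label,
                "category": a.category,
            }
            for a in assessments
        ]
    )
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path
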