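"""Template-comparison ("energy ranking") support for paired conformations.

A predictor run with an experimental structure as a template — but no MSA
and no sidechains to reveal residue identity — scores how compatible that
conformation is with the sequence. Passing each fold of a fold-switch pair
as a template and comparing composite confidence scores asks whether the
model's learned energetics prefer the ground state. This module prepares
templates (standardize seleno residues, strip sidechains, mask glycine with
an ideal CB), filters eligible pairs, combines scores, and tallies
ground-state ranking accuracy. Running the predictor itself is external.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .benchmark import FoldSwitchPair
from .structio import (
    TEMPLATE_ATOMS,
    RegionSpec,
    Structure,
    add_glycine_cb,
    standardize_residues,
    strip_sidechains,
)

__all__ = [
    "TemplateArtifacts",
    "RankScores",
    "Verdict",
    "eligibility",
    "prepare_template",
    "composite",
    "rank_folds",
    "ground_state_accuracy",
]


@dataclass(frozen=True)
class TemplateArtifacts:
    template: Structure
    provenance: tuple[str, ...]

    def __post_init__(self) -> None:
        for res in self.template.residues:
            for atom in res.atoms:
                if atom.name not in TEMPLATE_ATOMS:
                    raise ValueError(
                        f"template atom {atom.name} outside backbone+CB set"
                    )
            if res.name == "GLY" and res.atom("CB") is None:
                raise ValueError(f"glycine {res.number} lacks a CB in template")


@dataclass(frozen=True)
class RankScores:
    plddt: float  # mean per-model, 0-100
    ptm: float  # 0-1
    tm_out_template: float  # TM of predictor output vs its template, 0-1
    composite: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.plddt <= 100.0:
            raise ValueError("plddt outside [0, 100]")
        for name in ("ptm", "tm_out_template", "composite"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")

    @classmethod
    def from_raw(cls, tm: float, ptm: float, plddt: float) -> "RankScores":
        return cls(
            plddt=plddt,
            ptm=ptm,
            tm_out_template=tm,
            composite=composite(tm, ptm, plddt),
        )


@dataclass(frozen=True)
class Verdict:
    pair_id: str
    verdict: str  # {A, B, undetermined, excluded}
    correct: bool | None  # None when the pair has no definite ground state


def _gap_runs(s: Structure, region: RegionSpec) -> int:
    """Longest run of consecutive unresolved residue numbers inside the region."""
    present = {r.number for r in s.residues}
    longest = run = 0
    for n in range(region.start, region.end + 1):
        if n in present:
            run = 0
        else:
            run += 1
            longest = max(longest, run)
    return longest


def eligibility(
    pair: FoldSwitchPair, max_gap: int = 5, min_frac: float = 0.5
) -> tuple[bool, list[str]]:
    """Template-protocol eligibility: exclude short fragments and pairs with
    long gaps in the fold-switching region."""
    reasons = []
    la, lb = len(pair.conf_a), len(pair.conf_b)
    if min(la, lb) < min_frac * max(la, lb):
        reasons.append(
            f"short fragment: conformation lengths {la} vs {lb} "
            f"(< {min_frac:.0%} of the longer)"
        )
    for name, s, region in (("A", pair.conf_a, pair.region_a), ("B", pair.conf_b, pair.region_b)):
        gap = _gap_runs(s, region)
        if gap > max_gap:
            reasons.append(f"long gap: {gap} consecutive residues missing in conf {name}")
    return (not reasons), reasons


def prepare_template(s: Structure) -> TemplateArtifacts:
    """Standardize seleno residues, strip sidechains, add glycine CB.

    The result carries no residue-identity information beyond the backbone
    and a uniform CB, so the predictor cannot read the sequence off the
    template. Idempotent.
    """
    out = standardize_residues(s)
    out = strip_sidechains(out)
    out = add_glycine_cb(out)
    return TemplateArtifacts(
        template=out,
        provenance=("standardize_residues", "strip_sidechains", "add_glycine_cb"),
    )


def composite(tm: float, ptm: float, plddt: float) -> float:
    """Composite confidence: product of TM, pTM, and pLDDT/100.

    Monotone non-decreasing in each argument and confined to [0, 1]; the
    combination rule is configurable at the call sites that rank folds.
    """
    for name, v, hi in (("tm", tm, 1.0), ("ptm", ptm, 1.0), ("plddt", plddt, 100.0)):
        if not 0.0 <= v <= hi:
            raise ValueError(f"{name}={v} outside [0, {hi}]")
    return tm * ptm * (plddt / 100.0)


def rank_folds(
    scores_a: RankScores, scores_b: RankScores, pair: FoldSwitchPair
) -> Verdict:
    """Which conformation does the predictor score higher, and is it the
    ground state? Pairs that populate both folds at equilibrium are reported
    but excluded from accuracy."""
    if pair.ground_state == "both":
        return Verdict(pair_id=pair.id, verdict="excluded", correct=None)
    if scores_a.composite > scores_b.composite:
        verdict = "A"
    elif scores_b.composite > scores_a.composite:
        verdict = "B"
    elif scores_a.plddt > scores_b.plddt:
        verdict = "A"
    elif scores_b.plddt > scores_a.plddt:
        verdict = "B"
    else:
        return Verdict(pair_id=pair.id, verdict="undetermined", correct=None)
    return Verdict(pair_id=pair.id, verdict=verdict, correct=verdict == pair.ground_state)


def ground_state_accuracy(verdicts: Iterable[Verdict]) -> float:
    """Fraction of correct verdicts among pairs with a definite ground state."""
    scored = [v for v in verdicts if v.correct is not None]
    if not scored:
        raise ValueError("no scored pairs with a definite ground state")
    return sum(v.correct for v in scored) / len(scored)
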