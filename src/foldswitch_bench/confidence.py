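"""Confidence auditing of predicted-model ensembles.

A model's headline confidence here is the fraction of its residues with
pLDDT >= 70 ("confident residues"). Models are binned into nested pools —
All, Medium (>= 70% confident residues), Good (>= 80%), High (>= 90%) — and
reranked by that fraction to ask whether high-confidence models are enriched
or depleted for a given conformation. Depletion is tested with an exact
one-sided binomial test: if the overall identification rate among n proteins
is k_all/n, how surprising is seeing only k_high identifications among
high-confidence models?
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .benchmark import Assessment, census, label_fractions

__all__ = [
    "PLDDT_CONFIDENT",
    "CATEGORY_THRESHOLDS",
    "ConfidenceSummary",
    "DepletionTest",
    "confident_fraction",
    "category",
    "summarize",
    "pools",
    "rerank",
    "topk_summary",
    "binom_lower",
    "depletion_test",
]

PLDDT_CONFIDENT = 70.0
CATEGORY_THRESHOLDS = {"High": 0.9, "Good": 0.8, "Medium": 0.7}
POOL_ORDER = ("All", "Medium", "Good", "High")


@dataclass(frozen=True)
class ConfidenceSummary:
    model_id: str
    confident_fraction: float
    mean_plddt: float
    category: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.confident_fraction <= 1.0:
            raise ValueError("confident_fraction outside [0, 1]")
        if self.category != _category_of(self.confident_fraction):
            raise ValueError(
                f"category {self.category} inconsistent with fraction "
                f"{self.confident_fraction}"
            )


@dataclass(frozen=True)
class DepletionTest:
    k: int
    n: int
    p0: float
    pvalue: float

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError("k outside [0, n]")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 outside (0, 1)")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps({"k": self.k, "n": self.n, "p0": self.p0, "pvalue": self.pvalue})
        )
        return path


def confident_fraction(plddt: Sequence[float], cutoff: float = PLDDT_CONFIDENT) -> float:
    """Share of residues with pLDDT >= cutoff."""
    if len(plddt) == 0:
        raise ValueError("empty pLDDT profile")
    arr = np.asarray(plddt, dtype=float)
    if arr.min() < 0 or arr.max() > 100:
        raise ValueError("pLDDT values outside [0, 100]")
    return float((arr >= cutoff).mean())


def _category_of(fraction: float) -> str:
    if fraction >= CATEGORY_THRESHOLDS["High"]:
        return "High"
    if fraction >= CATEGORY_THRESHOLDS["Good"]:
        return "Good"
    if fraction >= CATEGORY_THRESHOLDS["Medium"]:
        return "Medium"
    return "None"


def category(fraction: float) -> str:
    """High/Good/Medium at >= 90/80/70% confident residues, else None."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    return _category_of(fraction)


def summarize(model_id: str, plddt: Sequence[float]) -> ConfidenceSummary:
    frac = confident_fraction(plddt)
    return ConfidenceSummary(
        model_id=model_id,
        confident_fraction=frac,
        mean_plddt=float(np.mean(plddt)),
        category=category(frac),
    )


def pools(models: Iterable[ConfidenceSummary]) -> dict[str, list[ConfidenceSummary]]:
    """Nested pools All ⊇ Medium ⊇ Good ⊇ High (a High model is in all four)."""
    models = list(models)
    out: dict[str, list[ConfidenceSummary]] = {"All": models}
    for name, thr in CATEGORY_THRESHOLDS.items():
        out[name] = [m for m in models if m.confident_fraction >= thr]
    return {name: out[name] for name in POOL_ORDER}


def rerank(models: Iterable[ConfidenceSummary]) -> list[ConfidenceSummary]:
    """Descending confident fraction; ties by mean pLDDT then model_id."""
    return sorted(
        models,
        key=lambda m: (-m.confident_fraction, -m.mean_plddt, m.model_id),
    )


def topk_summary(
    ordered: Sequence[ConfidenceSummary],
    k: int | None,
    assessments: Mapping[str, Assessment],
):
    """Label fractions and conformation census over the k most confident models.

    ``k=None`` means All. Assessments are joined by model_id; a missing join
    is an error because every reranked model must have been assessed.
    """
    if k is not None and k < 1:
        raise ValueError("k must be positive or None")
    selected = list(ordered) if k is None else list(ordered)[: min(k, len(ordered))]
    try:
        chosen = [assessments[m.model_id] for m in selected]
    except KeyError as exc:
        raise KeyError(f"no assessment for model {exc.args[0]}") from exc
    fractions = label_fractions(chosen)
    counts = census({"selected": {"all": chosen}})
    predicted = {
        row["conformation"]: bool(row["predicted"])
        for _, row in counts.iterrows()
    }
    return fractions, predicted


def binom_lower(k: int, n: int, p0: float) -> float:
    """Exact lower-tail binomial probability P(X <= k), X ~ Binomial(n, p0).

    Terms are computed in log space and accumulated from smallest to largest
    so tiny tails below 1e-300 in individual terms still sum stably.
    """
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0={p0} outside (0, 1)")
    ks = np.arange(0, k + 1)
    log_terms = (
        gammaln(n + 1)
        - gammaln(ks + 1)
        - gammaln(n - ks + 1)
        + ks * np.log(p0)
        + (n - ks) * np.log1p(-p0)
    )
    terms = np.exp(np.sort(log_terms))
    return float(min(1.0, terms.sum()))


def depletion_test(k_high: int, k_all: int, n: int) -> DepletionTest:
    """Is a conformation identified less often among high-confidence models?

    Null: the identification rate among high-confidence models equals the
    overall rate k_all/n; the p-value is the exact lower tail P(X <= k_high).
    """
    if not 0 <= k_high <= n or not 0 <= k_all <= n:
        raise ValueError("counts outside [0, n]")
    if k_all in (0, n):
        raise ValueError("overall rate of 0 or 1 leaves nothing to test")
    p0 = k_all / n
    return DepletionTest(k=k_high, n=n, p0=p0, pvalue=binom_lower(k_high, n, p0))


def write_confidence_report(
    models: Sequence[ConfidenceSummary], path: str | Path
) -> Path:
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "model_id": m.model_id,
                "confident_fraction": m.confident_fraction,
                "mean_plddt": m.mean_plddt,
                "category": m.category,
            }
            for m in models
        ]
    )
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path
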