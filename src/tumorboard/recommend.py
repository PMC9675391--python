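"""Rule-based targeted-agent selection for one patient's evidence bundle.

Selection order mirrors the tumor board's written policy:

1. **DNA priority** — if any actionable DNA alteration matches a rulebook
   DNA rule, its drug is selected.  Conflicts between DNA rules are resolved
   by rule specificity (a protein-change-level match beats a gene-level
   match), then alphabetically by drug name.
2. **Expression evidence** — otherwise every drug with expression rules is
   scored by the pair (number of its target genes carrying ``over_flag``,
   maximum NRZ among those genes) and the lexicographically highest-scoring
   drug wins; exact ties fall back to alphabetical order and are recorded on
   the recommendation.
3. **No match** — no DNA event and no flagged target gene.

The evidence trail lists every supporting gene so a report can reproduce a
tumor-board row verbatim.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .rulebook import DrugRulebook
from .variants import ActionableEvent

__all__ = ["Evidence", "Recommendation", "recommend", "cohort_drug_counts"]


@dataclass(frozen=True)
class Evidence:
    kind: str  # "DNA" | "expression"
    gene: str
    detail: str
    score: float | None = None  # NRZ for expression evidence
    contextual: bool = False


@dataclass
class Recommendation:
    patient_id: str
    drug: str | None
    status: str  # "dna" | "expression" | "no_match"
    evidence: list[Evidence] = field(default_factory=list)
    runners_up: list[tuple[str, int, float]] = field(default_factory=list)
    tie_broken: bool = False

    def __post_init__(self) -> None:
        if self.status != "no_match" and not self.evidence:
            raise ValueError("a matched recommendation must carry evidence")


def _expression_scores(
    gene_scores: pd.DataFrame, rulebook: DrugRulebook
) -> dict[str, tuple[int, float, list[str]]]:
    """Per drug: (n supporting genes, max NRZ among them, supporting genes)."""
    flagged = gene_scores[gene_scores["over_flag"].astype(bool)]
    out: dict[str, tuple[int, float, list[str]]] = {}
    for drug, targets in rulebook.expression_rules.items():
        support = [g for g in targets if g in flagged.index]
        if support:
            max_nrz = float(flagged.loc[support, "nrz"].max())
            out[drug] = (len(support), max_nrz, support)
    return out


def recommend(
    patient_id: str,
    gene_scores: pd.DataFrame,
    actionable_events: list[ActionableEvent],
    rulebook: DrugRulebook,
) -> Recommendation:
    """Select one agent from the panel for a patient; see module docstring.

    ``gene_scores`` is the per-gene frame from
    :func:`tumorboard.expression.score_patient` (index gene; columns must
    include ``nrz`` and ``over_flag``); ``actionable_events`` comes from
    :func:`tumorboard.variants.classify_actionable`.  Output is
    deterministic and independent of input row/event ordering.
    """
    if not rulebook.panel:
        raise ValueError("empty rulebook")
    contextual = set(rulebook.contextual_evidence)

    # --- DNA priority branch ---------------------------------------------
    candidates: dict[str, int] = {}
    for ev in sorted(actionable_events, key=lambda e: (e.gene, e.kind, e.detail)):
        for drug in ev.drugs:
            candidates[drug] = max(candidates.get(drug, 0), ev.specificity)
    if candidates:
        drug = min(candidates, key=lambda d: (-candidates[d], d))
        evidence = [
            Evidence("DNA", ev.gene, ev.detail)
            for ev in sorted(actionable_events, key=lambda e: (e.gene, e.kind, e.detail))
            if drug in ev.drugs
        ]
        evidence += _expression_evidence_for(drug, gene_scores, rulebook, contextual)
        return Recommendation(patient_id, drug, "dna", evidence)

    # --- Expression branch ------------------------------------------------
    scores = _expression_scores(gene_scores, rulebook)
    if not scores:
        return Recommendation(patient_id, None, "no_match")
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1][0], -kv[1][1], kv[0]))
    drug, (n, max_nrz, support) = ranked[0]
    tie = len(ranked) > 1 and ranked[1][1][:2] == (n, max_nrz)
    evidence = _expression_evidence_for(drug, gene_scores, rulebook, contextual)
    runners = [(d, s[0], s[1]) for d, s in ranked[1:]]
    return Recommendation(patient_id, drug, "expression", evidence, runners, tie)


def _expression_evidence_for(
    drug: str,
    gene_scores: pd.DataFrame,
    rulebook: DrugRulebook,
    contextual: set[str],
) -> list[Evidence]:
    flagged = gene_scores[gene_scores["over_flag"].astype(bool)]
    out = []
    for g in rulebook.expression_targets(drug):
        if g in flagged.index:
            nrz = float(flagged.loc[g, "nrz"])
            detail = f"overexpressed (NRZ {nrz:.2f})" if math.isfinite(nrz) else "overexpressed"
            out.append(Evidence("expression", g, detail, nrz, g in contextual))
    return out


def cohort_drug_counts(
    recommendations: list[Recommendation],
) -> dict[str, tuple[int, float]]:
    """Per drug: (count, fraction of matched recommendations)."""
    if not recommendations:
        raise ValueError("no recommendations to tally")
    matched = [r.drug for r in recommendations if r.drug is not None]
    counts = Counter(matched)
    n = len(matched)
    return {drug: (c, c / n) for drug, c in sorted(counts.items())}
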