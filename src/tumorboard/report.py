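"""Cohort-level outputs: oncoprint table, cohort summary, end-to-end pipeline.

Outputs are plain tables (TSV/JSON) so the pipeline stays testable headless;
figures are a convenience the caller can layer on top.  Oncoprint columns
are ordered by patient id; every output carries provenance (config hash,
seed, package version) and reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .expression import ExpressionPanel, score_patient
from .methylation import expression_methylation_concordance, promoter_beta_table
from .profile import PatientProfile
from .recommend import Recommendation, cohort_drug_counts, recommend
from .rulebook import DrugRulebook, load_rulebook
from .signatures import SignatureExposure, dominant_signature, fit_signatures
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort, read_fixtures
from .variants import (
    PANEL_GENE_REGIONS,
    ArmEvent,
    classify_actionable,
    call_arm_events,
    mutational_burden,
)

__all__ = ["build_oncoprint", "summarize_cohort", "run_pipeline", "CohortSummary",
           "PipelineResult"]

logger = logging.getLogger("tumorboard")

#: Arms displayed in the oncoprint (the recurrent segmental events).
ONCOPRINT_ARMS = ("1p", "1q", "2p", "3p", "7q", "11q", "17q")
#: log2 ratio at or above which a focal MYCN event is coded as amplification.
MYCN_AMP_LOG2 = 2.0


def _gene_cn_code(profile: PatientProfile, gene: str) -> str:
    region = PANEL_GENE_REGIONS.get(gene)
    if region is None:
        return ""
    chrom, start, end = region
    best = 0.0
    for seg in profile.segments:
        if seg.overlaps(chrom, start, end):
            best = max(best, seg.log2_ratio)
    if gene == "MYCN" and best >= MYCN_AMP_LOG2:
        return "AMP"
    if best >= 0.3:
        return "GAIN"
    return ""


def build_oncoprint(
    profiles: list[PatientProfile],
    recommendations: dict[str, Recommendation],
    arm_events: dict[str, list[ArmEvent]],
    exposures: dict[str, SignatureExposure],
) -> pd.DataFrame:
    """Features x patients categorical table mirroring a cohort oncoprint.

    Rows: dominant mutational signature, arm-level CNA per recurrent arm,
    gene alterations (MYCN amplification, ALK SNV / CN gain), then clinical
    annotation rows (age, sex, selected drug, best response pass-through).
    All inputs must be keyed by the same patient ids as ``profiles``.
    """
    pids = [p.patient_id for p in profiles]
    for name, keyed in (("recommendations", recommendations),
                        ("arm_events", arm_events), ("exposures", exposures)):
        missing = set(pids) - set(keyed)
        extra = set(keyed) - set(pids)
        if missing or extra:
            raise ValueError(
                f"patient id mismatch in {name}: missing={sorted(missing)} "
                f"extra={sorted(extra)}"
            )
    rows: dict[str, dict[str, str]] = {}
    for profile in sorted(profiles, key=lambda p: p.patient_id):
        pid = profile.patient_id
        col: dict[str, str] = {}
        dom = dominant_signature(exposures[pid])
        col["signature_dominant"] = dom if dom else "none"
        by_arm = {e.arm: e for e in arm_events[pid]}
        for arm in ONCOPRINT_ARMS:
            ev = by_arm.get(arm)
            col[f"arm_{arm}"] = ev.call.upper() if ev and ev.call != "neutral" else ""
        col["MYCN"] = _gene_cn_code(profile, "MYCN")
        alk_codes = []
        if any(v.gene == "ALK" for v in profile.variants):
            alk_codes.append("SNV")
        if _gene_cn_code(profile, "ALK") == "GAIN":
            alk_codes.append("GAIN")
        col["ALK"] = "+".join(alk_codes)
        col["age_years"] = str(profile.metadata.get("age_years", ""))
        col["sex"] = str(profile.metadata.get("sex", ""))
        rec = recommendations[pid]
        col["selected_drug"] = rec.drug if rec.drug else "none"
        col["best_response"] = str(profile.metadata.get("best_response", "NA"))
        rows[pid] = col
    table = pd.DataFrame(rows)
    table.index.name = "feature"
    return table.reindex(columns=sorted(pids)).fillna("")


@dataclass
class CohortSummary:
    """Counts/percentages per categorical characteristic plus age statistics."""

    n: int
    age_mean: float
    age_median: float
    age_range: tuple[float, float]
    categories: dict[str, dict[str, tuple[int, float]]]  # char -> label -> (count, frac)

    def as_table(self) -> pd.DataFrame:
        """Long-format table with whole-number percentages (raw fractions kept)."""
        rows = []
        for char, labels in self.categories.items():
            for label, (count, frac) in labels.items():
                rows.append(
                    {"characteristic": char, "category": label, "count": count,
                     "fraction": frac, "percent": round(100 * frac)}
                )
        return pd.DataFrame(rows)


_SUMMARY_FIELDS = ("sex", "stage", "mycn_status", "histology", "dna_index", "race")


def summarize_cohort(profiles: list[PatientProfile]) -> CohortSummary:
    """Patient-characteristics summary (counts, percentages, age stats)."""
    if not profiles:
        raise ValueError("need >=1 profile to summarize")
    n = len(profiles)
    ages = np.array([float(p.metadata.get("age_years", np.nan)) for p in profiles])
    categories: dict[str, dict[str, tuple[int, float]]] = {}
    for field_name in _SUMMARY_FIELDS:
        values = [str(p.metadata.get(field_name, "unknown")) for p in profiles]
        counts = pd.Series(values).value_counts()
        categories[field_name] = {
            label: (int(c), int(c) / n) for label, c in counts.items()
        }
    return CohortSummary(
        n=n,
        age_mean=float(np.nanmean(ages)),
        age_median=float(np.nanmedian(ages)),
        age_range=(float(np.nanmin(ages)), float(np.nanmax(ages))),
        categories=categories,
    )


@dataclass
class PipelineResult:
    out_dir: Path
    recommendations: dict[str, Recommendation]
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def _recommendation_doc(rec: Recommendation) -> dict:
    return {
        "patient_id": rec.patient_id,
        "drug": rec.drug,
        "status": rec.status,
        "tie_broken": rec.tie_broken,
        "evidence": [
            {"kind": e.kind, "gene": e.gene, "detail": e.detail,
             "score": e.score, "contextual": e.contextual}
            for e in rec.evidence
        ],
        "runners_up": [
            {"drug": d, "n_support": c, "max_nrz": m} for d, c, m in rec.runners_up
        ],
    }


def _recommendation_markdown(rec: Recommendation) -> str:
    lines = [f"# Tumor board report: {rec.patient_id}", ""]
    drug = rec.drug if rec.drug else "no matching agent"
    lines.append(f"**Selected agent:** {drug} ({rec.status})")
    lines.append("")
    if rec.evidence:
        lines.append("| Evidence | Gene | Detail |")
        lines.append("|---|---|---|")
        for e in rec.evidence:
            mark = " (contextual)" if e.contextual else ""
            lines.append(f"| {e.kind} | {e.gene}{mark} | {e.detail} |")
    else:
        lines.append("No supporting molecular evidence matched the rulebook.")
    lines.append("")
    return "\n".join(lines)


def run_pipeline(
    config: dict | None = None,
    out_dir: str | Path = "tumorboard_out",
    *,
    seed: int | None = None,
    strict: bool = False,
    rulebook: DrugRulebook | None = None,
) -> PipelineResult:
    """End-to-end cohort run: score, annotate, recommend, report.

    ``config`` either points at a fixture directory ({"fixtures": DIR}) or
    carries synthetic-generator overrides ({"synthetic": {...}}); ``None``
    runs the default synthetic cohort.  Per-patient failures are logged and
    skipped unless ``strict``; the result records them.  Reruns on the same
    inputs produce byte-identical outputs.
    """
    config = dict(config or {})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if rulebook is None:
        rulebook = load_rulebook(config.get("rulebook"))

    if "fixtures" in config:
        cohort = read_fixtures(config["fixtures"])
    else:
        overrides = dict(config.get("synthetic", {}))
        if seed is not None:
            overrides["seed"] = seed
        cohort = generate_cohort(CohortConfig(**overrides))

    recommendations: dict[str, Recommendation] = {}
    arm_events: dict[str, list[ArmEvent]] = {}
    exposures: dict[str, SignatureExposure] = {}
    failures: dict[str, str] = {}
    callable_bases = float(config.get("callable_mb", 30.0)) * 1e6

    for profile in cohort.profiles:
        pid = profile.patient_id
        try:
            scores = score_patient(profile.expression, cohort.normal_panel,
                                   cohort.cancer_panel)
            betas = promoter_beta_table(profile.methylation)
            events = classify_actionable(profile.variants, profile.segments,
                                         profile.fusions, rulebook)
            arms = call_arm_events(profile.segments)
            exposure = fit_signatures(profile.catalog, cohort.signature_matrix)
            rec = recommend(pid, scores, events, rulebook)
            concordance = expression_methylation_concordance(scores, betas)
            burden = mutational_burden(profile.variants, callable_bases)
        except Exception as exc:  # fault containment per patient
            logger.error("patient %s failed: %s", pid, exc)
            failures[pid] = str(exc)
            if strict:
                raise
            continue
        recommendations[pid] = rec
        arm_events[pid] = arms
        exposures[pid] = exposure
        pdir = out_dir / "patients" / pid
        pdir.mkdir(parents=True, exist_ok=True)
        scores.to_csv(pdir / "gene_scores.tsv", sep="\t")
        betas.to_csv(pdir / "gene_betas.tsv", sep="\t")
        doc = _recommendation_doc(rec)
        doc["mutational_burden_per_mb"] = burden
        doc["dominant_signature"] = dominant_signature(exposure)
        doc["signature_exposures"] = {k: float(v) for k, v in exposure.weights.items()}
        doc["concordance"] = {
            "spearman_rho": concordance.spearman_rho,
            "hypo_fraction_overexpressed": concordance.hypo_fraction_overexpressed,
        }
        (pdir / "recommendation.json").write_text(
            json.dumps(doc, sort_keys=True, indent=1) + "\n"
        )
        (pdir / "report.md").write_text(_recommendation_markdown(rec))

    done = [p for p in cohort.profiles if p.patient_id in recommendations]
    if done:
        counts = cohort_drug_counts(list(recommendations.values()))
        (out_dir / "drug_counts.json").write_text(
            json.dumps({d: {"count": c, "fraction": f} for d, (c, f) in counts.items()},
                       sort_keys=True, indent=1) + "\n"
        )
        summary = summarize_cohort(done)
        summary.as_table().to_csv(out_dir / "cohort_summary.tsv", sep="\t", index=False)
        oncoprint = build_oncoprint(done, recommendations, arm_events, exposures)
        oncoprint.to_csv(out_dir / "oncoprint.tsv", sep="\t")

    provenance = {
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed if seed is not None else getattr(cohort.config, "seed", None),
        "version": __version__,
        "n_patients": len(cohort.profiles),
        "n_failures": len(failures),
        "failures": failures,
    }
    (out_dir / "provenance.json").write_text(
        json.dumps(provenance, sort_keys=True, indent=1) + "\n"
    )
    return PipelineResult(out_dir, recommendations, failures)
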