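"""Somatic variant annotation: actionable events, arm-level CNA calls, burden.

Inputs are caller outputs, never reads: small variants as MAF-like records,
copy-number segments as SEG-style intervals (0-based half-open, log2 ratio),
and fusion calls as 5'/3' gene pairs.  Coordinates follow GRCh37; the
packaged chromosome-arm table can be overridden.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "SomaticVariant",
    "CopyNumberSegment",
    "FusionCall",
    "ArmEvent",
    "ActionableEvent",
    "classify_actionable",
    "call_arm_events",
    "mutational_burden",
    "load_arm_table",
    "PANEL_GENE_REGIONS",
    "CN_GAIN_LOG2",
    "CN_GAIN_CALL",
]

#: Minimum segment log2 ratio for a copy-number gain to count as actionable.
CN_GAIN_LOG2 = 0.3
#: Minimum integer copy-number call (when the caller provides one).
CN_GAIN_CALL = 3
#: Maximum segment span (bases) for a gain to count as a focal, gene-level
#: event.  Broad segmental changes (e.g. a whole-arm 2p gain that happens to
#: cover ALK) are recurrent chromosome-instability events, not drug-actionable
#: gene gains; they are reported through arm-level calls instead.
FOCAL_MAX_SPAN = 10_000_000

_PROTEIN_CHANGE_RE = re.compile(r"^([A-Z\*])(\d+)([A-Z\*]|fs|del|ins|dup)$")

#: GRCh37 spans for genes referenced by the default drug rulebook's DNA rules
#: (used to intersect copy-number segments with genes).  Callers may pass
#: their own mapping to :func:`classify_actionable`.
PANEL_GENE_REGIONS: dict[str, tuple[str, int, int]] = {
    "ALK": ("2", 29415640, 30144432),
    "MYCN": ("2", 16080683, 16087129),
}


@dataclass(frozen=True)
class SomaticVariant:
    """A somatic small variant (SNV or indel) from a caller's output."""

    gene: str
    protein_change: str | None = None  # e.g. "F1174L"
    variant_class: str = "SNV"  # "SNV" or "indel"
    chromosome: str = ""
    position: int = 1  # 1-based
    trinucleotide_context: str | None = None  # e.g. "G[C>A]A"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"variant position must be >=1, got {self.position}")
        if self.protein_change and not _PROTEIN_CHANGE_RE.match(self.protein_change):
            raise ValueError(f"unparseable protein change {self.protein_change!r}")


@dataclass(frozen=True)
class CopyNumberSegment:
    """A copy-number segment: 0-based half-open interval with log2 ratio."""

    chromosome: str
    start: int
    end: int
    log2_ratio: float
    cn_call: int | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"segment start must be < end, got [{self.start}, {self.end}) on {self.chromosome}"
            )

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chromosome == chrom and self.start < end and start < self.end


@dataclass(frozen=True)
class FusionCall:
    gene_5p: str
    gene_3p: str


@dataclass(frozen=True)
class ArmEvent:
    """Arm-level copy-number call for one chromosome arm (e.g. 17q gain)."""

    arm: str
    call: str  # "gain" | "loss" | "neutral"
    covered_fraction: float
    mean_log2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.covered_fraction <= 1.0:
            raise ValueError(f"covered fraction outside [0,1]: {self.covered_fraction}")


@dataclass(frozen=True)
class ActionableEvent:
    """A DNA alteration matched to one or more panel drugs by a rulebook rule.

    ``specificity`` records how precise the matching rule was (2 for a
    protein-change-level match, 1 for a gene-level match); the recommender
    uses it to resolve conflicts between DNA rules.
    """

    gene: str
    kind: str  # "SNV" | "CN-gain" | "fusion"
    drugs: tuple[str, ...]
    detail: str = ""
    specificity: int = 1


def _validate_segments(segments: list[CopyNumberSegment]) -> None:
    by_chrom: dict[str, list[CopyNumberSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chromosome, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping segments on {chrom}: [{a.start},{a.end}) and [{b.start},{b.end})"
                )


def classify_actionable(
    variants: list[SomaticVariant],
    segments: list[CopyNumberSegment],
    fusions: list[FusionCall],
    rulebook,
    *,
    gene_regions: dict[str, tuple[str, int, int]] | None = None,
    cn_gain_log2: float = CN_GAIN_LOG2,
    cn_gain_call: int = CN_GAIN_CALL,
    focal_max_span: int = FOCAL_MAX_SPAN,
) -> list[ActionableEvent]:
    """Match DNA alterations against the rulebook's DNA rules.

    Only DNA evidence is consulted; expression evidence is the recommender's
    job.  The result is sorted (gene, kind, detail) and therefore independent
    of input ordering.
    """
    if gene_regions is None:
        gene_regions = PANEL_GENE_REGIONS
    _validate_segments(segments)
    events: dict[tuple[str, str, str], ActionableEvent] = {}

    def _add(gene: str, kind: str, drug: str, detail: str, specificity: int) -> None:
        key = (gene, kind, detail)
        prev = events.get(key)
        if prev is None:
            events[key] = ActionableEvent(gene, kind, (drug,), detail, specificity)
        else:
            drugs = tuple(sorted(set(prev.drugs) | {drug}))
            events[key] = ActionableEvent(
                gene, kind, drugs, detail, max(prev.specificity, specificity)
            )

    for rule in rulebook.dna_rules:
        if rule.kind in ("SNV", "indel"):
            for v in variants:
                if v.gene != rule.gene or v.variant_class != rule.kind:
                    continue
                if rule.protein_change is not None and v.protein_change != rule.protein_change:
                    continue
                spec_level = 2 if rule.protein_change is not None else 1
                detail = f"{v.gene} {v.variant_class} {v.protein_change or '?'}"
                _add(v.gene, "SNV" if v.variant_class == "SNV" else "indel",
                     rule.drug, detail, spec_level)
        elif rule.kind == "CN-gain":
            region = gene_regions.get(rule.gene)
            if region is None:
                continue
            chrom, start, end = region
            for seg in segments:
                if not seg.overlaps(chrom, start, end):
                    continue
                if seg.end - seg.start > focal_max_span:
                    continue  # broad segmental change, not a gene-level gain
                is_gain = seg.log2_ratio >= cn_gain_log2 or (
                    seg.cn_call is not None and seg.cn_call >= cn_gain_call
                )
                if is_gain:
                    detail = f"{rule.gene} CN gain (log2 {seg.log2_ratio:+.2f})"
                    _add(rule.gene, "CN-gain", rule.drug, detail, 1)
        elif rule.kind == "fusion":
            for fus in fusions:
                if rule.gene in (fus.gene_5p, fus.gene_3p):
                    detail = f"{fus.gene_5p}--{fus.gene_3p} fusion"
                    _add(rule.gene, "fusion", rule.drug, detail, 1)
    return sorted(events.values(), key=lambda e: (e.gene, e.kind, e.detail))


def load_arm_table() -> pd.DataFrame:
    """Packaged GRCh37 chromosome-arm coordinates (chrom, arm, start, end)."""
    with resources.files("tumorboard.data").joinpath("grch37_arms.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def call_arm_events(
    segments: list[CopyNumberSegment],
    arm_table: pd.DataFrame | None = None,
    *,
    gain_threshold: float = 0.3,
    loss_threshold: float = -0.3,
    min_covered_fraction: float = 0.5,
) -> list[ArmEvent]:
    """Call gain/loss/neutral per chromosome arm.

    Per arm, segments overlapping the arm are clipped to it; the call uses
    the coverage-weighted mean log2 ratio and the fraction of the arm
    covered.  Gain requires mean >= ``gain_threshold`` and coverage >=
    ``min_covered_fraction``; loss is symmetric; anything else (including an
    uncovered arm) is neutral.
    """
    if arm_table is None:
        arm_table = load_arm_table()
    _validate_segments(segments)
    chrom_bounds = arm_table.groupby("chrom")["end"].max().to_dict()
    for seg in segments:
        bound = chrom_bounds.get(seg.chromosome)
        if bound is not None and seg.end > bound:
            raise ValueError(
                f"segment [{seg.start},{seg.end}) exceeds chromosome {seg.chromosome} "
                f"bound {bound}"
            )
    out: list[ArmEvent] = []
    for row in arm_table.itertuples(index=False):
        arm_len = row.end - row.start
        covered = 0
        weighted = 0.0
        for seg in segments:
            if not seg.overlaps(row.chrom, row.start, row.end):
                continue
            length = min(seg.end, row.end) - max(seg.start, row.start)
            covered += length
            weighted += length * seg.log2_ratio
        frac = covered / arm_len if arm_len else 0.0
        mean_log2 = weighted / covered if covered else float("nan")
        call = "neutral"
        if covered and frac >= min_covered_fraction:
            if mean_log2 >= gain_threshold:
                call = "gain"
            elif mean_log2 <= loss_threshold:
                call = "loss"
        out.append(ArmEvent(row.arm, call, frac, mean_log2))
    return out


def mutational_burden(variants: list[SomaticVariant], callable_size: float) -> float:
    """Coding mutations per megabase over the callable footprint (bases)."""
    if callable_size <= 0:
        raise ValueError(f"callable size must be positive, got {callable_size}")
    return len(variants) / (callable_size / 1e6)
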