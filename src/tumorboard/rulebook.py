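"""The declarative drug rulebook: six targeted agents and their evidence rules.

The panel mirrors the pilot-trial formulary — bortezomib, crizotinib,
dasatinib, lapatinib, sorafenib, vorinostat.  Two rule families exist:

* **DNA rules** map a gene + alteration kind (optionally a specific protein
  change) to a drug.  DNA-actionable alterations always take priority over
  expression evidence.
* **Expression rules** map a drug to its target-gene list; a drug earns
  expression support from every target gene flagged as overexpressed.

Some expression-rule genes (e.g. CTBP2, RAD23) are not canonical direct
targets of their drug but were used as contextual evidence by the tumor
board; they are listed under ``contextual_evidence`` so reports can flag
them.  Bortezomib and lapatinib ship with no expression rule rather than an
invented target list, so they are only ever selected through explicit rules
added by the user.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["DnaRule", "DrugRulebook", "load_rulebook", "dump_rulebook", "DEFAULT_PANEL"]

DNA_RULE_KINDS = ("SNV", "indel", "CN-gain", "fusion")

DEFAULT_PANEL = (
    "bortezomib",
    "crizotinib",
    "dasatinib",
    "lapatinib",
    "sorafenib",
    "vorinostat",
)


@dataclass(frozen=True)
class DnaRule:
    drug: str
    gene: str
    kind: str
    protein_change: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in DNA_RULE_KINDS:
            raise ValueError(
                f"DNA rule kind must be one of {DNA_RULE_KINDS}, got {self.kind!r}"
            )


@dataclass
class DrugRulebook:
    """Validated drug panel + rules; see :func:`load_rulebook` for the default."""

    panel: dict[str, str]  # drug -> dose string (may be empty)
    dna_rules: list[DnaRule]
    expression_rules: dict[str, list[str]]  # drug -> target genes
    contextual_evidence: list[str] = field(default_factory=list)
    tie_break: str = "alphabetical"

    def __post_init__(self) -> None:
        if not self.panel:
            raise ValueError("rulebook panel is empty")
        for rule in self.dna_rules:
            if rule.drug not in self.panel:
                raise ValueError(
                    f"DNA rule for {rule.gene} {rule.kind} references unknown drug "
                    f"{rule.drug!r}"
                )
        for drug, genes in self.expression_rules.items():
            if drug not in self.panel:
                raise ValueError(
                    f"expression rule references unknown drug {drug!r}"
                )
            if not genes:
                raise ValueError(
                    f"expression rule for {drug!r} has an empty gene list; "
                    "omit the drug instead"
                )
        if self.tie_break != "alphabetical":
            raise ValueError(f"unsupported tie-break policy {self.tie_break!r}")

    def expression_targets(self, drug: str) -> list[str]:
        return list(self.expression_rules.get(drug, []))


def _from_dict(doc: dict) -> DrugRulebook:
    try:
        panel = {str(d): str(v.get("dose", "") if isinstance(v, dict) else v or "")
                 for d, v in doc["panel"].items()}
        dna_rules = [
            DnaRule(
                drug=str(r["drug"]),
                gene=str(r["gene"]),
                kind=str(r["kind"]),
                protein_change=r.get("protein_change"),
            )
            for r in doc.get("dna_rules", [])
        ]
        expression_rules = {
            str(d): [str(g) for g in genes]
            for d, genes in doc.get("expression_rules", {}).items()
        }
    except (KeyError, TypeError, AttributeError) as exc:
        raise ValueError(f"malformed rulebook document: {exc}") from exc
    return DrugRulebook(
        panel=panel,
        dna_rules=dna_rules,
        expression_rules=expression_rules,
        contextual_evidence=[str(g) for g in doc.get("contextual_evidence", [])],
        tie_break=str(doc.get("tie_break", "alphabetical")),
    )


def load_rulebook(path: str | Path | None = None) -> DrugRulebook:
    """Load and validate a YAML/JSON rulebook; ``None`` loads the packaged default."""
    if path is None:
        with resources.files("tumorboard.data").joinpath("default_rulebook.yaml").open() as fh:
            doc = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError("rulebook document must be a mapping")
    return _from_dict(doc)


def dump_rulebook(rulebook: DrugRulebook, path: str | Path) -> None:
    """Serialize a rulebook back to YAML (round-trips through load_rulebook)."""
    doc = {
        "panel": {d: {"dose": dose} for d, dose in rulebook.panel.items()},
        "dna_rules": [
            {
                "drug": r.drug,
                "gene": r.gene,
                "kind": r.kind,
                **({"protein_change": r.protein_change} if r.protein_change else {}),
            }
            for r in rulebook.dna_rules
        ],
        "expression_rules": {d: list(g) for d, g in rulebook.expression_rules.items()},
        "contextual_evidence": list(rulebook.contextual_evidence),
        "tie_break": rulebook.tie_break,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
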