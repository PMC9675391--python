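"""The published 20-patient pilot-cohort evidence table.

Each row is one patient's tumor-board evidence as printed in the trial
report: the actionable gene mutation (if any) and the overexpressed genes
presented to the board.  Encoding a row as a minimal evidence bundle and
running it through :func:`tumorboard.variants.classify_actionable` and
:func:`tumorboard.recommend.recommend` reproduces the board's drug
selection; the cohort tallies (16 vorinostat, 2 crizotinib, 1 dasatinib,
1 sorafenib) follow.

Gene spellings are normalized to HGNC-style symbols ("HDAC 2" -> HDAC2,
"RAD 23" -> RAD23).  Overexpressed genes are encoded with ``over_flag`` set
and a nominal NRZ of 3.0 — the printed table reports which genes were
flagged, not their scores, and the recommender's primary key is the count of
flagged target genes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .variants import PANEL_GENE_REGIONS, CopyNumberSegment, FusionCall, SomaticVariant

__all__ = ["load_pilot_evidence", "encode_evidence_row", "NOMINAL_NRZ"]

#: Nominal NRZ assigned to genes the published table lists as overexpressed.
NOMINAL_NRZ = 3.0


def load_pilot_evidence() -> pd.DataFrame:
    """The packaged evidence table: patient_id, dna_events, overexpressed_genes."""
    with resources.files("tumorboard.data").joinpath("pilot_cohort_evidence.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str).fillna("")


def encode_evidence_row(
    row: pd.Series,
) -> tuple[str, pd.DataFrame, list[SomaticVariant], list[CopyNumberSegment], list[FusionCall]]:
    """Encode one evidence row as raw caller-level objects.

    Returns ``(patient_id, gene_scores, variants, segments, fusions)``; DNA
    evidence is expressed as variants/segments so that drug matching flows
    through the rulebook's DNA rules rather than being looked up here.  DNA
    tokens are ``GENE:KIND[:PROTEIN_CHANGE]`` separated by ``;``
    (e.g. ``ALK:SNV:F1174L``, ``ALK:CN-gain``).
    """
    genes = [g.strip() for g in str(row["overexpressed_genes"]).split(",") if g.strip()]
    gene_scores = pd.DataFrame(
        {
            "nrz": NOMINAL_NRZ,
            "cum_pct": 1.0,
            "over_flag": True,
            "under_flag": False,
        },
        index=pd.Index(genes, name="gene"),
    )
    variants: list[SomaticVariant] = []
    segments: list[CopyNumberSegment] = []
    for token in str(row["dna_events"]).split(";"):
        token = token.strip()
        if not token:
            continue
        parts = token.split(":")
        gene, kind = parts[0], parts[1]
        change = parts[2] if len(parts) > 2 else None
        region = PANEL_GENE_REGIONS.get(gene)
        if kind in ("SNV", "indel"):
            chrom, start, _ = region if region else ("", 0, 0)
            variants.append(
                SomaticVariant(
                    gene=gene,
                    protein_change=change,
                    variant_class=kind,
                    chromosome=chrom,
                    position=start + 1 if region else 1,
                )
            )
        elif kind == "CN-gain":
            if region is None:
                raise ValueError(f"no packaged coordinates for gene {gene!r}")
            chrom, start, end = region
            segments.append(CopyNumberSegment(chrom, start, end, log2_ratio=1.0, cn_call=4))
        else:
            raise ValueError(f"unknown DNA event kind {kind!r} in token {token!r}")
    return str(row["patient_id"]), gene_scores, variants, segments, []
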