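"""TSV/JSON readers and writers for the pipeline's exchange formats.

All tabular formats are tab-separated with a header row; expression matrices
carry a JSON sidecar (``<name>.meta.json``) declaring their role and scale.
Floats are written with full ``repr`` precision so write/read round-trips
are exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .expression import ExpressionPanel
from .variants import CopyNumberSegment, FusionCall, SomaticVariant

__all__ = [
    "write_expression_panel",
    "read_expression_panel",
    "write_variants",
    "read_variants",
    "write_segments",
    "read_segments",
    "write_fusions",
    "read_fusions",
    "write_catalog",
    "read_catalog",
]


def write_expression_panel(panel: ExpressionPanel, path: str | Path) -> None:
    path = Path(path)
    panel.values.rename_axis("gene").to_csv(path, sep="\t", float_format="%.17g")
    meta = {"role": panel.role, "scale": panel.scale}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, sort_keys=True) + "\n"
    )


def read_expression_panel(path: str | Path, role: str | None = None) -> ExpressionPanel:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col="gene", float_precision="round_trip")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ExpressionPanel(
        values=values,
        role=role or meta.get("role", "tumor"),
        scale=meta.get("scale", "log2(normcount+1)"),
    )


_VARIANT_COLS = ["gene", "chrom", "pos", "ref", "alt", "variant_class",
                 "protein_change", "context"]


def write_variants(variants: list[SomaticVariant], path: str | Path) -> None:
    rows = [
        {
            "gene": v.gene,
            "chrom": v.chromosome,
            "pos": v.position,
            "ref": "N",
            "alt": "N",
            "variant_class": v.variant_class,
            "protein_change": v.protein_change or "",
            "context": v.trinucleotide_context or "",
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=_VARIANT_COLS).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_variants(path: str | Path) -> list[SomaticVariant]:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip").fillna("")
    return [
        SomaticVariant(
            gene=str(r.gene),
            protein_change=str(r.protein_change) or None,
            variant_class=str(r.variant_class),
            chromosome=str(r.chrom),
            position=int(r.pos),
            trinucleotide_context=str(r.context) or None,
        )
        for r in table.itertuples(index=False)
    ]


def write_segments(segments: list[CopyNumberSegment], path: str | Path,
                   sample: str = "sample") -> None:
    rows = [
        {
            "sample": sample,
            "chrom": s.chromosome,
            "start": s.start,
            "end": s.end,
            "log2": s.log2_ratio,
            "cn_call": "" if s.cn_call is None else s.cn_call,
        }
        for s in segments
    ]
    pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "log2", "cn_call"]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_segments(path: str | Path) -> list[CopyNumberSegment]:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    out = []
    for r in table.itertuples(index=False):
        cn = None if pd.isna(r.cn_call) or r.cn_call == "" else int(r.cn_call)
        out.append(CopyNumberSegment(str(r.chrom), int(r.start), int(r.end),
                                     float(r.log2), cn))
    return out


def write_fusions(fusions: list[FusionCall], path: str | Path) -> None:
    pd.DataFrame(
        [{"gene5p": f.gene_5p, "gene3p": f.gene_3p} for f in fusions],
        columns=["gene5p", "gene3p"],
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_fusions(path: str | Path) -> list[FusionCall]:
    table = pd.read_csv(path, sep="\t")
    return [FusionCall(str(r.gene5p), str(r.gene3p)) for r in table.itertuples(index=False)]


def write_catalog(catalog: pd.Series, path: str | Path) -> None:
    catalog.rename_axis("channel").rename("count").to_csv(path, sep="\t", float_format="%.17g")


def read_catalog(path: str | Path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col="channel", float_precision="round_trip")["count"]
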