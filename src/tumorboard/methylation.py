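"""Promoter methylation scoring from probe-level beta values.

Array probes (EPIC-style) carry a beta value in [0,1] and a region
annotation relative to the nearest transcription start site.  Only probes
annotated TSS200 (within 200 bp upstream of the TSS) that pass QC contribute
to a gene's promoter score, which is the arithmetic mean beta across those
probes.  Genes with no qualifying probe are ``not_evaluable`` — this is how
a gene whose promoter probes sit farther upstream (outside TSS200) drops out
of the heat-table.  Classification uses strict thresholds: beta > 0.80
hypermethylated, beta < 0.20 hypomethylated, otherwise neutral (the 0.80 and
0.20 boundary values are neutral).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "MethylationProbe",
    "GeneBeta",
    "ConcordanceReport",
    "normalize_probe_table",
    "promoter_beta",
    "promoter_beta_table",
    "classify_beta",
    "expression_methylation_concordance",
    "HYPER_THRESHOLD",
    "HYPO_THRESHOLD",
    "PROMOTER_REGION",
]

HYPER_THRESHOLD = 0.80
HYPO_THRESHOLD = 0.20
#: The promoter window used for per-gene averaging.
PROMOTER_REGION = "TSS200"
#: Region annotations accepted in probe tables.
REGION_VOCAB = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR")
#: Default detection p-value cutoff when the table carries one.
DETECTION_P_CUTOFF = 0.01


@dataclass(frozen=True)
class MethylationProbe:
    probe_id: str
    gene: str
    region: str
    beta: float
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta outside [0,1] for probe {self.probe_id}: {self.beta}")
        if self.region not in REGION_VOCAB:
            raise ValueError(f"unknown region annotation {self.region!r} for {self.probe_id}")


@dataclass(frozen=True)
class GeneBeta:
    gene: str
    beta: float  # NaN when not evaluable
    n_probes: int
    methylation_class: str  # "hyper" | "neutral" | "hypo" | "not_evaluable"


def classify_beta(beta: float) -> str:
    """hyper if beta > 0.80, hypo if beta < 0.20, else neutral (strict)."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta outside [0,1]: {beta}")
    if beta > HYPER_THRESHOLD:
        return "hyper"
    if beta < HYPO_THRESHOLD:
        return "hypo"
    return "neutral"


def normalize_probe_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a probe table.

    Required columns: ``probe_id``, ``gene``, ``region``, ``beta``.  QC
    follows the available evidence: a ``detection_p`` column implies
    ``qc_pass = detection_p < 0.01``; otherwise an explicit ``qc_pass``
    column is taken verbatim; otherwise all probes pass.  Probes annotated to
    several genes (``;``-separated) are exploded to one row per gene.
    """
    required = {"probe_id", "gene", "region", "beta"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    t = table.copy()
    bad = ~t["beta"].between(0.0, 1.0)
    if bad.any():
        raise ValueError(
            f"beta outside [0,1] for probes: {t.loc[bad, 'probe_id'].tolist()}"
        )
    unknown = ~t["region"].isin(REGION_VOCAB)
    if unknown.any():
        raise ValueError(
            f"unknown region annotations: {sorted(t.loc[unknown, 'region'].unique())}"
        )
    if "detection_p" in t.columns:
        t["qc_pass"] = t["detection_p"] < DETECTION_P_CUTOFF
    elif "qc_pass" in t.columns:
        t["qc_pass"] = t["qc_pass"].astype(bool)
    else:
        t["qc_pass"] = True
    t = t.assign(gene=t["gene"].str.split(";")).explode("gene", ignore_index=True)
    t["gene"] = t["gene"].str.strip()
    return t


def promoter_beta(probes: pd.DataFrame | list[MethylationProbe], gene: str) -> GeneBeta:
    """Mean beta over the gene's QC-passing TSS200 probes."""
    table = _as_table(probes)
    sub = table[
        (table["gene"] == gene)
        & (table["region"] == PROMOTER_REGION)
        & table["qc_pass"]
    ]
    if len(sub) == 0:
        return GeneBeta(gene, float("nan"), 0, "not_evaluable")
    mean = float(sub["beta"].mean())
    return GeneBeta(gene, mean, len(sub), classify_beta(mean))


def promoter_beta_table(probes: pd.DataFrame | list[MethylationProbe]) -> pd.DataFrame:
    """Per-gene promoter betas for every gene in the table.

    Returns a DataFrame indexed by gene with columns ``beta``, ``n_probes``,
    ``methylation_class``; genes whose probes all fall outside TSS200 (or
    fail QC) appear with class ``not_evaluable``.
    """
    table = _as_table(probes)
    qualifying = table[(table["region"] == PROMOTER_REGION) & table["qc_pass"]]
    means = qualifying.groupby("gene")["beta"].agg(["mean", "size"])
    rows = []
    for g in sorted(table["gene"].unique()):
        if g in means.index:
            m = float(means.loc[g, "mean"])
            rows.append(GeneBeta(g, m, int(means.loc[g, "size"]), classify_beta(m)))
        else:
            rows.append(GeneBeta(g, float("nan"), 0, "not_evaluable"))
    return pd.DataFrame(
        {
            "beta": [r.beta for r in rows],
            "n_probes": [r.n_probes for r in rows],
            "methylation_class": [r.methylation_class for r in rows],
        },
        index=pd.Index([r.gene for r in rows], name="gene"),
    )


def _as_table(probes: pd.DataFrame | list[MethylationProbe]) -> pd.DataFrame:
    if isinstance(probes, pd.DataFrame):
        return normalize_probe_table(probes)
    return normalize_probe_table(
        pd.DataFrame(
            {
                "probe_id": [p.probe_id for p in probes],
                "gene": [p.gene for p in probes],
                "region": [p.region for p in probes],
                "beta": [p.beta for p in probes],
                "qc_pass": [p.qc_pass for p in probes],
            }
        )
    )


@dataclass
class ConcordanceReport:
    """Expression-methylation concordance across genes for one tumor."""

    spearman_rho: float | None
    p_value: float | None
    n_genes: int
    hypo_fraction_overexpressed: float | None
    n_overexpressed: int
    note: str = ""


def expression_methylation_concordance(
    gene_scores: pd.DataFrame, gene_betas: pd.DataFrame
) -> ConcordanceReport:
    """Spearman correlation between NRZ and promoter beta across shared genes,
    plus the fraction of overexpression-flagged genes that are hypomethylated.

    Promoter hypomethylation of overexpressed genes shows up as a negative
    correlation.  Requires >=3 genes evaluable in both inputs; a constant
    input yields an undefined correlation (reported with a reason) while the
    hypo fraction is still computed.
    """
    betas = gene_betas[gene_betas["methylation_class"] != "not_evaluable"]
    shared = gene_scores.index.intersection(betas.index)
    shared = shared[np.isfinite(gene_scores.loc[shared, "nrz"])]
    if len(shared) < 3:
        raise ValueError(f"need >=3 genes evaluable in both inputs, got {len(shared)}")
    nrz = gene_scores.loc[shared, "nrz"].to_numpy(dtype=float)
    beta = betas.loc[shared, "beta"].to_numpy(dtype=float)
    over = gene_scores.loc[shared, "over_flag"].astype(bool).to_numpy()
    n_over = int(over.sum())
    if n_over:
        hypo_frac = float(
            (betas.loc[shared[over], "methylation_class"] == "hypo").mean()
        )
    else:
        hypo_frac = None
    if np.all(nrz == nrz[0]) or np.all(beta == beta[0]):
        return ConcordanceReport(
            None, None, len(shared), hypo_frac, n_over,
            note="correlation undefined: constant input vector",
        )
    rho, p = spearmanr(nrz, beta)
    return ConcordanceReport(float(rho), float(p), len(shared), hypo_frac, n_over)
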