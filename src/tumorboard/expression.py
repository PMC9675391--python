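"""Reference-panel expression scoring.

A tumor sample's expression is scored gene-by-gene against two references:

* a *normal whole-body reference panel* (22 samples over 14 normal tissues),
  yielding the NRZ score ("normal Z-score"): the tumor value expressed in
  standard deviations from the normal-panel mean for that gene;
* a *cancer reference cohort* of high-risk neuroblastoma tumors (41 samples),
  yielding the cumulative cancer reference score: the empirical-CDF
  percentile of the tumor value within the cohort.

A gene is flagged as overexpressed evidence for the tumor board when
NRZ > 2 and the cumulative score > 0.75 (top quartile of the cancer cohort);
underexpression is flagged at NRZ < -2.  All scoring is done on whatever
scale the input matrices declare (by convention log2(normalized count + 1));
no re-normalization happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionPanel",
    "GeneScore",
    "compute_nrz",
    "compute_cum_pct",
    "score_patient",
    "NRZ_THRESHOLD",
    "CUM_PCT_THRESHOLD",
    "SD_ZERO_SENTINEL",
]

#: NRZ threshold for overexpression evidence (strict >).
NRZ_THRESHOLD = 2.0
#: Cumulative cancer reference score threshold (strict >, i.e. top quartile).
CUM_PCT_THRESHOLD = 0.75
#: Sign-coded sentinel reported when the normal panel has zero variance for a
#: gene; flagged via ``qc_sd_zero`` rather than dropped, since constant-zero
#: normal expression with tumor expression is itself informative.
SD_ZERO_SENTINEL = 1e6

PANEL_ROLES = ("tumor", "normal_reference", "cancer_reference")


@dataclass
class ExpressionPanel:
    """A gene x sample expression matrix with a declared role and scale.

    ``values`` is indexed by gene identifier with one column per sample.
    """

    values: pd.DataFrame
    role: str
    scale: str = "log2(normcount+1)"

    def __post_init__(self) -> None:
        if self.role not in PANEL_ROLES:
            raise ValueError(f"panel role must be one of {PANEL_ROLES}, got {self.role!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers in panel: {dups}")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("expression panel contains non-finite values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class GeneScore:
    """Per-gene evidence scores for one tumor sample."""

    gene: str
    nrz: float
    cum_pct: float
    over_flag: bool
    under_flag: bool
    qc_sd_zero: bool = field(default=False)


def _shared_genes(tumor: pd.Series, panel: ExpressionPanel) -> pd.Index:
    shared = tumor.index.intersection(panel.genes)
    if len(shared) == 0:
        raise ValueError("tumor sample and panel share no genes")
    return shared


def compute_nrz(tumor: pd.Series, normal_panel: ExpressionPanel) -> pd.Series:
    """NRZ score per gene: (tumor - normal mean) / normal sd (sample sd, ddof=1).

    Genes whose normal-panel sd is exactly zero receive the sign-coded
    sentinel ``SD_ZERO_SENTINEL`` (0 if the tumor equals the constant value);
    callers can recover the QC flag from :func:`score_patient`.
    """
    if normal_panel.n_samples < 2:
        raise ValueError(
            f"normal panel needs >=2 samples to estimate sd, got {normal_panel.n_samples}"
        )
    genes = _shared_genes(tumor, normal_panel)
    ref = normal_panel.values.loc[genes]
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    diff = tumor.loc[genes].astype(float) - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        nrz = diff / sd
    zero = sd == 0.0
    if zero.any():
        nrz[zero] = np.sign(diff[zero]) * SD_ZERO_SENTINEL
    nrz.name = "nrz"
    return nrz


def compute_cum_pct(tumor: pd.Series, cancer_panel: ExpressionPanel) -> pd.Series:
    """Empirical-CDF percentile of the tumor value within the cancer cohort.

    cum_pct(g) = #{cohort values <= x_g} / N; ties count toward the
    numerator, so a tumor value equal to the cohort maximum scores 1.0.
    """
    if cancer_panel.n_samples == 0:
        raise ValueError("cancer reference panel is empty")
    genes = _shared_genes(tumor, cancer_panel)
    ref = cancer_panel.values.loc[genes]
    x = tumor.loc[genes].astype(float)
    cum = ref.le(x, axis=0).sum(axis=1) / cancer_panel.n_samples
    cum.name = "cum_pct"
    return cum


def score_patient(
    tumor: pd.Series,
    normal_panel: ExpressionPanel,
    cancer_panel: ExpressionPanel,
    gene_subset: list[str] | None = None,
    *,
    flag_mode: str = "and",
) -> pd.DataFrame:
    """Score every shared gene; returns a DataFrame indexed by gene.

    Columns: ``nrz``, ``cum_pct``, ``over_flag``, ``under_flag``,
    ``qc_sd_zero``.  ``flag_mode`` selects the Boolean connective between the
    NRZ and cumulative-score thresholds for ``over_flag``: ``"and"``
    (default, both required) or ``"or"`` (either sufficient).
    """
    if flag_mode not in ("and", "or"):
        raise ValueError(f"flag_mode must be 'and' or 'or', got {flag_mode!r}")
    nrz = compute_nrz(tumor, normal_panel)
    cum = compute_cum_pct(tumor, cancer_panel)
    genes = nrz.index.intersection(cum.index)
    if gene_subset is not None:
        genes = genes.intersection(pd.Index(gene_subset))
    out = pd.DataFrame({"nrz": nrz.loc[genes], "cum_pct": cum.loc[genes]})
    passes_nrz = out["nrz"] > NRZ_THRESHOLD
    passes_cum = out["cum_pct"] > CUM_PCT_THRESHOLD
    if flag_mode == "and":
        out["over_flag"] = passes_nrz & passes_cum
    else:
        out["over_flag"] = passes_nrz | passes_cum
    out["under_flag"] = out["nrz"] < -NRZ_THRESHOLD
    sd = normal_panel.values.loc[genes].std(axis=1, ddof=1)
    out["qc_sd_zero"] = sd == 0.0
    return out
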