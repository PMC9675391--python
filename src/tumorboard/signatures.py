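"""Mutational-signature exposure fitting on 96-channel trinucleotide catalogs.

A catalog counts a tumor's somatic substitutions over the standard 96
channels (6 pyrimidine substitution types x 16 flanking contexts).  Exposures
are fitted by non-negative least squares between the catalog's channel
*proportions* and a signature matrix (96 rows x one column per signature,
each column a probability vector), then renormalized onto the simplex; fit
quality is reported as the cosine distance between the catalog and its
reconstruction.  Fitting on proportions rather than raw counts keeps the
objective comparable across catalogs of different sizes.

The packaged signature set is **synthetic**: five 96-channel probability
vectors built deterministically in code to occupy the roles of recurrent
COSMIC-v2 signatures (ids ``sig1``, ``sig3``, ``sig5``, ``sig13``,
``sig18``).  ``sig18`` concentrates mass on C>A channels, mimicking the
reactive-oxygen-species signature recurrent in neuroblastoma.  A real COSMIC
matrix can be supplied instead wherever a signature matrix is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.spatial.distance import cosine as cosine_distance

__all__ = [
    "SignatureExposure",
    "trinucleotide_channels",
    "synthetic_signature_matrix",
    "fit_signatures",
    "dominant_signature",
    "DOMINANT_THRESHOLD",
]

#: Minimum exposure weight for the largest signature to be called dominant.
DOMINANT_THRESHOLD = 0.4

_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")


def trinucleotide_channels() -> list[str]:
    """The 96 channel labels in standard order, e.g. ``A[C>A]A`` ... ``T[T>G]T``."""
    return [
        f"{five}[{sub}]{three}"
        for sub in _SUBSTITUTIONS
        for five in _BASES
        for three in _BASES
    ]


def synthetic_signature_matrix() -> pd.DataFrame:
    """Deterministic synthetic stand-in for a COSMIC-v2 signature matrix.

    Returns a 96 x 5 DataFrame (channels x signatures); columns sum to 1.
    Each signature concentrates ~70% of its mass on a distinct substitution
    block with geometric decay over contexts, leaving the rest flat, so the
    set is well conditioned for NNLS fitting.
    """
    channels = trinucleotide_channels()
    idx = pd.Index(channels, name="channel")

    def block(sub: str, mass: float, decay: float = 0.85) -> np.ndarray:
        v = np.full(96, (1.0 - mass) / (96 - 16))
        members = [i for i, ch in enumerate(channels) if f"[{sub}]" in ch]
        w = decay ** np.arange(len(members))
        w = mass * w / w.sum()
        for i, m in enumerate(members):
            v[m] = w[i]
        return v / v.sum()

    def cpg_block(mass: float) -> np.ndarray:
        # C>T concentrated at NpCpG contexts (3' G), spermine-deamination style
        v = np.full(96, (1.0 - mass) / (96 - 4))
        members = [i for i, ch in enumerate(channels) if "[C>T]" in ch and ch.endswith("G")]
        for m in members:
            v[m] = mass / len(members)
        return v / v.sum()

    flat = np.full(96, 1.0 / 96)
    mat = pd.DataFrame(
        {
            "sig1": cpg_block(0.7),
            "sig3": flat,
            "sig5": block("T>C", 0.7),
            "sig13": block("C>G", 0.7),
            "sig18": block("C>A", 0.7),
        },
        index=idx,
    )
    return mat


@dataclass
class SignatureExposure:
    """Fitted signature weights (simplex) plus reconstruction cosine distance."""

    weights: pd.Series
    reconstruction_error: float

    def __post_init__(self) -> None:
        w = self.weights.to_numpy(dtype=float)
        if (w < -1e-12).any():
            raise ValueError("exposure weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"exposure weights must sum to 1, got {w.sum()}")


def fit_signatures(
    catalog: pd.Series | np.ndarray,
    signature_matrix: pd.DataFrame | None = None,
) -> SignatureExposure:
    """Fit NNLS exposures of a 96-channel catalog to a signature matrix.

    The catalog is normalized to proportions; weights are renormalized to
    sum to 1 after the NNLS solve.  Raises on an all-zero or negative
    catalog, or on a signature matrix whose columns are not probability
    vectors.
    """
    if signature_matrix is None:
        signature_matrix = synthetic_signature_matrix()
    S = signature_matrix.to_numpy(dtype=float)
    colsums = S.sum(axis=0)
    if not np.allclose(colsums, 1.0, atol=1e-6):
        raise ValueError("signature matrix columns must each sum to 1")
    if isinstance(catalog, pd.Series):
        catalog = catalog.reindex(signature_matrix.index).fillna(0.0)
        c = catalog.to_numpy(dtype=float)
    else:
        c = np.asarray(catalog, dtype=float)
    if c.shape[0] != S.shape[0]:
        raise ValueError(f"catalog has {c.shape[0]} channels, expected {S.shape[0]}")
    if (c < 0).any():
        raise ValueError("catalog counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("catalog is all-zero; at least one mutation required")
    p = c / total
    w, _ = nnls(S, p)
    if w.sum() == 0:  # pathological; fall back to uniform
        w = np.full(S.shape[1], 1.0 / S.shape[1])
    w = w / w.sum()
    recon = S @ w
    err = float(cosine_distance(p, recon))
    weights = pd.Series(w, index=signature_matrix.columns, name="exposure")
    return SignatureExposure(weights, err)


def dominant_signature(
    exposure: SignatureExposure, threshold: float = DOMINANT_THRESHOLD
) -> str | None:
    """Largest-exposure signature id if its weight reaches ``threshold``, else None."""
    top = exposure.weights.idxmax()
    if exposure.weights.loc[top] >= threshold:
        return str(top)
    return None
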