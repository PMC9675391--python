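"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a 20-patient high-risk neuroblastoma cohort together
with its two expression references (a 22-sample / 14-tissue normal panel and
a 41-tumor cancer reference cohort).  Defaults encode the study conditions:
MYCN amplification in 45% of tumors, ALK alterations in 15% (one F1174L
SNV, one copy-number gain, plus frequent overexpression), HDAC2/MYCN/LIN28B
overexpressed in the majority of tumors, recurrent arm-level gains (1q, 2p,
7q, 17q) and losses (1p, 3p, 11q), promoter hypomethylation coupled to
overexpression, low coding mutational burden, and sig18-dominated
trinucleotide catalogs in 15 of 20 tumors.

Binary features are assigned by **exact quota** (round(prevalence x n)
patients, then shuffled) so that small cohorts hit the configured
prevalences exactly; an i.i.d. Bernoulli mode is available behind
``iid_features``.  All randomness flows from one root generator seeded by
``CohortConfig.seed``, so identical configs produce byte-identical fixtures.

Expression is generated (and meant to be scored) on a log2(normalized
count + 1) scale: each gene has a normal-tissue mean drawn once per cohort,
overexpressed tumor genes are shifted up by ``effect_lfc``, and
overexpression-prone genes get a milder ``ref_shift`` bump in the cancer
reference cohort (tumor cohorts share part of the signal, so percentiles
stay informative but not saturated).  Promoter methylation is coupled to
expression through a monotone decreasing map
``beta = base - coupling * tanh(z/2) + noise``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tbio
from .expression import ExpressionPanel
from .methylation import classify_beta
from .profile import PatientProfile
from .rulebook import load_rulebook, dump_rulebook
from .signatures import synthetic_signature_matrix, trinucleotide_channels
from .variants import (
    PANEL_GENE_REGIONS,
    CopyNumberSegment,
    SomaticVariant,
    load_arm_table,
)

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "generate_cohort",
    "write_fixtures",
    "read_fixtures",
]

NORMAL_TISSUES = (
    "adrenal gland", "brain", "bronchus", "esophagus", "heart",
    "large intestine", "liver", "lung", "lymph node", "pituitary gland",
    "skeletal muscle", "skin", "spleen", "uterus",
)

#: Drug-target and biology genes always present in generated cohorts.
NAMED_GENES = (
    "HDAC2", "HDAC4", "HDAC8", "HDAC9", "CTBP2", "RAD23",
    "ALK", "RET", "KIT", "PDGFRA", "BRAF",
    "PDGFRB", "DDR2", "SRC", "LCK",
    "MYCN", "LIN28B", "ODC1", "SOX2", "STAT3",
)

_DEFAULT_OVEREXPRESSION = {
    "MYCN": 0.90, "LIN28B": 1.00, "ODC1": 0.50,
    "HDAC2": 0.85, "HDAC9": 0.60, "HDAC4": 0.30, "HDAC8": 0.25,
    "CTBP2": 0.25, "RAD23": 0.10,
    "ALK": 0.90,
    "RET": 0.05, "KIT": 0.05, "PDGFRA": 0.05, "BRAF": 0.05,
    "PDGFRB": 0.05, "DDR2": 0.05, "SRC": 0.05, "LCK": 0.05,
    "SOX2": 0.05, "STAT3": 0.30,
}

_DEFAULT_ARM_EVENTS = {
    "1q": ("gain", 0.5), "2p": ("gain", 0.5), "7q": ("gain", 0.5), "17q": ("gain", 0.5),
    "1p": ("loss", 0.5), "3p": ("loss", 0.5), "11q": ("loss", 0.5),
}

#: Methylation baseline per gene (beta before expression coupling); SRC and
#: LCK promoters sit hypermethylated, SOX2 slightly hypomethylated.
_METHYL_BASE = {"SRC": 0.88, "LCK": 0.88, "SOX2": 0.38}
#: Genes whose promoter probes fall outside TSS200 (annotated TSS1500), so
#: they drop out of promoter scoring — mirrors array annotation gaps.
_NO_TSS200_GENES = ("BRAF", "PDGFRB", "HDAC8")


@dataclass
class CohortConfig:
    """Generator configuration; defaults encode the study cohort structure."""

    n_patients: int = 20
    seed: int = 12012
    n_normal_samples: int = 22
    n_normal_tissues: int = 14
    n_cancer_reference: int = 41
    n_background_genes: int = 150
    feature_prevalence: dict[str, float] = field(
        default_factory=lambda: {"MYCN_amp": 0.45, "ALK_snv": 0.05, "ALK_cn_gain": 0.05}
    )
    overexpression_prob: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_OVEREXPRESSION)
    )
    background_over_prob: float = 0.05
    arm_events: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(_DEFAULT_ARM_EVENTS)
    )
    gene_mean_range: tuple[float, float] = (3.0, 8.0)
    gene_sd: float = 0.5
    effect_lfc: float = 3.0
    ref_shift: float = 1.0
    beta_coupling: float = 0.45
    beta_noise: float = 0.08
    probe_noise: float = 0.03
    probes_per_gene: int = 2
    mutations_per_catalog: int = 150
    sig18_prevalence: float = 0.75
    dominant_weight: float = 0.7
    passenger_mean: int = 30
    callable_mb: float = 30.0
    arm_log2: float = 0.6
    iid_features: bool = False
    strict_quota: bool = False

    def __post_init__(self) -> None:
        for name, value in (
            ("n_patients", self.n_patients),
            ("n_normal_samples", self.n_normal_samples),
            ("n_cancer_reference", self.n_cancer_reference),
            ("n_background_genes", self.n_background_genes),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        probs = dict(self.feature_prevalence)
        probs.update(self.overexpression_prob)
        probs["sig18"] = self.sig18_prevalence
        probs["background"] = self.background_over_prob
        for arm, (_, p) in self.arm_events.items():
            probs[f"arm_{arm}"] = p
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {name} outside [0,1]: {p}")


@dataclass
class SyntheticTruth:
    """Per-patient ground truth, consistent with the generated data."""

    overexpressed: dict[str, list[str]] = field(default_factory=dict)
    actionable: dict[str, list[list[str]]] = field(default_factory=dict)
    signature_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    dominant_signature: dict[str, str] = field(default_factory=dict)
    arm_events: dict[str, dict[str, str]] = field(default_factory=dict)
    methylation_class: dict[str, dict[str, str]] = field(default_factory=dict)
    mycn_amplified: dict[str, bool] = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    profiles: list[PatientProfile]
    normal_panel: ExpressionPanel
    cancer_panel: ExpressionPanel
    tumor_panel: ExpressionPanel
    truth: SyntheticTruth
    config: CohortConfig
    signature_matrix: pd.DataFrame


def binary_quota(n: int, prevalence: float, rng: np.random.Generator,
                 *, iid: bool = False, strict: bool = False) -> np.ndarray:
    """Boolean assignment vector with exactly round(prevalence*n) True entries.

    With ``strict=True`` a non-integral quota is rejected; with ``iid=True``
    independent Bernoulli draws are used instead of the quota.
    """
    if iid:
        return rng.random(n) < prevalence
    exact = prevalence * n
    k = int(np.floor(exact + 0.5))
    if strict and abs(exact - round(exact)) > 1e-9:
        raise ValueError(f"non-integral quota: {prevalence} x {n} = {exact}")
    out = np.zeros(n, dtype=bool)
    out[:k] = True
    rng.shuffle(out)
    return out


def categorical_quota(n: int, probs: dict[str, float],
                      rng: np.random.Generator) -> list[str]:
    """Largest-remainder quota assignment of ``n`` items to categories, shuffled."""
    labels = list(probs)
    exact = np.array([probs[l] * n for l in labels])
    base = np.floor(exact).astype(int)
    remainder = n - base.sum()
    order = np.argsort(-(exact - base))
    for i in range(remainder):
        base[order[i % len(labels)]] += 1
    out: list[str] = []
    for label, k in zip(labels, base):
        out.extend([label] * k)
    out = list(np.array(out, dtype=object))
    rng.shuffle(out)
    return [str(x) for x in out]


def _subtract_intervals(start: int, end: int,
                        holes: list[tuple[int, int]]) -> list[tuple[int, int]]:
    pieces = [(start, end)]
    for h0, h1 in sorted(holes):
        nxt: list[tuple[int, int]] = []
        for s, e in pieces:
            if h1 <= s or e <= h0:
                nxt.append((s, e))
                continue
            if s < h0:
                nxt.append((s, h0))
            if h1 < e:
                nxt.append((h1, e))
        pieces = nxt
    return pieces


_AA = "ACDEFGHIKLMNPQRSTVWY"


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic given ``config.seed``."""
    if config is None:
        config = CohortConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    patient_ids = [f"P{i + 1:03d}" for i in range(n)]

    genes = list(NAMED_GENES) + [f"BG{i + 1:04d}" for i in range(config.n_background_genes)]
    gene_index = pd.Index(genes, name="gene")
    n_genes = len(genes)
    lo, hi = config.gene_mean_range
    gene_means = pd.Series(rng.uniform(lo, hi, n_genes), index=gene_index)
    sd = config.gene_sd

    # --- reference panels -------------------------------------------------
    tissues = [NORMAL_TISSUES[i % config.n_normal_tissues]
               for i in range(config.n_normal_samples)]
    normal_values = pd.DataFrame(
        gene_means.to_numpy()[:, None]
        + rng.normal(0.0, sd, (n_genes, config.n_normal_samples)),
        index=gene_index,
        columns=[f"N{i + 1:02d}" for i in range(config.n_normal_samples)],
    )
    normal_panel = ExpressionPanel(normal_values, "normal_reference")
    normal_panel.tissues = dict(zip(normal_values.columns, tissues))

    over_prob = pd.Series(0.0, index=gene_index)
    for g, p in config.overexpression_prob.items():
        if g in over_prob.index:
            over_prob[g] = p
    over_prob[[g for g in genes if g.startswith("BG")]] = config.background_over_prob

    ref_bump = (
        rng.random((n_genes, config.n_cancer_reference))
        < over_prob.to_numpy()[:, None]
    )
    cancer_values = pd.DataFrame(
        gene_means.to_numpy()[:, None]
        + config.ref_shift * ref_bump
        + rng.normal(0.0, sd, (n_genes, config.n_cancer_reference)),
        index=gene_index,
        columns=[f"C{i + 1:02d}" for i in range(config.n_cancer_reference)],
    )
    cancer_panel = ExpressionPanel(cancer_values, "cancer_reference")

    # --- per-gene overexpression assignment (exact quota) -----------------
    over_matrix = np.zeros((n_genes, n), dtype=bool)
    for gi in range(n_genes):
        p = over_prob.iloc[gi]
        if p > 0 and n > 0:
            over_matrix[gi] = binary_quota(
                n, p, rng, iid=config.iid_features, strict=config.strict_quota
            )
    tumor_values = pd.DataFrame(
        gene_means.to_numpy()[:, None]
        + config.effect_lfc * over_matrix
        + rng.normal(0.0, sd, (n_genes, n)),
        index=gene_index,
        columns=patient_ids,
    )
    tumor_panel = ExpressionPanel(tumor_values, "tumor")

    # --- binary clinical/genomic features ---------------------------------
    def quota(p: float) -> np.ndarray:
        return binary_quota(n, p, rng, iid=config.iid_features,
                            strict=config.strict_quota)

    mycn_amp = quota(config.feature_prevalence.get("MYCN_amp", 0.0))
    alk_snv = quota(config.feature_prevalence.get("ALK_snv", 0.0))
    alk_cn = quota(config.feature_prevalence.get("ALK_cn_gain", 0.0))
    arm_assign = {arm: quota(p) for arm, (_, p) in config.arm_events.items()}
    sig18_dom = quota(config.sig18_prevalence)

    ages = np.clip(rng.lognormal(np.log(3.0), 0.9, n), 0.25, 14.0).round(2)
    sexes = categorical_quota(n, {"male": 0.6, "female": 0.4}, rng)
    stages = categorical_quota(n, {"stage 4": 0.8, "stage 3": 0.2}, rng)
    histologies = categorical_quota(n, {"unfavorable": 0.9, "favorable": 0.1}, rng)
    dna_indices = categorical_quota(
        n, {"diploid": 0.5, "hyperdiploid": 0.2, "unknown": 0.3}, rng
    )
    races = categorical_quota(
        n, {"White": 0.65, "Black/African American": 0.25, "Multiracial": 0.10}, rng
    )

    arm_table = load_arm_table().set_index("arm")
    sig_matrix = synthetic_signature_matrix()
    sig_ids = list(sig_matrix.columns)
    other_sigs = [s for s in sig_ids if s != "sig18"]
    channels = trinucleotide_channels()

    truth = SyntheticTruth()
    profiles: list[PatientProfile] = []

    for pi, pid in enumerate(patient_ids):
        over_genes = [genes[gi] for gi in range(n_genes) if over_matrix[gi, pi]]

        # variants: driver ALK SNV plus low-burden passengers
        variants: list[SomaticVariant] = []
        actionable: list[list[str]] = []
        if alk_snv[pi]:
            variants.append(SomaticVariant("ALK", "F1174L", "SNV", "2", 29443695))
            actionable.append(["ALK", "SNV", "F1174L"])
        n_passengers = int(rng.poisson(config.passenger_mean))
        for _ in range(n_passengers):
            gi = int(rng.integers(0, config.n_background_genes))
            chrom = str(int(rng.integers(1, 23)))
            pos = int(rng.integers(1_000_000, 50_000_000))
            ref_aa, alt_aa = rng.choice(list(_AA), 2)
            change = f"{ref_aa}{int(rng.integers(10, 900))}{alt_aa}"
            variants.append(
                SomaticVariant(f"BG{gi + 1:04d}", change, "SNV", chrom, pos)
            )

        # copy-number segments: focal events first, arm pieces around them
        segments: list[CopyNumberSegment] = []
        focal_by_chrom: dict[str, list[tuple[int, int]]] = {}
        if mycn_amp[pi]:
            chrom, s0, e0 = PANEL_GENE_REGIONS["MYCN"]
            segments.append(CopyNumberSegment(chrom, s0, e0, 3.3, 20))
            focal_by_chrom.setdefault(chrom, []).append((s0, e0))
            # MYCN amplification is prognostic, not drug-actionable
        if alk_cn[pi]:
            chrom, s0, e0 = PANEL_GENE_REGIONS["ALK"]
            segments.append(CopyNumberSegment(chrom, s0, e0, 1.0, 4))
            focal_by_chrom.setdefault(chrom, []).append((s0, e0))
            actionable.append(["ALK", "CN-gain", ""])
        arm_truth: dict[str, str] = {}
        for arm, (kind, _) in config.arm_events.items():
            if not arm_assign[arm][pi]:
                arm_truth[arm] = "neutral"
                continue
            arm_truth[arm] = kind
            row = arm_table.loc[arm]
            length = int(row.end - row.start)
            seg_start = int(row.start + 0.1 * length)
            seg_end = int(row.start + 0.9 * length)
            log2 = config.arm_log2 if kind == "gain" else -config.arm_log2
            log2 += float(rng.normal(0.0, 0.02))
            holes = focal_by_chrom.get(str(row.chrom), [])
            for s0, e0 in _subtract_intervals(seg_start, seg_end, holes):
                segments.append(CopyNumberSegment(str(row.chrom), s0, e0, log2))

        # methylation probes coupled to expression
        z_true = (tumor_values[pid] - gene_means) / sd
        base = pd.Series(0.5, index=gene_index)
        for g, b in _METHYL_BASE.items():
            base[g] = b
        latent = np.clip(
            base - config.beta_coupling * np.tanh(z_true / 2.0)
            + rng.normal(0.0, config.beta_noise, n_genes),
            0.01, 0.99,
        )
        latent = pd.Series(latent, index=gene_index)
        probe_rows = []
        for gi, g in enumerate(genes):
            region = "TSS1500" if g in _NO_TSS200_GENES else "TSS200"
            for k in range(config.probes_per_gene):
                beta = float(np.clip(
                    latent[g] + rng.normal(0.0, config.probe_noise), 0.0, 1.0
                ))
                probe_rows.append(
                    (f"cg{pi:02d}{gi:04d}{k}", g, region, beta, True)
                )
            body_beta = float(rng.uniform(0.3, 0.9))
            probe_rows.append((f"cg{pi:02d}{gi:04d}b", g, "Body", body_beta, True))
        methylation = pd.DataFrame(
            probe_rows, columns=["probe_id", "gene", "region", "beta", "qc_pass"]
        )

        # trinucleotide catalog from the signature mixture
        if sig18_dom[pi]:
            dominant = "sig18"
        else:
            dominant = other_sigs[pi % len(other_sigs)]
        rest = rng.dirichlet(np.ones(len(sig_ids) - 1)) * (1.0 - config.dominant_weight)
        weights = pd.Series(0.0, index=sig_ids)
        weights[dominant] = config.dominant_weight
        weights[[s for s in sig_ids if s != dominant]] = rest
        spectrum = sig_matrix.to_numpy() @ weights.to_numpy()
        counts = rng.multinomial(config.mutations_per_catalog, spectrum)
        catalog = pd.Series(counts, index=pd.Index(channels, name="channel"))

        metadata = {
            "age_years": float(ages[pi]),
            "sex": sexes[pi],
            "stage": stages[pi],
            "mycn_status": "amplified" if mycn_amp[pi] else "non-amplified",
            "histology": histologies[pi],
            "dna_index": dna_indices[pi],
            "race": races[pi],
            "best_response": "NA",
        }

        profiles.append(
            PatientProfile(
                patient_id=pid,
                expression=tumor_values[pid].copy(),
                variants=variants,
                segments=sorted(segments, key=lambda s: (s.chromosome, s.start)),
                fusions=[],
                methylation=methylation,
                catalog=catalog,
                metadata=metadata,
            )
        )
        truth.overexpressed[pid] = over_genes
        truth.actionable[pid] = actionable
        truth.signature_weights[pid] = {s: float(weights[s]) for s in sig_ids}
        truth.dominant_signature[pid] = dominant
        truth.arm_events[pid] = arm_truth
        truth.methylation_class[pid] = {
            g: classify_beta(float(latent[g])) for g in genes
        }
        truth.mycn_amplified[pid] = bool(mycn_amp[pi])

    return SyntheticCohort(
        profiles, normal_panel, cancer_panel, tumor_panel, truth, config, sig_matrix
    )


# --------------------------------------------------------------------------
# fixture round-trip
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixtures(cohort: SyntheticCohort, directory: str | Path) -> dict:
    """Write every downstream input format plus a manifest with checksums."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    def track(path: Path) -> Path:
        files.append(path)
        return path

    tbio.write_expression_panel(cohort.normal_panel, track(directory / "normal_panel.tsv"))
    files.append(directory / "normal_panel.tsv.meta.json")
    tbio.write_expression_panel(cohort.cancer_panel, track(directory / "cancer_panel.tsv"))
    files.append(directory / "cancer_panel.tsv.meta.json")
    tbio.write_expression_panel(cohort.tumor_panel, track(directory / "tumor_panel.tsv"))
    files.append(directory / "tumor_panel.tsv.meta.json")
    cohort.signature_matrix.to_csv(track(directory / "signatures.tsv"), sep="\t", float_format="%.17g")
    dump_rulebook(load_rulebook(), track(directory / "rulebook.yaml"))

    for profile in cohort.profiles:
        pdir = directory / "patients" / profile.patient_id
        pdir.mkdir(parents=True, exist_ok=True)
        profile.expression.rename("value").rename_axis("gene").to_csv(
            track(pdir / "expression.tsv"), sep="\t", float_format="%.17g"
        )
        tbio.write_variants(profile.variants, track(pdir / "variants.tsv"))
        tbio.write_segments(profile.segments, track(pdir / "segments.seg"),
                            sample=profile.patient_id)
        tbio.write_fusions(profile.fusions, track(pdir / "fusions.tsv"))
        profile.methylation.to_csv(track(pdir / "methylation.tsv"), sep="\t", index=False, float_format="%.17g")
        tbio.write_catalog(profile.catalog, track(pdir / "catalog.tsv"))
        track(pdir / "metadata.json").write_text(
            json.dumps(profile.metadata, sort_keys=True) + "\n"
        )

    track(directory / "truth.json").write_text(
        json.dumps(asdict(cohort.truth), sort_keys=True) + "\n"
    )
    manifest = {
        "n_patients": len(cohort.profiles),
        "seed": cohort.config.seed,
        "patients": [p.patient_id for p in cohort.profiles],
        "files": {
            str(p.relative_to(directory)): _sha256(p) for p in sorted(set(files))
        },
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    return manifest


def read_fixtures(directory: str | Path) -> SyntheticCohort:
    """Read fixtures written by :func:`write_fixtures` back into memory.

    The returned cohort carries the stored truth but a default config (the
    config itself is not serialized beyond its seed).
    """
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    normal = tbio.read_expression_panel(directory / "normal_panel.tsv")
    cancer = tbio.read_expression_panel(directory / "cancer_panel.tsv")
    tumor = tbio.read_expression_panel(directory / "tumor_panel.tsv")
    sig_matrix = pd.read_csv(directory / "signatures.tsv", sep="\t", index_col="channel", float_precision="round_trip")
    truth_doc = json.loads((directory / "truth.json").read_text())
    truth = SyntheticTruth(**truth_doc)
    profiles = []
    for pid in manifest["patients"]:
        pdir = directory / "patients" / pid
        expression = pd.read_csv(pdir / "expression.tsv", sep="\t", index_col="gene", float_precision="round_trip")["value"]
        profiles.append(
            PatientProfile(
                patient_id=pid,
                expression=expression,
                variants=tbio.read_variants(pdir / "variants.tsv"),
                segments=tbio.read_segments(pdir / "segments.seg"),
                fusions=tbio.read_fusions(pdir / "fusions.tsv"),
                methylation=pd.read_csv(pdir / "methylation.tsv", sep="\t", float_precision="round_trip"),
                catalog=tbio.read_catalog(pdir / "catalog.tsv"),
                metadata=json.loads((pdir / "metadata.json").read_text()),
            )
        )
    config = CohortConfig(n_patients=len(profiles), seed=manifest["seed"])
    return SyntheticCohort(profiles, normal, cancer, tumor, truth, config, sig_matrix)
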