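"""Synthetic multi-tissue expression corpus with planted ground truth.

The generator emulates the statistical structure the heterogeneity
analysis relies on: every tissue owns a disjoint block of signature genes
elevated ``fold_change``-fold in that tissue's samples over a shared
log-normal baseline; a *contaminated* sample is a linear mixture
(1 - lambda) * own-tissue profile + lambda * contaminant profile on the
natural scale (cell admixture is additive in transcript abundance); a
*mislabelled* sample carries another tissue's full profile under the
wrong annotation.

Two per-sample nuisance factors emulate real corpora: an
expression-program strength (lognormal with sd ``signal_sd``) rescales
the planted elevation, modelling tissue purity and program intensity
differences between samples, and multiplicative log-normal noise with a
per-sample level drawn from noise_sd +/- noise_sd_jitter models platform
and sample-quality variation.  Marker genes share a common baseline
abundance so the planted fold-change is the only systematic tissue
signal; background genes keep gene-specific log-normal baselines.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import Vocabulary
from .matrix import ExpressionMatrix
from .signatures import ROLE_QUERY, ROLE_REFERENCE, GeneSignature, SignatureCollection

DEFAULT_TISSUE_NAMES = (
    "blood",
    "liver",
    "pancreas",
    "skin",
    "brain",
    "heart",
    "kidney",
    "lung",
    "muscle",
    "spleen",
    "testis",
    "thymus",
    "adipose",
    "colon",
    "stomach",
)

_RAW_VARIANTS = ("{t}", "{T}", " {t} ", "{t} tissue", "{t}.", "{T} TISSUE")


@dataclass
class SimConfig:
    n_tissues: int = 9
    genes_total: int = 4000
    signature_genes_per_tissue: int = 80
    samples_per_tissue: int = 50
    fold_change: float = 8.0
    signal_sd: float = 0.6
    noise_sd: float = 1.0
    noise_sd_jitter: float = 0.25
    contamination_fraction: float = 0.10
    mixing_proportion: float = 0.30
    mislabel_fraction: float = 0.02
    signature_overlap: float = 0.0
    baseline_meanlog: float = 3.0
    baseline_sdlog: float = 1.0
    studies_per_tissue: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_tissues,
            self.genes_total,
            self.signature_genes_per_tissue,
            self.samples_per_tissue,
            self.studies_per_tissue,
        ) < 1:
            raise ValueError("all counts must be positive")
        if self.n_tissues < 2:
            raise ValueError("need at least 2 tissues")
        if self.signature_genes_per_tissue * self.n_tissues > self.genes_total:
            raise ValueError("signature gene blocks exceed genes_total")
        if not 0 < self.mixing_proportion < 1:
            raise ValueError("mixing_proportion must lie in (0, 1)")
        if self.contamination_fraction + self.mislabel_fraction > 1:
            raise ValueError("contamination_fraction + mislabel_fraction must be <= 1")
        if not 0 <= self.signature_overlap < 1:
            raise ValueError("signature_overlap must lie in [0, 1)")
        if self.noise_sd_jitter > self.noise_sd and self.noise_sd_jitter > 0:
            raise ValueError("noise_sd_jitter may not exceed noise_sd")
        if self.signal_sd < 0:
            raise ValueError("signal_sd must be >= 0")

    @property
    def tissues(self) -> list:
        names = list(DEFAULT_TISSUE_NAMES)
        while len(names) < self.n_tissues:
            names.append(f"tissue{len(names) + 1}")
        return names[: self.n_tissues]

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class GroundTruth:
    """Planted truth: per-sample origins and per-gene ownership."""

    samples: pd.DataFrame  # sample_id, true_tissue, annotated_tissue, contaminant, lam
    gene_owner: pd.Series  # gene -> owning tissue or NaN

    def __post_init__(self) -> None:
        s = self.samples
        mislabel = s["true_tissue"] != s["annotated_tissue"]
        if not (s.loc[mislabel, "contaminant"].isna()).all():
            raise ValueError("a mislabelled sample cannot also be a mixture")

    @property
    def mixture_ids(self) -> set:
        return set(self.samples.loc[self.samples["contaminant"].notna(), "sample_id"])

    @property
    def mislabel_ids(self) -> set:
        s = self.samples
        return set(s.loc[s["true_tissue"] != s["annotated_tissue"], "sample_id"])

    @property
    def pure_ids(self) -> set:
        return set(self.samples["sample_id"]) - self.mixture_ids - self.mislabel_ids

    def to_tsv(self, path) -> Path:
        path = Path(path)
        self.samples.to_csv(path, sep="\t", index=False)
        return path


def _tissue_profiles(config: SimConfig, baseline: np.ndarray) -> np.ndarray:
    """Genes x tissues expected-expression profiles."""
    T = config.n_tissues
    spt = config.signature_genes_per_tissue
    profiles = np.tile(baseline[:, None], (1, T))
    n_shared = math.ceil(config.signature_overlap * spt)
    for t in range(T):
        block = slice(t * spt, (t + 1) * spt)
        profiles[block, t] *= config.fold_change
        if n_shared:
            # leading genes of the block are also elevated in the next
            # tissue, manufacturing correlated signatures on demand
            profiles[t * spt : t * spt + n_shared, (t + 1) % T] *= config.fold_change
    return profiles


def simulate_corpus(config: SimConfig):
    """Draw a corpus; returns (ExpressionMatrix, annotations, GroundTruth).

    Deterministic given ``config.rng_seed``: identical configs give
    bit-identical corpora.
    """
    rng = np.random.default_rng(config.rng_seed)
    T = config.n_tissues
    tissues = config.tissues
    spt = config.signature_genes_per_tissue
    genes = [f"G{i:05d}" for i in range(config.genes_total)]
    owner = pd.Series(
        [tissues[i // spt] if i < T * spt else None for i in range(config.genes_total)],
        index=genes,
        dtype=object,
    )

    baseline = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, config.genes_total)
    # marker genes share a common baseline abundance (the genome-scale
    # typical level) so that the planted fold-change is the only
    # systematic tissue signal; background genes keep gene-specific
    # baselines spanning the full dynamic range
    baseline[: T * spt] = math.exp(config.baseline_meanlog)
    profiles = _tissue_profiles(config, baseline)

    n = T * config.samples_per_tissue
    annotated = np.repeat(np.arange(T), config.samples_per_tissue)
    n_mix = round(config.contamination_fraction * n)
    n_mis = round(config.mislabel_fraction * n)
    special = rng.choice(n, size=n_mix + n_mis, replace=False)
    mix_idx = set(special[:n_mix].tolist())
    mis_idx = set(special[n_mix:].tolist())

    sample_ids = [f"S{i:05d}" for i in range(n)]
    true_t = annotated.copy()
    contaminant = np.full(n, None, dtype=object)
    lam = np.full(n, np.nan)

    def _program(t: int, strength: float) -> np.ndarray:
        """Tissue t's expected profile with a per-sample program strength.

        ``strength`` rescales the planted elevation (tissue purity /
        expression-program intensity varies between samples): the
        effective fold-change is fold_change * strength.
        """
        col = profiles[:, t]
        if config.fold_change == 1.0:
            return col
        factor = (config.fold_change * strength - 1.0) / (config.fold_change - 1.0)
        return baseline + (col - baseline) * factor

    strengths = rng.lognormal(0.0, config.signal_sd, n) if config.signal_sd > 0 else np.ones(n)
    expected = np.empty((config.genes_total, n))
    for i in range(n):
        t = annotated[i]
        if i in mix_idx:
            others = [u for u in range(T) if u != t]
            u = int(rng.choice(others))
            contaminant[i] = tissues[u]
            lam[i] = config.mixing_proportion
            s_cont = float(rng.lognormal(0.0, config.signal_sd)) if config.signal_sd > 0 else 1.0
            expected[:, i] = (1 - config.mixing_proportion) * _program(t, strengths[i]) + (
                config.mixing_proportion * _program(u, s_cont)
            )
        elif i in mis_idx:
            others = [u for u in range(T) if u != t]
            u = int(rng.choice(others))
            true_t[i] = u
            expected[:, i] = _program(u, strengths[i])
        else:
            expected[:, i] = _program(t, strengths[i])

    sd_lo = config.noise_sd - config.noise_sd_jitter
    sd_hi = config.noise_sd + config.noise_sd_jitter
    sample_sd = rng.uniform(sd_lo, sd_hi, n) if sd_hi > sd_lo else np.full(n, config.noise_sd)
    noise = np.exp(rng.normal(0.0, 1.0, expected.shape) * sample_sd[None, :])
    values = expected * noise

    # annotations with free-text tissue variants and study structure
    study_of = np.empty(n, dtype=object)
    platform = np.empty(n, dtype=object)
    year = np.empty(n, dtype=int)
    study_year = {}
    for t in range(T):
        for j in range(config.studies_per_tissue):
            sid = f"ST_{tissues[t]}_{j}"
            study_year[sid] = int(rng.integers(2002, 2021))
    for i in range(n):
        t = annotated[i]
        j = i % config.studies_per_tissue
        sid = f"ST_{tissues[t]}_{j}"
        study_of[i] = sid
        platform[i] = "microarray" if j % 2 == 0 else "rnaseq"
        year[i] = study_year[sid]
    variants = [_RAW_VARIANTS[int(v)] for v in rng.integers(0, len(_RAW_VARIANTS), n)]
    tissue_raw = [
        v.format(t=tissues[annotated[i]], T=tissues[annotated[i]].upper())
        for i, v in enumerate(variants)
    ]
    annotations = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "study_id": study_of,
            "tissue_raw": tissue_raw,
            "platform": platform,
            "year": year,
        }
    )
    truth = GroundTruth(
        samples=pd.DataFrame(
            {
                "sample_id": sample_ids,
                "true_tissue": [tissues[t] for t in true_t],
                "annotated_tissue": [tissues[t] for t in annotated],
                "contaminant": contaminant,
                "lam": lam,
            }
        ),
        gene_owner=owner,
    )
    expr = ExpressionMatrix(values, genes, sample_ids)
    return expr, annotations, truth


def planted_signatures(truth: GroundTruth):
    """Build per-tissue query and reference collections from the planted blocks.

    Returns (queries, references); names are ``<tissue>.query`` and
    ``<tissue>.ref``.
    """
    queries = []
    references = []
    for tissue in pd.unique(truth.gene_owner.dropna()):
        genes = tuple(truth.gene_owner.index[truth.gene_owner == tissue])
        queries.append(
            GeneSignature(f"{tissue}.query", genes, tissue=tissue, role=ROLE_QUERY)
        )
        references.append(
            GeneSignature(f"{tissue}.ref", genes, tissue=tissue, role=ROLE_REFERENCE)
        )
    return (
        SignatureCollection(queries, provenance="planted tissue blocks (query role)"),
        SignatureCollection(references, provenance="planted tissue blocks (reference role)"),
    )


def reference_map(references: SignatureCollection) -> dict:
    """tissue -> reference signature name."""
    return {sig.tissue: sig.name for sig in references}


def default_vocabulary(tissues) -> Vocabulary:
    """Controlled vocabulary covering the generator's free-text variants."""
    entries = {}
    for t in tissues:
        entries[t] = t
        entries[f"{t} tissue"] = t
    return Vocabulary(entries=entries, reference_tissues=frozenset(tissues))


def truth_confusion(calls, truth: GroundTruth) -> pd.Series:
    """Detection quality against the planted truth.

    sensitivity: flagged | (mixture or mislabel); specificity:
    not-flagged | pure; severity accuracy: severe | mislabel and
    moderate | mixture; plus the pure-sample severe rate.
    """
    call_ids = {c.sample_id for c in calls}
    truth_ids = set(truth.samples["sample_id"])
    if call_ids != truth_ids:
        raise ValueError(
            f"calls and truth cover different samples "
            f"({len(call_ids ^ truth_ids)} mismatched)"
        )
    status = {c.sample_id: c.status for c in calls}
    mix, mis, pure = truth.mixture_ids, truth.mislabel_ids, truth.pure_ids
    hetero = mix | mis

    def _rate(ids, pred) -> float:
        return float(np.mean([pred(status[s]) for s in ids])) if ids else float("nan")

    return pd.Series(
        {
            "sensitivity": _rate(hetero, lambda s: s != "none"),
            "specificity": _rate(pure, lambda s: s == "none"),
            "mislabel_severe_rate": _rate(mis, lambda s: s == "severe"),
            "mixture_moderate_rate": _rate(mix, lambda s: s == "moderate"),
            "pure_severe_rate": _rate(pure, lambda s: s == "severe"),
            "n_mixture": float(len(mix)),
            "n_mislabel": float(len(mis)),
            "n_pure": float(len(pure)),
        }
    )
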