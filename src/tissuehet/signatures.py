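"""Tissue gene signatures: GMT I/O, Gini-index generation, cross-validation.

A *signature* is a named set of genes whose joint high expression marks a
tissue.  Signatures come in two roles: *reference* signatures define what
a sample of the annotated tissue should express; *query* signatures are
sensitive scanners for foreign-tissue signal.

Signature generation follows the atlas recipe: summarize each gene to a
per-tissue median profile, keep genes whose profile is strongly
tissue-restricted (Gini index above a threshold) and whose target tissue
is among the top-ranking tissues for that gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

ROLE_QUERY = "query"
ROLE_REFERENCE = "reference"
#: Sentinel tissue label for signatures whose tissue is unknown/uncurated.
UNMAPPED = "unmapped"


@dataclass
class GeneSignature:
    """A named gene set tagged with a canonical tissue term.

    Gene symbols are uppercase-normalized and deduplicated preserving
    first occurrence; the stored order is meaningful (descending marker
    strength when generated here).
    """

    name: str
    genes: tuple
    tissue: str = UNMAPPED
    role: str = ROLE_QUERY
    description: str = ""

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for g in self.genes:
            sym = str(g).strip().upper()
            if sym and sym not in seen:
                seen[sym] = None
        self.genes = tuple(seen)
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")
        if self.role not in (ROLE_QUERY, ROLE_REFERENCE):
            raise ValueError(f"unknown signature role {self.role!r}")

    @property
    def gene_set(self) -> frozenset:
        return frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class SignatureCollection:
    """Ordered list of signatures with unique names."""

    signatures: list
    provenance: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.signatures]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate signature names: {dupes}")

    def __iter__(self):
        return iter(self.signatures)

    def __len__(self) -> int:
        return len(self.signatures)

    @property
    def names(self) -> list:
        return [s.name for s in self.signatures]

    def get(self, name: str) -> GeneSignature:
        for s in self.signatures:
            if s.name == name:
                return s
        raise KeyError(name)

    def tissue_of(self) -> dict:
        return {s.name: s.tissue for s in self.signatures}

    def subset_role(self, role: str) -> "SignatureCollection":
        return SignatureCollection(
            [s for s in self.signatures if s.role == role], provenance=self.provenance
        )

    def __add__(self, other: "SignatureCollection") -> "SignatureCollection":
        prov = "; ".join(p for p in (self.provenance, other.provenance) if p)
        return SignatureCollection(
            list(self.signatures) + list(other.signatures), provenance=prov
        )


# --- GMT I/O -----------------------------------------------------------


def read_gmt(path, role: str = ROLE_QUERY, tissue_map=None) -> SignatureCollection:
    """Parse a GMT file (name TAB description TAB gene TAB gene ...).

    By convention the description field carries the canonical tissue term;
    ``tissue_map`` (signature name -> tissue) overrides it.  Lines with
    fewer than three fields are a parse error naming the line number.
    """
    path = Path(path)
    sigs = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: malformed GMT line, expected >= 3 tab-separated "
                f"fields, got {len(fields)}"
            )
        name, description = fields[0], fields[1]
        if tissue_map is not None and name in tissue_map:
            tissue = tissue_map[name]
        else:
            tissue = description.strip().lower() or UNMAPPED
        sigs.append(
            GeneSignature(
                name=name,
                genes=tuple(fields[2:]),
                tissue=tissue,
                role=role,
                description=description,
            )
        )
    return SignatureCollection(sigs, provenance=str(path))


def write_gmt(collection: SignatureCollection, path) -> Path:
    """Write one tab-separated line per signature; description = tissue."""
    if len(collection) == 0:
        raise ValueError("refusing to write an empty signature collection")
    path = Path(path)
    lines = []
    for sig in collection:
        desc = sig.description or sig.tissue
        lines.append("\t".join([sig.name, desc, *sig.genes]))
    path.write_text("\n".join(lines) + "\n")
    return path


# --- Gini index --------------------------------------------------------


def gini_index(values) -> float:
    """Gini inequality index of a non-negative vector.

    For ascending-sorted x of length n:
    G = sum_i (2i - n - 1) x_i / (n sum_i x_i), i = 1..n.  G = 0 for a
    constant vector and approaches (n-1)/n as mass concentrates in a
    single entry; the statistic is scale-free.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("gini_index needs a 1-D vector of length >= 2")
    if np.any(x < 0):
        raise ValueError("gini_index is undefined for negative values")
    total = x.sum()
    if total == 0:
        raise ValueError("undefined Gini: all values are zero")
    xs = np.sort(x)
    n = xs.size
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * xs).sum() / (n * total))


# --- signature generation ---------------------------------------------


def _labels_vector(expr: ExpressionMatrix, tissue_labels) -> np.ndarray:
    """Align a per-sample tissue labelling with expr.samples."""
    if isinstance(tissue_labels, pd.Series):
        tissue_labels = tissue_labels.to_dict()
    if isinstance(tissue_labels, dict):
        missing = [s for s in expr.samples if s not in tissue_labels]
        if missing:
            raise ValueError(f"unlabeled samples: {missing[:5]}")
        return np.array([str(tissue_labels[s]) for s in expr.samples])
    labels = np.asarray(list(tissue_labels), dtype=object)
    if labels.size != expr.n_samples:
        raise ValueError("tissue labels do not cover all samples")
    if any(l is None or str(l) == "" for l in labels):
        raise ValueError("unlabeled sample in tissue labels")
    return labels.astype(str)


def tissue_profile(expr: ExpressionMatrix, tissue_labels) -> pd.DataFrame:
    """Per-gene median expression across the samples of each tissue."""
    labels = _labels_vector(expr, tissue_labels)
    tissues = sorted(set(labels))
    cols = {t: np.median(expr.values[:, labels == t], axis=1) for t in tissues}
    return pd.DataFrame(cols, index=expr.genes)


def generate_signatures(
    expr: ExpressionMatrix,
    tissue_labels,
    gini_min: float = 0.8,
    rank_max: int = 3,
    max_genes: int = 200,
    role: str = ROLE_QUERY,
) -> SignatureCollection:
    """Derive one tissue-enriched signature per tissue from an atlas matrix.

    A gene enters tissue t's signature iff (a) the Gini index of its
    per-tissue median profile is >= ``gini_min``, (b) t is among the
    ``rank_max`` highest-expressing tissues for the gene (competition
    ranking, so exact ties at the boundary are included), and (c) its
    median in t is positive.  Each signature keeps at most ``max_genes``
    genes, ordered by descending median in t.  Tissues ending up with no
    genes yield no signature.  Both the Gini index and the ranking are
    scale-free, so rescaling the matrix leaves the output unchanged.
    """
    profile = tissue_profile(expr, tissue_labels)
    if profile.shape[1] < 2:
        raise ValueError("signature generation needs at least 2 tissues")
    values = profile.to_numpy()
    nonzero = values.sum(axis=1) > 0  # all-zero genes cannot be tissue-enriched
    gini = np.full(values.shape[0], -1.0)
    gini[nonzero] = np.apply_along_axis(gini_index, 1, values[nonzero])
    # competition rank from the top: 1 + number of tissues strictly higher
    comp_rank = values.shape[1] - rankdata(values, axis=1, method="max") + 1

    sigs = []
    for j, tissue in enumerate(profile.columns):
        keep = nonzero & (gini >= gini_min) & (comp_rank[:, j] <= rank_max) & (values[:, j] > 0)
        idx = np.flatnonzero(keep)
        if idx.size == 0:
            continue
        order = idx[np.argsort(-values[idx, j], kind="stable")][:max_genes]
        sigs.append(
            GeneSignature(
                name=tissue,
                genes=tuple(profile.index[order]),
                tissue=tissue,
                role=role,
            )
        )
    prov = (
        f"generated from {expr.n_samples} samples / {profile.shape[1]} tissues; "
        f"gini_min={gini_min}, rank_max={rank_max}, max_genes={max_genes}, "
        f"aggregation=median"
    )
    return SignatureCollection(sigs, provenance=prov)


# --- cross-validation --------------------------------------------------


@dataclass
class ValidationReport:
    """Outcome of validating signatures on an independent labelled dataset.

    score_matrix: signature x tissue median enrichment score (-log10 p).
    confusion: annotated tissue x top-hit signature tissue counts; each
    row sums to the number of validation samples of that tissue.
    sensitivity: per-tissue fraction of samples whose top hit matches.
    """

    score_matrix: pd.DataFrame
    confusion: pd.DataFrame
    sensitivity: pd.Series

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        long = self.score_matrix.stack().rename("score").reset_index()
        long.columns = ["signature", "tissue", "score"]
        long.to_csv(outdir / "validation_scores.tsv", sep="\t", index=False)
        self.confusion.to_csv(outdir / "validation_confusion.tsv", sep="\t")
        self.sensitivity.rename("sensitivity").to_csv(
            outdir / "validation_sensitivity.tsv", sep="\t"
        )


def crossvalidate_signatures(
    collection: SignatureCollection, expr: ExpressionMatrix, tissue_labels
) -> ValidationReport:
    """Score every validation sample against every signature.

    The top hit of a sample is the signature with the smallest enrichment
    p-value; sensitivity per tissue is the fraction of that tissue's
    samples whose top-hit signature is tagged with the same tissue.
    """
    from .enrich import P_FLOOR, run_enrichment

    labels = _labels_vector(expr, tissue_labels)
    table = run_enrichment(expr, collection, min_genes=1)
    scores = -np.log10(np.clip(table.pvals.to_numpy(), P_FLOOR, 1.0))
    score_df = pd.DataFrame(scores, index=table.pvals.index, columns=table.pvals.columns)

    sig_tissue = {s.name: s.tissue for s in collection}
    top_sig = table.pvals.idxmin(axis=1)
    top_tissue = top_sig.map(sig_tissue)

    tissues = sorted(set(labels))
    sig_tissues = sorted(set(sig_tissue.values()))
    confusion = pd.DataFrame(0, index=tissues, columns=sig_tissues, dtype=int)
    for t, u in zip(labels, top_tissue.to_numpy()):
        confusion.loc[t, u] += 1

    sens = {}
    for t in tissues:
        mask = labels == t
        sens[t] = float(np.mean(top_tissue.to_numpy()[mask] == t))
    sensitivity = pd.Series(sens).sort_index()

    label_series = pd.Series(labels, index=score_df.index)
    score_matrix = score_df.groupby(label_series).median().T
    score_matrix.index.name = "signature"
    score_matrix.columns.name = "tissue"
    return ValidationReport(score_matrix, confusion, sensitivity)
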