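"""Sample annotations, controlled-vocabulary tissue mapping, corpus filtering.

Free-text tissue labels in public repositories are inconsistent
("Liver", "liver tissue", "LIVER biopsy"), so they are mapped onto a
curated controlled vocabulary before any analysis.  Corpus filtering then
restricts the matrix to samples of tissues that have a validated
reference signature and removes studies whose processing breaks the
within-sample rank assumption (per-gene normalized profiles).
"""

from __future__ import annotations

import json
import logging
import re
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["sample_id", "study_id", "tissue_raw", "platform", "year"]


@dataclass(frozen=True)
class Vocabulary:
    """Mapping from normalized free-text tissue terms to canonical tissues.

    ``reference_tissues`` is the subset of canonical tissues that have a
    validated reference signature; only their samples survive filtering.
    """

    entries: dict
    reference_tissues: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "entries", {normalize_term(k): v for k, v in self.entries.items()}
        )
        canon = set(self.entries.values())
        if not self.reference_tissues <= canon:
            extra = sorted(self.reference_tissues - canon)
            raise ValueError(f"reference tissues missing from vocabulary: {extra}")

    @property
    def canonical_tissues(self) -> frozenset:
        return frozenset(self.entries.values())


def normalize_term(raw: str) -> str:
    """Lowercase, strip, collapse internal whitespace, drop trailing punctuation."""
    term = re.sub(r"\s+", " ", str(raw).strip().lower())
    return term.rstrip(string.punctuation + " ")


def map_tissue_term(raw: str, vocab: Vocabulary):
    """Exact lookup of a normalized free-text term; None when unmapped."""
    return vocab.entries.get(normalize_term(raw))


def apply_vocabulary(annotations: pd.DataFrame, vocab: Vocabulary) -> pd.DataFrame:
    """Add/overwrite the canonical ``tissue`` column from ``tissue_raw``."""
    out = annotations.copy()
    out["tissue"] = [map_tissue_term(t, vocab) for t in out["tissue_raw"]]
    return out


def load_annotations(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "study_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation table lacks columns: {missing}")
    if ann["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in annotations")
    return ann


def save_annotations(annotations: pd.DataFrame, path) -> Path:
    path = Path(path)
    annotations.to_csv(path, sep="\t", index=False)
    return path


def load_vocabulary(path, reference_path=None) -> Vocabulary:
    """Read a two-column TSV (raw_term, canonical_tissue) and an optional
    one-term-per-line reference-tissue list."""
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise ValueError("vocabulary TSV needs columns raw_term, canonical_tissue")
    entries = dict(zip(table.iloc[:, 0].astype(str), table.iloc[:, 1].astype(str)))
    if reference_path is not None:
        refs = frozenset(
            line.strip()
            for line in Path(reference_path).read_text().splitlines()
            if line.strip()
        )
    else:
        refs = frozenset(entries.values())
    return Vocabulary(entries=entries, reference_tissues=refs)


def save_vocabulary(vocab: Vocabulary, path, reference_path=None) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"raw_term": list(vocab.entries), "canonical_tissue": list(vocab.entries.values())}
    ).to_csv(path, sep="\t", index=False)
    if reference_path is not None:
        Path(reference_path).write_text("\n".join(sorted(vocab.reference_tissues)) + "\n")
    return path


@dataclass
class FilterReport:
    """Per-rule sample counts dropped by corpus filtering."""

    n_input: int = 0
    n_output: int = 0
    unmapped: int = 0
    non_reference: int = 0
    per_gene_normalized: int = 0
    small_study: int = 0
    dropped_studies: list = field(default_factory=list)

    @property
    def counts(self) -> dict:
        return {
            "unmapped": self.unmapped,
            "non_reference": self.non_reference,
            "per_gene_normalized": self.per_gene_normalized,
            "small_study": self.small_study,
        }

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "n_input": self.n_input,
                "n_output": self.n_output,
                **self.counts,
                "dropped_studies": self.dropped_studies,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def looks_per_gene_normalized(
    values: np.ndarray,
    negative_fraction: float = 0.25,
    centered_row_fraction: float = 0.50,
    centered_tol: float = 0.01,
) -> bool:
    """Heuristic for per-gene normalized (e.g. mean-centered) matrices.

    Rank-based enrichment needs values comparable *within* a sample, which
    per-gene normalization destroys.  A matrix is flagged when more than
    ``negative_fraction`` of its entries are negative, or when more than
    ``centered_row_fraction`` of gene rows have an absolute mean below
    ``centered_tol`` times the global interdecile range.
    """
    vals = np.asarray(values, dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return False
    if np.mean(finite < 0) > negative_fraction:
        return True
    q10, q90 = np.nanpercentile(vals, [10, 90])
    idr = q90 - q10
    row_means = np.nanmean(vals, axis=1)
    return bool(np.mean(np.abs(row_means) < centered_tol * idr) > centered_row_fraction)


def filter_corpus(
    expr: ExpressionMatrix,
    annotations: pd.DataFrame,
    vocab: Vocabulary,
    min_samples_per_study: int = 1,
    negative_fraction: float = 0.25,
    centered_row_fraction: float = 0.50,
    centered_tol: float = 0.01,
):
    """Apply the corpus study-selection rules, in order, with counts.

    Drops (1) samples with unmapped tissue, (2) samples whose tissue has
    no reference signature, (3) whole studies detected as per-gene
    normalized, (4) studies left with fewer than ``min_samples_per_study``
    samples.  Returns (filtered matrix, filtered annotations, report);
    raises if nothing survives.
    """
    ann = annotations.copy()
    missing = [s for s in expr.samples if s not in set(ann["sample_id"])]
    if missing:
        raise ValueError(f"annotations do not cover matrix columns: {missing[:5]}")
    ann = ann.set_index("sample_id", drop=False).loc[expr.samples].reset_index(drop=True)

    report = FilterReport(n_input=expr.n_samples)
    if "tissue" not in ann.columns:
        ann = apply_vocabulary(ann, vocab)

    keep = ann["tissue"].notna().to_numpy()
    report.unmapped = int((~keep).sum())
    ann = ann[keep]

    in_ref = ann["tissue"].isin(vocab.reference_tissues).to_numpy()
    report.non_reference = int((~in_ref).sum())
    ann = ann[in_ref]

    sample_pos = {s: i for i, s in enumerate(expr.samples)}
    surviving = []
    for study, group in ann.groupby("study_id", sort=True):
        cols = [sample_pos[s] for s in group["sample_id"]]
        sub = expr.values[:, cols]
        if looks_per_gene_normalized(
            sub, negative_fraction, centered_row_fraction, centered_tol
        ):
            report.per_gene_normalized += len(cols)
            report.dropped_studies.append(str(study))
            log.warning("study %s dropped: per-gene normalized profile detected", study)
            continue
        if len(cols) < min_samples_per_study:
            report.small_study += len(cols)
            report.dropped_studies.append(str(study))
            continue
        surviving.append(group)

    if not surviving:
        raise ValueError(f"empty corpus after filtering; report: {report.to_json()}")
    ann_out = pd.concat(surviving)
    # restore original column order
    ann_out = ann_out.set_index("sample_id", drop=False)
    ordered = [s for s in expr.samples if s in set(ann_out["sample_id"])]
    ann_out = ann_out.loc[ordered].reset_index(drop=True)
    report.n_output = len(ordered)
    return expr.subset_samples(ordered), ann_out, report
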