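"""Per-sample Wilcoxon-Mann-Whitney signature enrichment.

For each sample independently, the genes of a signature are tested
against all other measured genes ("background") for higher within-sample
expression ranks.  The test is one-sided ("greater"): a small p-value
means the signature genes sit near the top of the sample's expression
ranking.  Because only ranks enter, the result is invariant under any
strictly increasing transform of a sample's values.

Two computation modes exist: an exact permutation distribution (all
C(N, k) equally likely placements of the signature ranks) for small
numbers of genes, and the tie-corrected, continuity-corrected normal
approximation, which is the default at corpus scale.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .matrix import ExpressionMatrix
from .signatures import ROLE_REFERENCE, SignatureCollection

log = logging.getLogger(__name__)

#: Smallest representable p-value; applied before any |log10 p| transform.
P_FLOOR = 1e-300
#: Largest total gene count for which "auto" mode uses the exact distribution.
EXACT_LIMIT = 25
#: Largest enumeration size attempted when ties force brute-force counting.
_MAX_ENUM = 500_000


def _tie_term(values: np.ndarray) -> float:
    """Sum of t^3 - t over groups of tied values."""
    _, counts = np.unique(values, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float((t**3 - t).sum())


def _approx_pvalue(u: float, k: int, m: int, tie_term: float) -> float:
    n = k + m
    var = k * m / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values identical: point-mass permutation distribution
        return 1.0
    z = (u - k * m / 2.0 - 0.5) / np.sqrt(var)
    return float(np.clip(norm.sf(z), P_FLOOR, 1.0))


def _exact_pvalue_noties(u: float, k: int, n: int) -> float:
    """P(U >= u) over all C(n, k) placements of distinct ranks, by counting.

    Convolution over ranks 1..n of the number of k-subsets attaining each
    rank sum; exact integer arithmetic.
    """
    max_sum = n * (n + 1) // 2
    ways = np.zeros((k + 1, max_sum + 1), dtype=np.int64)
    ways[0, 0] = 1
    for r in range(1, n + 1):
        for j in range(min(k, r), 0, -1):
            ways[j, r:] += ways[j - 1, : max_sum + 1 - r]
    counts = ways[k]
    r_obs = u + k * (k + 1) / 2.0
    first = int(np.ceil(r_obs - 1e-9))
    hits = int(counts[first:].sum())
    return max(hits / comb(n, k), P_FLOOR)


def _exact_pvalue_ties(ranks: np.ndarray, mask: np.ndarray) -> float:
    """Exact p by enumerating placements of the smaller partition's midranks."""
    k = int(mask.sum())
    n = ranks.size
    m = n - k
    r_obs = float(ranks[mask].sum())
    total_sum = float(ranks.sum())
    side = min(k, m)
    if comb(n, side) > _MAX_ENUM:
        log.warning(
            "exact WMW enumeration too large (C(%d,%d)); using normal approximation",
            n,
            side,
        )
        u = r_obs - k * (k + 1) / 2.0
        return _approx_pvalue(u, k, m, _tie_term(ranks))
    hits = 0
    total = 0
    if side == k:
        for combo in itertools.combinations(ranks, k):
            total += 1
            if sum(combo) >= r_obs - 1e-9:
                hits += 1
    else:  # enumerate background side; signature sum = total - background sum
        for combo in itertools.combinations(ranks, m):
            total += 1
            if total_sum - sum(combo) >= r_obs - 1e-9:
                hits += 1
    return max(hits / total, P_FLOOR)


def wmw_pvalue(sample_values, signature_mask, mode: str = "auto") -> float:
    """One-sided WMW p-value for signature genes ranking above background.

    ``sample_values`` are one sample's expression values over all measured
    genes; ``signature_mask`` is a boolean vector marking signature genes.
    Midranks resolve ties; ``mode`` is "auto", "exact" or "approx".  If the
    tie-corrected variance is zero (all values identical) the p-value is 1.
    """
    values = np.asarray(sample_values, dtype=float)
    mask = np.asarray(signature_mask, dtype=bool)
    if values.shape != mask.shape or values.ndim != 1:
        raise ValueError("sample values and signature mask must be aligned 1-D vectors")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite expression value in sample")
    k = int(mask.sum())
    m = values.size - k
    if k == 0 or m == 0:
        raise ValueError("both signature and background partitions must be non-empty")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")

    ranks = rankdata(values)
    u = float(ranks[mask].sum()) - k * (k + 1) / 2.0
    use_exact = mode == "exact" or (mode == "auto" and values.size <= EXACT_LIMIT)
    if use_exact:
        if _tie_term(values) == 0:
            return _exact_pvalue_noties(u, k, values.size)
        return _exact_pvalue_ties(ranks, mask)
    return _approx_pvalue(u, k, m, _tie_term(values))


@dataclass
class EnrichmentTable:
    """(sample x signature) one-sided enrichment p-values plus metadata."""

    pvals: pd.DataFrame
    sig_tissue: dict
    sig_role: dict
    n_genes_used: dict

    def __post_init__(self) -> None:
        vals = self.pvals.to_numpy()
        if np.any(~np.isfinite(vals)) or np.any(vals <= 0) or np.any(vals > 1):
            raise ValueError("enrichment p-values must lie in (0, 1]")
        for name in self.pvals.columns:
            if self.n_genes_used.get(name, 0) < 1:
                raise ValueError(f"retained signature {name!r} has no genes used")

    @property
    def samples(self) -> list:
        return list(self.pvals.index)

    @property
    def signatures(self) -> list:
        return list(self.pvals.columns)

    def query_signatures(self) -> list:
        return [s for s in self.signatures if self.sig_role[s] != ROLE_REFERENCE]

    def to_long(self) -> pd.DataFrame:
        long = self.pvals.stack().rename("pvalue").reset_index()
        long.columns = ["sample_id", "signature", "pvalue"]
        long["tissue"] = long["signature"].map(self.sig_tissue)
        long["role"] = long["signature"].map(self.sig_role)
        return long

    def to_tsv(self, path) -> Path:
        path = Path(path)
        self.to_long().to_csv(path, sep="\t", index=False)
        return path

    def to_dense_tsv(self, path) -> Path:
        path = Path(path)
        self.pvals.to_csv(path, sep="\t", index_label="sample_id")
        return path

    @classmethod
    def from_tsv(cls, path) -> "EnrichmentTable":
        long = pd.read_csv(path, sep="\t")
        pvals = long.pivot(index="sample_id", columns="signature", values="pvalue")
        meta = long.drop_duplicates("signature").set_index("signature")
        return cls(
            pvals=pvals,
            sig_tissue=meta["tissue"].to_dict(),
            sig_role=meta["role"].to_dict(),
            n_genes_used={s: 1 for s in pvals.columns},
        )


def expected_pairs(n_samples: int, n_signatures: int) -> int:
    """Size contract of the enrichment table: one p-value per pair."""
    if n_samples < 1 or n_signatures < 1:
        raise ValueError("counts must be positive")
    return n_samples * n_signatures


def run_enrichment(
    expr: ExpressionMatrix,
    collection: SignatureCollection,
    min_genes: int = 5,
    mode: str = "approx",
) -> EnrichmentTable:
    """Test every signature in every sample; one p-value per pair.

    Signatures with fewer than ``min_genes`` genes present in the matrix
    are dropped with a warning.  Gene matching is by uppercase symbol.
    NaN values are treated as missing and dropped from the affected
    sample's ranking (pairwise-complete); infinities are an error.
    """
    if expr.n_genes < 2:
        raise ValueError("expression matrix must contain at least 2 genes")
    gene_pos = {g.strip().upper(): i for i, g in enumerate(expr.genes)}

    retained = []
    masks = []
    n_used = {}
    for sig in collection:
        idx = [gene_pos[g] for g in sig.genes if g in gene_pos]
        if len(idx) < max(min_genes, 1):
            log.warning(
                "dropping signature %r: only %d of %d genes found (min_genes=%d)",
                sig.name,
                len(idx),
                len(sig.genes),
                min_genes,
            )
            continue
        if len(idx) == expr.n_genes:
            raise ValueError(f"signature {sig.name!r} covers every measured gene")
        mask = np.zeros(expr.n_genes, dtype=bool)
        mask[idx] = True
        retained.append(sig)
        masks.append(mask)
        n_used[sig.name] = len(idx)
    if not retained:
        raise ValueError("no signature retained: zero usable gene overlap with matrix")

    mask_matrix = np.column_stack(masks)  # genes x signatures
    k = mask_matrix.sum(axis=0).astype(float)
    values = expr.values
    if np.any(np.isinf(values)):
        raise ValueError("infinite expression value in matrix")

    out = np.empty((expr.n_samples, len(retained)))
    for j in range(expr.n_samples):
        col = values[:, j]
        finite = np.isfinite(col)
        if finite.all():
            colf, maskf, kf = col, mask_matrix, k
        else:
            log.debug("sample %s: dropping %d missing values", expr.samples[j], (~finite).sum())
            colf = col[finite]
            maskf = mask_matrix[finite]
            kf = maskf.sum(axis=0).astype(float)
        n = colf.size
        mf = n - kf
        if np.any(kf < 1) or np.any(mf < 1):
            raise ValueError(
                f"sample {expr.samples[j]!r}: a signature lost all genes or all "
                "background after dropping missing values"
            )
        if mode == "exact" or (mode == "auto" and n <= EXACT_LIMIT):
            for s in range(len(retained)):
                out[j, s] = wmw_pvalue(colf, maskf[:, s], mode="exact")
            continue
        ranks = rankdata(colf)
        rank_sums = ranks @ maskf
        u = rank_sums - kf * (kf + 1) / 2.0
        tie = _tie_term(colf)
        var = kf * mf / 12.0 * ((n + 1) - tie / (n * (n - 1)))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (u - kf * mf / 2.0 - 0.5) / np.sqrt(var)
        p = np.where(var > 0, norm.sf(z), 1.0)
        out[j] = np.clip(p, P_FLOOR, 1.0)

    pvals = pd.DataFrame(out, index=list(expr.samples), columns=[s.name for s in retained])
    return EnrichmentTable(
        pvals=pvals,
        sig_tissue={s.name: s.tissue for s in retained},
        sig_role={s.name: s.role for s in retained},
        n_genes_used=n_used,
    )
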