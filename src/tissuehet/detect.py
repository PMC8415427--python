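"""Five-step tissue-heterogeneity detection and prevalence estimation.

Given per-sample enrichment p-values for query and reference signatures,
a sample annotated as tissue t is called *heterogeneous* when a foreign
query signature is detected at BH FDR < tau, after removing (tissue,
query) signature pairs whose enrichment tracks the reference signature
(robust-line slope >= slope_threshold, which indicates physiological
correlation rather than contamination).  Heterogeneity is *severe* when
additionally the tissue's own reference signature is not detected
(unadjusted p_ref > severe_alpha) -- the pattern expected from
mislabelling -- and *moderate* otherwise, the pattern of partial
contamination or infiltration.  Per-tissue prevalences carry percentile
bootstrap confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .enrich import P_FLOOR, EnrichmentTable

log = logging.getLogger(__name__)

STATUS_NONE = "none"
STATUS_MODERATE = "moderate"
STATUS_SEVERE = "severe"


@dataclass
class DetectionConfig:
    fdr_threshold: float = 0.01
    slope_threshold: float = 0.01
    severe_alpha: float = 0.05
    bootstrap_n: int = 1000
    ci_level: float = 0.95
    rng_seed: int = 0
    #: BH family: "global" adjusts jointly over all (sample, query) pairs
    #: of the run; "per_tissue" adjusts within each annotated tissue.
    bh_family: str = "global"

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.slope_threshold < 0:
            raise ValueError("slope_threshold must be >= 0")
        if not 0 < self.severe_alpha < 1:
            raise ValueError("severe_alpha must be in (0, 1)")
        if self.bootstrap_n < 1:
            raise ValueError("bootstrap_n must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.bh_family not in ("global", "per_tissue"):
            raise ValueError("bh_family must be 'global' or 'per_tissue'")


@dataclass
class ExclusionRecord:
    tissue: str
    query_signature: str
    slope: float
    n_samples_fit: int
    excluded: bool


@dataclass
class Trigger:
    signature: str
    tissue: str
    qvalue: float


@dataclass
class HeterogeneityCall:
    sample_id: str
    tissue: str
    status: str
    triggers: list
    p_ref: float

    @property
    def flagged(self) -> bool:
        return self.status != STATUS_NONE

    @property
    def q_min(self) -> float:
        return min((t.qvalue for t in self.triggers), default=float("nan"))


@dataclass
class TissueSummary:
    tissue: str
    n_samples: int
    n_moderate_or_severe: int
    n_severe: int
    fraction: float
    ci_low: float
    ci_high: float


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("bh_adjust needs at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fit_robust_line(x, y, tuning: float = 1.345, tol: float = 1e-8, maxiter: int = 50):
    """Huber M-estimated straight line y ~ a + b x; returns (slope, intercept).

    IRLS with tuning constant 1.345 and MAD scale (rescaled for normal
    consistency).  A zero-variance x yields slope 0 by contract; an exact
    linear relation is returned directly (the MAD scale degenerates there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-D vectors")
    if x.size < 3:
        raise ValueError("insufficient samples for exclusion fit (need >= 3 points)")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite input to robust fit")
    if np.ptp(x) == 0:
        return 0.0, float(np.median(y))
    design = sm.add_constant(x)
    ols = sm.OLS(y, design).fit()
    resid = y - ols.fittedvalues
    scale_y = max(np.max(np.abs(y)), 1.0)
    if np.max(np.abs(resid)) < 1e-10 * scale_y:  # exact line: IRLS scale degenerates
        return float(ols.params[1]), float(ols.params[0])
    rlm = sm.RLM(y, design, M=sm.robust.norms.HuberT(t=tuning))
    res = rlm.fit(scale_est="mad", conv="coefs", tol=tol, maxiter=maxiter)
    return float(res.params[1]), float(res.params[0])


def _abs_log10(p: np.ndarray) -> np.ndarray:
    return np.abs(np.log10(np.clip(p, P_FLOOR, 1.0)))


def _annotation_tissues(annotations: pd.DataFrame, samples) -> pd.Series:
    ann = annotations.set_index("sample_id")["tissue"]
    missing = [s for s in samples if s not in ann.index]
    if missing:
        raise ValueError(f"samples missing from annotations: {missing[:5]}")
    return ann.loc[samples]


def detect(
    table: EnrichmentTable,
    annotations: pd.DataFrame,
    ref_map: dict,
    config: Optional[DetectionConfig] = None,
):
    """Run the detection procedure; returns (calls, exclusions).

    Steps: (i) BH-adjust the query p-values (family per config); (ii) for
    every (annotated tissue t, query signature k) pair fit a robust line
    of |log10 p_query| on |log10 p_ref| over all samples annotated t;
    (iii) exclude pairs with slope >= slope_threshold; (iv) flag samples
    with q < tau for a retained foreign query signature, severe when the
    sample's own unadjusted p_ref > severe_alpha, else moderate.  Query
    signatures of the sample's own annotated tissue never count as
    heterogeneity evidence.
    """
    config = config or DetectionConfig()
    tissues_by_sample = _annotation_tissues(annotations, table.samples)
    tissues = sorted(tissues_by_sample.unique())
    for t in tissues:
        if t not in ref_map:
            raise ValueError(f"annotated tissue {t!r} has no reference signature mapping")
        if ref_map[t] not in table.pvals.columns:
            raise ValueError(f"reference signature {ref_map[t]!r} absent from enrichment table")

    query_names = table.query_signatures()
    if not query_names:
        raise ValueError("enrichment table contains no query signatures")
    pq = table.pvals[query_names]

    # (i) multiple-testing adjustment over the query family
    if config.bh_family == "global":
        q_flat = bh_adjust(pq.to_numpy().ravel())
        q = pd.DataFrame(
            q_flat.reshape(pq.shape), index=pq.index, columns=pq.columns
        )
    else:
        q = pq.copy()
        for t in tissues:
            ids = tissues_by_sample.index[tissues_by_sample == t]
            block = pq.loc[ids]
            q.loc[ids] = bh_adjust(block.to_numpy().ravel()).reshape(block.shape)

    # (ii)-(iii) robust-line exclusion per (tissue, query) pair
    exclusions: list[ExclusionRecord] = []
    excluded_for: dict[str, set] = {t: set() for t in tissues}
    for t in tissues:
        ids = tissues_by_sample.index[tissues_by_sample == t]
        if len(ids) < 3:
            log.warning("tissue %s: %d samples, too few for exclusion fits", t, len(ids))
            continue
        x = _abs_log10(table.pvals.loc[ids, ref_map[t]].to_numpy())
        for k in query_names:
            y = _abs_log10(table.pvals.loc[ids, k].to_numpy())
            slope, _ = fit_robust_line(x, y)
            excluded = bool(slope >= config.slope_threshold)
            exclusions.append(ExclusionRecord(t, k, slope, len(ids), excluded))
            if excluded:
                excluded_for[t].add(k)
        evaluable = [
            k for k in query_names
            if k not in excluded_for[t] and table.sig_tissue[k] != t
        ]
        if not evaluable:
            log.warning("tissue %s: 0 evaluable query signatures after exclusion", t)

    # (iv) per-sample calls
    calls: list[HeterogeneityCall] = []
    for t in tissues:
        ids = tissues_by_sample.index[tissues_by_sample == t]
        allowed = [
            k for k in query_names
            if k not in excluded_for[t] and table.sig_tissue[k] != t
        ]
        p_ref = table.pvals.loc[ids, ref_map[t]].to_numpy()
        q_block = q.loc[ids, allowed].to_numpy() if allowed else np.empty((len(ids), 0))
        hit = q_block < config.fdr_threshold
        for i, sample in enumerate(ids):
            triggers = [
                Trigger(allowed[j], table.sig_tissue[allowed[j]], float(q_block[i, j]))
                for j in np.flatnonzero(hit[i])
            ]
            triggers.sort(key=lambda tr: tr.qvalue)
            if not triggers:
                status = STATUS_NONE
            elif p_ref[i] > config.severe_alpha:
                status = STATUS_SEVERE
            else:
                status = STATUS_MODERATE
            calls.append(HeterogeneityCall(str(sample), t, status, triggers, float(p_ref[i])))

    order = {s: i for i, s in enumerate(table.samples)}
    calls.sort(key=lambda c: order[c.sample_id])
    return calls, exclusions


def bootstrap_ci(flags, bootstrap_n: int = 1000, ci_level: float = 0.95, rng=None):
    """Percentile bootstrap CI for the mean of a binary vector."""
    flags = np.asarray(flags, dtype=float)
    if flags.size == 0:
        raise ValueError("cannot bootstrap an empty tissue")
    rng = np.random.default_rng(rng)
    idx = rng.integers(0, flags.size, size=(bootstrap_n, flags.size))
    means = flags[idx].mean(axis=1)
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(means, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def tissue_fractions(calls, config: Optional[DetectionConfig] = None):
    """Per-tissue heterogeneous fraction with percentile bootstrap CI.

    The fraction counts samples with at least one triggering signature
    (moderate or severe).  Deterministic given config.rng_seed; tissues
    are processed in sorted order.
    """
    config = config or DetectionConfig()
    rng = np.random.default_rng(config.rng_seed)
    by_tissue: dict[str, list] = {}
    for c in calls:
        by_tissue.setdefault(c.tissue, []).append(c)
    summaries = []
    for tissue in sorted(by_tissue):
        group = by_tissue[tissue]
        if not group:
            log.warning("tissue %s has 0 samples; omitted", tissue)
            continue
        flags = np.array([c.flagged for c in group], dtype=float)
        n_severe = sum(c.status == STATUS_SEVERE for c in group)
        lo, hi = bootstrap_ci(flags, config.bootstrap_n, config.ci_level, rng)
        summaries.append(
            TissueSummary(
                tissue=tissue,
                n_samples=len(group),
                n_moderate_or_severe=int(flags.sum()),
                n_severe=int(n_severe),
                fraction=float(flags.mean()),
                ci_low=lo,
                ci_high=hi,
            )
        )
    return summaries


def confusion_counts(calls, sig_tissue: Optional[dict] = None, exclusions=None):
    """Annotated-tissue x detected-signature-tissue sample counts.

    Entry (t, u) counts samples annotated t in which at least one query
    signature of tissue u triggered.  Returns (counts, excluded) frames;
    ``excluded`` marks (t, u) pairs for which one or more query
    signatures were removed by the correlation exclusion.
    """
    row_tissues = sorted({c.tissue for c in calls})
    col_pool = set()
    if sig_tissue:
        col_pool.update(sig_tissue.values())
    for c in calls:
        col_pool.update(tr.tissue for tr in c.triggers)
    col_tissues = sorted(col_pool)
    counts = pd.DataFrame(0, index=row_tissues, columns=col_tissues, dtype=int)
    for c in calls:
        for u in {tr.tissue for tr in c.triggers}:
            counts.loc[c.tissue, u] += 1
    excluded = pd.DataFrame(False, index=row_tissues, columns=col_tissues)
    if exclusions:
        if sig_tissue is None:
            raise ValueError("sig_tissue mapping required to place exclusions")
        for rec in exclusions:
            if rec.excluded and rec.tissue in excluded.index:
                u = sig_tissue.get(rec.query_signature)
                if u in excluded.columns:
                    excluded.loc[rec.tissue, u] = True
    counts.index.name = "annotated_tissue"
    counts.columns.name = "detected_tissue"
    excluded.index.name = "annotated_tissue"
    excluded.columns.name = "detected_tissue"
    return counts, excluded


# --- tabular serialization --------------------------------------------


def calls_to_frame(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "sample_id": c.sample_id,
                "tissue": c.tissue,
                "status": c.status,
                "triggering_signatures": ",".join(
                    f"{t.signature}:{t.tissue}:{t.qvalue:.3g}" for t in c.triggers
                ),
                "q_min": c.q_min,
                "p_ref": c.p_ref,
            }
        )
    return pd.DataFrame(
        rows, columns=["sample_id", "tissue", "status", "triggering_signatures", "q_min", "p_ref"]
    )


def exclusions_to_frame(exclusions) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tissue": e.tissue,
                "query_signature": e.query_signature,
                "slope": e.slope,
                "n_samples_fit": e.n_samples_fit,
                "excluded": e.excluded,
            }
            for e in exclusions
        ],
        columns=["tissue", "query_signature", "slope", "n_samples_fit", "excluded"],
    )


def summaries_to_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tissue": s.tissue,
                "n_samples": s.n_samples,
                "n_moderate_or_severe": s.n_moderate_or_severe,
                "n_severe": s.n_severe,
                "fraction": s.fraction,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
            }
            for s in summaries
        ],
        columns=[
            "tissue",
            "n_samples",
            "n_moderate_or_severe",
            "n_severe",
            "fraction",
            "ci_low",
            "ci_high",
        ],
    )
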