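"""End-to-end pipeline orchestration and human-readable reporting.

``run_pipeline`` wires the stages together -- corpus filtering, per-sample
enrichment, heterogeneity detection, per-tissue prevalence with bootstrap
CIs and the tissue confusion matrix -- and writes every result as a
plain-text table plus run metadata.  A MANIFEST records the completed
stages so partial output of a failed run remains interpretable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .corpus import filter_corpus, load_annotations, load_vocabulary
from .detect import (
    DetectionConfig,
    calls_to_frame,
    confusion_counts,
    detect,
    exclusions_to_frame,
    summaries_to_frame,
    tissue_fractions,
)
from .enrich import run_enrichment
from .matrix import ExpressionMatrix
from .signatures import ROLE_QUERY, ROLE_REFERENCE, read_gmt, write_gmt
from .simulate import (
    SimConfig,
    default_vocabulary,
    planted_signatures,
    reference_map,
    simulate_corpus,
)

log = logging.getLogger(__name__)

REPORT_INPUTS = ["summaries.tsv", "confusion.tsv", "calls.tsv", "run_metadata.json"]


@dataclass
class RunConfig:
    outdir: Path
    expression: Optional[Path] = None
    annotations: Optional[Path] = None
    vocabulary: Optional[Path] = None
    reference_tissues: Optional[Path] = None
    query_gmt: Optional[Path] = None
    reference_gmt: Optional[Path] = None
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    sim: Optional[SimConfig] = None
    min_samples_per_study: int = 1
    min_genes: int = 5
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        det = DetectionConfig(**raw.pop("detection", {}))
        sim = raw.pop("sim", None)
        sim = SimConfig(**sim) if sim is not None else None
        paths = {
            k: Path(v)
            for k, v in raw.items()
            if k
            in (
                "outdir",
                "expression",
                "annotations",
                "vocabulary",
                "reference_tissues",
                "query_gmt",
                "reference_gmt",
            )
            and v is not None
        }
        rest = {k: v for k, v in raw.items() if k not in paths}
        return cls(detection=det, sim=sim, **paths, **rest)


def _digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(rc: RunConfig) -> Path:
    """Execute filter -> enrich -> detect -> fractions -> confusion.

    Inputs come either from files (expression + annotations + vocabulary +
    GMT signatures) or from the synthetic generator when ``rc.sim`` is
    set.  Returns the output directory; raises on stage failure after
    writing a MANIFEST of the completed stages.
    """
    logging.basicConfig(level=getattr(logging, rc.log_level.upper(), logging.INFO))
    outdir = Path(rc.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    counts: dict[str, int] = {}
    t_start = time.time()

    def _manifest() -> None:
        (outdir / "MANIFEST.json").write_text(
            json.dumps({"completed_stages": completed, "stage_counts": counts}, indent=2)
            + "\n"
        )

    digests = {}
    try:
        # --- load or simulate ------------------------------------------
        if rc.sim is not None:
            expr, annotations, truth = simulate_corpus(rc.sim)
            queries, references = planted_signatures(truth)
            vocab = default_vocabulary(rc.sim.tissues)
            truth.to_tsv(outdir / "truth.tsv")
            rc.sim.to_json(outdir / "sim_config.json")
            write_gmt(queries, outdir / "query_signatures.gmt")
            write_gmt(references, outdir / "reference_signatures.gmt")
        else:
            for name in ("expression", "annotations", "vocabulary", "query_gmt", "reference_gmt"):
                p = getattr(rc, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"required input {name!r} missing: {p}")
                digests[name] = _digest(p)
            expr = ExpressionMatrix.from_tsv(rc.expression)
            annotations = load_annotations(rc.annotations)
            vocab = load_vocabulary(rc.vocabulary, rc.reference_tissues)
            queries = read_gmt(rc.query_gmt, role=ROLE_QUERY)
            references = read_gmt(rc.reference_gmt, role=ROLE_REFERENCE)
        counts["input_samples"] = expr.n_samples
        counts["input_genes"] = expr.n_genes
        completed.append("load")
        log.info("load: %d genes x %d samples", expr.n_genes, expr.n_samples)

        expr, annotations, filter_report = filter_corpus(
            expr, annotations, vocab, min_samples_per_study=rc.min_samples_per_study
        )
        filter_report.to_json(outdir / "filter_report.json")
        counts["filtered_samples"] = expr.n_samples
        completed.append("filter")
        log.info("filter: %d samples retained", expr.n_samples)

        table = run_enrichment(expr, queries + references, min_genes=rc.min_genes)
        table.to_tsv(outdir / "enrichment.tsv")
        counts["enrichment_pairs"] = table.pvals.size
        completed.append("enrich")
        log.info("enrich: %d (sample, signature) pairs", table.pvals.size)

        calls, exclusions = detect(
            table, annotations, reference_map(references), rc.detection
        )
        calls_to_frame(calls).to_csv(outdir / "calls.tsv", sep="\t", index=False)
        exclusions_to_frame(exclusions).to_csv(
            outdir / "exclusions.tsv", sep="\t", index=False
        )
        counts["flagged_samples"] = sum(c.flagged for c in calls)
        counts["severe_samples"] = sum(c.status == "severe" for c in calls)
        completed.append("detect")
        log.info(
            "detect: %d flagged (%d severe) of %d",
            counts["flagged_samples"],
            counts["severe_samples"],
            len(calls),
        )

        summaries = tissue_fractions(calls, rc.detection)
        summaries_to_frame(summaries).to_csv(outdir / "summaries.tsv", sep="\t", index=False)
        completed.append("fractions")

        conf, excl = confusion_counts(
            calls, sig_tissue={s.name: s.tissue for s in queries}, exclusions=exclusions
        )
        conf.to_csv(outdir / "confusion.tsv", sep="\t")
        excl.to_csv(outdir / "confusion_excluded.tsv", sep="\t")
        completed.append("confusion")

        meta = {
            "package_version": __version__,
            "detection_config": rc.detection.__dict__,
            "sim_config": rc.sim.__dict__ if rc.sim else None,
            "input_digests": digests,
            "stage_counts": counts,
            "seconds": round(time.time() - t_start, 2),
        }
        (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2) + "\n")
        completed.append("metadata")
    finally:
        _manifest()
    return outdir


def render_report(outdir, max_severe_listed: int = 15) -> str:
    """Render the output bundle as a markdown report; writes report.md.

    Every number shown is read back from the bundle's TSV files, so the
    report is reproducible from the bundle alone and regeneration is
    idempotent.
    """
    outdir = Path(outdir)
    missing = [f for f in REPORT_INPUTS if not (outdir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete output bundle, missing: {missing}")
    summaries = pd.read_csv(outdir / "summaries.tsv", sep="\t")
    confusion = pd.read_csv(outdir / "confusion.tsv", sep="\t", index_col=0)
    calls = pd.read_csv(outdir / "calls.tsv", sep="\t")
    meta = json.loads((outdir / "run_metadata.json").read_text())
    excl_path = outdir / "confusion_excluded.tsv"
    excluded = (
        pd.read_csv(excl_path, sep="\t", index_col=0)
        if excl_path.exists()
        else pd.DataFrame(False, index=confusion.index, columns=confusion.columns)
    )

    n = len(calls)
    n_flag = int((calls["status"] != "none").sum())
    n_severe = int((calls["status"] == "severe").sum())
    lines = [
        "# Tissue heterogeneity report",
        "",
        f"Samples analysed: {n}; heterogeneous: {n_flag} "
        f"({100 * n_flag / max(n, 1):.1f}%), of which severe: {n_severe} "
        f"({100 * n_severe / max(n, 1):.1f}%).",
        "",
        "## Fraction of heterogeneous samples per tissue",
        "",
        "| tissue | n | moderate+severe | severe | fraction | 95% CI |",
        "|---|---|---|---|---|---|",
    ]
    for _, row in summaries.iterrows():
        lines.append(
            f"| {row['tissue']} | {row['n_samples']} | {row['n_moderate_or_severe']} "
            f"| {row['n_severe']} | {row['fraction']:.3f} "
            f"| [{row['ci_low']:.3f}, {row['ci_high']:.3f}] |"
        )
    lines += ["", "## Tissue confusion matrix", ""]
    lines.append(
        "Rows: annotated tissue; columns: tissue of the detected query "
        "signature; '*' marks pairs with signatures removed by the "
        "correlation exclusion."
    )
    lines.append("")
    header = "| annotated \\ detected | " + " | ".join(confusion.columns) + " |"
    lines += [header, "|" + "---|" * (len(confusion.columns) + 1)]
    for t in confusion.index:
        cells = []
        for u in confusion.columns:
            mark = "*" if bool(excluded.loc[t, u]) else ""
            cells.append(f"{confusion.loc[t, u]}{mark}")
        lines.append(f"| {t} | " + " | ".join(cells) + " |")

    severe = calls[calls["status"] == "severe"].sort_values("q_min")
    lines += ["", "## Most severely heterogeneous samples", ""]
    if severe.empty:
        lines.append("0 severe samples detected.")
    else:
        lines += [
            "| sample | tissue | q_min | p_ref | triggering signatures |",
            "|---|---|---|---|---|",
        ]
        for _, row in severe.head(max_severe_listed).iterrows():
            lines.append(
                f"| {row['sample_id']} | {row['tissue']} | {row['q_min']:.3g} "
                f"| {row['p_ref']:.3g} | {row['triggering_signatures']} |"
            )
    lines += [
        "",
        f"_Pipeline version {meta.get('package_version', '?')}; "
        f"run took {meta.get('seconds', '?')} s._",
        "",
    ]
    text = "\n".join(lines)
    (outdir / "report.md").write_text(text)
    return text
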