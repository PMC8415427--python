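"""Heterogeneity detection: BH, robust-line exclusion, calls, fractions."""

import numpy as np
import pandas as pd
import pytest

import tissuehet as th
from tissuehet.detect import (
    STATUS_MODERATE,
    STATUS_NONE,
    STATUS_SEVERE,
    confusion_counts,
)
from tissuehet.enrich import EnrichmentTable


def bh_stepup_oracle(p):
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum(1.0, p[order] * m / np.arange(1, m + 1))
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    out = np.empty(m)
    out[order] = q_sorted
    return out


class TestBhAdjust:
    def test_single_pvalue_identity(self):
        assert th.bh_adjust([0.05]) == pytest.approx([0.05])

    def test_stepup_collapse(self):
        assert th.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.uniform(1e-8, 1.0, size=int(rng.integers(1, 100)))
            assert th.bh_adjust(p) == pytest.approx(bh_stepup_oracle(p), abs=1e-12)

    def test_dominates_input_and_preserves_order(self, rng):
        p = rng.uniform(1e-6, 1, size=50)
        q = th.bh_adjust(p)
        assert np.all(q >= p)
        # significance order preserved: q is monotone in p (ties may collapse)
        assert np.all(np.diff(q[np.argsort(p, kind="stable")]) >= -1e-15)

    @pytest.mark.parametrize("bad", [[], [0.0, 0.5], [0.5, 1.2]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            th.bh_adjust(bad)


class TestRobustLine:
    def test_noiseless_recovery(self):
        x = np.linspace(0, 10, 20)
        slope, intercept = th.fit_robust_line(x, 0.5 * x + 1.0)
        assert slope == pytest.approx(0.5, abs=1e-8)
        assert intercept == pytest.approx(1.0, abs=1e-8)

    def test_resists_gross_outliers_where_ols_fails(self, rng):
        x = rng.uniform(0, 10, size=55)
        y = 0.2 * x + rng.normal(0, 0.05, size=55)
        y[:5] += 50.0
        slope, _ = th.fit_robust_line(x, y)
        ols_slope = np.polyfit(x, y, 1)[0]
        assert abs(slope - 0.2) < 0.05
        assert abs(ols_slope - 0.2) > abs(slope - 0.2)

    def test_constant_x_gives_zero_slope(self):
        slope, intercept = th.fit_robust_line(np.full(10, 3.0), np.arange(10.0))
        assert slope == 0.0
        assert intercept == pytest.approx(4.5)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            th.fit_robust_line([1.0, 2.0], [1.0, 2.0])


def _hand_built_table(rng):
    """Two tissues x 6 samples each, p-values wired for known outcomes.

    Tissue A's reference is detected in all A samples except a5 (p_ref
    0.2); the query signature of tissue B fires in a0 (moderate: own ref
    detected) and a5 (severe: own ref missed).  Self-signatures fire
    everywhere and must never count.
    """
    samples = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
    tissue = ["A"] * 6 + ["B"] * 6
    pvals = pd.DataFrame(1.0, index=samples, columns=["A.q", "B.q", "A.ref", "B.ref"])
    pvals["A.ref"] = [1e-8, 1e-9, 1e-7, 1e-10, 1e-6, 0.2] + [0.8, 0.9, 0.7, 0.85, 0.6, 0.75]
    pvals["B.ref"] = [0.5, 0.6, 0.7, 0.8, 0.9, 0.55] + [1e-9, 1e-8, 1e-7, 1e-10, 1e-6, 1e-9]
    # self queries mirror the reference (always detected in own tissue)
    pvals["A.q"] = pvals["A.ref"].where(pd.Series(tissue, index=samples) == "A", 0.9)
    pvals["B.q"] = pvals["B.ref"].where(pd.Series(tissue, index=samples) == "B", 1.0)
    # foreign firing: B.q in a0 and a5
    pvals.loc["a0", "B.q"] = 1e-6
    pvals.loc["a5", "B.q"] = 1e-6
    # background noise values strictly in (0,1]
    noise = rng.uniform(0.3, 1.0, size=(12,))
    for i, s in enumerate(samples):
        if pvals.loc[s, "B.q"] == 1.0:
            pvals.loc[s, "B.q"] = noise[i]
    table = EnrichmentTable(
        pvals=pvals,
        sig_tissue={"A.q": "A", "B.q": "B", "A.ref": "A", "B.ref": "B"},
        sig_role={"A.q": "query", "B.q": "query", "A.ref": "reference", "B.ref": "reference"},
        n_genes_used={c: 10 for c in pvals.columns},
    )
    ann = pd.DataFrame({"sample_id": samples, "tissue": tissue})
    return table, ann


class TestDetect:
    def test_statuses_and_self_signature_suppression(self, rng):
        table, ann = _hand_built_table(rng)
        calls, exclusions = th.detect(
            table, ann, {"A": "A.ref", "B": "B.ref"}, th.DetectionConfig(fdr_threshold=0.01)
        )
        status = {c.sample_id: c.status for c in calls}
        assert status["a0"] == STATUS_MODERATE  # foreign hit, own ref detected
        assert status["a5"] == STATUS_SEVERE  # foreign hit, own ref missed
        assert all(status[f"b{i}"] == STATUS_NONE for i in range(6))
        assert all(status[f"a{i}"] == STATUS_NONE for i in (1, 2, 3, 4))
        trig = {c.sample_id: [t.signature for t in c.triggers] for c in calls}
        assert trig["a0"] == ["B.q"]
        assert all("A.q" not in t for t in trig.values())  # self never triggers
        # severe call carries its reference p-value above the alpha
        severe = [c for c in calls if c.status == STATUS_SEVERE]
        assert all(c.p_ref > 0.05 for c in severe)
        # self-pairs track the reference exactly and are excluded
        self_pairs = [e for e in exclusions if e.tissue == "A" and e.query_signature == "A.q"]
        assert self_pairs and self_pairs[0].excluded and self_pairs[0].slope >= 0.01

    def test_missing_reference_mapping_rejected(self, rng):
        table, ann = _hand_built_table(rng)
        with pytest.raises(ValueError, match="reference"):
            th.detect(table, ann, {"A": "A.ref"}, th.DetectionConfig())

    def test_invariant_to_sample_and_signature_order(self, small_enrichment, small_sim):
        ann = small_sim["annotations"]
        ref_map = th.reference_map(small_sim["refs"])
        base_calls, base_excl = th.detect(small_enrichment, ann, ref_map)

        rng = np.random.default_rng(5)
        perm_samples = rng.permutation(small_enrichment.pvals.index)
        perm_cols = rng.permutation(small_enrichment.pvals.columns)
        shuffled = EnrichmentTable(
            pvals=small_enrichment.pvals.loc[perm_samples, perm_cols],
            sig_tissue=small_enrichment.sig_tissue,
            sig_role=small_enrichment.sig_role,
            n_genes_used=small_enrichment.n_genes_used,
        )
        calls, excl = th.detect(shuffled, ann, ref_map)
        base_by_id = {c.sample_id: c for c in base_calls}
        assert len(calls) == len(base_calls)
        for c in calls:
            b = base_by_id[c.sample_id]
            assert c.status == b.status
            assert {t.signature for t in c.triggers} == {t.signature for t in b.triggers}
        assert {(e.tissue, e.query_signature, e.excluded) for e in excl} == {
            (e.tissue, e.query_signature, e.excluded) for e in base_excl
        }

    def test_severe_never_exceeds_flagged_per_tissue(self, small_enrichment, small_sim):
        calls, _ = th.detect(
            small_enrichment, small_sim["annotations"], th.reference_map(small_sim["refs"])
        )
        for s in th.tissue_fractions(calls):
            assert s.n_severe <= s.n_moderate_or_severe <= s.n_samples


class TestTissueFractions:
    def _calls(self, tissue, flags, severe=()):
        from tissuehet.detect import Trigger

        out = []
        for i, f in enumerate(flags):
            status = STATUS_NONE
            if f:
                status = STATUS_SEVERE if i in severe else STATUS_MODERATE
            out.append(
                th.HeterogeneityCall(
                    sample_id=f"{tissue}{i}",
                    tissue=tissue,
                    status=status,
                    triggers=[Trigger("x.q", "x", 1e-4)] if f else [],
                    p_ref=0.5 if status == STATUS_SEVERE else 1e-8,
                )
            )
        return out

    def test_degenerate_and_simple_fractions(self):
        calls = self._calls("liver", [False] * 50)
        (summary,) = th.tissue_fractions(calls)
        assert summary.fraction == 0.0
        assert (summary.ci_low, summary.ci_high) == (0.0, 0.0)

        calls = self._calls("liver", [True] * 10 + [False] * 90)
        (summary,) = th.tissue_fractions(calls)
        assert summary.fraction == pytest.approx(0.10)
        assert summary.ci_low <= summary.fraction <= summary.ci_high

    def test_deterministic_given_seed(self):
        calls = self._calls("liver", [True] * 20 + [False] * 80)
        a = th.tissue_fractions(calls, th.DetectionConfig(rng_seed=42))
        b = th.tissue_fractions(calls, th.DetectionConfig(rng_seed=42))
        assert (a[0].ci_low, a[0].ci_high) == (b[0].ci_low, b[0].ci_high)

    def test_bootstrap_ci_brackets_binomial_proportion(self, rng):
        flags = rng.random(400) < 0.3
        lo, hi = th.bootstrap_ci(flags, bootstrap_n=2000, ci_level=0.95, rng=rng)
        assert lo < flags.mean() < hi
        assert hi - lo < 0.12


class TestConfusion:
    def _call(self, sid, tissue, trigger_tissues):
        from tissuehet.detect import Trigger

        return th.HeterogeneityCall(
            sample_id=sid,
            tissue=tissue,
            status=STATUS_MODERATE if trigger_tissues else STATUS_NONE,
            triggers=[Trigger(f"{u}.q", u, 1e-4) for u in trigger_tissues],
            p_ref=1e-8,
        )

    def test_counts_and_multiplicity(self):
        calls = [
            self._call("s1", "liver", ["blood"]),
            self._call("s2", "liver", ["blood", "pancreas"]),
            self._call("s3", "liver", []),
            self._call("s4", "blood", []),
        ]
        counts, _ = confusion_counts(
            calls, sig_tissue={"blood.q": "blood", "pancreas.q": "pancreas"}
        )
        assert counts.loc["liver", "blood"] == 2
        assert counts.loc["liver", "pancreas"] == 1
        assert counts.loc["blood"].sum() == 0
        flagged_per_tissue = {"liver": 2, "blood": 0}
        for t, n in flagged_per_tissue.items():
            assert counts.loc[t].sum() >= n

    def test_zero_flags_preserve_exclusion_marks(self):
        calls = [self._call("s1", "liver", []), self._call("s2", "blood", [])]
        excl = [th.ExclusionRecord("liver", "blood.q", 0.5, 10, True)]
        counts, marks = confusion_counts(
            calls, sig_tissue={"blood.q": "blood"}, exclusions=excl
        )
        assert (counts.to_numpy() == 0).all()
        assert bool(marks.loc["liver", "blood"])
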