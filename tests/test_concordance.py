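import numpy as np
import pytest

from gremnet.concordance import (
    ConcordanceThresholds,
    classify_concordance,
    gene_level_accessibility,
    simple_differential,
    zscore_matrix,
)
from gremnet.types import DiffRecord, ExpressionMatrix, GremnetError


def _expr(vals, genes=None):
    vals = np.asarray(vals, dtype=float)
    genes = genes or [f"g{j}" for j in range(vals.shape[1])]
    return ExpressionMatrix(
        vals, [f"s{i}" for i in range(vals.shape[0])], genes, "lognorm"
    )


class TestSimpleDifferential:
    def test_identical_groups_zero_fold_change(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(5, 10))
        recs = simple_differential(_expr(vals), _expr(vals.copy()))
        assert all(r.log2fc == 0 for r in recs)

    def test_bh_step_up_hand_example(self):
        # means differ per gene so raw p-values land near (.01,.02,.03,.04)
        # verified instead directly against the BH formula on fixed p-values
        from statsmodels.stats.multitest import multipletests

        padj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(padj, [0.04, 0.04, 0.04, 0.04])

    def test_shifted_gene_detected(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(10, 20), scale=0.05)
        shifted = base.copy()
        shifted[:, 0] += 1.0
        recs = simple_differential(_expr(shifted), _expr(base))
        assert recs[0].padj < 0.05
        assert recs[0].log2fc == pytest.approx(1.0 / np.log(2), abs=0.1)

    def test_flat_gene_gets_p_one(self):
        a = _expr(np.column_stack([np.ones(4), np.arange(4.0)]))
        b = _expr(np.column_stack([np.ones(4), np.arange(4.0) + 0.5]))
        recs = simple_differential(a, b)
        assert recs[0].pvalue == 1.0


class TestGeneLevelAccessibility:
    def test_smallest_padj_wins(self):
        recs = [
            DiffRecord("pk1", 0.5, 0.1, 0.2),
            DiffRecord("pk2", 0.3, 0.005, 0.01),
        ]
        asg = {"pk1": ["gA"], "pk2": ["gA"]}
        out = gene_level_accessibility(recs, asg)
        assert out["gA"].feature_id == "pk2"

    def test_padj_tie_broken_by_larger_lfc(self):
        recs = [
            DiffRecord("pk1", 0.3, 0.01, 0.05),
            DiffRecord("pk2", -0.5, 0.01, 0.05),
        ]
        out = gene_level_accessibility(recs, {"pk1": ["gA"], "pk2": ["gA"]})
        assert out["gA"].feature_id == "pk2"

    def test_gene_without_peaks_absent(self):
        out = gene_level_accessibility([DiffRecord("pk1", 0.1, 0.5, 0.6)],
                                       {"pk1": ["gA"]})
        assert "gB" not in out


def brute_force_states(rec, alpha, lfc):
    """Independent re-statement of the significance filter."""
    if rec.padj is None:
        return "ns"
    if rec.padj <= alpha and rec.log2fc >= lfc:
        return "up"
    if rec.padj <= alpha and rec.log2fc <= -lfc:
        return "down"
    return "ns"


LABEL = {
    ("up", "up"): "concordant_up",
    ("down", "down"): "concordant_down",
    ("up", "down"): "discordant",
    ("down", "up"): "discordant",
    ("up", "ns"): "expression_only",
    ("down", "ns"): "expression_only",
    ("ns", "up"): "accessibility_only",
    ("ns", "down"): "accessibility_only",
    ("ns", "ns"): "neither",
}


class TestClassify:
    def test_concordant_up_example(self):
        rna = [DiffRecord("gA", 0.5, 0.001, 0.01)]
        atac = {"gA": DiffRecord("pk1", 0.2, 0.001, 0.01)}
        (rec,) = classify_concordance(rna, atac)
        assert rec.label == "concordant_up"
        assert rec.best_peak_id == "pk1"

    def test_thresholds_are_inclusive(self):
        rna = [DiffRecord("gA", 0.25, 0.01, 0.05)]  # exactly at both cuts
        (rec,) = classify_concordance(rna, {})
        assert rec.rna_state == "up"

    def test_discordant_directions(self):
        rna = [DiffRecord("gA", -0.5, 0.001, 0.01)]
        atac = {"gA": DiffRecord("pk1", 0.15, 0.001, 0.01)}
        (rec,) = classify_concordance(rna, atac)
        assert rec.label == "discordant"

    def test_missing_padj_is_never_significant(self):
        rna = [DiffRecord("gA", 5.0, 0.0001, None)]
        (rec,) = classify_concordance(rna, {})
        assert rec.rna_state == "ns"
        assert rec.label == "neither"

    def test_duplicate_gene_rejected(self):
        rna = [DiffRecord("gA", 1.0, 0.01, 0.01), DiffRecord("gA", 1.0, 0.01, 0.01)]
        with pytest.raises(GremnetError):
            classify_concordance(rna, {})

    def test_matches_brute_force_on_random_records(self):
        """1000 random records, including values pinned exactly at the
        significance boundaries, agree with an independent filter."""
        rng = np.random.default_rng(123)
        t = ConcordanceThresholds()
        boundary_p = [0.05, 0.049999, 0.050001, None]
        boundary_fc_rna = [0.25, -0.25, 0.2499, -0.2501]
        boundary_fc_atac = [0.1, -0.1, 0.0999, -0.1001]
        rna, atac = [], {}
        for i in range(1000):
            g = f"g{i}"
            if i % 5 == 0:
                padj = boundary_p[i // 5 % 4]
                lfc = boundary_fc_rna[i // 20 % 4]
            else:
                padj = float(rng.random())
                lfc = float(rng.normal())
            rna.append(DiffRecord(g, lfc, min(padj or 0.5, 1.0), padj))
            if i % 3 != 0:
                if i % 10 == 0:
                    apadj = boundary_p[i // 10 % 4]
                    alfc = boundary_fc_atac[i // 30 % 4]
                else:
                    apadj = float(rng.random())
                    alfc = float(rng.normal())
                atac[g] = DiffRecord(f"pk{i}", alfc, min(apadj or 0.5, 1.0), apadj)
        out = classify_concordance(rna, atac, t)
        assert len(out) == len(rna)
        counts = {}
        for rec, rrec in zip(out, rna):
            rs = brute_force_states(rrec, t.rna_alpha, t.rna_lfc)
            arec = atac.get(rrec.feature_id)
            as_ = (brute_force_states(arec, t.atac_alpha, t.atac_lfc)
                   if arec else "ns")
            assert rec.rna_state == rs
            assert rec.atac_state == as_
            assert rec.label == LABEL[(rs, as_)]
            counts[rec.label] = counts.get(rec.label, 0) + 1
        assert sum(counts.values()) == 1000  # labels partition the gene set

    def test_raising_lfc_threshold_is_monotone(self):
        rng = np.random.default_rng(9)
        rna = [DiffRecord(f"g{i}", float(rng.normal()), 0.01, 0.01)
               for i in range(200)]
        lo = classify_concordance(rna, {}, ConcordanceThresholds(rna_lfc=0.1))
        hi = classify_concordance(rna, {}, ConcordanceThresholds(rna_lfc=0.5))
        for a, b in zip(lo, hi):
            if a.rna_state == "ns":
                assert b.rna_state == "ns"


class TestZscore:
    def test_hand_example(self):
        x = _expr(np.array([[1.0], [2.0], [3.0]]))
        z, flagged = zscore_matrix(x)
        np.testing.assert_allclose(z[:, 0], [-1.0, 0.0, 1.0])
        assert flagged == []

    def test_constant_gene_flagged_and_zeroed(self):
        x = _expr(np.array([[5.0, 1.0], [5.0, 2.0]]))
        z, flagged = zscore_matrix(x)
        assert flagged == ["g0"]
        assert np.all(z[:, 0] == 0)

    def test_rows_standardized(self):
        rng = np.random.default_rng(2)
        x = _expr(rng.normal(size=(20, 6)))
        z, _ = zscore_matrix(x)
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)
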