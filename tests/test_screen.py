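import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as scipy_stats
from statsmodels.stats.multitest import fdrcorrection

from cernascreen import (
    DEGeneRecord,
    DegenerateInputError,
    ExpressionMatrix,
    ScreenConfig,
    correlate_pairs,
    de_filter,
    filter_expressed,
    pearson,
    screen_triplets,
    simulate_study_sequences,
    targets_table,
)
from cernascreen.screen import _bh_adjust
from helpers import brute_force_pearson


def matrix(values, genes, samples, scale="linear"):
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale=scale)


class TestPearson:
    def test_exact_linearity(self):
        result = pearson([1, 2, 3], [2, 4, 6])
        assert result.r == 1.0
        assert result.pvalue > 0  # smallest positive double, never zero

    def test_exact_antilinearity(self):
        assert pearson([1, 2, 3], [3, 2, 1]).r == -1.0

    def test_hand_worked_example(self):
        result = pearson([1, 2, 3, 4], [1, 3, 2, 4])
        assert result.r == pytest.approx(0.8, abs=1e-12)
        assert result.t == pytest.approx(0.8 * np.sqrt(2 / 0.36), abs=1e-12)
        assert result.n == 4

    def test_matches_scipy_and_textbook_formula(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 100))
            x, y = rng.normal(size=n), rng.normal(size=n)
            result = pearson(x, y)
            r_ref, p_ref = scipy_stats.pearsonr(x, y)
            r_bf, t_bf = brute_force_pearson(list(x), list(y))
            assert result.r == pytest.approx(r_ref, abs=1e-12)
            assert result.pvalue == pytest.approx(p_ref, rel=1e-9)
            assert result.r == pytest.approx(r_bf, abs=1e-12)
            assert result.t == pytest.approx(t_bf, abs=1e-9)

    @given(
        st.lists(st.floats(-50, 50), min_size=5, max_size=20),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    @settings(max_examples=60, derandomize=True)
    def test_symmetry_and_affine_invariance(self, values, scale_factor, offset):
        rng = np.random.default_rng(7)
        x = np.asarray(values)
        y = rng.normal(size=len(values))
        if np.var(x) == 0 or np.var(y) == 0:
            return
        base = pearson(x, y)
        assert pearson(y, x).r == pytest.approx(base.r, abs=1e-12)
        scaled = pearson(scale_factor * x + offset, y)
        assert scaled.r == pytest.approx(base.r, abs=1e-9)
        flipped = pearson(-scale_factor * x + offset, y)
        assert flipped.r == pytest.approx(-base.r, abs=1e-9)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateInputError, match="zero variance"):
            pearson([1, 1, 1], [1, 2, 3])
        with pytest.raises(DegenerateInputError, match="at least 3"):
            pearson([1, 2], [3, 4])


class TestCorrelatePairs:
    def test_self_pair_on_identical_matrices(self, rng):
        m = matrix(rng.lognormal(size=(2, 10)), ["g1", "g2"], [f"s{i}" for i in range(10)])
        results, skipped = correlate_pairs(m, m, [("g1", "g1")])
        assert skipped == []
        assert results[0].r == pytest.approx(1.0)

    def test_disjoint_samples_error(self, rng):
        a = matrix(rng.lognormal(size=(1, 4)), ["g"], ["s1", "s2", "s3", "s4"])
        b = matrix(rng.lognormal(size=(1, 4)), ["g"], ["t1", "t2", "t3", "t4"])
        with pytest.raises(DegenerateInputError, match="no sample"):
            correlate_pairs(a, b, [("g", "g")])

    def test_composition_equals_elementwise_pearson(self, rng):
        samples = [f"s{i}" for i in range(30)]
        a = matrix(rng.lognormal(size=(5, 30)), [f"a{i}" for i in range(5)], samples)
        b = matrix(rng.lognormal(size=(4, 30)), [f"b{i}" for i in range(4)], samples)
        pairs = [(f"a{i % 5}", f"b{i % 4}") for i in range(20)]
        results, _ = correlate_pairs(a, b, pairs)
        log_a = np.log2(a.data + 1)
        log_b = np.log2(b.data + 1)
        for (id_a, id_b), res in zip(pairs, results):
            expected = pearson(log_a.loc[id_a], log_b.loc[id_b])
            assert res.r == pytest.approx(expected.r, abs=1e-14)
            assert res.pvalue == pytest.approx(expected.pvalue, abs=1e-14)

    def test_degenerate_pair_reported_not_dropped(self, rng):
        samples = [f"s{i}" for i in range(6)]
        a = matrix([[0, 0, 0, 0, 0, 0], list(range(6))], ["flat", "ok"], samples)
        results, skipped = correlate_pairs(a, a, [("flat", "ok"), ("ok", "ok")])
        assert skipped == [("flat", "ok")]
        assert len(results) == 1


class TestFilterExpressed:
    def test_all_zero_gene_removed(self):
        m = matrix([[0, 0, 0], [1, 2, 3]], ["zero", "on"], ["s1", "s2", "s3"])
        assert filter_expressed(m, 0.1).gene_ids == ["on"]

    def test_zero_fraction_is_identity(self):
        m = matrix([[0, 0, 0], [1, 2, 3]], ["zero", "on"], ["s1", "s2", "s3"])
        assert filter_expressed(m, 0.0).gene_ids == ["zero", "on"]

    def test_half_fraction_boundary_at_58_samples(self, rng):
        values = np.zeros((2, 58))
        values[0, :29] = 1.0  # nonzero in 29/58 = 0.5 -> kept
        values[1, :28] = 1.0  # nonzero in 28/58 < 0.5 -> removed
        m = matrix(values, ["kept", "removed"], [f"s{i}" for i in range(58)])
        assert filter_expressed(m, 0.5).gene_ids == ["kept"]


class TestDeFilter:
    @pytest.mark.parametrize(
        "log2fc,pvalue,expected",
        [
            (1.5, 0.01, "up"),
            (-1.2, 0.001, "down"),
            (1.0, 0.01, None),  # strict |log2FC| > 1
            (-1.0, 0.01, None),
            (1.5, 0.05, None),  # strict p < 0.05
            (0.5, 0.001, None),
            (3.0, 0.049, "up"),
        ],
    )
    def test_strict_threshold_boundaries(self, log2fc, pvalue, expected):
        up, down = de_filter([DEGeneRecord("g", log2fc, pvalue)])
        observed = "up" if up else "down" if down else None
        assert observed == expected


class TestBHAdjustment:
    def test_matches_statsmodels(self, rng):
        pvals = rng.uniform(size=200)
        adjusted = _bh_adjust(pvals)
        _, expected = fdrcorrection(pvals, method="indep")
        np.testing.assert_allclose(adjusted, expected, atol=1e-12)


class TestScreenTriplets:
    def test_empty_target_list_yields_no_triplets(self, planted_dataset):
        _, lnc, mir, mrna, _ = planted_dataset
        from cernascreen import universal_target_support

        support = universal_target_support(mir.gene_ids, mrna.gene_ids)
        assert screen_triplets(lnc, mir, mrna, [], support) == []

    def test_planted_triplet_recovered_with_sequence_evidence(self, planted_dataset):
        config, lnc, mir, mrna, truth = planted_dataset
        mirnas, transcripts = simulate_study_sequences(config)
        matches = targets_table(mirnas, transcripts)
        lnc_genes, mrna_genes = set(lnc.gene_ids), set(mrna.gene_ids)
        triplets = screen_triplets(
            lnc,
            mir,
            mrna,
            [m for m in matches if m.transcript_id in lnc_genes],
            [m for m in matches if m.transcript_id in mrna_genes],
        )
        found = {(t.lncrna_id, t.mirna_id, t.mrna_id) for t in triplets}
        assert tuple(truth.planted[0]) in found
        # sign postcondition on everything returned
        for t in triplets:
            assert t.edge_lnc_mir.r < 0
            assert t.edge_mir_mrna.r < 0
            assert t.edge_lnc_mrna.r > 0
            assert max(t.edge_lnc_mir.pvalue, t.edge_mir_mrna.pvalue, t.edge_lnc_mrna.pvalue) < 0.05
        # deterministic, sorted by |r(lnc, mrna)| descending
        again = screen_triplets(
            lnc,
            mir,
            mrna,
            [m for m in matches if m.transcript_id in lnc_genes],
            [m for m in matches if m.transcript_id in mrna_genes],
        )
        assert again == triplets
        strengths = [abs(t.edge_lnc_mrna.r) for t in triplets]
        assert strengths == sorted(strengths, reverse=True)

    def test_shrinking_alpha_never_adds_triplets(self, planted_dataset):
        config, lnc, mir, mrna, _ = planted_dataset
        mirnas, transcripts = simulate_study_sequences(config)
        matches = targets_table(mirnas, transcripts)
        lnc_genes, mrna_genes = set(lnc.gene_ids), set(mrna.gene_ids)
        lnc_t = [m for m in matches if m.transcript_id in lnc_genes]
        mrna_t = [m for m in matches if m.transcript_id in mrna_genes]
        loose = screen_triplets(lnc, mir, mrna, lnc_t, mrna_t, config=ScreenConfig(alpha=0.05))
        tight = screen_triplets(lnc, mir, mrna, lnc_t, mrna_t, config=ScreenConfig(alpha=0.005))
        loose_ids = {(t.lncrna_id, t.mirna_id, t.mrna_id) for t in loose}
        tight_ids = {(t.lncrna_id, t.mirna_id, t.mrna_id) for t in tight}
        assert tight_ids <= loose_ids

    def test_candidate_panel_restricts_but_never_adds(self, planted_dataset):
        config, lnc, mir, mrna, truth = planted_dataset
        mirnas, transcripts = simulate_study_sequences(config)
        matches = targets_table(mirnas, transcripts)
        lnc_genes, mrna_genes = set(lnc.gene_ids), set(mrna.gene_ids)
        lnc_t = [m for m in matches if m.transcript_id in lnc_genes]
        mrna_t = [m for m in matches if m.transcript_id in mrna_genes]
        full = screen_triplets(lnc, mir, mrna, lnc_t, mrna_t)
        panel = {truth.planted[0][2]}
        restricted = screen_triplets(lnc, mir, mrna, lnc_t, mrna_t, candidate_mrnas=panel)
        restricted_ids = {(t.lncrna_id, t.mirna_id, t.mrna_id) for t in restricted}
        full_ids = {(t.lncrna_id, t.mirna_id, t.mrna_id) for t in full}
        assert restricted_ids <= full_ids
        assert all(t.mrna_id in panel for t in restricted)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ScreenConfig(alpha=0.0)
        with pytest.raises(ValueError):
            ScreenConfig(expression_fraction=1.5)
        with pytest.raises(ValueError):
            ScreenConfig(site_types=("5mer",))
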