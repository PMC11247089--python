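from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from circaclock import (
    CohortConfig,
    SelectionThresholds,
    TumorConfig,
    apply_tumor,
    ccm,
    correlate_to_reference,
    cosine_similarity,
    dphi_rs_curve,
    generate_cohort,
    rs_consistency,
    select_phase_groups,
    spearman,
)
from circaclock.corrselect import PhaseGroupSelector
from conftest import brute_force_spearman


class TestSpearman:
    def test_monotone_vectors(self):
        assert spearman([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_quadrature_sinusoids_match_oracle(self):
        t = np.arange(24.0)
        x = np.sin(2 * np.pi * t / 24.0)
        y = np.cos(2 * np.pi * t / 24.0)
        rs = spearman(x, y)
        assert rs == pytest.approx(brute_force_spearman(x, y), abs=1e-12)
        assert abs(rs) < 0.1

    def test_zero_rank_variance_flagged_nan(self):
        assert np.isnan(spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    @given(st.lists(st.integers(-70000, 70000), min_size=3, max_size=8,
                    unique=True),
           st.integers(0, 1000))
    @settings(max_examples=60, deadline=None)
    def test_matches_oracle_and_monotone_invariance(self, xs, seed):
        """r_S equals the brute-force rank oracle on small distinct-valued
        vectors, is symmetric, and is invariant to strictly monotone
        transforms of either argument.  Values are kept well separated so
        the exp transform stays injective in float arithmetic."""
        rng = np.random.default_rng(seed)
        x = np.array(xs, dtype=float) / 700.0
        y = rng.permutation(x)
        rs = spearman(x, y)
        assert rs == pytest.approx(brute_force_spearman(x, y), abs=1e-12)
        assert spearman(y, x) == pytest.approx(rs, abs=1e-12)
        assert spearman(np.exp(x / 100.0), y) == pytest.approx(rs, abs=1e-12)


class TestCorrelateToReference:
    def test_reference_excluded_and_antiphase_is_minus_one(self, noiseless_cohort):
        matrix, truth = noiseless_cohort
        rs = correlate_to_reference(matrix, "PER3")
        assert "PER3" not in rs.index
        anti = truth.genes.index[truth.genes.group == "12h"]
        assert np.allclose(rs[anti], -1.0, atol=0.01)

    def test_quadrature_low_correlation(self, noiseless_cohort):
        matrix, truth = noiseless_cohort
        rs = correlate_to_reference(matrix, "PER3")
        quad = truth.genes.index[truth.genes.group.isin(["+6h", "-6h"])]
        assert (rs[quad].abs() < 0.15).all()

    def test_values_match_pairwise_oracle(self, noisy_cohort):
        matrix, _ = noisy_cohort
        rs = correlate_to_reference(matrix, "PER3")
        ref = matrix.values.loc["PER3"].to_numpy()
        for gene in list(rs.index)[:10]:
            assert rs[gene] == pytest.approx(
                brute_force_spearman(ref, matrix.values.loc[gene].to_numpy()),
                abs=1e-12)

    def test_missing_reference_lists_near_matches(self, noiseless_cohort):
        matrix, _ = noiseless_cohort
        with pytest.raises(KeyError, match="PER3"):
            correlate_to_reference(matrix, "per3")


class TestSelectPhaseGroups:
    def test_noiseless_planted_groups_recovered_exactly(self):
        cfg = CohortConfig(n_genes_per_group={"0h": 20, "12h": 20, "+6h": 5, "-6h": 5},
                           n_background=0, n_samples=24, noise_sd=0.0,
                           phase_jitter_sd_h=0.0, seed=5)
        matrix, truth = generate_cohort(cfg)
        lst = select_phase_groups(matrix, "PER3", "ARNTL",
                                  thresholds=SelectionThresholds(k_top=19, k_bottom=20))
        assert set(lst.group("IN_PHASE")) == set(truth.genes.index[truth.genes.group == "0h"])
        assert set(lst.group("ANTI_PHASE")) == set(truth.genes.index[truth.genes.group == "12h"])
        assert set(lst.group("QUADRATURE")) == set(
            truth.genes.index[truth.genes.group.isin(["+6h", "-6h"])])

    def test_gene_outside_band_not_in_quadrature(self, noisy_cohort):
        matrix, _ = noisy_cohort
        lst = select_phase_groups(matrix, "PER3", "ARNTL",
                                  thresholds=SelectionThresholds(k_top=10, k_bottom=10))
        rs = correlate_to_reference(matrix, "PER3")
        for gene in lst.group("QUADRATURE"):
            assert -0.4 < rs[gene] < 0.4

    def test_background_excluded_by_r2_filter(self, noisy_cohort):
        matrix, _ = noisy_cohort
        lst = select_phase_groups(matrix, "PER3", "ARNTL",
                                  thresholds=SelectionThresholds(k_top=10, k_bottom=10))
        assert not any(g.startswith("BG_") for g in lst.group("QUADRATURE"))

    def test_too_few_genes_error(self, noiseless_cohort):
        matrix, _ = noiseless_cohort
        with pytest.raises(ValueError, match="too few"):
            select_phase_groups(matrix, "PER3", "ARNTL",
                                thresholds=SelectionThresholds(k_top=100, k_bottom=100))

    def test_recovery_rate_under_noise(self):
        """Rank selection recovers in/anti-phase groups nearly perfectly and
        most of the quadrature group at moderate noise (qualitative check;
        low-amplitude quadrature genes legitimately fail the R^2 filter)."""
        rec_in, rec_anti, rec_quad = [], [], []
        for seed in range(5):
            cfg = CohortConfig(n_genes_per_group=25, n_background=150, n_samples=24,
                               noise_sd=0.25, phase_jitter_sd_h=0.5, seed=seed)
            matrix, truth = generate_cohort(cfg)
            lst = select_phase_groups(matrix, "PER3", "ARNTL",
                                      thresholds=SelectionThresholds(k_top=25, k_bottom=25))
            for rec, groups, sel in (
                (rec_in, ["0h"], lst.group("IN_PHASE")),
                (rec_anti, ["12h"], lst.group("ANTI_PHASE")),
                (rec_quad, ["+6h", "-6h"], lst.group("QUADRATURE")),
            ):
                planted = set(truth.genes.index[truth.genes.group.isin(groups)])
                rec.append(len(planted & set(sel)) / len(planted))
        assert np.mean(rec_in) > 0.95
        assert np.mean(rec_anti) > 0.95
        assert np.mean(rec_quad) > 0.75

    def test_sklearn_selector_transform(self, noiseless_cohort):
        matrix, _ = noiseless_cohort
        X = matrix.values.T
        sel = PhaseGroupSelector(k_top=4, k_bottom=4).fit(X, matrix.sample_times_h)
        reduced = sel.transform(X)
        assert set(reduced.columns) == set(sel.gene_list_.genes)
        assert sel.get_support().sum() == reduced.shape[1]


class TestCCM:
    def test_antiphase_pair_off_diagonal_minus_one(self, noiseless_cohort):
        matrix, _ = noiseless_cohort
        cm = ccm(matrix, ["PER3", "ARNTL"])
        assert cm.values.loc["PER3", "ARNTL"] == pytest.approx(-1.0, abs=0.01)
        assert (np.diag(cm.values) == 1.0).all()

    def test_gene_order_permutation_permutes_consistently(self, noiseless_cohort):
        matrix, _ = noiseless_cohort
        genes = ["PER3", "ARNTL", "RORC", "TEF"]
        cm1 = ccm(matrix, genes)
        cm2 = ccm(matrix, genes[::-1])
        pd.testing.assert_frame_equal(
            cm1.values, cm2.values.loc[genes, genes], rtol=1e-12)

    def test_entrywise_oracle_recomputation(self, noisy_cohort):
        matrix, _ = noisy_cohort
        genes = ["PER3", "ARNTL", "RORC", "TEF", "G0H_002"]
        cm = ccm(matrix, genes)
        for gi in genes:
            for gj in genes:
                expected = 1.0 if gi == gj else brute_force_spearman(
                    matrix.values.loc[gi], matrix.values.loc[gj])
                assert cm.values.loc[gi, gj] == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_range(self, noisy_cohort):
        matrix, _ = noisy_cohort
        cm = ccm(matrix, matrix.genes[:20])
        v = cm.values.to_numpy()
        np.testing.assert_allclose(v, v.T, atol=1e-12)
        assert (v >= -1 - 1e-12).all() and (v <= 1 + 1e-12).all()

    def test_fewer_than_two_genes_error(self, noiseless_cohort):
        matrix, _ = noiseless_cohort
        with pytest.raises(ValueError, match="fewer than 2"):
            ccm(matrix, ["PER3", "NOT_A_GENE"])


class TestCosineSimilarity:
    def test_self_similarity_is_one(self, noisy_cohort):
        matrix, _ = noisy_cohort
        cm = ccm(matrix, matrix.genes[:15])
        assert cosine_similarity(cm, cm) == pytest.approx(1.0, abs=1e-12)

    def test_sign_flip_gives_minus_one(self, noisy_cohort):
        matrix, _ = noisy_cohort
        cm = ccm(matrix, matrix.genes[:10])
        flipped = replace(cm, values=-cm.values)
        np.fill_diagonal(flipped.values.values, 1.0)
        assert cosine_similarity(cm, flipped) == pytest.approx(-1.0, abs=1e-12)

    def test_missing_genes_ignored(self, noisy_cohort):
        matrix, _ = noisy_cohort
        full = ccm(matrix, ["PER3", "ARNTL", "RORC", "TEF", "ABSENT"])
        partial = ccm(matrix, ["PER3", "ARNTL", "RORC", "TEF"])
        assert cosine_similarity(full, partial) == pytest.approx(1.0, abs=1e-12)

    def test_insufficient_overlap_error(self, noisy_cohort):
        matrix, _ = noisy_cohort
        a = ccm(matrix, ["PER3", "ARNTL", "RORC"])
        b = ccm(matrix, ["PER3", "ARNTL", "G0H_002"])
        with pytest.raises(ValueError, match="shared"):
            cosine_similarity(a, b)

    def test_replicate_cohorts_highly_similar(self):
        cfg = CohortConfig(n_genes_per_group=15, n_background=0, n_samples=24,
                           noise_sd=0.2, phase_jitter_sd_h=0.0, seed=1)
        m1, _ = generate_cohort(cfg)
        m2, _ = generate_cohort(replace(cfg, seed=2))
        genes = m1.genes
        assert cosine_similarity(ccm(m1, genes), ccm(m2, genes)) > 0.9


class TestDphiRsCurve:
    def test_endpoints_exact(self):
        curve = dphi_rs_curve(24, 1, [0.0, 12.0, -12.0])
        rs = dict(zip(curve.dphi_h, curve.rs))
        assert rs[0.0] == 1.0
        assert rs[12.0] == -1.0
        assert rs[-12.0] == -1.0

    def test_quadrature_matches_oracle(self):
        t = np.arange(24.0)
        x = np.round(np.cos(2 * np.pi * t / 24.0), 12)
        y = np.round(np.cos(2 * np.pi * (t - 6.0) / 24.0), 12)
        curve = dphi_rs_curve(24, 1, [6.0])
        assert curve.rs.iloc[0] == pytest.approx(brute_force_spearman(x, y), abs=1e-12)
        assert abs(curve.rs.iloc[0]) < 0.1

    def test_even_and_monotone_with_zero_crossing(self):
        grid = np.arange(-12.0, 12.5, 0.5)
        curve = dphi_rs_curve(24, 1, grid).set_index("dphi_h")["rs"]
        for d in np.arange(0.5, 12.5, 0.5):
            assert curve[d] == pytest.approx(curve[-d], abs=1e-12)
        pos = curve[curve.index >= 0]
        assert (np.diff(pos.to_numpy()) <= 1e-12).all()
        assert curve[5.0] > 0 > curve[7.0]


class TestRsConsistency:
    def test_equal_values_conserved(self):
        snap = pd.Series({"PER3": 0.5})
        ref = pd.DataFrame({"gene": ["PER3", "PER3"], "rs": [0.45, 0.55]})
        rep = rs_consistency(snap, ref)
        assert rep.loc["PER3", "abs_diff"] == pytest.approx(0.0)
        assert bool(rep.loc["PER3", "conserved"])

    def test_large_shift_flagged_altered(self):
        rep = rs_consistency(pd.Series({"RORC": 0.2}),
                             pd.DataFrame({"gene": ["RORC"], "rs": [-0.4]}),
                             tolerance=0.25)
        assert not bool(rep.loc["RORC", "conserved"])

    def test_empty_overlap_empty_report(self):
        rep = rs_consistency(pd.Series(dtype=float), pd.DataFrame(columns=["gene", "rs"]))
        assert rep.empty

    def test_tumor_transformed_genes_flagged(self):
        """Damping only the anti-phase genes in a noisy tumor cohort pushes
        their r_S to the reference toward zero, flagging them altered, while
        untouched in-phase correlations stay conserved (majority over seeds)."""
        altered_votes, conserved_votes = [], []
        for seed in range(10):
            cfg = CohortConfig(n_genes_per_group=10, n_background=0, n_samples=24,
                               noise_sd=0.2, phase_jitter_sd_h=0.0, seed=seed)
            m, truth = generate_cohort(cfg)
            anti_genes = list(truth.genes.index[truth.genes.group == "12h"])
            tm, _ = apply_tumor(m, truth, TumorConfig(
                amplitude_factor=0.2, damped_genes=anti_genes,
                sample_phase_jitter_sd_h=0.0, seed=seed + 50))
            ref_rows = []
            rs_norm = correlate_to_reference(m, "PER3")
            for g in rs_norm.index:
                ref_rows.append({"gene": g, "rs": rs_norm[g]})
            rs_tum = correlate_to_reference(tm, "PER3")
            rep = rs_consistency(rs_tum, pd.DataFrame(ref_rows))
            anti = truth.genes.index[truth.genes.group == "12h"]
            inph = [g for g in truth.genes.index[truth.genes.group == "0h"] if g != "PER3"]
            altered_votes.append((~rep.loc[anti, "conserved"]).mean())
            conserved_votes.append(rep.loc[inph, "conserved"].mean())
        assert np.mean(altered_votes) > 0.5
        assert np.mean(conserved_votes) > 0.5
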