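import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosphopipe.kinase import (
    KinaseEnrichmentModel,
    KinaseSpec,
    KSRelation,
    calibrate_cutoff,
    family_summary,
    fisher_enrich,
    load_substitution_matrix,
    predict_substrates,
    score_site,
    score_windows,
    shuffle_flanks,
    window_similarity,
)
from phosphopipe.preprocess import preprocess_experiment
from phosphopipe.diffstats import SiteDifferentialModel

from conftest import make_site
from oracles import fisher_greater_oracle

B62 = load_substitution_matrix("BLOSUM62")
ALL_A = "AAAAAAASAAAAAAA".replace("S", "A")  # plain 15-mer of alanines
WIN = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY_", min_size=15, max_size=15)


class TestWindowSimilarity:
    def test_identical_alanine_windows_score_15x_saa(self):
        # BLOSUM62 s(A,A) = 4, read from the published matrix
        from Bio.Align import substitution_matrices

        saa = substitution_matrices.load("BLOSUM62")["A", "A"]
        assert saa == 4
        assert window_similarity(ALL_A, ALL_A, B62) == 15 * saa

    def test_padded_positions_contribute_zero(self):
        w1 = "___AAAASAAAA___"
        w2 = "___AAAASAAAA___"
        w3 = "CCCAAAASAAAAWWW"  # differs only at w1's padded positions
        assert window_similarity(w1, w2, B62) == window_similarity(w1, w3, B62)

    @settings(derandomize=True, max_examples=50)
    @given(WIN, WIN)
    def test_symmetry(self, w1, w2):
        assert window_similarity(w1, w2, B62) == window_similarity(w2, w1, B62)

    def test_invalid_character_is_error(self):
        with pytest.raises(ValueError, match="alphabet"):
            window_similarity("B" * 15, ALL_A, B62)

    def test_wrong_length_is_error(self):
        with pytest.raises(ValueError, match="length"):
            window_similarity("A" * 14, ALL_A, B62)


class TestScoreSite:
    def test_single_identical_reference_gives_self_similarity(self):
        w = "LMRKRASTSDFGHIK"[:7] + "S" + "DFGHIKL"
        k = KinaseSpec("K", "CAMK", [w])
        assert score_site(w, k, B62) == window_similarity(w, w, B62)

    def test_two_references_give_arithmetic_mean(self):
        q = "A" * 7 + "S" + "A" * 7
        r1 = "C" * 7 + "S" + "C" * 7
        r2 = "D" * 7 + "T" + "D" * 7
        k = KinaseSpec("K", "CMGC", [r1, r2])
        expected = (window_similarity(q, r1, B62) + window_similarity(q, r2, B62)) / 2
        assert score_site(q, k, B62) == pytest.approx(expected, abs=1e-12)

    def test_all_padding_query_scores_zero(self):
        k = KinaseSpec("K", "CAMK", ["A" * 7 + "S" + "A" * 7])
        assert score_site("_" * 15, k, B62) == 0.0

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError, match="no reference"):
            KinaseSpec("K", "CAMK", [])


class TestCalibrateCutoff:
    def _background(self, n, seed=0):
        rng = np.random.default_rng(seed)
        base = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 15)) for _ in range(50)]
        base = [w[:7] + "S" + w[8:] for w in base]
        return shuffle_flanks(base, n, rng)

    def test_tiny_fpr_exceeds_all_background(self):
        k = KinaseSpec("K", "CAMK", ["A" * 7 + "S" + "A" * 7])
        bg = self._background(40)
        cutoff = calibrate_cutoff(k, bg, fpr=0.01, substitution_matrix=B62)  # < 1/n
        assert all(s < cutoff for s in score_windows(bg, k.reference_windows, B62))

    def test_fpr_one_admits_all_background(self):
        k = KinaseSpec("K", "CAMK", ["A" * 7 + "S" + "A" * 7])
        bg = self._background(40)
        cutoff = calibrate_cutoff(k, bg, fpr=1.0, substitution_matrix=B62)
        scores = score_windows(bg, k.reference_windows, B62)
        assert cutoff <= scores.min()

    def test_quantile_bound_on_1000_windows(self):
        """At fpr=0.02, at most 20 of 1000 background windows reach the cutoff."""
        k = KinaseSpec("K", "CAMK", ["LMRKRAS" + "S" + "DFGHIKL"])
        bg = self._background(1000, seed=3)
        cutoff = calibrate_cutoff(k, bg, fpr=0.02, substitution_matrix=B62)
        scores = score_windows(bg, k.reference_windows, B62)
        assert np.sum(scores >= cutoff) <= 20

    def test_heldout_background_fpr_within_binomial_tolerance(self):
        """Cutoff generalises: held-out background FPR <= fpr + 3 binomial SDs."""
        k = KinaseSpec("K", "CAMK", ["LMRKRAS" + "S" + "DFGHIKL"])
        cutoff = calibrate_cutoff(k, self._background(1000, seed=5), 0.02, B62)
        held = self._background(1000, seed=6)
        fpr_emp = np.mean(score_windows(held, k.reference_windows, B62) >= cutoff)
        assert fpr_emp <= 0.02 + 3 * np.sqrt(0.02 * 0.98 / 1000)

    def test_empty_background_is_error(self):
        k = KinaseSpec("K", "CAMK", ["A" * 7 + "S" + "A" * 7])
        with pytest.raises(ValueError, match="background"):
            calibrate_cutoff(k, [], 0.02, B62)


class TestPredictSubstrates:
    def test_uncalibrated_kinase_is_error(self):
        k = KinaseSpec("K", "CAMK", ["A" * 7 + "S" + "A" * 7])
        with pytest.raises(ValueError, match="cutoff"):
            predict_substrates([make_site()], [k], B62)

    def test_residue_class_gate(self):
        k = KinaseSpec("K", "TK", ["F" * 7 + "Y" + "F" * 7], cutoff=-1e9)
        s_site = make_site("P1", 1, "S", 0.9, "F" * 7 + "S" + "F" * 7)
        y_site = make_site("P2", 1, "Y", 0.9, "F" * 7 + "Y" + "F" * 7)
        rel = predict_substrates([s_site, y_site], [k], B62)[0]
        assert rel.predicted_site_ids == {"P2_Y1"}

    def test_impossible_cutoff_gives_empty_relation(self):
        k = KinaseSpec("K", "CAMK", ["A" * 7 + "S" + "A" * 7], cutoff=1e9)
        rel = predict_substrates([make_site()], [k], B62)[0]
        assert rel.predicted_site_ids == frozenset()

    def test_planted_motif_recovery(self, small_experiment):
        """The planted kinase's predicted set recovers >= 80% of motif sites."""
        _, (sites, proteins, design, kinases, truth) = small_experiment
        pre = preprocess_experiment(sites, proteins, design)
        class1 = pre["class1_sites"]
        model = KinaseEnrichmentModel(
            class1, kinases, truth.diff_site_ids_up & {s.site_id for s in class1},
            truth.diff_site_ids_down & {s.site_id for s in class1}, seed=1,
        )
        res = model.fit()
        rel = {r.kinase: r for r in res.relations}["CAMK2A"]
        motif = truth.motif_site_ids["CAMK2A"] & {s.site_id for s in class1}
        assert len(rel.predicted_site_ids & motif) / len(motif) >= 0.8


class TestFisherEnrich:
    def test_paper_shaped_table_matches_combinatorial_oracle(self):
        rel = KSRelation("K", frozenset(f"r{i}" for i in range(5)))
        regulated = frozenset(f"r{i}" for i in range(5)) | frozenset(f"n{i}" for i in range(5))
        universe = regulated | frozenset(f"u{i}" for i in range(10))
        res = fisher_enrich(rel, regulated, universe)
        assert (res.a, res.b, res.c, res.d) == (5, 5, 0, 10)
        assert res.p_value == pytest.approx(fisher_greater_oracle(5, 5, 0, 10), abs=1e-12)
        assert res.odds_ratio == np.inf

    def test_empty_predicted_set_gives_p_one(self):
        res = fisher_enrich(KSRelation("K", frozenset()), {"a"}, {"a", "b"})
        assert res.a == res.c == 0 and res.p_value == 1.0 and res.odds_ratio == 0.0

    def test_regulated_equals_universe_degenerate(self):
        # the remainder margin is empty: c = d = 0 and no enrichment is possible
        u = frozenset({"a", "b", "c"})
        res = fisher_enrich(KSRelation("K", frozenset({"a"})), u, u)
        assert res.c == res.d == 0 and res.p_value == 1.0
        assert res.a + res.b == len(u)

    def test_regulated_outside_universe_is_error(self):
        with pytest.raises(ValueError, match="subset"):
            fisher_enrich(KSRelation("K", frozenset()), {"x"}, {"a"})

    def test_matches_oracle_exhaustively_small_and_sampled_large(self):
        """Fisher p equals exact big-integer enumeration, |dp| < 1e-10."""
        worst = 0.0
        for N in range(1, 25):
            for a in range(N + 1):
                for b in range(N - a + 1):
                    for c in range(N - a - b + 1):
                        d = N - a - b - c
                        rel = _table_relation(a, b, c, d)
                        p = fisher_enrich(*rel).p_value
                        worst = max(worst, abs(p - fisher_greater_oracle(a, b, c, d)))
        rng = np.random.default_rng(0)
        for _ in range(2000):
            N = int(rng.integers(25, 61))
            cuts = np.sort(rng.integers(0, N + 1, size=3))
            a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
            d = N - a - b - c
            p = fisher_enrich(*_table_relation(a, b, c, d)).p_value
            worst = max(worst, abs(p - fisher_greater_oracle(a, b, c, d)))
        assert worst < 1e-10

    def test_monotonicity_in_regulated_substrates(self):
        """Moving a substrate site into the regulated set never raises p."""
        universe = frozenset(f"s{i}" for i in range(30))
        predicted = frozenset(f"s{i}" for i in range(8))
        rel = KSRelation("K", predicted)
        regulated = set(f"s{i}" for i in range(4)) | {f"s{i}" for i in range(10, 14)}
        p_prev = fisher_enrich(rel, regulated, universe).p_value
        for nxt in ["s4", "s5", "s6"]:  # add substrate sites one at a time
            swap = next(x for x in sorted(regulated) if x not in predicted)
            regulated = (regulated - {swap}) | {nxt}
            p_new = fisher_enrich(rel, regulated, universe).p_value
            assert p_new <= p_prev + 1e-15
            p_prev = p_new


def _table_relation(a, b, c, d):
    """Construct (relation, regulated, universe) realising a given 2x2 table."""
    reg_sub = {f"rs{i}" for i in range(a)}
    reg_non = {f"rn{i}" for i in range(b)}
    non_sub = {f"ns{i}" for i in range(c)}
    non_non = {f"nn{i}" for i in range(d)}
    relation = KSRelation("K", frozenset(reg_sub | non_sub))
    return relation, frozenset(reg_sub | reg_non), frozenset(
        reg_sub | reg_non | non_sub | non_non
    )


class TestFamilySummary:
    def _res(self, kinase, p, direction):
        from phosphopipe.kinase import ContingencyResult

        return ContingencyResult(kinase, 1, 1, 1, 1, 1.0, p, direction)

    def _specs(self):
        w = ["A" * 7 + "S" + "A" * 7]
        return [
            KinaseSpec("K1", "CAMK", w),
            KinaseSpec("K2", "CMGC", w),
        ]

    def test_counts_by_family_and_direction(self):
        results = [
            self._res("K1", 0.001, "up"),
            self._res("K1", 0.9, "down"),
            self._res("K2", 0.2, "up"),
            self._res("K2", 0.01, "down"),
        ]
        table = family_summary(results, self._specs()).set_index("family")
        assert table.loc["CAMK", "n_enriched_up"] == 1
        assert table.loc["CAMK", "n_enriched_down"] == 0
        assert table.loc["CMGC", "n_enriched_down"] == 1

    def test_no_significant_kinases_gives_zero_table(self):
        table = family_summary([self._res("K1", 0.9, "up")], self._specs())
        assert (table[["n_enriched_up", "n_enriched_down"]].values == 0).all()

    def test_unknown_kinase_is_error(self):
        with pytest.raises(ValueError, match="unknown kinase"):
            family_summary([self._res("K9", 0.01, "up")], self._specs())

    def test_planted_families_top_their_directions(self, small_experiment):
        """CAMK-motif up-activity and CMGC-motif down-activity land in the
        right family columns."""
        _, (sites, proteins, design, kinases, truth) = small_experiment
        pre = preprocess_experiment(sites, proteins, design)
        diff = SiteDifferentialModel(pre["calibrated"], design, "caput", "cauda").fit()
        model = KinaseEnrichmentModel(
            pre["class1_sites"], kinases, diff.direction_ids("up"),
            diff.direction_ids("down"), seed=2,
        )
        table = model.fit().family_summary().set_index("family")
        assert table["n_enriched_up"].idxmax() == "CAMK"
        assert table["n_enriched_down"].idxmax() == "CMGC"


class TestSubstitutionMatrixIO:
    def test_ncbi_format_file_roundtrip(self, tmp_path):
        """A matrix written in NCBI text format loads identically to the
        bundled BLOSUM62."""
        from Bio.Align import substitution_matrices

        path = tmp_path / "blosum62.txt"
        path.write_text(str(substitution_matrices.load("BLOSUM62")))
        from_file = load_substitution_matrix(str(path))
        assert np.array_equal(from_file, B62)
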