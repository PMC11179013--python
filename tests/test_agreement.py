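"""Agreement statistics against independent oracles.

The brute-force oracles below were written before the implementation
and stay independent of it: observed agreement by explicit pairwise
comparison, expected agreement from category proportions, kappa from
the definition.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from sceval.agreement import (
    AgreementBreakdown,
    RatingMatrix,
    categorize_agreement,
    cohen_kappa,
    complaint_agreement,
    encode_outcomes,
    fleiss_kappa,
    intratester_agreement,
    landis_koch_band,
)
from sceval.simulator import SimConfig, TesterProfile, simulate_study
from sceval.types import ABSENT, IncompleteDesignError, StudyDataset
from .conftest import ZERO_NOISE, make_consultation


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def fleiss_oracle(codes: np.ndarray):
    """Po by explicit pairwise comparison, Pe from pooled proportions."""
    codes = np.asarray(codes)
    n, r = codes.shape
    per_subject = []
    for row in codes:
        agree = sum(
            1 for i, j in itertools.combinations(range(r), 2) if row[i] == row[j]
        )
        per_subject.append(agree / (r * (r - 1) / 2))
    po = float(np.mean(per_subject))
    flat = codes.ravel()
    pe = float(sum((np.sum(flat == c) / flat.size) ** 2 for c in set(flat.tolist())))
    kappa = None if pe >= 1 else (po - pe) / (1 - pe)
    return po, pe, kappa


def cohen_oracle(a, b):
    a, b = list(a), list(b)
    n = len(a)
    po = sum(x == y for x, y in zip(a, b)) / n
    cats = set(a) | set(b)
    pe = sum((a.count(c) / n) * (b.count(c) / n) for c in cats)
    kappa = None if pe >= 1 else (po - pe) / (1 - pe)
    return po, pe, kappa


def matrix(codes) -> RatingMatrix:
    codes = np.asarray(codes)
    n, r = codes.shape
    return RatingMatrix(
        subjects=[f"s{i}" for i in range(n)],
        raters=[f"r{j}" for j in range(r)],
        codes=codes,
    )


# ---------------------------------------------------------------------------
# Fleiss kappa
# ---------------------------------------------------------------------------

class TestFleissKappa:
    def test_perfect_agreement_is_one(self):
        codes = np.array([[c] * 3 for c in (5, 2, 5, 9, 1, 2, 3, 4, 5, 6)])
        res = fleiss_kappa(matrix(codes))
        assert res.kappa == pytest.approx(1.0)
        assert res.po == pytest.approx(1.0)

    def test_small_matrix_matches_hand_oracle(self):
        codes = np.array([[1, 1, 2], [2, 2, 2], [1, 3, 2], [3, 3, 1]])
        po, pe, kappa = fleiss_oracle(codes)
        res = fleiss_kappa(matrix(codes))
        assert res.po == pytest.approx(po)
        assert res.pe == pytest.approx(pe)
        assert res.kappa == pytest.approx(kappa)

    def test_exhaustive_four_subject_matrices(self):
        """Every 4-subject x 3-rater binary matrix agrees with the oracle."""
        checked = 0
        for cells in itertools.product((1, 2), repeat=12):
            codes = np.array(cells).reshape(4, 3)
            po, pe, kappa = fleiss_oracle(codes)
            res = fleiss_kappa(matrix(codes))
            assert res.po == pytest.approx(po)
            assert res.pe == pytest.approx(pe)
            if kappa is None:
                assert res.kappa is None
            else:
                assert res.kappa == pytest.approx(kappa)
                checked += 1
        assert checked > 4000

    def test_matches_statsmodels_point_estimate(self):
        from statsmodels.stats.inter_rater import aggregate_raters
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        rng = np.random.default_rng(5)
        codes = rng.integers(0, 4, size=(60, 4))
        table, _ = aggregate_raters(codes)
        res = fleiss_kappa(matrix(codes))
        assert res.kappa == pytest.approx(sm_fleiss(table), abs=1e-12)

    def test_independence_gives_kappa_near_zero(self):
        rng = np.random.default_rng(2024)
        codes = rng.integers(1, 3, size=(10_000, 3))
        res = fleiss_kappa(matrix(codes))
        assert abs(res.kappa) <= 3 * res.se

    def test_single_category_reported_undefined(self):
        res = fleiss_kappa(matrix(np.ones((6, 3), dtype=int)))
        assert res.kappa is None
        assert not res.defined
        assert res.po == pytest.approx(1.0)
        assert res.landis_koch_band == "undefined"

    def test_invariant_under_code_relabeling(self):
        rng = np.random.default_rng(11)
        codes = rng.integers(0, 3, size=(40, 3))
        relabeled = np.take(np.array([7, 2, 5]), codes)
        a = fleiss_kappa(matrix(codes))
        b = fleiss_kappa(matrix(relabeled))
        assert a.kappa == pytest.approx(b.kappa)

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(3)
        codes = rng.integers(0, 3, size=(80, 3))
        res = fleiss_kappa(matrix(codes), bootstrap=300, seed=9)
        assert res.ci_low <= res.kappa <= res.ci_high


# ---------------------------------------------------------------------------
# Cohen kappa
# ---------------------------------------------------------------------------

class TestCohenKappa:
    def test_identical_sequences(self):
        res = cohen_kappa([1, 2, 3, 1], [1, 2, 3, 1])
        assert res.kappa == pytest.approx(1.0)
        assert res.po == pytest.approx(1.0)

    def test_perfect_disagreement_equal_marginals(self):
        # 2 categories, equal marginals, zero concordant pairs: Po=0, Pe=0.5
        res = cohen_kappa([1, 2, 1, 2], [2, 1, 2, 1])
        assert res.po == pytest.approx(0.0)
        assert res.pe == pytest.approx(0.5)
        assert res.kappa == pytest.approx(-1.0)

    def test_two_by_two_closed_form(self):
        # table a=20, b=5, c=10, d=15 laid out as paired ratings
        a_seq = [1] * 25 + [2] * 25
        b_seq = [1] * 20 + [2] * 5 + [1] * 10 + [2] * 15
        n = 50
        po = (20 + 15) / n
        pe = (25 / n) * (30 / n) + (25 / n) * (20 / n)
        expected = (po - pe) / (1 - pe)
        res = cohen_kappa(a_seq, b_seq)
        assert res.kappa == pytest.approx(expected)

    def test_exhaustive_four_pair_sequences(self):
        for a in itertools.product((1, 2), repeat=4):
            for b in itertools.product((1, 2), repeat=4):
                po, pe, kappa = cohen_oracle(a, b)
                res = cohen_kappa(a, b)
                assert res.po == pytest.approx(po)
                if kappa is None:
                    assert res.kappa is None
                else:
                    assert res.kappa == pytest.approx(kappa)

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(17)
        a = rng.integers(0, 4, size=200)
        b = rng.integers(0, 4, size=200)
        assert cohen_kappa(a, b).kappa == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(Exception, match="equal-length"):
            cohen_kappa([1, 2], [1])


# ---------------------------------------------------------------------------
# Landis-Koch bands and breakdowns
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "kappa, band",
    [
        (-0.4, "negative"),
        (0.1, "slight"),
        (0.3, "fair"),
        (0.49, "moderate"),
        (0.72, "substantial"),
        (0.95, "almost_perfect"),
    ],
)
def test_landis_koch_bands(kappa, band):
    assert landis_koch_band(kappa) == band


class TestBreakdown:
    @pytest.mark.parametrize(
        "row, kind",
        [((5, 5, 5), "full"), ((1, 2, 3), "none"), ((1, 1, 2), "partial")],
    )
    def test_single_subject_classification(self, row, kind):
        br = categorize_agreement(matrix(np.array([row])))
        assert getattr(br, f"n_{kind}") == 1

    def test_published_restricted_counts_give_published_percentages(self):
        br = AgreementBreakdown(n_full=73, n_partial=32, n_none=9)
        assert br.total == 114
        assert round(br.pct_full, 1) == 64.0
        assert round(br.pct_partial, 1) == 28.1
        assert round(br.pct_none, 1) == 7.9

    def test_counts_invariant_under_relabeling(self):
        rng = np.random.default_rng(4)
        codes = rng.integers(0, 3, size=(50, 3))
        a = categorize_agreement(matrix(codes))
        b = categorize_agreement(matrix(np.take(np.array([9, 4, 1]), codes)))
        assert (a.n_full, a.n_partial, a.n_none) == (b.n_full, b.n_partial, b.n_none)


# ---------------------------------------------------------------------------
# outcome encoding and study-level wiring
# ---------------------------------------------------------------------------

class TestEncodeOutcomes:
    def test_absent_maps_to_zero_and_labels_to_first_appearance(self, tiny_study):
        m = encode_outcomes(tiny_study, "condition")
        # v-knee row: all three 'septic arthritis' -> code 1
        assert m.codes[0].tolist() == [1, 1, 1]
        # v-abdo row: uti, uti, ABSENT
        assert m.codes[1].tolist() == [2, 2, 0]

    def test_normalization_merges_label_variants(self, tiny_study):
        tiny_study.consultation("t2", "v-knee").outcome_condition = "Septic  Arthritis "
        m = encode_outcomes(tiny_study, "condition")
        assert m.codes[0].tolist() == [1, 1, 1]

    def test_triage_uses_nine_level_codes(self, tiny_study):
        m = encode_outcomes(tiny_study, "triage")
        assert m.codes[0].tolist() == [7, 7, 7]  # urgent_12h
        assert m.codes[1].tolist() == [5, 5, 0]  # routine, routine, ABSENT

    def test_missing_cell_raises(self, tiny_study):
        tiny_study.consultations.pop()
        with pytest.raises(IncompleteDesignError):
            encode_outcomes(tiny_study, "condition")


class TestComplaintAgreement:
    def _free_study(self, tiny_study, complaints_by_tester) -> StudyDataset:
        for t, words in complaints_by_tester.items():
            for vid in tiny_study.vignettes:
                c = tiny_study.consultation(t, vid)
                c.entered_complaints = list(words)
                c.regime = "free"
        return tiny_study

    def test_identical_wording_full_agreement_both_levels(self, tiny_study):
        ds = self._free_study(
            tiny_study, {t: ["headache"] for t in ("t1", "t2", "t3")}
        )
        for level in ("exact_wording", "concept"):
            _, res, br = complaint_agreement(ds, level)
            assert br.n_full == br.total

    def test_synonyms_disagree_on_wording_agree_on_concept(self, tiny_study):
        ds = self._free_study(
            tiny_study,
            {"t1": ["tummy ache"], "t2": ["pain in the abdomen"], "t3": ["Tummy Ache"]},
        )
        _, _, br_word = complaint_agreement(ds, "exact_wording")
        _, _, br_concept = complaint_agreement(ds, "concept")
        assert br_word.n_full == 0  # t1/t3 match, t2 differs -> partial
        assert br_concept.n_full == br_concept.total

    def test_order_insensitive(self, tiny_study):
        ds = self._free_study(
            tiny_study,
            {"t1": ["headache", "fever"], "t2": ["fever", "headache"],
             "t3": ["Fever", "headache"]},
        )
        for level in ("exact_wording", "concept"):
            _, _, br = complaint_agreement(ds, level)
            assert br.n_full == br.total


class TestIntratester:
    def test_zero_noise_retest_kappa_is_one(self):
        profiles = [TesterProfile(**ZERO_NOISE) for _ in range(3)]
        ds = simulate_study(
            SimConfig(seed=5, n_vignettes=20, n_conditions=8, n_symptoms=20,
                      profiles=profiles, rounds=2)
        )
        for res in intratester_agreement(ds, "condition").values():
            assert res.po == pytest.approx(1.0)
            # several conditions appear, so kappa is defined and perfect
            assert res.kappa == pytest.approx(1.0)

    def test_noisy_retest_below_one(self):
        profiles = [TesterProfile(p_human_error=0.15, p_misinterpret=0.1,
                                  p_complaint_rephrase=0.5) for _ in range(3)]
        ds = simulate_study(
            SimConfig(seed=6, n_vignettes=40, n_conditions=10, n_symptoms=24,
                      profiles=profiles, rounds=2)
        )
        results = intratester_agreement(ds, "condition")
        assert any(res.kappa < 1.0 for res in results.values())
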