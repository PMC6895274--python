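"""CN, CC, CE and CS scoring.

The entropy-difference oracle: for any pair-count table, the score of an
alpha->gamma substitution must equal S(after) - S(before), where
S = ln(N!/prod n!) is the log-multinomial entropy of the table evaluated
via log-gamma, and "after" moves one count from (alpha, beta) to
(gamma, beta).
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from cescore.coupling import CouplingSet, covariation_matrix, select_couplings
from cescore.msa_io import Variant, apply_column_filters, from_rows
from cescore.scores import (
    PairCountTable,
    ScoreError,
    ce_score,
    cost_of_coupling,
    coupling_number,
    cs_score,
    delta_entropy,
    pair_counts,
    score_variants,
)
from cescore.synthetic import default_spec, generate_coupled_msa


def log_multinomial_entropy(counts):
    """S = ln(N!/prod n!) via log-gamma."""
    n = list(counts)
    N = sum(n)
    return float(gammaln(N + 1) - sum(gammaln(x + 1) for x in n))


def make_coupling_set(pairs, L):
    partners = {}
    for i, j in pairs:
        partners.setdefault(i, []).append(j)
        partners.setdefault(j, []).append(i)
    return CouplingSet(
        pairs=tuple(pairs),
        partners={k: tuple(sorted(v)) for k, v in partners.items()},
        budget=2 * L,
        L=L,
    )


class TestCouplingNumber:
    def test_hand_enumerated_ranks(self):
        # counts [3, 1, 2] over L=3 -> CN [1.0, 0.0, 0.5]
        cs = make_coupling_set([(1, 2), (1, 3), (1, 2)], L=3)
        # build counts directly: pairs (1,2),(1,3),(1,2) give counts 3,2,1
        prof = coupling_number(cs, L=3)
        assert prof.counts.tolist() == [3, 2, 1]
        assert prof.cn.tolist() == [1.0, 0.5, 0.0]

    def test_full_tie_gives_half(self):
        cs = make_coupling_set([(1, 2), (3, 4)], L=4)
        prof = coupling_number(cs, L=4)
        assert prof.counts.tolist() == [1, 1, 1, 1]
        assert all(v == 0.5 for v in prof.cn)

    def test_strict_max_gets_one_and_strict_min_gets_zero(self):
        cs = make_coupling_set([(1, 2), (1, 3), (2, 3), (1, 4)], L=4)
        prof = coupling_number(cs, L=4)
        assert prof.cn_at(1) == 1.0   # count 3, untied max
        assert prof.cn_at(4) == 0.0   # count 1, untied min
        assert np.all((prof.cn >= 0) & (prof.cn <= 1))

    def test_count_conservation(self):
        cs = make_coupling_set([(1, 2), (2, 3), (4, 5), (1, 5)], L=6)
        prof = coupling_number(cs, L=6)
        assert prof.counts.sum() == 2 * cs.n_selected

    def test_cn_monotone_in_count(self):
        cs = make_coupling_set([(1, 2), (1, 3), (1, 4), (2, 3)], L=5)
        prof = coupling_number(cs, L=5)
        order = np.argsort(prof.counts)
        assert np.all(np.diff(prof.cn[order]) >= 0)

    def test_short_protein_rejected(self):
        cs = make_coupling_set([(1, 2)], L=2)
        with pytest.raises(ScoreError):
            coupling_number(cs, L=1)


class TestPairCounts:
    def test_direct_tally(self):
        rows = ("AK", "AK", "AK", "SE", "SE", "AE")
        aln = from_rows(tuple(f"s{k}" for k in range(6)), rows, "s0")
        t = pair_counts(aln, 1, 2)
        assert t.n("A", "K") == 3
        assert t.n("S", "E") == 2
        assert t.n("A", "E") == 1
        assert t.N == 6

    def test_gapped_rows_excluded(self):
        rows = ("AK", "A-", "-K", "SE")
        aln = from_rows(("q", "a", "b", "c"), rows, "q")
        t = pair_counts(aln, 1, 2)
        assert t.N == 2
        assert t.n("A", "K") == 1

    def test_query_pair_always_counted(self):
        rows = ("AK", "SE", "SE")
        aln = from_rows(("q", "a", "b"), rows, "q")
        t = pair_counts(aln, 1, 2)
        assert t.n("A", "K") >= 1

    def test_unselected_pair_rejected_when_couplings_given(self):
        rows = ("AKD", "SED", "AKC")
        aln = from_rows(("q", "a", "b"), rows, "q")
        cs = make_coupling_set([(1, 2)], L=3)
        with pytest.raises(ScoreError, match="not a selected coupling"):
            pair_counts(aln, 1, 3, cs)


class TestDeltaEntropy:
    def _table(self, counts):
        return PairCountTable(i=1, j=2, counts=counts)

    def test_closed_forms(self):
        t = self._table({("A", "K"): 4, ("G", "K"): 1, ("S", "E"): 2})
        # n(gamma,beta)+1 = 2, n(alpha,beta) = 4 -> ln 2
        assert delta_entropy(t, "A", "K", "G") == pytest.approx(math.log(2))
        t2 = self._table({("A", "K"): 5})
        # unseen variant pair: -ln(1/5) = ln 5
        assert delta_entropy(t2, "A", "K", "W") == pytest.approx(math.log(5))

    def test_zero_when_counts_balance(self):
        t = self._table({("A", "K"): 3, ("G", "K"): 2})
        assert delta_entropy(t, "A", "K", "G") == pytest.approx(0.0)

    def test_missing_wildtype_pair_rejected(self):
        t = self._table({("S", "E"): 3})
        with pytest.raises(ScoreError, match="wild type"):
            delta_entropy(t, "A", "K", "G")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        n_ab=st.integers(1, 50),
        n_gb=st.integers(0, 50),
        extra=st.lists(st.integers(1, 30), min_size=0, max_size=6),
    )
    def test_matches_log_factorial_entropy_difference(self, n_ab, n_gb, extra):
        counts = {("A", "K"): n_ab}
        if n_gb:
            counts[("G", "K")] = n_gb
        for idx, c in enumerate(extra):
            counts[(f"X{idx}", "E")] = c  # labels only need to be distinct
        before = list(counts.values())
        after = dict(counts)
        after[("A", "K")] -= 1
        after[("G", "K")] = after.get(("G", "K"), 0) + 1
        s_before = log_multinomial_entropy(before)
        s_after = log_multinomial_entropy(after.values())
        t = PairCountTable(i=1, j=2, counts=counts)
        assert delta_entropy(t, "A", "K", "G") == pytest.approx(
            s_after - s_before, abs=1e-9
        )


class TestCostOfCoupling:
    def _alignment(self):
        #       pos: 123
        rows = (
            "AKD",
            "AKD",
            "AKC",
            "AKD",
            "SEC",
            "SED",
        )
        return from_rows(tuple(f"s{k}" for k in range(6)), rows, "s0")

    def test_mean_over_partners(self):
        aln = self._alignment()
        cs = make_coupling_set([(1, 2), (1, 3)], L=3)
        v = Variant(position=1, wt_aa="A", alt_aa="G")
        # partner 2 (beta=K): n(A,K)=4, n(G,K)=0 -> ln 4
        # partner 3 (beta=D): n(A,D)=3, n(G,D)=0 -> ln 3
        expected = (math.log(4) + math.log(3)) / 2
        assert cost_of_coupling(aln, cs, v) == pytest.approx(expected)

    def test_no_partners_scores_zero(self):
        aln = self._alignment()
        cs = make_coupling_set([(2, 3)], L=3)
        v = Variant(position=1, wt_aa="A", alt_aa="G")
        assert cost_of_coupling(aln, cs, v) == 0.0

    def test_wildtype_mismatch_rejected(self):
        aln = self._alignment()
        cs = make_coupling_set([(1, 2)], L=3)
        with pytest.raises(ScoreError, match="does not match query"):
            cost_of_coupling(aln, cs, Variant(position=1, wt_aa="S", alt_aa="G"))

    def test_compensatory_substitution_costs_nothing(self):
        # variant to a residue pairing exactly as often as wild type
        rows = ("AK", "GK", "GK", "AK", "AK")
        aln = from_rows(tuple(f"s{k}" for k in range(5)), rows, "s0")
        cs = make_coupling_set([(1, 2)], L=2)
        v = Variant(position=1, wt_aa="A", alt_aa="G")
        # n(G,K)+1 = 3 = n(A,K) -> dS = 0
        assert cost_of_coupling(aln, cs, v) == pytest.approx(0.0)


class TestCeAndCs:
    def test_ce_is_product(self):
        assert ce_score(0.0, 7.3) == 0.0
        assert ce_score(0.5, 2.0) == 1.0
        with pytest.raises(ScoreError):
            ce_score(1.5, 1.0)

    def test_cs_conserved_column(self):
        rows = tuple("AK" for _ in range(10))
        aln = from_rows(tuple(f"s{k}" for k in range(10)), rows, "s0")
        v = Variant(position=1, wt_aa="A", alt_aa="G")
        assert cs_score(aln, v) == pytest.approx(math.log(10))

    def test_cs_zero_when_counts_balance(self):
        rows = ("AK", "AK", "AK", "GK", "GK")
        aln = from_rows(tuple(f"s{k}" for k in range(5)), rows, "s0")
        v = Variant(position=1, wt_aa="A", alt_aa="G")
        # n(G)+1 = 3 = n(A)
        assert cs_score(aln, v) == pytest.approx(0.0)

    def test_cs_monotone_in_variant_frequency(self):
        # rarer alternate residue never lowers the score
        scores = []
        for n_g in (4, 2, 0):
            rows = tuple("AK" for _ in range(6 - n_g)) + tuple("GK" for _ in range(n_g))
            aln = from_rows(tuple(f"s{k}" for k in range(6)), rows, "s0")
            scores.append(cs_score(aln, Variant(position=1, wt_aa="A", alt_aa="G")))
        assert scores == sorted(scores)


class TestScoreVariants:
    def test_ce_equals_cn_times_cc_on_every_row(self):
        aln, _ = generate_coupled_msa(default_spec(L=30, N=80, n_pairs=2, seed=3))
        variants = [
            Variant(position=p, wt_aa=aln.query_residue(p),
                    alt_aa="W" if aln.query_residue(p) != "W" else "Y")
            for p in range(1, aln.L + 1)
        ]
        results = score_variants(aln, variants, with_cs=True)
        ok = [r for r in results if not any(f.startswith("error") for f in r.flags)]
        assert len(ok) == len(results)
        for r in ok:
            assert r.CE == r.CN * r.CC  # bit-exact product

    def test_batch_equals_single_calls_and_duplicates_identical(self):
        aln, _ = generate_coupled_msa(default_spec(L=20, N=60, n_pairs=1, seed=5))
        p = 10
        v = Variant(position=p, wt_aa=aln.query_residue(p), alt_aa="W")
        batch = score_variants(aln, [v, v])
        single = score_variants(aln, [v])
        assert batch[0] == batch[1]
        assert batch[0].CE == single[0].CE

    def test_wt_mismatch_flagged_not_fatal(self):
        aln, _ = generate_coupled_msa(default_spec(L=20, N=60, n_pairs=1, seed=5))
        wt = aln.query_residue(5)
        wrong = "A" if wt != "A" else "S"
        bad = Variant(position=5, wt_aa=wrong, alt_aa="Y" if wrong != "Y" else "W")
        good_wt = aln.query_residue(6)
        good = Variant(position=6, wt_aa=good_wt, alt_aa="W" if good_wt != "W" else "Y")
        results = score_variants(aln, [bad, good])
        assert any(f.startswith("error:") for f in results[0].flags)
        assert math.isnan(results[0].CE)
        assert not results[1].flags or not any(
            f.startswith("error") for f in results[1].flags
        )

    def test_breaking_planted_pair_scores_above_random_site(self):
        """A substitution destroying a planted compatible state gets a
        higher mean CE, over 20 seeds, than one at an independent
        background column (per-seed CE is noisy: one planted pair adds
        only a single count to the site's coupling number)."""
        ce_planted, ce_background = [], []
        n_seeds = 20
        for seed in range(n_seeds):
            spec = default_spec(L=30, N=120, n_pairs=1, w=0.95,
                                gap_rate=0.0, seed=seed)
            aln, truth = generate_coupled_msa(spec)
            i, _ = truth.planted_pairs[0]
            background = [
                p for p, cat in truth.category.items() if cat == "background"
            ][5]
            vi = Variant(position=i, wt_aa=aln.query_residue(i), alt_aa="W")
            vb = Variant(
                position=background,
                wt_aa=aln.query_residue(background),
                alt_aa="W" if aln.query_residue(background) != "W" else "Y",
            )
            res = score_variants(aln, [vi, vb])
            ce_planted.append(res[0].CE)
            ce_background.append(res[1].CE)
        assert np.mean(ce_planted) > np.mean(ce_background)
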