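"""Top binders, position frequencies, consensus/specific calling, similarity."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phosphobind import (
    AffinityRecord,
    PeptideMotif,
    consensus_binders,
    isoform_specific,
    position_frequencies,
    randomization_pvalue,
    similarity_score,
    top_k,
)
from phosphobind.aa_tables import CANONICAL_AA

aa = st.sampled_from(CANONICAL_AA)
triple = st.tuples(aa, aa, aa)

ISOFORMS = ("beta", "epsilon", "eta", "gamma", "sigma", "tau", "zeta")


def motif(residues, terminal="N"):
    return PeptideMotif(terminal, tuple(residues))


class TestTopK:
    def test_all_records(self, paper_library_n, rng):
        records = [
            AffinityRecord(m, float(a))
            for m, a in zip(paper_library_n[:20], rng.uniform(0, 100, 20))
        ]
        assert set(top_k(records, 20)) == {r.motif for r in records}

    def test_descending_prefix(self, paper_library_n):
        records = [
            AffinityRecord(m, float(i)) for i, m in enumerate(paper_library_n[:10])
        ]
        assert top_k(records, 3) == [r.motif for r in records[-3:][::-1]]

    def test_tie_breaks_lexicographically(self):
        tied = [motif("RGG"), motif("RAG"), motif("REG")]
        records = [AffinityRecord(m, 5.0) for m in tied]
        records.append(AffinityRecord(motif("EEE"), 9.0))
        out = top_k(records, 2)
        # EEE wins outright; among the three tied at 5, RAGsXXX sorts first
        assert out == [motif("EEE"), motif("RAG")]

    def test_bad_k_rejected(self):
        records = [AffinityRecord(motif("RAF"), 1.0)]
        with pytest.raises(ValueError):
            top_k(records, 0)
        with pytest.raises(ValueError):
            top_k(records, 2)


class TestPositionFrequencies:
    def test_identical_motifs(self):
        pwm = position_frequencies([motif("RAF")] * 5)
        assert pwm.weights.loc["P-3", "R"] == 1.0
        assert pwm.weights.loc["P-2", "A"] == 1.0
        assert pwm.covered == (True, True, True, False, False, False)
        assert pwm.weights.loc["P+1"].isna().all()

    def test_uniform_random_approaches_uniform(self, rng):
        n = 4000
        motifs = [
            motif(rng.choice(list(CANONICAL_AA), 3)) for _ in range(n)
        ]
        pwm = position_frequencies(motifs)
        freqs = pwm.weights.loc["P-2"].to_numpy()
        se = np.sqrt((1 / 20) * (19 / 20) / n)
        assert np.abs(freqs - 1 / 20).max() < 3.5 * se

    def test_equal_weights_match_unweighted(self, paper_library_n):
        motifs = paper_library_n[:50]
        unweighted = position_frequencies(motifs)
        weighted = position_frequencies(motifs, weights=[2.0] * 50)
        assert np.allclose(
            unweighted.weights.to_numpy(), weighted.weights.to_numpy(), equal_nan=True
        )
        assert weighted.mode == "affinity-weighted"

    def test_merged_terminals_cover_all_positions(self, paper_library_n, paper_library_c):
        pwm = position_frequencies(paper_library_n[:10] + paper_library_c[:10])
        assert all(pwm.covered)
        sums = pwm.weights.sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            position_frequencies([])


class TestConsensusAndSpecific:
    def test_identical_lists(self, paper_library_n):
        lists = {iso: list(paper_library_n[:10]) for iso in ISOFORMS}
        assert set(consensus_binders(lists)) == set(paper_library_n[:10])
        assert isoform_specific(lists, "sigma") == []

    def test_one_empty_list(self, paper_library_n):
        lists = {"a": list(paper_library_n[:5]), "b": []}
        assert consensus_binders(lists) == []

    def test_disjoint_target(self, paper_library_n):
        lists = {
            "sigma": list(paper_library_n[:5]),
            "beta": list(paper_library_n[5:10]),
            "tau": list(paper_library_n[10:15]),
        }
        assert isoform_specific(lists, "sigma") == list(paper_library_n[:5])

    def test_against_set_algebra_oracle(self, paper_library_n, rng):
        pool = paper_library_n[:60]
        lists = {
            iso: [pool[i] for i in rng.choice(60, 25, replace=False)]
            for iso in ISOFORMS
        }
        expected = set(pool)
        for lst in lists.values():
            expected &= set(lst)
        assert set(consensus_binders(lists)) == expected
        assert all(m in lists["sigma"] for m in isoform_specific(lists, "sigma"))
        others = set(itertools.chain(*(lists[i] for i in ISOFORMS if i != "sigma")))
        assert set(isoform_specific(lists, "sigma")) == set(lists["sigma"]) - others

    def test_unknown_isoform_rejected(self, paper_library_n):
        lists = {"sigma": list(paper_library_n[:5]), "beta": []}
        with pytest.raises(ValueError, match="unknown"):
            isoform_specific(lists, "omega")

    def test_consensus_needs_two_lists(self, paper_library_n):
        with pytest.raises(ValueError):
            consensus_binders({"sigma": list(paper_library_n[:5])})


class TestSimilarityScore:
    def test_identical_scores_nine(self, categories):
        s = similarity_score(motif("RAF"), ("R", "A", "F"), categories)
        assert s.total == 9 and s.per_position == (3, 3, 3)

    def test_reference_binder_worked_examples(self, categories):
        """The three sigma-specific N motifs vs LFG give {1, 3, 4}; FGP vs LLR gives 1."""
        totals = {
            similarity_score(motif(t), ("L", "F", "G"), categories).total
            for t in ("RAG", "EAK", "RGG")
        }
        assert totals == {1, 3, 4}
        c = similarity_score(motif("FGP", "C"), ("L", "L", "R"), categories)
        assert c.total == 1

    @given(a=triple, b=triple)
    def test_symmetric(self, categories, a, b):
        s_ab = similarity_score(motif(a), b, categories).total
        s_ba = similarity_score(motif(b), a, categories).total
        assert s_ab == s_ba

    @given(a=triple)
    def test_self_score_is_nine(self, categories, a):
        assert similarity_score(motif(a), a, categories).total == 9


def exact_score_distribution(reference, categories):
    """Enumerate the null score distribution for uniform 20-AA draws."""
    dist = {0: 1.0}
    for ref in reference:
        cat_size = len(categories.members(categories.assignment[ref]))
        probs = {3: 1 / 20, 1: (cat_size - 1) / 20, 0: (20 - cat_size) / 20}
        new = {}
        for tot, p in dist.items():
            for sc, q in probs.items():
                new[tot + sc] = new.get(tot + sc, 0.0) + p * q
        dist = new
    return dist


class TestRandomizationPvalue:
    def test_observed_zero_gives_one(self, categories):
        p = randomization_pvalue(0, ("L", "F", "G"), categories, n_iter=100, seed=1)
        assert p == 1.0

    def test_unreachable_observed_gives_zero(self, categories):
        p = randomization_pvalue(10, ("L", "F", "G"), categories, n_iter=100, seed=1)
        assert p == 0.0

    def test_matches_exact_enumeration(self, categories):
        """Monte-Carlo p for score >= 4 vs LFG agrees with the exact tail."""
        dist = exact_score_distribution(("L", "F", "G"), categories)
        exact = sum(p for tot, p in dist.items() if tot >= 4)
        n_iter = 100_000
        mc = randomization_pvalue(
            4, ("L", "F", "G"), categories, n_iter=n_iter, seed=3
        )
        se = np.sqrt(exact * (1 - exact) / n_iter)
        assert abs(mc - exact) < 3 * se

    def test_se_halves_when_quadrupling_iterations(self, categories):
        """Monte-Carlo convergence: 4x the iterations halve the spread."""
        dist = exact_score_distribution(("L", "F", "G"), categories)
        exact = sum(p for tot, p in dist.items() if tot >= 4)

        def spread(n_iter, seeds):
            vals = [
                randomization_pvalue(4, ("L", "F", "G"), categories,
                                     n_iter=n_iter, seed=s)
                for s in seeds
            ]
            return np.sqrt(np.mean([(v - exact) ** 2 for v in vals]))

        s_small = spread(500, range(30))
        s_large = spread(2000, range(30, 60))
        assert s_large < s_small / 1.4

    def test_restricted_alphabet(self, categories):
        from phosphobind.peptide_library import PAPER_ALPHABET_P12, PAPER_ALPHABET_P3

        alphabets = (PAPER_ALPHABET_P3, PAPER_ALPHABET_P12, PAPER_ALPHABET_P12)
        p = randomization_pvalue(
            4, ("L", "F", "G"), categories, null_alphabets=alphabets,
            n_iter=2000, seed=5,
        )
        assert 0.0 <= p <= 1.0

    def test_empty_alphabet_rejected(self, categories):
        with pytest.raises(ValueError):
            randomization_pvalue(
                4, ("L", "F", "G"), categories, null_alphabets=((), ("A",), ("A",))
            )
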