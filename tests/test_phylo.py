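"""Pairwise-identity DP against an independent aligner, clade null test,
Fisher-exact enrichment against hypergeometric enumeration."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from rumherit.errors import InputError
from rumherit.phylo import (
    AlignmentScoring,
    SequenceSet,
    alignment_score,
    mean_pairwise_similarity,
    pairwise_identity,
    similarity_null_test,
    taxon_at_rank,
    taxon_enrichment,
)

DNA = st.text(alphabet="ACGT", min_size=1, max_size=40)


def biopython_aligner(sc: AlignmentScoring):
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.Array(
        "ACGTN", dims=2, data=sc.substitution()
    )
    aligner.open_gap_score = sc.gap_open
    aligner.extend_gap_score = sc.gap_extend
    return aligner


def oracle_identities(aligner, a, b, cap=2000):
    """Identity values over the oracle's optimal alignments, counting a
    column as a match only for equal non-N symbols.  Returns (values,
    complete) where complete says the enumeration was not truncated."""
    out = set()
    alns = aligner.align(a, b)
    complete = True
    for i, aln in enumerate(alns):
        if i >= cap:
            complete = False
            break
        sa, sb = str(aln[0]), str(aln[1])
        m = sum(1 for x, y in zip(sa, sb) if x == y and x not in "-N")
        out.add(round(100.0 * m / len(sa), 9))
    return out, complete


class TestPairwiseIdentity:
    def test_self_identity(self):
        assert pairwise_identity("ACGTACGTAC", "ACGTACGTAC") == 100.0

    def test_disjoint_alphabets(self):
        assert pairwise_identity("AAAA", "TTTT") == 0.0

    def test_n_never_matches(self):
        assert pairwise_identity("NNNN", "NNNN") == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            pairwise_identity("", "ACGT")

    def test_non_alphabet_symbol_rejected(self):
        with pytest.raises(InputError):
            pairwise_identity("ACGX", "ACGT")

    @given(DNA, DNA)
    def test_symmetry_and_range(self, a, b):
        i1 = pairwise_identity(a, b)
        assert i1 == pairwise_identity(b, a)
        assert 0.0 <= i1 <= 100.0

    @given(DNA, DNA)
    def test_reverse_complement_invariance(self, a, b):
        rc = lambda s: s[::-1].translate(str.maketrans("ACGT", "TGCA"))
        assert pairwise_identity(a, b) == pytest.approx(
            pairwise_identity(rc(a), rc(b))
        )

    def test_matches_independent_dp_aligner(self):
        sc = AlignmentScoring()
        aligner = biopython_aligner(sc)
        rng = np.random.default_rng(17)
        for _ in range(25):
            la, lb = rng.integers(15, 70, 2)
            a = "".join(rng.choice(list("ACGTN"), la, p=[0.24] * 4 + [0.04]))
            b = "".join(rng.choice(list("ACGTN"), lb, p=[0.24] * 4 + [0.04]))
            assert alignment_score(a, b) == aligner.score(a, b)
            ids, complete = oracle_identities(aligner, a, b)
            mine = round(pairwise_identity(a, b), 9)
            if complete:
                # identity is defined as max matches among optimal alignments
                assert mine == max(ids)
            else:
                assert mine >= max(ids) or mine in ids


class TestMeanPairwiseSimilarity:
    def test_single_identical_pair(self):
        s = SequenceSet({"a": "ACGTACGTAC", "b": "ACGTACGTAC"})
        assert mean_pairwise_similarity(s, ["a", "b"]) == 100.0

    def test_arithmetic_mean_of_constructed_identities(self):
        # equal-length, gap-free optima: b differs from a at 1/10 sites (90),
        # c differs from a at 2 (80) and from b at 3 (70)
        a = "ACGTACGTAC"
        b = "TCGTACGTAC"
        c = "AGCTACGTAC"
        s = SequenceSet({"a": a, "b": b, "c": c})
        assert pairwise_identity(a, b) == 90.0
        assert pairwise_identity(a, c) == 80.0
        assert pairwise_identity(b, c) == 70.0
        assert mean_pairwise_similarity(s, ["a", "b", "c"]) == pytest.approx(80.0)

    def test_pair_count_for_22_sequences(self):
        rng = np.random.default_rng(2)
        seqs = {f"o{i}": "".join(rng.choice(list("ACGT"), 30)) for i in range(22)}
        cache = {}
        mean_pairwise_similarity(SequenceSet(seqs), list(seqs), _cache=cache)
        assert len(cache) == math.comb(22, 2)  # 231 unique pairs evaluated

    def test_singleton_rejected(self):
        s = SequenceSet({"a": "ACGT"})
        with pytest.raises(InputError):
            mean_pairwise_similarity(s, ["a"])


@pytest.fixture(scope="module")
def seqs():
    rng = np.random.default_rng(3)
    return SequenceSet(
        {f"o{i}": "".join(rng.choice(list("ACGT"), 60)) for i in range(30)}
    )


class TestSimilarityNullTest:

    def test_degenerate_pool_gives_p_one(self, seqs):
        ids = [f"o{i}" for i in range(5)]
        res = similarity_null_test(seqs, ids, ids, n_draws=20, seed=0)
        assert res.p_value == 1.0
        assert np.allclose(res.null_means, res.observed)

    def test_fixed_seed_reproducible(self, seqs):
        ids = [f"o{i}" for i in range(4)]
        r1 = similarity_null_test(seqs, ids, seqs.ids, n_draws=15, seed=5)
        r2 = similarity_null_test(seqs, ids, seqs.ids, n_draws=15, seed=5)
        assert np.array_equal(r1.null_means, r2.null_means)

    def test_p_never_zero(self, seqs):
        ids = [f"o{i}" for i in range(4)]
        res = similarity_null_test(seqs, ids, seqs.ids, n_draws=15, seed=5)
        assert res.p_value >= 1.0 / 16

    def test_p_decreases_with_planted_identity_gap(self):
        from rumherit.simulate import PlantedMicrobiome, simulate_sequences

        ps = []
        for clade in (0.78, 0.86, 0.95):
            spec = PlantedMicrobiome(
                n_otus=60, n_heritable=10, clade_divergence=clade,
                background_divergence=0.75, seq_length=120, seed=40,
            )
            s = simulate_sequences(spec)
            res = similarity_null_test(s, spec.planted_ids(), s.ids,
                                       n_draws=40, seed=41)
            ps.append(res.p_value)
        assert ps[0] >= ps[1] >= ps[2]
        assert ps[2] <= 0.05


def fisher_two_sided_enumeration(hc, hn, nc, nn):
    """Exact two-sided Fisher p by hypergeometric enumeration: sum the
    probabilities of all tables (fixed margins) no more probable than the
    observed one."""
    row1, col1 = hc + hn, hc + nc
    total = hc + hn + nc + nn

    def table_p(k):
        return (
            math.comb(col1, k)
            * math.comb(total - col1, row1 - k)
            / math.comb(total, row1)
        )

    p_obs = table_p(hc)
    lo, hi = max(0, row1 + col1 - total), min(row1, col1)
    return sum(table_p(k) for k in range(lo, hi + 1) if table_p(k) <= p_obs * (1 + 1e-12))


class TestTaxonEnrichment:
    def test_fisher_matches_enumeration(self):
        from scipy.stats import fisher_exact

        _, p = fisher_exact([[10, 12], [100, 900]])
        assert p == pytest.approx(fisher_two_sided_enumeration(10, 12, 100, 900), abs=1e-12)

    def test_extreme_table_closed_form(self):
        # all 5 heritable OTUs in one taxon of size 5 within a pool of 20:
        # two-sided reduces to the single hypergeometric point + tail
        tax = pd.Series(
            ["x;y;z;OrderA;f;g"] * 5 + ["x;y;z;OrderB;f;g"] * 15,
            index=[f"o{i}" for i in range(20)],
        )
        out = taxon_enrichment(tax, [f"o{i}" for i in range(5)], rank="order")
        expect = fisher_two_sided_enumeration(5, 0, 0, 15)
        assert out.loc["OrderA", "p_value"] == pytest.approx(expect, abs=1e-12)
        assert out.loc["OrderA", "hc"] == 5 and out.loc["OrderA", "nn"] == 15

    def test_unparseable_lineage_counted_as_unclassified(self):
        tax = pd.Series(["Bacteria;Firmicutes", "x;y;z;OrderA;f;g"], index=["o1", "o2"])
        out = taxon_enrichment(tax, ["o1"], rank="order")
        assert "unclassified" in out.index
        assert out.loc["unclassified", "hc"] == 1

    def test_null_pvalues_roughly_uniform(self):
        """Candidate sets drawn uniformly give non-concentrated Fisher p."""
        rng = np.random.default_rng(50)
        taxa = ["A", "B", "C", "D"]
        ids = [f"o{i}" for i in range(60)]
        tax = pd.Series(
            [f"x;y;z;{rng.choice(taxa)};f;g" for _ in ids], index=ids
        )
        ps = []
        for _ in range(100):
            pick = rng.choice(ids, size=12, replace=False)
            out = taxon_enrichment(tax, list(pick), rank="order")
            ps.extend(out["p_value"])
        ps = np.asarray(ps)
        # discrete conservative test: small p-values are not enriched
        assert (ps < 0.05).mean() < 0.08

    def test_rank_parsing(self):
        assert taxon_at_rank("Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;f;g",
                             "order") == "Bacteroidales"
        assert taxon_at_rank("Bacteria", "order") == "unclassified"
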