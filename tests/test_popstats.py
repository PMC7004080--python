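"""Marker-level statistics: distances, diversity, F_ST, FDR, four-gamete, PCA."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from divmig.popstats import (
    FourGameteResult,
    HaplotypeAlignment,
    SaturationError,
    StatError,
    by_adjust,
    four_gamete_blocks,
    haplotype_diversity,
    hudson_fst,
    k2p_distance,
    pca_genotypes,
)

SEQ = st.text(alphabet="ACGT", min_size=10, max_size=40)


class TestK2P:
    def test_identical_sequences_zero(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_single_transition_closed_form(self):
        # P = 0.1, Q = 0 -> -0.5*ln(0.8)
        assert k2p_distance("A" * 9 + "G", "A" * 10) == pytest.approx(0.11157, abs=5e-6)

    def test_single_transversion_closed_form(self):
        # P = 0, Q = 0.1 -> -0.5*ln(0.9) - 0.25*ln(0.8) = 0.108466
        assert k2p_distance("A" * 9 + "C", "A" * 10) == pytest.approx(
            -0.5 * math.log(0.9) - 0.25 * math.log(0.8), abs=1e-12
        )
        assert k2p_distance("A" * 9 + "C", "A" * 10) == pytest.approx(0.10846, abs=1e-5)

    def test_pairwise_deletion_of_gaps_and_n(self):
        # gap/N columns drop out, leaving 1 transition over 9 sites
        a = "A" * 8 + "-G"
        b = "A" * 7 + "NAA"
        assert k2p_distance(a, b) == pytest.approx(-0.5 * math.log(1 - 2 / 8), abs=1e-9)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_distance("AAAA", "GGGG")

    @given(SEQ, SEQ)
    @hsettings(max_examples=50, deadline=None)
    def test_symmetry_and_nonnegativity(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        try:
            d_ab = k2p_distance(a, b)
            d_ba = k2p_distance(b, a)
        except SaturationError:
            return
        assert d_ab == pytest.approx(d_ba)
        assert d_ab >= 0.0


class TestHaplotypeDiversity:
    def test_monomorphic_is_zero(self):
        h, sd = haplotype_diversity(["x"] * 5)
        assert h == 0.0
        assert sd == 0.0

    def test_two_haplotypes_balanced(self):
        h, _ = haplotype_diversity(["a", "a", "b", "b"])
        assert h == pytest.approx(2.0 / 3.0)

    def test_all_distinct(self):
        h, _ = haplotype_diversity(["a", "b", "c"])
        assert h == pytest.approx(1.0)

    def test_needs_two_sequences(self):
        with pytest.raises(StatError):
            haplotype_diversity(["only"])


class TestHudsonFst:
    def test_identical_populations_zero(self):
        pop = ["AAAA", "AAAT", "AATT"]
        assert hudson_fst(pop, list(pop)) == pytest.approx(0.0)

    def test_fixed_difference_monomorphic_within(self):
        assert hudson_fst(["AAAA", "AAAA"], ["TTTT", "TTTT"]) == pytest.approx(1.0)

    def test_matches_bruteforce_all_pairs_oracle(self, rng):
        # mean pairwise difference "with replacement" (ordered pairs incl.
        # self) equals the per-site 1 - sum p^2 identity the estimator uses
        bases = np.array(list("ACGT"))
        pop1 = ["".join(bases[rng.integers(0, 4, 12)]) for _ in range(4)]
        pop2 = ["".join(bases[rng.integers(0, 4, 12)]) for _ in range(4)]

        def diff(a, b):
            return sum(x != y for x, y in zip(a, b)) / len(a)

        hw1 = np.mean([diff(a, b) for a in pop1 for b in pop1])
        hw2 = np.mean([diff(a, b) for a in pop2 for b in pop2])
        hb = np.mean([diff(a, b) for a in pop1 for b in pop2])
        expected = 1 - 0.5 * (hw1 + hw2) / hb
        assert hudson_fst(pop1, pop2) == pytest.approx(expected)

    def test_allele_relabelling_invariance(self):
        # swapping A<->G everywhere changes no pairwise difference
        pop1 = ["AAGG", "AGGG", "AAAG"]
        pop2 = ["GGAA", "GGGA", "GGAA"]
        swap = str.maketrans("AG", "GA")
        assert hudson_fst(pop1, pop2) == pytest.approx(
            hudson_fst([s.translate(swap) for s in pop1],
                       [s.translate(swap) for s in pop2])
        )

    def test_zero_between_diversity_raises(self):
        with pytest.raises(StatError, match="undefined"):
            hudson_fst(["AAAA", "AAAA"], ["AAAA", "AAAA"])


class TestBenjaminiYekutieli:
    def test_hand_computed_toy(self):
        # c(3) = 11/6: adjusted = (0.055, 0.055, 0.0733...)
        adj = by_adjust([0.01, 0.02, 0.04])
        assert adj == pytest.approx([0.055, 0.055, 0.0733333], abs=1e-6)

    def test_all_ones_stay_one(self):
        assert by_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_single_p_value(self):
        assert by_adjust([0.03]) == pytest.approx([0.03])

    def test_out_of_range_raises(self):
        with pytest.raises(StatError):
            by_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @hsettings(max_examples=50, deadline=None)
    def test_monotone_and_at_least_raw(self, pvals):
        adj = np.array(by_adjust(pvals))
        raw = np.array(pvals)
        assert np.all(adj >= raw - 1e-12)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-12)


def _aln(seqs):
    return HaplotypeAlignment(
        seqs, [f"i{k}" for k in range(len(seqs))], ["pop1"] * len(seqs)
    )


class TestFourGamete:
    def test_forced_split_two_sites(self):
        res = four_gamete_blocks(_aln(["AA", "AT", "TA", "TT"]))
        assert res.length == 1
        assert (res.start, res.end) == (0, 1)  # leftmost of the two singletons

    def test_no_incompatibility_returns_full_locus(self):
        res = four_gamete_blocks(_aln(["AAAA", "AATT", "TTTT"]))
        assert (res.start, res.end) == (0, 4)

    def test_no_segregating_sites_notes_whole_locus(self):
        res = four_gamete_blocks(_aln(["ACGT", "ACGT"]))
        assert (res.start, res.end) == (0, 4)
        assert "no biallelic" in res.note

    def test_six_site_toy_matches_exhaustive_oracle(self):
        # single incompatible pair between columns 1 and 4 (0-based)
        seqs = [
            "AAAAAA",
            "AAAATA",
            "ATAAAA",
            "ATAATA",
        ]
        cols = np.array([list(s) for s in seqs])

        def incompatible(c1, c2):
            return len(set(zip(cols[:, c1], cols[:, c2]))) == 4

        seg = [c for c in range(6) if len(set(cols[:, c])) == 2]
        assert incompatible(1, 4)
        # oracle: exhaustively score every contiguous interval
        best = None
        for lo in range(6):
            for hi in range(lo + 1, 7):
                window = [c for c in seg if lo <= c < hi]
                if any(incompatible(a, b) for a, b in itertools.combinations(window, 2)):
                    continue
                if best is None or hi - lo > best[1] - best[0]:
                    best = (lo, hi)
        res = four_gamete_blocks(_aln(seqs))
        assert (res.start, res.end) == best == (0, 4)
        assert isinstance(res, FourGameteResult)


class TestPca:
    def test_zero_variance_error_path(self):
        g = np.array([[1, 1, 1], [1, 1, 1]])
        with pytest.raises(StatError):
            pca_genotypes(g)

    def test_separates_two_simulated_clusters(self, rng):
        a = rng.binomial(2, 0.9, size=(5, 40))
        b = rng.binomial(2, 0.1, size=(5, 40))
        coords, varfrac = pca_genotypes(np.vstack([a, b]))
        pc1 = coords[:, 0]
        assert (pc1[:5] > 0).all() != (pc1[5:] > 0).all()  # sign-invariant split
        assert np.sign(pc1[:5]).sum() in (5, -5)
        assert varfrac[0] > 0.3

    def test_variance_fractions_match_eigendecomposition_oracle(self, rng):
        g = rng.integers(0, 3, size=(6, 20))
        coords, varfrac = pca_genotypes(g)
        # independent route: eigenvalues of the scaled covariance matrix
        p = g.mean(axis=0) / 2.0
        keep = (p > 0) & (p < 1)
        x = (g[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
        lam = np.linalg.eigvalsh(x @ x.T)[::-1]
        lam = lam[lam > 1e-10]
        expected = lam / lam.sum()
        assert np.allclose(np.sort(varfrac[varfrac > 1e-10])[::-1][: len(expected)],
                           expected, atol=1e-8)
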