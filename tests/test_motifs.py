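"""PWM scoring, exact p-values, scanning, scrambling and enrichment."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from atacnet.expression import PeakGeneLink
from atacnet.motifs import (
    PWM,
    dinucleotide_scramble,
    ebox_cagctg_pwm,
    fixture_library,
    fold_enrichment,
    load_jaspar,
    load_meme,
    log_odds_score,
    motif_target_genes,
    reverse_complement,
    scan,
    score_pvalue,
    scramble,
)

BASES = "ACGT"


def uniform_pwm(width=4):
    return PWM("uni", "UNI", np.full((width, 4), 0.25), pseudocount=0.0)


def brute_force_pvalue(pwm: PWM, score: float) -> float:
    lods = pwm.log_odds()
    total = 0.0
    for kmer in itertools.product(range(4), repeat=pwm.width):
        s = sum(lods[i, b] for i, b in enumerate(kmer))
        if s >= score - 1e-9:
            total += float(np.prod([pwm.background[b] for b in kmer]))
    return total


class TestScoring:
    def test_single_informative_column_contributes_one_bit(self):
        m = np.full((4, 4), 0.25)
        m[0] = [0.5, 0.25, 0.125, 0.125]
        pwm = PWM("x", "X", m, pseudocount=0.0)
        assert log_odds_score(pwm, "AAAA") == pytest.approx(1.0)

    def test_background_matching_kmer_scores_zero(self):
        assert log_odds_score(uniform_pwm(), "ACGT") == pytest.approx(0.0)

    def test_consensus_score_equals_column_maxima_sum(self):
        rng = np.random.default_rng(0)
        m = rng.dirichlet(np.ones(4), size=6)
        pwm = PWM("x", "X", m)
        expected = float(np.log2(pwm.matrix.max(axis=1) / 0.25).sum())
        assert log_odds_score(pwm, pwm.consensus) == pytest.approx(expected)

    def test_input_validation(self):
        pwm = uniform_pwm()
        with pytest.raises(ValueError, match="length"):
            log_odds_score(pwm, "ACG")
        with pytest.raises(ValueError, match="non-ACGT"):
            log_odds_score(pwm, "ACGN")

    def test_matrix_validation(self):
        with pytest.raises(ValueError):
            PWM("x", "X", np.full((3, 4), 0.25))  # too narrow
        with pytest.raises(ValueError):
            PWM("x", "X", -np.ones((5, 4)))


class TestPvalues:
    def test_below_minimum_is_one(self):
        pwm = uniform_pwm()
        assert score_pvalue(pwm, -100.0) == 1.0

    def test_above_maximum_is_zero(self):
        pwm = uniform_pwm()
        assert score_pvalue(pwm, 100.0) == 0.0

    def test_uniform_pwm_every_kmer_ties(self):
        # all 4^4 k-mers score 0, so P(S >= 0) = 1
        assert score_pvalue(uniform_pwm(), 0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("width", [4, 5, 6])
    def test_equals_exhaustive_enumeration(self, width):
        rng = np.random.default_rng(width)
        pwm = PWM("x", "X", rng.dirichlet(np.ones(4), size=width))
        for _ in range(25):
            kmer = "".join(rng.choice(list(BASES), width))
            s = log_odds_score(pwm, kmer)
            assert score_pvalue(pwm, s) == pytest.approx(brute_force_pvalue(pwm, s), abs=1e-9)

    def test_monotone_nonincreasing(self):
        rng = np.random.default_rng(1)
        pwm = PWM("x", "X", rng.dirichlet(np.ones(4), size=6))
        grid = np.linspace(-20, 15, 200)
        ps = [score_pvalue(pwm, s) for s in grid]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_lattice_path_agrees_with_exact_on_boundary_width(self):
        # width 10 uses exact enumeration; force the lattice path on the
        # same matrix and compare at modest precision
        rng = np.random.default_rng(2)
        pwm = PWM("x", "X", rng.dirichlet(np.ones(4), size=10))
        exact = pwm._exact_distribution()
        lattice = pwm._lattice_distribution()
        for s in np.linspace(-10, 10, 21):
            pe = float(exact[1][np.searchsorted(exact[0], s - 1e-9)]) if s <= exact[0][-1] else 0.0
            pl = float(lattice[1][np.searchsorted(lattice[0], s - 1e-9)]) if s <= lattice[0][-1] else 0.0
            assert pe == pytest.approx(pl, abs=1e-3)


class TestScan:
    def test_palindromic_ebox_hits_both_strands(self):
        pwm = ebox_cagctg_pwm()
        hits = scan(pwm, {"s": "AACAGCTGAA"}, p_threshold=3e-4)
        assert [(h.offset, h.strand) for h in hits] == [(2, "+"), (2, "-")]

    def test_empty_sequences(self):
        assert scan(ebox_cagctg_pwm(), {}, p_threshold=3e-4) == []

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(3)
        pwm = PWM("x", "X", rng.dirichlet(np.full(4, 0.5), size=7))
        seq = "".join(rng.choice(list(BASES), 800))
        n_fwd = len(scan(pwm, {"s": seq}, 1e-2))
        n_rev = len(scan(pwm, {"s": reverse_complement(seq)}, 1e-2))
        assert n_fwd == n_rev

    def test_n_containing_windows_skipped(self):
        pwm = ebox_cagctg_pwm()
        hits = scan(pwm, {"s": "AACAGNTGAA"}, p_threshold=3e-4)
        assert hits == []

    def test_hits_sorted(self):
        pwm = ebox_cagctg_pwm()
        seqs = {"b": "TTCAGCTGTTTTCAGCTGTT", "a": "GGCAGCTGGG"}
        hits = scan(pwm, seqs, p_threshold=3e-4)
        keys = [(h.peak_id, h.offset, h.strand) for h in hits]
        assert keys == sorted(keys)


class TestScramble:
    def test_homopolymer_invariant(self):
        assert scramble("AAAA", 3) == "AAAA"

    def test_composition_preserved(self):
        seq = "ACGTACGTTTGCA"
        assert sorted(scramble(seq, 7)) == sorted(seq)

    def test_deterministic_and_seed_sensitive(self):
        seq = "".join(np.random.default_rng(0).choice(list(BASES), 1000))
        assert scramble(seq, 5) == scramble(seq, 5)
        assert scramble(seq, 5) != scramble(seq, 6)

    def test_dinucleotide_shuffle_preserves_dinucleotides(self):
        seq = "".join(np.random.default_rng(1).choice(list(BASES), 300))
        shuf = dinucleotide_scramble(seq, 2)
        count = lambda s: {d: sum(1 for i in range(len(s) - 1) if s[i : i + 2] == d)
                           for d in set(s[i : i + 2] for i in range(len(s) - 1))}
        assert count(shuf) == count(seq)
        assert len(shuf) == len(seq)


class TestFoldEnrichment:
    def test_zero_observed_zero_fold(self):
        pwm = fixture_library()["EBOX_ASCL1"]
        seqs = {"s": "A" * 200}
        e = fold_enrichment(pwm, seqs, seed=0)
        assert e.observed == 0
        assert e.fold == 0.0
        assert not e.enriched

    def test_implanted_motifs_flagged(self):
        # 20 peaks, one CAGCTG each, in i.i.d. uniform flanks
        rng = np.random.default_rng(4)
        pwm = ebox_cagctg_pwm()
        seqs = {}
        for i in range(20):
            flank = rng.choice(list(BASES), 300)
            off = int(rng.integers(0, 294))
            flank[off : off + 6] = list("CAGCTG")
            seqs[f"p{i}"] = "".join(flank)
        e = fold_enrichment(pwm, seqs, p_threshold=3e-4, seed=1)
        assert e.observed >= 20
        assert e.fold >= 2.0
        assert e.enriched

    def test_null_fold_near_one(self):
        # on uniform sequence with adequate expected counts the regularized
        # fold concentrates near 1
        rng = np.random.default_rng(5)
        pwm = ebox_cagctg_pwm()
        seqs = {f"p{i}": "".join(rng.choice(list(BASES), 500)) for i in range(4)}
        e = fold_enrichment(pwm, seqs, p_threshold=1e-2, seed=2)
        assert 0.5 <= e.fold < 2.0

    def test_n_shuffles_validated(self):
        with pytest.raises(ValueError):
            fold_enrichment(ebox_cagctg_pwm(), {}, n_shuffles=0)


class TestTargetGenes:
    HITS_LINKS = None

    def test_selected_genes_collected_with_evidence(self):
        pwm = ebox_cagctg_pwm()
        hits = scan(pwm, {"pk1": "AACAGCTGAA", "pk2": "TTTTTTTTTT"}, p_threshold=3e-4)
        links = [PeakGeneLink("pk1", "g1", 5), PeakGeneLink("pk1", "g2", 5),
                 PeakGeneLink("pk2", "g3", 5)]
        tg = motif_target_genes(hits, links, {"g1", "g2", "g3"})
        assert set(tg["EBOX6"]) == {"g1", "g2"}
        assert tg["EBOX6"]["g1"][0][0] == "pk1"

    def test_unselected_genes_excluded(self):
        pwm = ebox_cagctg_pwm()
        hits = scan(pwm, {"pk1": "AACAGCTGAA"}, p_threshold=3e-4)
        links = [PeakGeneLink("pk1", "g1", 5)]
        assert motif_target_genes(hits, links, set()) == {}


class TestReaders:
    JASPAR = """>MA0000.1 TESTTF
A  [ 10  0  0 10 ]
C  [  0 10  0  0 ]
G  [  0  0 10  0 ]
T  [  0  0  0  0 ]
"""

    MEME = """MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF TESTM testtf
letter-probability matrix: alength= 4 w= 4 nsites= 20 E= 0
1.0 0.0 0.0 0.0
0.0 1.0 0.0 0.0
0.0 0.0 1.0 0.0
0.0 0.0 0.0 1.0
"""

    def test_jaspar_reader(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(self.JASPAR)
        pwms = load_jaspar(path)
        assert len(pwms) == 1
        assert pwms[0].width == 4
        assert pwms[0].consensus == "ACGA"
        assert np.allclose(pwms[0].matrix.sum(axis=1), 1.0)

    def test_meme_reader(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text(self.MEME)
        pwms = load_meme(path)
        assert len(pwms) == 1
        assert pwms[0].consensus == "ACGT"
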