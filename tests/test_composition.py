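from collections import Counter

import numpy as np
import pytest

from nucadapt.composition import (
    aa_profile,
    combo_load,
    dinuc_frequencies,
    dinucleotide_contrast,
    dipeptide_contrast,
    nat_over_null_ratio,
    nuc_composition,
    ry_collapse,
)
from conftest import random_cds

COMPLEMENT = str.maketrans("ACGT", "TGCA")


class TestNucComposition:
    def test_uniform_whole(self):
        assert nuc_composition(["ACGT"]).freqs == {
            "A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25
        }

    def test_codon_position_three(self):
        comp = nuc_composition(["ATGAAA"], "codon-pos-3")
        assert comp.freqs["G"] == 0.5 and comp.freqs["A"] == 0.5

    def test_matches_index_filtered_counting(self, rng):
        seqs = [random_cds(rng, 40) for _ in range(5)]
        for k in (1, 2, 3):
            comp = nuc_composition(seqs, f"codon-pos-{k}")
            brute = Counter(
                ch for s in seqs for i, ch in enumerate(s) if i % 3 == k - 1
            )
            total = sum(brute.values())
            for nt in "ACGT":
                assert comp.freqs[nt] == pytest.approx(brute[nt] / total, abs=1e-12)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            nuc_composition([])


class TestComboLoad:
    def test_equifrequent_gc(self):
        table = nuc_composition(["ACGT"])
        assert combo_load(table, "GC") == pytest.approx(0.5)

    def test_completeness(self, rng):
        table = nuc_composition([random_cds(rng, 100)])
        assert combo_load(table, "ACGT") == pytest.approx(1.0)


class TestDinucFrequencies:
    def test_homopolymer(self):
        table = dinuc_frequencies(["AAAA"], "any")
        assert table.freqs["AA"] == 1.0 and table.counts["AA"] == 3

    def test_single_31_junction(self):
        table = dinuc_frequencies(["ATGAAA"], "3-1")
        assert table.counts["GA"] == 1 and table.total == 1

    def test_matches_brute_force_enumeration(self, rng):
        seqs = [random_cds(rng, 30) for _ in range(4)]
        offsets = {"1-2": (0, 1), "2-3": (1, 2), "3-1": (2, 3)}
        for junction, (a, b) in offsets.items():
            table = dinuc_frequencies(seqs, junction)
            brute = Counter(
                s[i + a] + s[i + b]
                for s in seqs
                for i in range(0, len(s) - b - (a == 2) * 0, 3)
                if i + b < len(s)
            )
            assert table.counts == {d: brute.get(d, 0) for d in table.counts}

    def test_no_cross_gene_pairs(self, rng):
        """Positional tables are unchanged by gene concatenation order."""
        a, b = random_cds(rng, 30), random_cds(rng, 30)
        t1 = dinuc_frequencies([a, b], "3-1")
        t2 = dinuc_frequencies([b, a], "3-1")
        assert t1.counts == t2.counts


class TestContrast:
    def test_iid_uniform_limit(self, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 10**6)])
        dct = dinucleotide_contrast(dinuc_frequencies([seq], "any"))
        for v in dct.contrasts.values():
            assert v == pytest.approx(1.0, abs=0.02)

    def test_hand_computed_acac(self):
        dct = dinucleotide_contrast(dinuc_frequencies(["ACAC"], "any"))
        assert dct.contrasts["AC"] == pytest.approx((2 / 3) / 0.25, abs=1e-12)

    def test_markov_round_trip(self):
        """First-order text with a prescribed contrast is recovered."""
        from nucadapt.synth import markov_sequence

        target = np.ones((4, 4))
        target[0, 2] = 1.3  # ApG
        seq = markov_sequence(target, 10**6, np.random.default_rng(8))
        dct = dinucleotide_contrast(dinuc_frequencies([seq], "any"))
        assert dct.contrasts["AG"] == pytest.approx(1.3, abs=0.02)

    def test_reverse_complement_symmetry_double_strand(self, rng):
        """DCT(ApG) = DCT(CpT) exactly when both strands are pooled."""
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3000)])
        rc = seq.translate(COMPLEMENT)[::-1]
        dct = dinucleotide_contrast(dinuc_frequencies([seq, rc], "any"))
        assert dct.contrasts["AG"] == pytest.approx(dct.contrasts["CT"], abs=1e-12)
        assert dct.contrasts["AA"] == pytest.approx(dct.contrasts["TT"], abs=1e-12)


class TestRYCollapse:
    def test_uniform(self, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 10**5)])
        ry = ry_collapse(dinuc_frequencies([seq], "any"))
        for v in ry.contrasts.values():
            assert v == pytest.approx(1.0, abs=0.05)

    def test_all_purine(self):
        ry = ry_collapse(dinuc_frequencies(["AGAGAG"], "any"))
        assert ry.counts["RpR"] == 5
        assert ry.counts["RpY"] == 0

    def test_pooled_counts_additive(self, rng):
        seq = random_cds(rng, 100)
        table = dinuc_frequencies([seq], "any")
        ry = ry_collapse(table)
        members = {"RpR": ["AA", "AG", "GA", "GG"], "YpY": ["CC", "CT", "TC", "TT"],
                   "RpY": ["AC", "AT", "GC", "GT"], "YpR": ["CA", "CG", "TA", "TG"]}
        for cls, dins in members.items():
            assert ry.counts[cls] == sum(table.counts[d] for d in dins)


class TestRatio:
    def test_trivial_values(self):
        assert nat_over_null_ratio(1.0, 1.0) == 1.0
        assert nat_over_null_ratio(0.30, 0.24) == pytest.approx(1.25)

    def test_zero_null_raises(self):
        with pytest.raises(ZeroDivisionError):
            nat_over_null_ratio(1.0, 0.0)


class TestProteinComposition:
    def test_simple_profile(self):
        prof = aa_profile(["MKMK"])
        assert prof.freqs["M"] == 0.5 and prof.freqs["K"] == 0.5

    def test_class_totals_sum_to_one(self, rng):
        from nucadapt.genetics import AA_LETTERS

        prot = "".join(np.array(list(AA_LETTERS))[rng.integers(0, 20, 5000)])
        prof = aa_profile([prot])
        assert sum(prof.class_freqs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_profile_matches_counting_oracle(self, rng):
        from nucadapt.genetics import AA_LETTERS

        prots = ["".join(np.array(list(AA_LETTERS))[rng.integers(0, 20, 200)])
                 for _ in range(5)]
        prof = aa_profile(prots)
        brute = Counter("".join(prots))
        total = sum(brute.values())
        for a in AA_LETTERS:
            assert prof.freqs[a] == pytest.approx(brute[a] / total, abs=1e-12)

    def test_dipeptide_iid_contrasts_near_one(self, rng):
        from nucadapt.genetics import AA_LETTERS

        # 4e6 residues: each of the 400 cells holds ~10^4 counts, so even
        # the worst of the 400 contrasts sits within ~4.5 sd = 0.045 of 1
        prot = "".join(np.array(list(AA_LETTERS))[rng.integers(0, 20, 4 * 10**6)])
        contrasts, classes = dipeptide_contrast([prot])
        assert max(abs(v - 1) for v in contrasts.values()) < 0.05
        assert max(abs(v - 1) for v in classes.values()) < 0.01

    def test_degenerate_two_residue_protein(self):
        contrasts, _ = dipeptide_contrast(["MM"])
        assert contrasts["MM"] == pytest.approx(1.0)
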