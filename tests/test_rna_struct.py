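import numpy as np
import pytest

from nucadapt.genome_io import GenomeMetadata
from nucadapt.rna_struct import (
    FoldedWindow,
    dshfld_normalize,
    energy_summaries,
    fold_windows,
    phase_of_pair,
    phase_spectrum,
    region_purine_metrics,
    sliding_windows,
    stem_loop_annotate,
    window_from_structure,
)
from nucadapt.synth import SyntheticSpec, synth_folded_windows
from nucadapt.wstats import loop_stem_wilcoxon, ogt_correlation
from conftest import random_cds


class TestWindows:
    def test_exact_length_single_window(self):
        assert len(sliding_windows("A" * 50)) == 1

    def test_step_arithmetic(self):
        wins = sliding_windows("A" * 60, step=10)
        assert [s for s, _ in wins] == [0, 10]

    def test_short_cds_no_windows(self):
        assert sliding_windows("A" * 49) == []

    def test_codon_position_from_absolute_coordinates(self):
        w = FoldedWindow(gene_id="g", start=6, sequence="A" * 50, structure="." * 50, energy=0.0)
        # CDS index 7 = window index 1 -> codon position 2
        assert w.codon_position(1) == 2
        w2 = FoldedWindow(gene_id="g", start=10, sequence="A" * 50, structure="." * 50, energy=0.0)
        assert w2.codon_position(0) == (10 % 3) + 1


class TestPhaseRule:
    @pytest.mark.parametrize(
        "pi,pj,phase", [(2, 3, "I"), (1, 1, "I"), (1, 3, "II"), (2, 2, "II"),
                        (3, 3, "III"), (1, 2, "III"), (2, 1, "III"), (3, 1, "II")]
    )
    def test_sum_mod_three_rule(self, pi, pj, phase):
        assert phase_of_pair(pi, pj) == phase

    def test_rejects_bad_positions(self):
        with pytest.raises(ValueError):
            phase_of_pair(0, 2)

    def test_codon_aligned_stem_is_pure_phase_three(self):
        """A stem pairing position 3 with position 3 throughout -> 100% III."""
        # 12 codons; pair (3k+2, 47-3k-...) constructed explicitly
        n = 48
        seq = list("AAA" * 8 + "UUU" * 8)
        pairs = []
        for k in range(8):
            i = 3 * k + 2          # codon position 3
            j = n - 1 - 3 * k      # also codon position 3 (n multiple of 3)
            pairs.append((i, j))
        w = FoldedWindow(
            gene_id="g", start=0, sequence="".join(seq),
            structure="", energy=0.0, pairs=pairs,
        )
        phases = {w.pair_phase(i, j) for i, j in pairs}
        assert phases == {"III"}

    def test_label_format(self):
        w = FoldedWindow(
            gene_id="g", start=0, sequence="AUGGGC" + "A" * 44,
            structure="." * 50, energy=0.0, pairs=[(2, 4)],
        )
        # G at codon position 3 paired with G at codon position 2
        assert w.pair_label(2, 4) == "G3•2G"
        assert w.pair_phase(2, 4) == "I"


class TestPhaseSpectrum:
    def test_single_pair(self):
        w = FoldedWindow(
            gene_id="g", start=0, sequence="AAGAU" + "A" * 45,
            structure="." * 50, energy=0.0, pairs=[(2, 4)],
        )
        spec = phase_spectrum([w])
        assert spec.counts["I"]["G3•2U"] == 1
        assert spec.total_pairs == 1

    def test_totals_conserved(self, rng):
        cds = random_cds(rng, 40)
        windows = fold_windows(cds, max_windows=3)
        spec = phase_spectrum(windows)
        assert spec.total_pairs == sum(w.n_pairs for w in windows)


class TestStemLoop:
    def test_all_dots(self):
        w = window_from_structure("g", 0, "A" * 50, "." * 50)
        assert stem_loop_annotate(w) == ["loop"] * 50

    def test_hairpin_counts(self):
        w = window_from_structure("g", 0, "GGGAAAACCC" + "A" * 40, "(((....)))" + "." * 40)
        labels = stem_loop_annotate(w)
        assert labels.count("stem") == 6
        assert labels.count("loop") == 44

    def test_conservation(self, rng):
        cds = random_cds(rng, 30)
        for w in fold_windows(cds, max_windows=2):
            labels = stem_loop_annotate(w)
            assert len(labels) == 50


class TestRegionMetrics:
    def test_loop_apg_hand_count(self):
        # hairpin whose loop reads AGAG: ApG in 2 of 3 adjacent loop pairs
        w = window_from_structure("g", 0, "GGGGAGAGCCCC", "((((....))))")
        m = region_purine_metrics([w], "loop")
        assert m.apg_frequency == pytest.approx(2 / 3)
        assert m.ag_fraction == 1.0
        assert m.ry_ratio is None  # zero pyrimidines, flagged

    def test_planted_purine_gap_recovered(self):
        """Loop 0.56 / stem 0.50 construction recovers both means."""
        spec = SyntheticSpec(windows_per_genome=40)
        rng = np.random.default_rng(21)
        all_loop, all_stem = [], []
        for k in range(50):
            meta = GenomeMetadata(genome_id=f"g{k}", domain="Bacteria", ogt=40.0)
            wins = synth_folded_windows(spec, meta, rng)
            all_loop.append(region_purine_metrics(wins, "loop").ag_fraction)
            all_stem.append(region_purine_metrics(wins, "stem").ag_fraction)
        assert np.mean(all_loop) == pytest.approx(0.56, abs=0.01)
        assert np.mean(all_stem) == pytest.approx(0.50, abs=0.01)
        assert loop_stem_wilcoxon(all_loop, all_stem) < 0.01

    def test_codon_class_assignment_majority(self):
        # one codon fully in stem: GGA -> GGR
        seq = "GGGGGAAAACCCCC" + "A" * 36
        struct = "(((((....)))))" + "." * 36
        w = window_from_structure("g", 0, seq, struct)
        m = region_purine_metrics([w], "stem")
        assert m.codon_class_freqs["GGR"] > 0


class TestEnergies:
    def test_energy_per_pair(self):
        w = FoldedWindow(gene_id="g", start=0, sequence="A" * 50,
                         structure="." * 50, energy=-6.0,
                         pairs=[(0, 10), (1, 9), (2, 8)])
        e_sg, e_bp = energy_summaries([w])
        assert e_sg == -6.0 and e_bp == -2.0

    def test_unpaired_windows(self):
        w = FoldedWindow(gene_id="g", start=0, sequence="A" * 50,
                         structure="." * 50, energy=0.0)
        e_sg, e_bp = energy_summaries([w])
        assert e_sg == 0.0 and e_bp is None

    def test_ebp_anticorrelates_with_ogt_when_gc_rises(self):
        """GC-richer stems at higher OGT give lower energy per pair."""
        spec = SyntheticSpec(n_genomes=40, windows_per_genome=12)
        rng = np.random.default_rng(5)
        ogts = spec.ogts()[:40]
        ebps, kept = [], []
        for k, ogt in enumerate(ogts):
            meta = GenomeMetadata(genome_id=f"g{k}", domain="Archaea", ogt=float(ogt))
            g = 0.3 + 0.005 * (ogt - spec.ogt_min)
            wins = synth_folded_windows(spec, meta, rng, stem_gc=g)
            _, e_bp = energy_summaries(wins)
            ebps.append(e_bp)
            kept.append(ogt)
        res = ogt_correlation(ebps, kept)
        assert res.r < -0.5

    def test_dshfld_normalize(self):
        assert dshfld_normalize(-4.0, -2.0) == 2.0
        assert dshfld_normalize(3.0, 3.0) == 1.0
        with pytest.raises(ZeroDivisionError):
            dshfld_normalize(1.0, 0.0)
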