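import numpy as np
import pytest
from scipy import stats

from nucadapt.composition import (
    dinuc_frequencies,
    dinucleotide_contrast,
    gc3,
    nuc_composition,
)
from nucadapt.genetics import translate_cds
from nucadapt.genome_io import classify_thermal_group
from nucadapt.synth import (
    BASE_AA_FREQS,
    ContrastFitError,
    SyntheticSpec,
    aa_frequencies_for,
    back_translate_biased,
    calibrate_apg_weight,
    fit_markov_to_contrasts,
    markov_sequence,
    measure_apg_dct31,
    synth_collection,
    synth_metadata,
    synth_proteome,
    synth_structural_rna,
)


class TestMetadata:
    def test_even_ogt_grid(self):
        spec = SyntheticSpec(n_genomes=5, ogt_min=10, ogt_max=90)
        metas = synth_metadata(spec, np.random.default_rng(0))
        assert [m.ogt for m in metas] == [10, 30, 50, 70, 90]

    def test_zero_aerobe_fraction(self):
        spec = SyntheticSpec(n_genomes=10, aerobe_fraction=0.0)
        metas = synth_metadata(spec, np.random.default_rng(0))
        assert all(m.oxygen == "anaerobic" for m in metas)

    def test_oxygen_independent_of_thermal_group(self):
        """Planted orthogonality: aerobicity x thermal group independence."""
        spec = SyntheticSpec(n_genomes=500)
        metas = synth_metadata(spec, np.random.default_rng(42))
        groups = sorted({classify_thermal_group(m.ogt) for m in metas})
        table = np.array(
            [
                [
                    sum(
                        1
                        for m in metas
                        if classify_thermal_group(m.ogt) == g and m.oxygen == oxy
                    )
                    for g in groups
                ]
                for oxy in ("aerobic", "anaerobic")
            ]
        )
        res = stats.chi2_contingency(table)
        assert res.pvalue > 0.01


class TestProteome:
    def test_zero_slope_flat_composition(self):
        spec = SyntheticSpec(t2_trend_slope=0.0, t2_noise_sd=0.0)
        f_cold = aa_frequencies_for(spec, 10.0)
        f_hot = aa_frequencies_for(spec, 95.0)
        assert np.allclose(f_cold, f_hot)

    def test_sampled_frequencies_match_target(self):
        spec = SyntheticSpec(genes_per_genome=400, t2_noise_sd=0.0)
        metas = synth_metadata(spec, np.random.default_rng(1))
        prot = synth_proteome(spec, metas[30], np.random.default_rng(2))
        joined = "".join(prot)
        target = aa_frequencies_for(spec, metas[30].ogt)
        from nucadapt.genetics import AA_LETTERS

        for k, a in enumerate(AA_LETTERS):
            assert joined.count(a) / len(joined) == pytest.approx(
                target[k], abs=0.005
            )


class TestBackTranslation:
    def test_translation_round_trip(self):
        spec = SyntheticSpec()
        metas = synth_metadata(spec, np.random.default_rng(3))
        rng = np.random.default_rng(4)
        prot = synth_proteome(spec, metas[0], rng)[0]
        cds = back_translate_biased(prot, metas[0], spec, rng)
        assert translate_cds(cds) == prot

    def test_neutral_settings_give_half_gc3(self):
        spec = SyntheticSpec(gc3_aerobe_offset=0.0)
        metas = synth_metadata(spec, np.random.default_rng(5))
        rng = np.random.default_rng(6)
        prots = synth_proteome(spec, metas[10], rng)
        cds = [back_translate_biased(p, metas[10], spec, rng) for p in prots]
        # Met/Trp contribute fixed G3, so slightly above one half
        assert gc3(cds) == pytest.approx(0.5, abs=0.03)

    def test_aerobe_offset_recovered_as_gap(self):
        spec = SyntheticSpec(genes_per_genome=60)
        metas = synth_metadata(spec, np.random.default_rng(7))
        rng = np.random.default_rng(8)
        aer = next(m for m in metas if m.oxygen == "aerobic")
        ana = next(m for m in metas if m.oxygen == "anaerobic")
        gc_aer = gc3(
            [back_translate_biased(p, aer, spec, rng) for p in synth_proteome(spec, aer, rng)]
        )
        gc_ana = gc3(
            [back_translate_biased(p, ana, spec, rng) for p in synth_proteome(spec, ana, rng)]
        )
        assert gc_aer - gc_ana == pytest.approx(0.20, abs=0.02)

    def test_apg_boost_round_trip(self):
        """Junction resampling realizes the requested 3-1 DCT(ApG)."""
        spec = SyntheticSpec(apg_boost_31=1.3, genes_per_genome=60)
        metas = synth_metadata(spec, np.random.default_rng(9))
        rng = np.random.default_rng(10)
        meta = metas[0]
        t = spec.gc3_base + (spec.gc3_aerobe_offset if meta.oxygen == "aerobic" else 0)
        w = calibrate_apg_weight(spec, rng, gc3_probability=t)
        prots = synth_proteome(spec, meta, rng)
        cds = [back_translate_biased(p, meta, spec, rng, apg_weight=w) for p in prots]
        assert measure_apg_dct31(cds) == pytest.approx(1.3, abs=0.03)
        assert all(translate_cds(c) == p for c, p in zip(cds, prots))


class TestMarkov:
    def test_identity_contrasts_give_iid_text(self):
        seq = markov_sequence(np.ones((4, 4)), 10**6, np.random.default_rng(11))
        dct = dinucleotide_contrast(dinuc_frequencies([seq], "any"))
        assert max(abs(v - 1) for v in dct.contrasts.values()) < 0.02

    def test_target_apa_recovered(self):
        target = np.ones((4, 4))
        target[0, 0] = 1.25
        seq = markov_sequence(target, 10**6, np.random.default_rng(12))
        dct = dinucleotide_contrast(dinuc_frequencies([seq], "any"))
        assert dct.contrasts["AA"] == pytest.approx(1.25, abs=0.03)

    def test_stationarity_of_halves(self):
        target = SyntheticSpec().ncdna_contrast_matrix()
        seq = markov_sequence(target, 200_000, np.random.default_rng(13))
        h1 = nuc_composition([seq[:100_000]]).freqs
        h2 = nuc_composition([seq[100_000:]]).freqs
        assert all(abs(h1[n] - h2[n]) < 0.01 for n in "ACGT")

    def test_infeasible_target_raises(self):
        target = np.ones((4, 4))
        target[0, :] = 5.0  # a whole row that high cannot row-normalize
        with pytest.raises((ContrastFitError, ValueError)):
            fit_markov_to_contrasts(target)


class TestStructuralRNA:
    def test_zero_slope_flat_gc(self):
        spec = SyntheticSpec(rna_gc_slope=0.0, rna_gc_noise_sd=0.0)
        metas = synth_metadata(spec, np.random.default_rng(14))
        rng = np.random.default_rng(15)
        gc_cold = nuc_composition(
            synth_structural_rna(spec, metas[0], rng, "rrna")
        ).freqs
        gc_hot = nuc_composition(
            synth_structural_rna(spec, metas[-1], rng, "rrna")
        ).freqs
        assert abs((gc_cold["G"] + gc_cold["C"]) - (gc_hot["G"] + gc_hot["C"])) < 0.02

    def test_gc_trend_recovered(self):
        from nucadapt.wstats import ogt_correlation

        spec = SyntheticSpec(n_genomes=40)
        metas = synth_metadata(spec, np.random.default_rng(16))
        rng = np.random.default_rng(17)
        gc, ogts = [], []
        for m in metas:
            comp = nuc_composition(synth_structural_rna(spec, m, rng, "rrna")).freqs
            gc.append(comp["G"] + comp["C"])
            ogts.append(m.ogt)
        assert ogt_correlation(gc, ogts).r > 0.6

    def test_palindrome_folds_into_stem(self):
        from nucadapt.fold import fold_mfe, validate_structure

        spec = SyntheticSpec(trna_count=1)
        metas = synth_metadata(spec, np.random.default_rng(18))
        rng = np.random.default_rng(19)
        seq = synth_structural_rna(spec, metas[5], rng, "trna")[0]
        structure, energy = fold_mfe(seq[:60])
        pairs = validate_structure(seq[:60].replace("T", "U"), structure)
        assert len(pairs) >= 4


class TestDeterminism:
    def test_identical_seed_identical_collection(self):
        spec = SyntheticSpec(
            n_genomes=4, genes_per_genome=5, gene_length_codons_mean=80,
            ncdna_segments=2, ncdna_length=200, trna_count=2, rrna_count=1,
            rrna_length=300,
        )
        a = synth_collection(spec, 31)
        b = synth_collection(spec, 31)
        assert [g.cds for g in a] == [g.cds for g in b]
        assert [g.ncdna for g in a] == [g.ncdna for g in b]
        assert [g.metadata for g in a] == [g.metadata for g in b]
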