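# Methods

This note records the models behind each module, the defaults and why,
and the choices made where the design was genuinely open.

## Ingestion and cohorts

A genome is four sequence partitions (CDS, non-coding DNA, tRNA, rRNA)
plus metadata: domain (Archaea/Bacteria), OGT in °C, oxygen class
(aerobic / anaerobic / facultative / microaerophilic / unknown) and
genome size.  Thermal groups use left-closed OGT bounds 24, 50, 80 °C
(psychrophile < 24 ≤ mesophile < 50 ≤ thermophile < 80 ≤
hyperthermophile).  OGT-correlation cohorts drop genomes with OGT exactly
26, 30 or 37 °C; those bins are dominated by host-associated organisms
whose composition tracks the host, not the environment.  Oxygen cohorts
keep only the two unambiguous classes.

Translation uses NCBI table 11 by default (prokaryotic context); other
tables are accepted.  Records containing ambiguity codes are dropped
whole with a logged count — substituting bases would silently distort
dinucleotide statistics.  CDS with internal stops are rejected by default
(config to truncate), since the null models assume a clean protein image.
How intergenic ncDNA segments were delimited is outside the ingestion
contract: they are taken as given.

## Null models

All three generators preserve the protein exactly and are bit-reproducible
under a fixed seed.

* **NCB** draws each codon uniformly from its synonymous family.
* **Shfld** draws from the family weighted by genome-wide codon usage
  (counts pooled over all CDS, normalized within families; an amino acid
  absent from the genome falls back to uniform, logged).  Positional
  nucleotide composition and 1-2/2-3 dinucleotides are preserved in
  expectation; 3-1 junction structure is destroyed.
* **dShfld** is a constrained swap sampler: propose exchanging the codons
  at two positions encoding the same amino acid; accept iff the multiset
  of dinucleotides at the (≤ 4) affected codon junctions is unchanged.
  This makes the protein, the per-amino-acid codon multiset (hence all
  positional nucleotide compositions and within-codon dinucleotides) and
  the global dinucleotide count vector *exact* invariants.  The sampler
  approximates, but does not guarantee, uniformity over the constrained
  space — adequate for a null model used through averages.  One sweep is
  one proposal per codon; the default 30 sweeps moves essentially every
  gene of realistic length (same-codon swaps are no-ops and excluded from
  mobility accounting; a gene with no accepted move is returned unchanged
  with a logged warning).

## Composition and contrasts

Genome-level frequencies are ratios of summed counts pooled across genes
(never means of per-gene frequencies), and paired counting never crosses
gene boundaries.  The dinucleotide contrast is
`DCT(XpY) = f(XpY)/(m1(X)·m2(Y))`.  The marginals are the whole-sequence
composition for unrestricted counting and the full codon-position
compositions for junction classes (for 3-1: position-3 and position-1
compositions).  This choice makes DCT exactly 1 in the independence limit
and keeps the reverse-complement identity DCT(ApG) = DCT(CpT) exact when
both strands are pooled.  Dinucleotides are counted on the sense strand
only.  R/Y (purine/pyrimidine) tables pool *counts* before re-contrasting,
so they are genuine two-letter contrasts rather than averages of
four-letter ones.  Dipeptide contrasts use the same construction over the
20-letter alphabet, with h/p/c class tables (hydrophobic CFILMPVW, polar
AGHNQSTY, charged DEKR) pooled at count level.  Entries with a zero
marginal are reported absent, not zero.

## Weighted statistics

Weighted variance uses the frequency-weight convention: weights normalized
to sum to N, `s² = Σ wᵢ(xᵢ−x̄_w)²/(N−1)`.  This is the convention under
which every weighted statistic reduces *exactly* to its unweighted
counterpart at equal weights, which the test suite enforces at 1e-10
against textbook formulas.  The two-sample test is Welch's construction on
weighted moments with genome counts as the Nᵢ; degrees of freedom by
Welch–Satterthwaite.  All p-values are two-sided.  OGT correlations are
unweighted Pearson r (group weighting belongs to meta-genome averaging,
not to correlation), with p from `t = r√((n−2)/(1−r²))`.  The paired
loop-vs-stem comparison uses the Wilcoxon signed-rank test with Pratt
zero handling; the all-zero-difference degenerate case returns p = 1,
flagged.  Zero-variance group comparisons return t = 0, p = 1 when means
agree and a flagged degenerate p → 0 otherwise.  No multiple-testing
correction is applied: tables report raw tiers, as is conventional for
this kind of descriptive comparative screen, and readers should treat
borderline tiers accordingly.

## RNA folding

The internal engine is a deliberately small nearest-neighbour MFE model,
not a Turner-parameter thermodynamic engine.  Energy of a structure is a
sum over its loop decomposition:

* pair strengths `s(G:C) = s(C:G) = 3.0`, `s(A:U) = s(U:A) = 2.0`,
  `s(G:U) = s(U:G) = 1.0` kcal/mol;
* each stack of adjacent pairs contributes `−(s_outer + s_inner)/2`;
* penalties: hairpin loop +3.0, internal loop/bulge +2.0, multiloop +3.0;
  exterior bases free;
* hairpin loops ≥ 3 unpaired bases; internal loops ≤ 30 unpaired in
  total; no dangles or coaxial terms; sequences ≤ 200 bases.

These constants are exported so that the test oracle (exhaustive
enumeration of all valid structures at length ≤ 14, scored by an
independent decomposition) shares the model while sharing no code path.
The dynamic program is exact for this model; co-optimal ties are resolved
by a fixed deterministic traceback preference (stack, hairpin, internal,
multiloop; smallest branch first), which keeps outputs reproducible.  The
temperature argument is accepted for engine-contract parity and logged;
only an external folder uses it physically.  The adapter parses the
standard dot-bracket-plus-energy output dialect and validates structures
against the same pairing rules.  The model reproduces the comparative
behaviour that the analysis needs — GC-richer stems fold lower, wobble
pairs allowed but weak — and is not a quantitative free-energy predictor.

Windows are 50 bases (windows of 100–150 behave qualitatively alike in
this kind of analysis); the stride defaults to 10 and is configurable.
Codon positions of window bases are always computed from absolute CDS
coordinates.  Phase of a pair at codon positions (p_i, p_j) is
`(p_i+p_j) mod 3`: residue 2 → Phase I, 1 → II, 0 → III, the unique rule
consistent with position-k-facing-position-k.  Region metrics label every
paired base stem and every unpaired base loop (hairpin, bulge, interior
and exterior alike); codons are assigned to the region holding ≥ 2 of
their 3 bases; ApG frequencies count only adjacent same-region pairs.
Genome summaries pool over all folded windows of the genome (per-genome
pooling, not per-gene).  ⟨E_sg⟩ is the mean window energy; ⟨E_bp⟩ the
mean of energy/pairs over windows with ≥ 1 pair.  mRNA-level statistics
are normalized by the same statistic on dShfld controls of the same genes.

## OGT predictors

Amino-acid frequencies are standardized per letter across genomes ((n−1)
sd; constant letters excluded, logged).  A predictor set is scored by the
summed z-scores and selected by Pearson r with OGT — exhaustive over a
restricted alphabet (the 2²⁰ full search is intractable) or greedy
forward selection by default, ties broken lexicographically.  A linear
regression of OGT on score provides prediction; Archaea and Bacteria are
fitted separately when both are present in sufficient numbers.

## Synthetic study conditions

The generator's defaults define the study conditions for all recovery
tests; they are chosen once and documented, not tuned:

* 60 genomes, OGT evenly spread over 5–100 °C; 25% Archaea; oxygen labels
  assigned independently of OGT (aerobe fraction 0.5) so temperature and
  aerobicity signals are orthogonal and separable downstream.
* 80 genes per genome, lengths ~N(250, 40) codons (min 60): large enough
  that per-genome sampling noise (≈0.004 on GC3) is well below the
  planted effects, small enough for desk-scale runtimes.
* Proteomes i.i.d. from average proteome frequencies with the total
  frequency of the strong hydrophobes F, I, L, M, V (exactly the residues
  with thymine at codon position 2) moving at +0.0008/°C around the
  52.5 °C midpoint, plus per-genome scatter sd 0.0228.  These two numbers
  set a planted population correlation r(T2, OGT) ≈ 0.70, computed — not
  asserted — by `SyntheticSpec.planted_t2_r`.
* Back-translation draws the third base G/C with probability 0.50, raised
  by +0.20 for aerobes; within the chosen G/C or A/T subset codons are
  uniform.  Met and Trp have fixed G3, so the realized cohort gap is
  marginally below the offset (≈0.19–0.20).  The optional ApG junction
  bias redraws codons right-to-left, up-weighting A-ending codons before
  G-starting codons by a factor calibrated on a pilot proteome (scalar
  root-finding) so the realized 3-1 DCT(ApG) equals the requested value;
  an analytic solution is confounded by Leu/Arg/Ser, whose first base
  co-varies with the synonymous choice.  Default off (1.0): the
  acceptance-grade temperature and aerobicity conditions do not need it,
  and the round-trip is exercised explicitly where it is the subject.
* ncDNA is first-order Markov text realizing a target contrast matrix
  (ApA = TpT = 1.15 by default).  A full 16-entry DCT target is
  over-determined for a stationary chain — if 15 entries sit at exactly 1
  the 16th cannot deviate, since the joint probabilities would sum past
  1 — so the chain is fitted by least squares over row-softmax transition
  parameters with targeted entries weighted 10×, plus a softly weighted
  uniform-composition anchor that excludes degenerate chains avoiding a
  nucleotide.  Targeted contrasts are realized to < 0.005; untargeted
  entries absorb a stationarity-forced compensation of up to ~0.05.
* tRNA/rRNA-like sequences are i.i.d. with GC = 0.45 + 0.002/°C·(OGT −
  52.5) plus per-genome sd 0.04 (planted r ≈ 0.8); tRNAs carry an 8-base
  palindromic insert so folding them yields a stem.
* Constructed stem-loop windows plant the loop-vs-stem purine gap: loops
  i.i.d. with purine probability 0.56; stems are admissible base pairs,
  which *forces* a stem purine fraction of 0.5 (every allowed pair holds
  exactly one purine) — the same mechanism that pins real stem purine
  loads near one half.

What the generator does not emulate: phylogenetic correlation between
genomes, gene structure (operons, UTRs, strand asymmetry), realistic
codon-usage tables, amino-acid interactions beyond i.i.d. draws, and any
coupling between the planted signals.  Passing recovery tests therefore
demonstrates that the pipeline measures what it claims to measure at
realistic magnitudes and sample sizes — not that real genomes behave like
the generator.

## Problem sizes

The default test suite and the acceptance script run at the sizes above:
100 CDS for exact null-model invariants, 10⁶-base texts for contrast
calibration, 10⁴ null replicates for type-I error, 200 sequences ≤ 14 nt
for the folding oracle, one 60-genome collection for end-to-end recovery
and 100 frequency-level replicates for predictor recovery.  Pipeline
folding is capped per genome by configuration (`max_fold_genes`,
`max_fold_windows`); the internal engine folds a 50-base window in tens
of milliseconds, so genome-scale folding studies should raise those caps
deliberately or plug in an external folder.

## Known limitations

* The folding model is comparative, not thermodynamic; absolute energies
  are not Turner energies, and ⟨E⟩–OGT correlations should be read as
  rank-level signals.
* dShfld samples the constrained space non-uniformly; statistics that are
  sensitive to fine structure of the null ensemble (beyond means) should
  be interpreted with care.
* The weighted Welch test treats genome counts as sample sizes; weights
  enter through the moments only.
* Exhaustive predictor search is feasible only for restricted alphabets;
  greedy selection carries no optimality guarantee (the suite checks it
  never beats exhaustive, not that it matches it).
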