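# Methods

This note documents the models and procedures `mitosrna` implements, the
parameters that matter, what the synthetic data does and does not
emulate, and the numerical choices made where the design was open.

## Read cleaning

Raw reads are fixed-length sequencer tags (50 nt by default) of the form
*insert + 3′ adapter + padding*. Cleaning proceeds in a fixed order with
exact accounting (`n_clean = n_raw − Σ removals`, enforced, never
approximated):

1. **5′ contamination.** A read containing the 5′ adapter anywhere with
   ≤ 1 substitution is an adapter-ligation artefact and is discarded. A
   pigeonhole prefilter (one exact adapter half must occur) keeps the
   scan linear in practice.
2. **3′ junction.** The 3′ adapter is located as the best
   prefix-of-adapter match: a junction is valid with ≥ 6 exactly
   matching bases, or ≥ 10 bases with one mismatch; offsets are scored
   by matches − mismatches, ties to the leftmost. Reads with no valid
   junction are discarded — without the junction the insert's 3′
   boundary is undefined.
3. **Filters.** Inserts < 18 nt or > 30 nt (the size-selected range),
   inserts containing N (the only quality rule applied; no quality-score
   trimming), and poly-A degradation products are removed. The poly-A
   rule is quantified here as *A fraction ≥ 0.75 or a 3′ run of ≥ 8 A*
   — the filter itself is standard but no published threshold exists, so
   the two-sided rule catches both full-length poly-A reads and A-tailed
   fragments.
4. **Collapsing.** Identical inserts collapse to unique tags
   (descending count, then lexicographic; stable ids), preserving the
   unique-vs-total distinction used throughout the summaries.

## Mapping

A hash index stores every k-mer (default k = 9) of the forward strand.
For a tag of length ≥ 18, the first and last 9-mers cannot overlap, so
any placement with ≤ 1 substitution matches one seed exactly
(pigeonhole); candidates are verified base by base. Both strands are
searched (the reverse strand by seeding the tag's reverse complement);
substitutions only, no indels — consistent with small-RNA practice where
reads are short and contiguous. *All* hits are reported and each record
carries the tag's genome-wide multiplicity for copy-number filtering
downstream. Default `max_mismatch = 1`: the analyses are defined on
"perfect match or one mismatch" alignments, and that rule takes
precedence over stricter aligner flag combinations. Coordinates are
0-based half-open in memory, 1-based closed in GFF/TSV output.

## Annotation cascade

Feature overlaps are collected across **all** of a tag's hits: an
overlap requires ≥ 50% of the tag length inside the feature (robust to
1–2 nt boundary noise; no published threshold exists) and strand
agreement unless the feature is unstranded. The tag's single category is
the highest-priority class with evidence, under

    rRNA > tRNA > snRNA > snoRNA > srpRNA > scRNA
         > known miRNA > piRNA > repeat > exon > intron > unannotated

with Genbank preferred over Rfam as the rRNA source. The published
cascade names only `rRNA (Genbank > Rfam) > known miRNA > repeat > exon
> intron`; the remaining small structural RNA classes are slotted
between rRNA and known miRNA (they are rRNA-like library components,
not repeat-derived), and the full order is a configurable total order.

Known-miRNA identity is sequence-based, not positional: a tag is called
mature (or star) when it aligns to the reference sequence with ≤ 1
mismatch and its 5′ end within ± 2 nt of the reference 5′ end (isomiR
tolerance); tags matching only a precursor body are `precursor_only`
and count as miRNA in the cascade. Ambiguous multi-reference tags report
all matches with a deterministic primary (best match type, then
lexicographically smallest id) so tables are reproducible. piRNA calls
are exact-sequence membership in the supplied set.

## Differential association

Levels are transcripts per million, `TPM = count·10⁶ / library total`;
a level of zero is replaced by 0.01 **after** normalisation (raw counts
entering the test are never substituted). Fold change is log₂ of the
library-2 : library-1 TPM ratio; ratio > 2 classifies "up", < 1/2
"down".

The exact test conditions on the pair of counts: given x in a library
of N₁ and a common underlying level, Y in a library of N₂ follows

    p(y | x) = (N₂/N₁)^y (x+y)! / (x! y! (1 + N₂/N₁)^{x+y+1}),

the negative-binomial NB(x+1, N₁/(N₁+N₂)) distribution. Tails are
therefore regularised incomplete beta functions, evaluated with
`scipy.special.betainc` — exact and stable for counts far beyond 10⁵
(an explicit log-gamma summation is kept in the test suite as the
independent oracle, agreeing to 1e-10 relative). The two-sided p-value
doubles the smaller point-inclusive tail and caps at 1; this standard
convention reproduces the closed forms p(5,5,N,N) = 1 and
p(0,20,N,N) = 2⁻¹⁹. Being discrete, the test is conservative (measured
type-I error ≈ 0.044 at α = 0.05 under a paired-Poisson null with
rate 50, 10 000 replicates) and exchange-symmetric only up to the point
mass at the observed outcome — exact symmetry is impossible for any
point-inclusive two-tail rule. No multiple-testing correction is applied
by default (an optional Benjamini–Hochberg column is available); no
significance threshold is imposed unless the caller supplies α.

The ΔΔCT helper: ΔCT = mean(target CT) − mean(reference CT) per
condition, ΔΔCT = ΔCT(test) − ΔCT(calibrator), RQ = 2^−ΔΔCT, with
replicate variances propagated through both subtractions and
SE(RQ) = ln2 · RQ · SE(ΔΔCT). At least two replicates per cell.

## Energy model and folding

Full Turner-parameter folding is deliberately out of scope; the −18
kcal/mol precursor threshold is model-relative, so the model ships with
the package (`data/energy_model.yaml`) and is calibrated such that
canonical miRNA-like stems pass and random sequence rarely does (a
12 bp GC-clamped stem + 4 nt loop folds to ≈ −25; a 15 bp A/U stem to
≈ −10). The reduced nearest-neighbour model keeps the standard
decomposition — every pair closes exactly one loop — with:

* stacking energies by pair class only (GU −0.5, AU −1.1, GC −3.3 on
  the diagonal; symmetric off-diagonal values between),
* logarithmic loop penalties `base + slope·ln(size/ref)` for hairpins
  (5.6 + 1.6·ln(s/3)), bulges (3.6 + 1.6·ln s) and internal loops
  (1.7 + 1.6·ln(s/2)),
* minimum hairpin loop 3; interior loops capped at 30 unpaired bases
  (standard practice; part of the model definition),
* multiloops legal but discouraged (close 7.0 + 0.9 per branch) —
  single-hairpin candidates should not branch; the exterior loop is
  free.

Folding is a Zuker-style dynamic program over V (i pairs j), WM
(multiloop segment) and W (exterior) tables, numba-compiled, with
backpointers for structure recovery. It reports the exact optimum for
the model: on random sequences ≤ 25 nt the DP equals exhaustive
enumeration over *all* nested structures (the test-suite oracle). A
sequence with no favourable pairing reports the all-unpaired structure
at 0.0 kcal/mol, so the reported MFE is never positive.

## Novel miRNA prediction

Unannotated tags' alignments are clustered per (contig, strand) by
transitive 30 nt adjacency. The **cut site** is the 5′ position with the
greatest summed read count (leftmost on ties) — 5′ homogeneity is the
processing signature — and the candidate mature is the highest-count tag
anchored there. Two precursor windows are extracted per cluster
(cluster as 5′ arm and as 3′ arm), each at most
26 + 35 + 26 + 2·10 = 107 nt with 10 nt flanks, reverse-complemented
for minus-strand clusters and clipped at contig bounds.

Each window is folded and nine criteria evaluated on the MFE structure;
all failures are recorded and rejection is a verdict, not an error:

| criterion         | quantity                                      | default |
|-------------------|-----------------------------------------------|---------|
| mature_length     | mature sequence length                        | 18–26 nt |
| min_read_depth    | summed count at the cut site                  | ≥ 3 |
| max_genome_copies | exact genomic copies of the mature            | ≤ 20 |
| max_free_energy   | precursor model MFE                           | ≤ −18 kcal/mol |
| max_loop_space    | gap between mature 3′ and star 5′ end         | ≤ 35 |
| min_duplex_pairs  | paired mature bases in the duplex             | ≥ 14 |
| max_bulge         | largest one-sided unpaired run in the duplex  | ≤ 4 |
| max_asymmetry     | Σ unpaired mature − Σ unpaired star in duplex | ≤ 5 |
| single_hairpin    | exactly one terminal loop in the precursor    | — |

Interpretation choices where the original tool's internals are not
published: duplex statistics are computed between the first and last
paired mature base (unpaired mature ends outside the duplex belong to
flank/loop, not the duplex); a one-sided gap is a bulge while a
two-sided gap is an internal loop contributing to the asymmetry balance
only; the star arm is reported with the canonical 2 nt 3′ overhang;
copy number counts exact genomic occurrences of the *mature* sequence
(flag-configurable); the single-hairpin test counts terminal loops
within the mature-to-star span, so unrelated pairing in the distal flank
does not disqualify a candidate; a configured "reference sequence
length 20–24 nt" is recorded but imposes no additional filter beyond
the 18–26 mature bound. When both windows of a cluster are accepted the
lower-MFE one is reported (window start breaks ties); accepted
candidates are named `<library label>-miRN` in genomic order.

## Circular mitochondrial alignment

The mitochondrial reference is circular: the sequence is extended by its
own first L−1 bases, mapped with the standard rules, and hits are
de-duplicated modulo L. Coordinates are 1-based closed to match the
mitochondrial reference convention; an origin-spanning hit has
end < start. The candidate screen is exact placement of the first 11
bases on both strands (an 11-mer expects ≈ 2·16 569/4¹¹ ≈ 0.008 chance
hits on a mitochondrial-sized genome; prefixes below 8 nt are refused as
uninformative). The published analysis used three engines (a genomic
aligner, a hairpin-aware mapper, and BLASTN for the 11-base screen);
the hairpin re-scoring is redundant with the discovery module here, so
two modes suffice. Gene labels attach at ≥ 1 base overlap, wrap-around
features supported; heavy/light strand naming is replaced by the +/−
strands of the reference sequence.

## Synthetic data: what it emulates, and what it does not

The generator is the study-conditions module: every downstream claim the
tests make is measured against its planted truth.

**Reference.** Two nuclear-like contigs (50 kb each by default) and a
16.5 kb contig flagged circular, uniform random sequence; per-category
feature tracks placed without overlap (so truth labels are unambiguous);
rRNA features alternate Genbank/Rfam sources to exercise the source
preference; a deterministic mitochondrial gene layout echoing the human
map (wrap-around D-loop, two rRNAs, interspersed tRNAs, 13 protein
genes). 20 known-miRNA loci are planted as hairpins with fixed 22 nt
matures; exactly 90% start with U (a quota, not a coin flip, so the
read-weighted first-base bias is 0.9 up to sampling noise). True-hairpin
designs carry 2–3 G·U wobbles: real duplexes are imperfect, and a
perfectly complementary stem would fold as a hairpin on *both* strands
and duplicate every locus in strand-aware analyses.

**Planted truth.** `plant_hairpin_loci` writes criteria-compliant
hairpin loci and single-violation decoys into unannotated space (40 nt
exclusion margins). Eight decoy kinds cycle: weak A/U stem
(max_free_energy), 13-pair GC duplex (min_duplex_pairs), depth-2 stack
(min_read_depth), 21 genomic mature copies (max_genome_copies), 27 nt
mature (mature_length), 40 nt loop (max_loop_space), 5 nt bulge
(max_bulge), 1-vs-7 internal loop (max_asymmetry). Decoy alphabets are
chosen so the intended duplex is the only strong pairing, and **every
locus is verified at planting time by the real extraction/folding/
criteria engine on the written genome** — with the cluster geometry the
pipeline will actually build (star stacks merge only within the 30 nt
gap; stars shorter than 18 nt are length-filtered and get no read) —
redrawing until the verdict matches the design. TruthSet invariants
therefore hold by construction, not by hope.

**Libraries.** Reads are insert + 3′ adapter + padding at 50 nt,
constant quality. The category mix is rRNA-dominated (0.65 rRNA, 0.08
known miRNA, 0.07 unannotated, 0.03 novel, …); insert lengths follow a
18–30 nt distribution with its mode at 25 (0.22 mass); planted loci are
*guaranteed* their designed mature-read depth with homogeneous 5′ ends
plus a lower-abundance star read; poly-A reads (0.002), 5′-adapter
contamination (0.01) and uniform substitution errors (0.001/base
default) provide the removal classes. Every read gets a truth row. One
`numpy.random.default_rng(seed)` per operation; identical (config,
seed) is byte-identical.

**Not emulated:** realistic quality scores or position-dependent error
profiles, PCR duplication, ligation bias, isomiR 5′/3′ heterogeneity
beyond the planted stacks, repeat-family sequence structure (repeat
features are intervals over random sequence), and real genome
composition. Passing tests therefore demonstrate the *algorithms* —
exact accounting, oracle-equivalent mapping and folding, correct
cascade order, criteria logic, recovery of planted signal under the
stated noise — not performance on real libraries, where adapter
chemistry, error structure and genomic repetitiveness are harsher.

## Problem sizes and determinism

Tests run at desk scale as the package's own study conditions: 50 kb
genomes and 1000 tags for mapper-oracle equivalence; 100 random
sequences ≤ 25 nt for the folding oracle; 10 000 replicates for the
null calibration; 50 planted hairpins + 50 decoys on a 2×80 kb genome
with 40 000 noiseless reads for parameter recovery; one 100 000-read
simulation shared by the conservation, cascade-partition and
profile-emulation checks; 5 kb rotated circular genomes for the
wrap-around property. All seeds are fixed; `scripts/acceptance.py`
derives every stream from its `--seed` argument.

## Known limitations

* The reduced energy model ranks structures like the full
  nearest-neighbour model only approximately; MFE values are
  model-relative and not comparable to Turner-parameter folders.
* The mapper is hash-based and exact for ≤ 1 substitution only; no
  indels, no quality awareness — adequate for 18–30 nt tags, not a
  general aligner.
* piRNA assignment is exact-sequence membership; positional piRNA
  cluster logic is not modelled.
* The exact test assumes Poisson sampling within each library;
  overdispersion across biological replicates is out of scope (no
  moderated-dispersion model).
* Published headline counts from the original libraries (e.g. raw-read
  totals or the 196/13 novel-candidate counts) depend on the deposited
  data and database versions and are not reproduction targets at desk
  scale; the pipeline's correctness is established against planted
  truth instead.
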