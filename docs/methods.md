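# Methods

## Simulated experiment

The generator emulates a biparental doubled-haploid (DH) RAD-seq design.
Two parental genomes share a set of RAD loci, drawn uniformly per
chromosome on [0, L] cM (default L = 150, seven chromosomes). Every tag is
92 bp and starts with the EcoRI overhang AATTC, mimicking digestion
context; at a `snp_fraction` subset of loci the second parent's tag
differs at 1 or 2 positions, drawn uniformly outside the overhang (a real
SNP inside the recognition site would abolish the cut and the locus with
it).

DH meiosis is a Poisson crossover process at rate 1 per 100 cM with no
interference — the Haldane model — so recombination fractions have the
closed form r = (1 − e^(−2d/100))/2 that the test suite checks by Monte
Carlo. Genotype segments are half-open [left, right): a locus exactly at a
breakpoint takes the right segment's phase. Starting phase is a fair coin
per chromosome. Downstream map distances use Kosambi, as is conventional
for field populations; on Haldane-simulated data Kosambi compresses
distances slightly (a known, documented mismatch — 862 vs 1,050 true cM at
the reference scale), which leaves marker order and QTL inference
unaffected.

Reads are barcode + tag with i.i.d. substitution errors at `error_rate`
(default 0: read cleaning on real data is performed by external tools and
is out of scope) and per-individual, per-locus Poisson(`coverage_mean`)
depth. Quality strings are constant 'I' (Phred 40). Barcodes are random
8-mers kept at pairwise Hamming distance ≥ 3. The ten-lane library
structure of a real HiSeq experiment has no downstream consequence and is
not modelled; one barcode table covers all 96 individuals.

Phenotypes follow y_i = μ + Σ_q a_q x_iq + ε_i with x = +1 for the
parent-1 allele and ε ~ N(0, σ²). With a single QTL the expected percent
variance explained is a²/(a²+σ²); the reference parameters a = 8.9 cm and
σ = 9.9391 cm solve PVE = 44.5%, with μ = 71 cm midway between parental
heights of roughly 80 and 62 cm.

What the generator does *not* emulate — variable tag lengths, indels, PCR
duplicates, coverage that tracks GC or restriction-fragment length,
segregation distortion, shared repetitive families that collide distinct
loci onto near-identical tags — bounds what green tests mean: they verify
the algorithms on data obeying the stated model, not robustness to every
artifact of a real library.

## Tag clustering and SNP calling

Tags are exact-sequence clusters of the 92 bp after the barcode,
case-normalized; tags containing non-ACGT characters are dropped rather
than wildcard-matched. Tags with more than 100 reads in an individual
(strictly > 100) are removed as putative repetitive-region collapses. A
tag is "present" in an individual at ≥ 1 read by default
(`min_presence_reads`); the depth that should count as presence is a
judgement call exposed in configuration.

Candidate SNPs are unordered tag pairs at Hamming distance 1–2. The finder
splits each tag into `max_mismatch`+1 blocks; any pair within distance 2
must agree exactly on one block (pigeonhole), so hashing blocks yields a
candidate set that full Hamming verification reduces to exactly the
brute-force result — the equivalence is asserted against an O(T²) scan in
the acceptance suite. A tag participating in more than one pair is treated
as a putative paralog and all its pairs are discarded (configurable to
keep the best-p pair).

The allele test is a two-sided Fisher exact test on the 2×2
presence/absence table of the two tags over the non-parent individuals:
the two-sided p sums every hypergeometric point probability not exceeding
the observed one (1e-7 relative slack for floating-point ties; degenerate
margins give p = 1). True alternative alleles in a DH population are
mutually exclusive, so a pair passes only when p < α (default 0.01) *and*
the association is negative. A marker is phaseable only when parent 1
carries exactly one tag and parent 2 only the other; per line, the
parent-1 tag alone calls A, the parent-2 tag alone calls B, both tags
(a heterozygous signal, impossible in a true DH line) or neither call
missing. Filters then run in order: pair presence fraction must exceed
0.80 (strict); markers with more than 20 missing calls are removed; the
map-construction tier additionally requires a missing rate strictly below
7% (20/94 ≈ 21%, so the two rules are genuinely different tiers).

## Map construction

Pairwise statistics over co-called lines give recombination counts, r̂,
and a Fisher independence p (the same exact kernel — exactness matters at
n = 94 where chi-square approximations are unreliable in the extreme
tail). Linkage groups are connected components of the graph with edges
where p < 10⁻⁶ and r̂ < 0.5; singletons are reported as unanchored.
Markers with zero observed recombination collapse into bins (map loci) by
connected-component closure, with a consensus genotype per line (conflicts
introduced by the closure become missing and are logged).

Ordering minimizes the COUNT objective — the total number of recombination
events between adjacent bins. The heuristic builds a Kruskal MST (ties
broken by (weight, marker id) for reproducibility), seeds with the tree's
longest path, inserts off-path bins greedily, and polishes with 2-opt
segment reversals plus or-opt relocation of 1–3-bin segments (either
orientation) to a local optimum; for ≤ 12 bins a dozen deterministic
random restarts guard against local optima, and the acceptance suite
checks objective equality with exhaustive search on instances of up to 8
bins. Orientation is canonicalized so the lexicographically smaller
terminal marker id sits at 0 cM; comparisons against truth are therefore
reversal-tolerant.

Adjacent-bin r̂ converts to cM by Kosambi; r̂ ≥ 0.5 (possible under
noise) is clamped to 0.4999 with a warning. One pass of bad-data cleaning
sets to missing any call that disagrees with both immediate flanking bins
where those agree — a double-recombinant singleton, overwhelmingly a
genotyping error at tight spacing (on error-free data ~0.1% of calls are
true tight double crossovers and absorb the small false-positive budget).
Groups finally split at adjacent gaps strictly above 35 cM, and split
groups are renumbered. The MSTMap-style parameters no_map_dist 25.0,
no_map_size 0, missing_threshold 1.00 and estimation_before_clustering no
are honored as pass-through configuration: the 0/1.00 settings disable the
corresponding filters, so no active logic implements them.

## QTL scan

The scan is Haley–Knott regression: at each grid point (every bin position
plus a 1 cM step grid) each line's expected genotype score x ∈ [−1, 1]
comes from its nearest informative flanking bins under the
no-interference Markov model (Haldane r from cM distances; one flank
yields the marginal expectation, none yields 0 — this doubles as the
missing-call imputation). LOD = (n/2)·log₁₀(RSS₀/RSS₁) from the
single-regressor fit, the additive effect is the slope (half the
difference of genotype-class means), and PVE = 100·(1 − RSS₁/RSS₀), so
PVE and LOD satisfy the identity PVE = 100·(1 − 10^(−2·LOD/n)) exactly. At
a bin position the score is the observed genotype, making the scan LOD
equal single-marker regression LOD there (asserted to 1e-9). A perfect
fit caps LOD at 50 with a warning. Haley–Knott was chosen over a full
EM mixture likelihood: it is standard, fast enough to vectorize the
10,000-permutation null as one matrix product, and exactly equivalent at
marker positions.

Genome-wide significance is the empirical (1−α) quantile (linear, type-7
interpolation) of the per-permutation maximum LOD over the genome,
phenotypes shuffled across lines, seeded. QTL declaration is two-stage:
an interval scan locates the strongest peak; the nearest mapped marker
becomes a cofactor and the final profile is the MQM scan (cofactors
within 10 cM of the evaluation point are dropped from the model at that
point), from which maximal contiguous super-threshold segments are
reported with peak, flanking bins, effect, PVE and 1-LOD support
interval. The MQM pass matters: a 44.5%-PVE QTL throws super-threshold
"shoulders" tens of cM away on its own chromosome, and conditioning on
the peak marker absorbs them; without it roughly a quarter of replicates
at the reference design report spurious extra segments. Cofactor choice
beyond this automatic single cofactor is user-supplied, with a greedy
forward-selection helper. An empty report (nothing above threshold) is a
valid outcome.

## Scales, defaults, and reproducibility

Reference scale throughout (tests and the acceptance script): 94 DH lines
plus 2 parents, seven 150 cM chromosomes, 1,001 RAD loci with 30%
polymorphic, coverage 8, error-free reads. Permutation counts are 10,000
in the acceptance run and 200 in the repeated calibration studies, whose
500-replicate type-I error lands at 0.05 ± 0.03. Sparser maps are
supported but attenuate Haley–Knott signal: with ~18 markers per
chromosome the flanking gaps near a QTL can exceed 15 cM and shrink
apparent PVE by a third, which is why the reference density matches the
dense-map setting the method is meant for.

All randomness flows from one top-level seed through named substreams per
stage (parents, meiosis, barcodes, reads, phenotype), so identical seed +
configuration reproduce every artifact byte-for-byte — asserted by the
determinism test — and every pipeline run writes a manifest embedding the
resolved configuration. Positions in outputs are cM with 3 decimals;
genotype symbols are {A, B, U}.

## Known limitations

- Kosambi-on-Haldane compression biases total map length low by ~5–20%
  depending on marker spacing; order and grouping are unaffected.
- Group naming and orientation are arbitrary (no reference genome to
  anchor to); all truth comparisons align groups by shared-marker overlap
  and tolerate reversal.
- The Fisher screen assumes presence/absence is informative at coverage
  ≥ a few reads; at very low coverage absence is mostly sampling noise
  and the negative-association requirement loses power.
- detect_bad_data runs a single pass with a ±1-bin window; clustered
  errors or errors in terminal bins are not corrected.
- The MQM scan handles collinear cofactors by least-squares pseudo-inverse
  with a warning rather than dropping them.
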