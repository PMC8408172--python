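# Methods

## Segment model

All coordinates are genetic (cM) on a user-supplied map; intervals are
closed `[start, end]` and a segment's length is `end − start`, so a
single-marker match has length 0. Markers at identical positions are
allowed (file order preserved) and contribute no length. Chromosome
boundaries always terminate segments.

Per marker, a pair of genotypes is in one of three states:

* **match** — the sets of *called* alleles intersect. A half-called
  genotype (`A –`) can match through its called allele.
* **mismatch** — both genotypes fully called and disjoint.
* **uninformative** — anything else. A half-called genotype can never
  mismatch: the missing allele could have matched.

A shared segment is a maximal run bounded by match markers, containing no
mismatch, with uninformative markers allowed inside but trimmed from the
ends. Missing data therefore *bridges* segments rather than truncating
them. The null allele C is an ordinary third allele (C matches only C);
it is distinct from missing data. Segments are never extrapolated beyond
their flanking match markers: the neighbouring recombination point is
unknowable, and the conservative bound keeps lengths reproducible across
implementations. SPLoSH at threshold *t* sums lengths of segments with
length ≥ *t* (ties kept).

Phasing modes: UU compares unphased genotypes. PU sums, over the two
homologs of the phased individual (each as a doubled genotype), the kept
segment lengths against the other's unphased genotype; UP is the mirror
image, and the mixed statistic is the PU/UP average. PP takes, per homolog
of A, the length of the union of kept segments against either homolog of
B, sums over A's homologs, and averages the A→B and B→A directions (the
union prevents a homolog matching both homologs of the partner — e.g.
through a homozygous stretch — from being counted twice *within* one
direction, while homozygous regions are still counted once per matching
homolog, i.e. doubled relative to UU, which is inherent to per-homolog
accounting). The symmetrised form guarantees PP(a,b) = PP(b,a). The exact
PP aggregation is a design choice of this package; the averaging of the
two mixed arrangements and the double-counting of homozygous stretches
under phased modes are fixed behaviour.

## IBS classes, ROH

From unphased data, **double IBS** at a marker means the two genotypes are
identical as multisets; **single** means sharing without identity; **none**
means fully-called disjoint. Double-IBS genome intervals are maximal runs
of identity (uninformative bridging, other classes breaking) — robust,
because a region IBD on both homolog pairs is identical at every error-free
marker. Single-IBS intervals are *not* built from marker-level runs:
within a region sharing exactly one homolog, the other homolog pair is
identical by chance at roughly half the markers, so marker-level single
runs fragment far below any reporting threshold. Single intervals are
therefore the shared-haplotype coverage minus the reported double
intervals, which is also what makes the single/double genome tracks
complementary. Runs of homozygosity are maximal runs of fully-called
homozygous markers (heterozygous breaks, missing bridges), default
threshold 10 cM. All genome fractions are relative to total map span, not
physical distance.

## Relatedness

COR is twice the kinship coefficient from the standard recursive (tabular)
algorithm, with founders unrelated and non-inbred. The recursion handles
clonal reuse of an individual across generations, which path counting makes
awkward. The pedigree is truncated at `max_depth` generations above the
two query individuals (default 3, the great-grandparent level): deeper
ancestors become founders. The test suite cross-checks the recursion
against an independent exhaustive path-enumeration oracle on random small
pedigrees.

The SPLoSH~COR association is an unweighted OLS of SPLoSH on COR per
(threshold, phasing type), reporting slope, intercept, R² and residual
standard error; COR for a query pair is estimated by inverse prediction,
clamped to [0, 1]. Pairs sharing individuals are not deduplicated or
reweighted.

The Close Relationship Estimator is deliberately non-parametric: per
relationship class (FSIB → COR 0.5, HSIB → 0.25, HAAM → 0.125, OSGP →
0.0625) the reference values at one threshold (default 40 cM) are
subsampled without replacement to the smallest group's size and the
subsamples of 10 iterations concatenated, equalising class loading; a
query *s* counts pooled values within ±20 cM and normalises across classes.
Queries with an empty window are flagged undefined rather than
extrapolated.

## Reconstruction operators

*Obligate alleles.* The allele a child inherited from its ungenotyped
parent is forced when the child is homozygous, or heterozygous with the
known parent homozygous for one of the child's alleles. A fully-called
known parent carrying neither child allele flags a Mendelian conflict
(data, not an exception — real arrays produce them through uncalled nulls).

*Group-parent imputation.* Across a putative half-sib group, two distinct
obligate alleles at a marker resolve the hypothetical parent's genotype;
three or more flag the marker (impossible for one diploid parent). A
single distinct allele resolves one slot; the parent is additionally
called homozygous only when at least `min_homozygous_evidence` (default
12) members show a determined obligate there, since a heterozygous parent
transmits one allele to n offspring with probability 2^(1−n) — smaller
groups leave the slot open rather than guess. Resolved heterozygous
markers are then phased into two parental homologs by a greedy
majority-linkage vote along each chromosome (members mostly stay on one
homolog between neighbouring markers), and each member's obligate track is
assigned to the homologs left-to-right, counting switches. A candidate
half-sib is accepted when it has zero allele-level conflicts with the
imputed parent and at most `max_switches_per_chrom` (default 2) switches —
"occasional recombination". A full HMM phaser would be sharper; the greedy
switch count is what the manual procedure actually inspects.

*Grandparent-couple test.* The unknown parent received one homolog from
each candidate grandparent, so every obligate allele must occur in at least
one of the two candidates; markers where either candidate has a missing
call are excluded from the count and listed for manual review rather than
weighted.

*Candidate ranking* orders a population by SPLoSH with the target (whole
genotype, or one targeted homolog doubled), ties broken by id — a
shortlist generator, not a verdict. Haplotype-containment evidence for
generation ordering (segments in A-not-B vs B-not-A) is reported as counts
and total cM without an automatic decision.

*GPGC criteria* (phased grandchild required): genome coverage of shared
haplotypes at a display threshold (5 cM apple-style, 10 cM cherry-style);
chromosomes whose sharing on the better homolog is a single run touching
exactly one chromosome end (single-recombination evidence); and the
fraction of covered homolog-ends, counted over both homologs and both ends
(four per chromosome), for which a true grandparent expects ~25% — each
homolog-end traces to the candidate with probability 1/4. Cutoffs for the
three booleans are configurable and intentionally loose; the report is
evidence, not a classifier.

## Simulator

`pedsim` gene-drops founder genomes through relationship templates (FSIB,
HSIB, GPGC, HAAM, OSGP, NKCR pairs) with exact founder-origin labels, so
true IBD between any two individuals — at multiplicity 1 (≥ one homolog
pairing) or 2 (both, under a disjoint pairing) — is read directly off the
label tracks. Meiosis is Haldane: per chromosome, crossover count ~
Poisson(span/100), positions uniform, starting homolog fair; crossover
interference would change segment-length distributions but not the mean
sharing the validations target. Defaults emulate the cherry-scale
reference setting: 8 chromosomes, 655 cM, 1,617 markers placed uniformly
with both chromosome ends marked; an apple-like preset (17 chromosomes,
1,267 cM, 10,295 markers) is provided. Founder B-allele frequencies are
uniform on (0.2, 0.8) per marker — enough minor-allele frequency to keep
chance IBS realistic but bounded; null alleles are a third founder allele
at configurable frequency. The observation layer adds whole-genotype
missingness and allele-call errors on top of the retained truth; an
endogamy switch reuses founders across families to reproduce inflated
background sharing qualitatively.

What the simulator does *not* emulate: linkage disequilibrium and
population structure among founders, array-specific marker ascertainment,
clustered genotyping error, segregation distortion, or real gap structure
in maps. Passing tests therefore demonstrate correctness of the segment
arithmetic and the genetics of transmission, not robustness to every
artefact of real array data.

## Problem sizes and numerical choices

Validation runs use 10,000 simulated pairs for the IBD means (standard
error ≈ 1 cM on a 655 cM map), 1,000 random ≤ 20-marker instances for the
brute-force oracle comparison, and a ~75-pair error-free panel at 800
markers for containment and invariance sweeps; these sizes put Monte-Carlo
error well inside the tolerances tested. Threshold comparisons use ≥
(ties kept). Floating-point cM arithmetic is exact for the comparisons
performed (no accumulated sums are compared for equality beyond 1e-9
tolerances).

A known quantitative limitation, measured and documented rather than
hidden: at threshold 0 the UU SPLoSH of *unrelated* pairs already covers
most of the genome, because two unphased biallelic genotypes share an
allele at ~90% of markers (a heterozygote matches everything), and
match-run coverage is a marker-count ratio independent of map density.
Observed threshold-0 UU SPLoSH consequently regresses on COR with a slope
of roughly 0.2 × (2L), far below the 2L slope that the multiplicity-
weighted *true IBD* total recovers exactly (verified in the test suite).
This is why the method is operated at 20–40 cM thresholds, where chance
segments are rare; the same saturation is the reason reference
distributions, not raw coverage, drive relationship calls.
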