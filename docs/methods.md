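# Methods notes

This note documents the models, parameter choices and numerical decisions
behind `asmdiff`, and what the synthetic benchmarks do and do not
demonstrate.

## Input model and coordinates

A whole-genome alignment is a set of local alignments between a reference
and a query assembly, both at chromosome level with a known (or
name-inferred) homologous-chromosome pairing. All internal coordinates are
1-based inclusive on both genomes; orientation is a strand flag and
coordinates are never stored reversed, which removes an entire class of
interval-arithmetic errors. PAF input (0-based half-open) is converted on
ingest; VCF output is 1-based.

The per-alignment score is `identity × (ref_len + qry_len)/2`. The choice
is deliberate plumbing: it is symmetric in the two genomes, proportional to
aligned length, and strictly monotone in identity and length, which is all
the chaining and selection steps require. Any score with those properties
yields the same qualitative behaviour.

## Syntenic path (step 1)

The collinearity DAG has an edge a → b iff b starts strictly after a ends
on both genomes; this relation is an interval order, hence transitive and
acyclic. The chain score is the plain sum of member scores with no gap
penalty — gaps are accounted for later, by the candidate-TD score and by
the gap-variant calls. Ties between equal-score chains are broken towards
smaller total gap length and then smaller alignment ids, making the output
deterministic; the gap tie-break also resolves the genuinely symmetric case
of a tandem duplication, where either copy could serve as the syntenic one
(the copy contiguous with its neighbours wins, so the inserted copy is the
one reported as the duplicate). Alignments overlapping the chosen chain are
excluded, not trimmed: trimming would produce coordinates present in
neither input alignment set and would break the exact partition checks.

The dynamic program is exact; its oracle in the tests is subset enumeration
over bitmasks (pairwise comparability suffices because the order is
transitive), kept deliberately independent of the DP.

## Inversions (step 2a)

Mirroring the query intervals of inverted alignments turns an inversion
into a collinear chain, so candidate construction reuses the synteny
predicate. Candidates are all contiguous subchains of all maximal chains of
the *transitively reduced* mirrored DAG — reduction keeps "chains" from
skipping members they could include, and gives the expected n(n+1)/2
candidates for a linear chain of n alignments. Per connected component the
enumeration is capped at 5000 candidates; beyond the cap (deeply repetitive
regions) the component falls back to its single best chain. Candidates
overlapping a syntenic alignment by more than 10 bp on either genome are
discarded; the 10 bp margin absorbs aligner boundary jitter.

Conflict-free selection is a maximum-weight independent set on the conflict
graph (overlapping reference spans, overlapping query spans, or shared
members). Components of ≤ 20 vertices are solved exactly by
branch-and-bound with a remaining-weight bound; larger components fall back
to greedy-by-weight with single-vertex exchange. 20 keeps the exact search
well under a millisecond per component while 2²⁰ subset enumeration would
not be; the tests verify oracle equality up to 15 vertices.

## Translocations and duplications (step 2b)

Residual alignments are chained per (reference chromosome, query
chromosome, orientation) bucket with a 10 kb bound on the gap between
consecutive members, which stops chains from sprawling across unrelated
repeats. Candidate score = mean aligned length − mean gap length (means
over the two genomes); the filter requires score ≥ 0.5 × mean span length,
i.e. at least half of a candidate's span must be net-aligned. A candidate
is redundant — dropped before selection — only when *both* its spans are
overlapped by syntenic/inverted annotations: one-sided overlap is exactly
the footprint of a duplication and must survive.

Conflicts for selection are query-span overlaps (double placement of the
same query sequence) and shared members; reference-side overlaps are *not*
conflicts, because several query copies legitimately align to one
reference region. After selection, candidates are classified in descending
score order against the accumulated annotation set: reference span ≥ 80%
covered by other annotations ⇒ the query holds an extra copy (DUP,
`copy_in_query`); the symmetric case marks `copy_in_ref`; otherwise TRANS
(or INVTR when inverted), with intra- vs inter-chromosomal relocation
distinguished by the chromosome fields. A duplication is tandem when the
copy lies within 100 bp of the image, on the copy's genome, of the region
it duplicates — with the simulated tandem copies inserted adjacently and
distal copies placed uniformly, the two populations separate by orders of
magnitude, so the threshold is not delicate. Alignments in no selected
candidate are reported as redundant, never silently dropped.

## Blocks and local variants (step 3)

Annotation blocks are maximal runs of same-type annotations in reference
order. Two refinements keep block spans truthful in rearranged regions: an
annotation nested inside the reference extent of the current run (the
origin of a duplication inside a syntenic stretch) becomes its own block
without interrupting the run, and a run splits wherever the query-side gap
between consecutive members is occupied by another annotation (a
transposition or translocation target), because the run is not contiguous
in the query there. Without these, block bounding boxes would
double-cover relocated material and break the partition property.

SNP/indel parsing walks the CIGAR; `M` operations are split into match and
mismatch against the sequences, and produce no SNPs (with a warning) when
sequences are unavailable. For minus-strand alignments the query segment is
reverse-complemented before the walk and positions mapped back, so the
reported query coordinates are genomic. Insertions use the
zero-reference-length convention anchored at the preceding base.

Between consecutive block members with reference gap r and query gap q
(negative = overlap), the classification is total: r>0,q>0 → HDR; r>0,q=0 →
DEL; r=0,q>0 → INS; r<0,q<0 → TDM; r<0 → CPL; q<0 → CPG. HDRs are reported
as regions and not re-aligned internally. Copy gain/loss is named from the
query's perspective (CPG = query gained copies) — one fixed frame avoids
the ambiguity of "CNV". Un-aligned (NOTAL) regions are the per-chromosome
complement of the union of block spans, reported down to 1 bp. The
resulting invariant — block bases plus NOTAL bases equal the chromosome
length, with double coverage only where duplications are involved — is
asserted in the tests on every simulated fixture.

## The simulator

The simulator emulates the study conditions of assembly-vs-assembly
benchmarking: events are planted into a genome with non-overlapping source
intervals and insertion points that never split another event, so every
breakpoint is exact by construction. Default event counts are the
benchmark mix (40 inversions, 436 transpositions, 100 translocations, 100
tandem duplications of 100–1000 bp, 1241 distal duplications; the indel
preset plants 1000 indels of 1–500 bp, half insertions and half
deletions). Translocation sizes are uniform in 1–5 kb. Sizes with no
stated range (inversions, transpositions, distal duplications) default to
log-uniform over 500 bp–10 kb: empirical rearrangement size distributions
are heavy-tailed, and log-uniform is the simplest configurable stand-in.
The benchmark scale used in the tests and the acceptance script — 2 Mb
genomes and 110 rearrangements, or 1 Mb and 1000 indels — keeps per-run
cost at a few seconds while leaving every event surrounded by enough
syntenic context for anchoring; the recovery rates are insensitive to the
genome size at fixed event density.

`truth_alignments` emits the alignments an *ideal* aligner would produce:
identity 1, all-match CIGARs, alignments split at indels and event
boundaries. This isolates the identification logic from aligner behaviour.
Consequently the green benchmarks show that the graph algorithms recover
what is recoverable from a correct WGA; they do not exercise aligner noise
(boundary jitter, missed or spurious alignments, diverged sequence), which
on real data is absorbed only up to the 10 bp overlap margin and the
±150 bp evaluation tolerance. The random-genome generator (i.i.d. bases at
a set GC content, default 0.38) contains no repeats, so the
redundant-alignment machinery is exercised by the duplication events
rather than by genomic repeat families.

Evaluation follows the four-category scheme — identified / indicated /
incorrect / missed — at ±150 bp breakpoint tolerance, with any
duplication-like predicted type accepted for duplication truth. Indels are
matched one-to-one, greedily by position, requiring the same type and both
position and size errors within the limit (5 or 100 bp); with zero
predictions, precision is reported as 1.0 and flagged.

## Translocation validation

Expected copy number of translocated DNA in an F2 recombinant is
(# genome-1 haplotypes at the first insertion locus) + (# genome-2
haplotypes at the second), range 0–4. Testable translocations are > 1 kb,
outside centromeres, and not N-dominated (mean per-sample fraction of
N-heavy reads ≤ 0.25).

Test 1 (absence) requires at least two expected-zero-copy samples and
validates only when every one of them is below a 0.2× coverage ratio.
Test 2 (copy-number fit) excludes samples with identical genotypes at the
two loci (they pile up at two copies and bias the fit), requires ≥ 3
distinct expected values, fits ordinary least squares of observed
(2 × region/genome coverage) on expected copies, and uses a one-sided p
for positive slope — directionality is implied by the slope > 0.75
criterion; thresholds are adjusted p < 10⁻⁶ and slope > 0.75, BH-adjusted
across translocations. Test 3 (clustering) requires ≥ 2 genotype classes
with ≥ 3 samples each, ≥ 3 markers, and non-degenerate alternate counts
(mean per-marker variance across samples ≥ 1). Counts are normalised by
per-sample total depth, markers with mean count above 3× the median are
dropped as outliers, and each marker is centred; the closeness score is
then computed on the flattened (reference, alternate) vectors.

The null distribution of the closeness score is built by resampling:
group-wise Poisson rates are taken from the observed per-group means, each
simulated cohort draws every sample's counts from the rates of a randomly
permuted group assignment, and the score is computed against the original
grouping. This is a permutation null with Poisson noise: under no
genotype–count association it reproduces the observed score distribution,
while genuine clustering makes the observed score an extreme lower-tail
value. p = (1 + #{sim ≤ obs}) / (1 + n_sim) with n_sim = 10,000 by default
(a pseudo-count avoids p = 0); calibration checks in the test suite use
smaller n_sim (200–2000), which only coarsens the p-value grid. Validated
means BH-adjusted p < 0.05; a translocation is *confirmed* when any test
validates. Note that BH across a mixture of strong positives and nulls
intentionally admits ≈ α of the nulls — the calibration test bounds the
null confirmation rate at 7% over 200 replicate cohorts.

The F2 generator draws genotypes 1:2:1 independently at the two loci,
region read counts Poisson with mean ∝ copy number (copy 2 = genome
average), and marker counts Poisson with the reference rate tracking the
A-haplotype dose and the alternate rate the B-haplotype dose; genome-wide
coverage is taken as the nominal depth. Cohorts default to 50 samples at
5× depth. The `null` mode emulates a mis-predicted translocation: two
copies always present, marker counts independent of genotype. Real
cohorts additionally have mapping bias, shared markers between overlapping
events and non-Poisson overdispersion, none of which the generator models;
the recovery results therefore demonstrate correctness of the statistics,
not robustness to those artefacts.

## Degenerate inputs and determinism

Empty alignment sets, empty chromosomes and empty candidate sets flow
through every step and produce empty outputs. Unclassifiable candidates
are impossible by construction (the classification rules are exhaustive);
contract violations (mixed strands in the synteny DAG, CIGARs inconsistent
with coordinates, out-of-range mirror intervals) raise immediately rather
than degrade. All randomness flows through a single seeded generator per
entry point; reruns with one seed are byte-identical, and the CLI refuses
stochastic commands without a seed.

## Known limitations

- Nested rearrangements (an inversion inside a translocated block) are
  annotated as their dominant outer class only.
- HDRs are not decomposed by re-alignment.
- The greedy fallback above the exact-search limit is not guaranteed
  optimal (the tests bound its use to large conflict components).
- Chaining is O(n²) per chromosome pair in the number of alignments, which
  is fine up to tens of thousands of alignments but would need banding for
  highly repetitive, unmasked genomes.
- Breakpoint precision on real data is limited by the aligner's local
  alignment boundaries; no split-read refinement is attempted.
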