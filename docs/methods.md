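# Methods

## Model

A k-mer that occurs at exactly one locus of a diploid genome ("unique")
is sequenced from both haplotypes; its count in the reads is modelled as
the sum of two per-haplotype normals, estimated directly as a sample-wide
N(μ, σ²) because reads cannot be assigned to haplotypes. Assuming equal
coverage of the two haplotypes, a k-mer present on one haplotype follows
N(μ/2, σ²/2), and a k-mer absent from the genome is given mean 0 and a
small fixed variance ε. Every selected k-mer carries an expected diploid
copy number per genotype: alt-derived k-mers (breakpoint junctions,
inserted sequence) map {0/0→0, 0/1→1, 1/1→2}; ref-derived k-mers
(deleted sequence, reference breakpoint context) map {0/0→2, 0/1→1,
1/1→0}. The per-SV likelihood of each genotype is the product of the
per-k-mer normal densities. This independence approximation is knowingly
wrong for overlapping k-mers drawn from the same reads — it sharpens the
likelihood without biasing the argmax appreciably — and the
maximum-likelihood genotype is reported together with the per-genotype
log-likelihoods and the number of supporting k-mers.

Model parameters and the reasoning behind the defaults:

| parameter | default | meaning |
|---|---|---|
| k | 32 | k-mer length; fits one 64-bit word at 2 bits/base, long enough to be unique in mammalian-scale genomes. Configurable 8–32. |
| ε | max(1, (μ/10)²) | variance of the copy-0 model. Scaling with μ tolerates the occasional error-derived occurrence at high depth while the floor of 1 keeps the density proper at low depth. |
| count cap | 2μ | per-k-mer counts are truncated before likelihood evaluation so a repetitive k-mer that escaped filtering cannot dominate an SV's likelihood. |
| control k-mers | 10 000 | unique reference k-mers outside every SV footprint, counted alongside the panel to estimate μ, σ². Counts are trimmed 2.5% per tail before taking mean/variance (ddof=1); σ² is floored at 1. |
| max k-mers per SV | 64 | junction k-mers preferred over inner ones; caps the cost of very long deletions without hurting accuracy (even 5–10 concordant k-mers give a sharp likelihood). |
| flank | k | bases of reference context kept on each side when splicing the alternate haplotype; one more than the k−1 minimum so every junction window has both neighbors recorded. |
| clip search radius | 100 bp | how far from a breakpoint a soft-clip may start and still contribute candidate k-mers; matches typical breakpoint imprecision in short-read call sets. |

Ties in the likelihood break toward fewer alternate alleles
(0/0 < 0/1 < 1/1), a conservative choice that only matters for exactly
degenerate inputs.

## Counting

k-mers are packed into unsigned integers (A=0, C=1, G=2, T=3,
most-significant first) and counted canonically — a code and its reverse
complement are one key — because the reads are unmapped and strandless.
The scan updates the forward and reverse-complement codes incrementally
per base; windows covering an ambiguous base are skipped, and a base
other than ACGT invalidates only the windows that cover it. Counting is
per occurrence, not per read; the two differ only for k-mers repeated
within one read, which the reference-occurrence filter removes anyway.

Neighbor verification: extraction stores the canonical codes of the
windows one base left and right of each selected k-mer in its source
haplotype. An occurrence in a read is counted only if at least one
*checkable* adjacent window (one that exists within the read and is free
of ambiguous bases) matches a stored neighbor; occurrences with no
checkable adjacent window — at read ends — are accepted, since rejecting
them would systematically undercount. A k-mer with no stored neighbors
at all is counted unconditionally. Verification can only remove
occurrences, never add them.

## Extraction filters

1. **Reference occurrences.** Every candidate is located across the whole
   reference. Alt-derived candidates must not occur outside the footprint
   (interval ± (k−1)) of any input SV; ref-derived candidates must occur
   exactly once, at their own locus. The filter is idempotent and purely
   subtractive.
2. **Cross-SV deduplication.** A k-mer claimed by two SVs is dropped from
   both; the base method does not attempt to share evidence between
   events.
3. **Training concordance.** Candidates (plus controls) are counted in
   each training sample; each candidate's single-k-mer maximum-likelihood
   genotype must equal the sample's known genotype for its SV, in every
   sample where that genotype is known (strict AND across samples;
   unknown genotypes pass vacuously). This removes k-mers sitting on
   hidden paralogs or otherwise mis-tracking depth.

An SV whose candidates all fail is recorded as un-genotypeable and is
reported as missing (`./.`) at genotyping time; the fraction of SVs with
at least one surviving k-mer is the extraction rate. Clipped-read
candidates, when alignments are given, are unioned with reference-derived
ones before filtering; they receive the alt-derived copy table since
clipped bases spell alternate-haplotype sequence. Inversions contribute
junction k-mers from both breakpoints; their interior is excluded because
reverse-complementing a segment does not change canonical copy numbers.

## Simulator

The bundled simulator generates the conditions under which the method is
evaluated: a uniform random reference; non-overlapping SVs (default
50% DEL / 50% INS, 50–500 bp, footprints ≥ 2k apart) with genotypes drawn
from {0/1, 1/1} for training samples or all three for test samples; the
two haplotypes implied by the genotypes; and paired-end reads emulating a
wgsim-style generator — fragments of 400 ± 50 bp drawn uniformly from
both haplotypes, 100 bp mates (mate 2 reverse-complemented), i.i.d.
substitution errors at 0.1%, and no indel errors (an indel error merely
lowers a k-mer count slightly; substitutions are the error mode that
matters for exact-match counting). The pair count is
coverage × total_diploid_length / (2 × 2 × read_length), so each genomic
locus is covered `coverage` times in expectation across its two haplotype
copies. All randomness derives from one seed; a fixed seed reproduces
the FASTQ output byte-for-byte.

What the simulator does *not* emulate — and what passing tests therefore
do not demonstrate — is the repeat structure of real genomes: a uniform
random reference has essentially no paralogy, so the reference-occurrence
and training filters are exercised only lightly, and extraction rates on
real satellite or tandem-repeat SVs will be lower. Quality scores, GC
bias and chimeric fragments are also not modelled.

The canned protocols run at desk scale: the extraction-rate protocol uses
a 5 Mb genome with 300 SVs at 30× or 10×, and the end-to-end accuracy
test a 2 Mb genome with 150 SVs — sizes chosen so the full two-stage
pipeline completes in about a minute per run while leaving every SV with
the same local read depth and k-mer structure it would have at full
scale.

## Numerical and degenerate-input choices

- Densities are evaluated in log space; the normal is used as a
  continuous density over integer counts (μ ≥ 10 in intended use).
- μ is floored at 0.1 and σ² at 1.0; all-zero control counts abort with a
  panel/sample-mismatch error rather than producing calls.
- A zero-length deletion or empty insertion yields no candidates (its
  alternate haplotype is the reference).
- SVs shorter than k yield junction k-mers only.
- Coordinates are 0-based half-open internally; BED is native, VCF POS is
  converted on read (symbolic ALTs use INFO END; literal indels use the
  shared-leading-base convention).
- Genotyping never touches coordinates, so a panel extracted against one
  reference version genotypes samples mapped to (or unmapped from) any
  other.

## Known limitations

- Duplications, translocations and multi-allelic or nested events are out
  of scope; overlapping input SVs beyond the dedup rule are rejected.
- Approximate breakpoints degrade the reference-derived candidate path;
  only the clipped-read path learns junction sequence from reads.
- Precision/recall use presence-level matching (a positive call on a
  truly positive event counts as a true positive even with the wrong
  dosage); exact-genotype agreement is what TGR/FGR measure.
- The per-k-mer independence approximation overstates confidence; the
  reported log-likelihoods rank genotypes reliably but are not calibrated
  posteriors.
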