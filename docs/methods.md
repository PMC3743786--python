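# Methods

## What the package models

`mirprof` re-creates, at desk scale, the computational core of a small-RNA
deep-sequencing comparison between laryngeal cancer and non-cancer
(papilloma) tissue at the two miR-196a loci, together with the expression
statistics that typically accompany such a study. Four stages compose the
pipeline:

1. **Library simulation** (`mirprof.simulate`, `mirprof.references`) —
   seeded references and reads with known ground truth;
2. **Hierarchical classification** (`mirprof.classify`) — sequential
   mapping against rRNA/tRNA decoys, miRNA precursors, then genome, with
   reads-per-million (RPM) normalization;
3. **IsomiR profiling** (`mirprof.isomir`) — signed 5'/3' end offsets
   relative to the canonical mature boundaries, percentage size spectra,
   and a descriptive two-group comparison;
4. **Statistics** (`mirprof.stats`) — comparative-Ct quantification, the
   Welch + fold-change candidate screen, and paired t / Tukey–Kramer /
   Mann–Whitney group tests.

## Reference model

Each reference set contains two precursors embedding the identical 22-nt
mature miR-196a-5p sequence (`UAGGUAGUUUCAUGUUGUUGGG`, stored DNA-encoded):
a 70-nt hairpin modeled on the chr17 locus (`chr17:46709852-46709921[-]`)
and a 110-nt hairpin modeled on the chr12 locus
(`chr12:54385522-54385631[+]`). Printed genomic spans are interpreted as
1-based inclusive (UCSC convention), so the two lengths are end−start+1 =
70 and 110; all in-memory coordinates are 0-based half-open. Minus-strand
loci are stored already reverse-complemented: every stored sequence is the
5'→3' transcript, and no strand arithmetic happens downstream. Flanks,
loops, extra precursors, decoys, and the background contig are random but
seeded; extra precursors keep ≥2 nt of flank on each side of the mature
interval so that ±1–2 nt end shifts never leave the precursor (this keeps
offset draws rejection-free and hence unbiased).

## Cleavage profiles

A `CleavageProfile` holds two probability tables over signed end offsets
(`off5 = read_start − mature_start`, positive = 5'-truncated;
`off3 = read_end − mature_end`, positive = 3'-extended; the canonical form
is (+0, +0)), a four-way category mixture over
(rRNA/tRNA, miRNA, genome, unmapped), and a per-base substitution error
rate. The two presets encode the qualitative contrast the pipeline is built
to detect; the exact probabilities are presets, not measured quantities:

* **cancer-like** — `p5 = {0: .86, +1: .06, −1: .05, +2: .03}`,
  `p3 = {0: .86, −1: .06, +1: .05, −2: .03}` (joint canonical mass 0.74),
  mixture (0.25, 0.55, 0.15, 0.05);
* **non-cancer-like** — `p5 = {+1: .40, +2: .28, 0: .18, +3: .08, −1: .06}`,
  `p3 = {−1: .40, −2: .28, 0: .18, −3: .08, +1: .06}` (modal form (+1, −1),
  i.e. a 20-nt read truncated at both ends), mixture
  (0.40, 0.35, 0.20, 0.05).

The miRNA mixing fraction is deliberately higher in the cancer-like preset
so that locus RPM is higher in the cancer group, and the default experiment
uses 2 cancer-like and 3 non-cancer-like libraries of 50,000 reads each —
the group sizes of the study design being emulated, at a read depth chosen
so the whole experiment runs in about a minute on one CPU while leaving
every offset class with hundreds of reads. The default per-base error rate
is 1%, a conventional order of magnitude for short-read substitution error.

What the simulator does **not** emulate: quality-score structure (all bases
get a dummy Phred 40), indels and non-templated 3' additions, adapter
read-through, ligation and PCR bias, colorspace encoding, and any
sequence-dependent error structure. Passing tests therefore demonstrate
correctness of the pipeline's bookkeeping and statistics under a clean
substitution-only error model — not robustness to every artifact of real
library preparation.

## Classification

Reads are first length-filtered to 10–40 nt inclusive, then tested against
the tiers in order; the first tier with ≥1 hit wins and later tiers are not
consulted. Matching is ungapped Hamming comparison on the sense strand with
a default budget of 1 substitution — reads are ≤40 nt and references are
stored as transcripts, so gapped or reverse-strand alignment would add
nothing. Within the winning tier every hitting reference is recorded, and a
multi-mapping read increments **every** hit feature while counting once for
its category (the two miR-196a loci share the mature arm, so the same reads
legitimately appear at both); feature counts may therefore exceed the
category count, and the tested invariant is the policy-consistent one. The
matcher enumerates all windows via a NumPy sliding-window view and is
checked against an exhaustive position-by-position scan; identical read
sequences are resolved once and cached.

RPM = 1e6 × feature_count / mapped_reads, where mapped_reads counts all
reference-mapped reads including the decoy tier by default; a flag excludes
decoys from the denominator for users who prefer the post-contaminant
convention. Zero mapped reads is an explicit error, never a NaN.

## IsomiR profiling

IsomiRs are keyed by (precursor, off5, off3, sequence): positional identity
first, with sequencing-error variants of the same coordinates collapsing by
coordinates while distinct sequences remain visible in the table. Only
mature-overlapping hits enter a locus spectrum; hits elsewhere on the
hairpin (e.g. un-annotated 3'-arm products) are reported in a separate
table rather than forced into the mature coordinate frame, since no
canonical annotation exists for them. Size spectra are percentages of locus
reads per attained length and sum to 100. The dominant isomiR is the
highest pooled count, with ties broken toward the smaller |off5|+|off3| and
then the smaller off5. Group comparison aggregates the unweighted mean of
per-sample locus RPM (each sample is already depth-normalized) and calls a
group *canonical-dominant* when its modal offsets are (0, 0), *truncated*
when the modal off5 ∈ {+1, +2} and modal off3 ∈ {−2, −1}, and
*indeterminate* otherwise. The comparison is deliberately descriptive — no
test is attached to a 2-vs-3 library contrast.

## Statistics

* **Comparative Ct:** rq = 2^(−ΔΔCt) with ΔCt = Ct_target − Ct_reference
  (U6-analog) and ΔΔCt measured against a calibrator sample whose rq is
  exactly 1. Replicate Cts are averaged; rq is invariant to adding a
  constant to all Cts.
* **Screen:** per feature, Welch's unequal-variance t on log2 values and a
  geometric fold change (difference of mean log2, exponentiated); selected
  iff p < α (0.05) and fold ≥ 2 in either direction. Log/geometric scale is
  the standard treatment for intensity-like data. No multiple-testing
  correction by default (a Benjamini–Hochberg column is available behind a
  flag but does not alter selection).
* **Group tests:** paired t as a one-sample t on differences; Tukey–Kramer
  via the studentized range with the unequal-n Kramer adjustment;
  Mann–Whitney U with exact enumeration for total n ≤ 12 without ties and
  otherwise a normal approximation with tie correction and no continuity
  correction. All tests are two-sided at α = 0.05. Degenerate inputs
  (zero-variance groups, zero-variance differences) raise errors rather
  than returning NaN; fully tied Mann–Whitney data return p = 1.
* The scipy.stats engines compute the test statistics; the contracts above
  (error behavior, the exact/asymptotic switch, the screen rule) are this
  package's, and the test suite checks the results against independent
  oracles (closed-form Welch, exhaustive enumeration, the studentized-range
  distribution directly).

## Numerical and design choices

* Per-sample seeds derive from the run seed by SHA-256, keeping every seed
  below 2^31 and runs byte-reproducible end to end.
* Probability tables must sum to 1 within 1e-9; RPM is exact to floating
  tolerance; spectra sum to 100 within 1e-6.
* Non-miRNA fragments (decoy/genome/unmapped) are drawn at 18–30 nt so that
  chance cross-tier matches at ≤1 mismatch are negligible (~4^-18 scale),
  which is what makes error-free truth recovery exact.
* Type-I calibration of the Mann–Whitney test is measured at n = 12 vs 12,
  where the asymptotic branch runs; at very small n the exact test's
  discreteness caps the attainable level well below 0.05, which would
  measure discreteness rather than calibration.
* The config file is a flat YAML mapping; validation collects the complete
  list of violations rather than failing on the first.

## Known limitations

* The naive window scan is fine for kilobase-scale backgrounds but would
  need a seeded index for a real genome; emitting SAM/BAM is likewise out
  of scope (the assignments TSV is the exchange format).
* The screen operates on an already-normalized expression matrix;
  platform-specific normalization is upstream of this package.
* Offset presets are qualitative stand-ins: real cleavage-offset
  distributions vary by locus and tissue, and the pipeline's calls should
  be read as reproducing a pattern, not estimating biological rates.
* Amplification-efficiency correction (Pfaffl-style) is not implemented;
  the comparative-Ct method assumes ~100% efficiency for both assays.
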