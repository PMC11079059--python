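# Methods

## Scope and data model

`vhhseq` characterizes a VHH amplicon library sequenced with paired-end
2×300 chemistry, before and after one selection round. The unit of
analysis is the merged amplicon (~371 nt). All stages operate on plain
sequence strings; copy counts ride along in `ClusterSet`/`ClonePool`
multisets. The reference construct carries the reading frame
(`frame_offset=1`, i.e. translation starts at the second base), an ordered
FR1–FR4/CDR1–CDR3 interval map in 0-based half-open nucleotide
coordinates, the primer-binding intervals, and the offset of the insert
from the plasmid origin of replication.

The bundled default reference is **synthetic**: the experimental VHH and
its CDR3 are proprietary, so the package ships an artificial camelid-style
scaffold (generic framework residues, preferred-codon back-translation)
whose 10-residue CDR3 fixes the residues used by the positional analyses
(P1, Q2, R4, S5, A6, R7, L8, S9) and fills positions 3 and 10 arbitrarily.
All region coordinates are config-driven (`reference.fasta` +
`regions.yaml`), so a real construct substitutes cleanly.

## Read processing

* **Adapter removal**: an adapter prefix of ≥ `min_overlap` (11) bases
  matching the read with at most one mismatch per ten compared bases cuts
  the read at the match position. Note that low-complexity adapters can
  legitimately match one base early under this fuzzy rule.
* **Quality trimming**: 5-base windows slide 5'→3'; the read is truncated
  at the start of the first window whose mean Phred falls below Q25.
  Truncating at the window *start* makes the operation idempotent (all
  surviving windows passed already). Reads shorter than 150 nt before or
  after trimming are discarded. The trim direction follows the dominant
  MiSeq failure mode (3' decay).
* **Merging**: the reverse mate is reverse-complemented and slid against
  the forward mate; candidate overlaps need ≥ 11 bases and a mismatch
  fraction ≤ 1/3; the winner maximizes matches − mismatches, ties broken
  toward the longest overlap. Consensus keeps agreeing bases, prefers the
  higher-quality base on disagreement, and emits `N` on an equal-quality
  disagreement. Input `N`s never count as mismatches and defer to the
  mate. This is the pipeline's only source of new `N`s; real data may also
  carry basecaller `N`s, which are handled transparently.
* The report always reconciles: raw = merged + discarded + unmerged.

## Translation, clustering, statistics

Frame-2 translation uses the standard genetic code; codons containing `N`
give `X`; stops give `*`; trailing partial codons are dropped. Sequences
containing a stop are the "low-quality" fraction.

Clustering is exact string equality — a deliberate simplification of
100 %-identity clustering with length-asymmetric containment: at
full-amplicon read lengths containment differences are negligible, and
exact equality is verifiable against a brute-force partition oracle.
`N`/`X` are literal symbols, so the merged pool deduplicates exactly as
written.

Ledger formulas: DNA diversity = nt clusters / merged reads; protein
diversity = aa clusters / functional sequences. The denominator choice for
protein diversity (functional rather than merged) is the one consistent
with every published worked example the test suite reproduces. Percentages
are rounded half-up to two decimals, with 0-decimal headline figures.

## Region analysis

Cluster representatives are aligned to the reference with a global
affine-gap aligner (match +1, mismatch −1, gap open −4, gap extend −1,
end gaps penalized; Biopython's `PairwiseAligner`, checked against an
exhaustive Gotoh DP in the tests). Equal-length queries within 20 %
mismatches take a gap-free fast path — under this scoring a gap pair costs
at least two opens (−8), which such queries can never recoup.

Region sequences are the query symbols aligned to the reference columns of
the region; gapped extractions are flagged and excluded from positional
tallies (their mass is reported as `excluded_units`).

Per position: symbol frequencies over reads (copy-weighted) or clusters;
PID = frequency of the reference symbol, with `N`/`X` counting against it;
the regional consensus is the arithmetic mean of per-position PID.
Information content is `log2(|A|) − H` on the canonical-alphabet
frequencies renormalized after removing the ambiguous mass, which is
reported separately — no small-sample correction, as pool sizes dwarf the
alphabet. Positions are numbered 1-based within the region.

Mutation ranking enumerates non-reference, non-ambiguous symbols sorted by
frequency (ties: position, then symbol). Clone reports classify each
substitution as transition/transversion by the standard purine/pyrimidine
definition and as synonymous or not by single-substitution codon
replacement; indels are reported without a synonymy call. Mutations inside
primer intervals are flagged so they can be excluded from library-level
interpretation (primer-site artifacts inflate cluster counts).

## Enrichment comparison

Codon enrichment works on *clusters* (distinct nucleotide sequences), not
reads: for each requested CDR3 amino-acid position, the percent of
clusters carrying each codon, in both pools; fold = post/pre; codons new
to the post pool get fold = ∞; codons whose codon window is gapped or
contains `N` are excluded from numerators and tallied separately, so
per-position frequencies sum to ≤ 100 %. The significance rule applies to
the post-selection frequency only: a call requires post ≥ 0.1 %, the
accepted MiSeq substitution error rate — a codon absent before selection
cannot have a meaningful pre-frequency test, and depletion calls are out
of scope. `encoded_aa` always comes from the codon table; published codon
tables occasionally mislabel blocks (e.g. an ACx block labeled tyrosine
though it encodes threonine), and deriving from the table sidesteps that.

The comparison report adds the protein-diversity delta (percentage
points), copy-number histograms (buckets 1…9, ≥10, percentages over
clusters so bucket 1 equals the singleton fraction), reference-region
fractions, and CDR3 positions with PID > 95 % in both pools.

## Simulator

* **Mutagenesis** emulates a low-fidelity DNA polymerase I mutator strain
  over four iterative rounds. `per_base_rate_per_round` is the *mean*
  per-base substitution probability per round; the position-rate vector —
  substitution-weight row sums (site mutability) times the ori-proximal
  hotspot multiplier — is normalized to that mean over the reference, so
  the biases redistribute mutations rather than inflate them. The default
  rate 1.5×10⁻³ gives ≈ 2.2 substitutions per 371 nt clone after four
  rounds (P(≤3) ≈ 0.8), matching the regime where most library members
  carry few mutations. The default weight matrix gives every base's
  transition partner exactly 0.8 of the conditional mass (so the expected
  transition share is exactly the `transition_fraction` parameter,
  estimable by a binomial CI) and doubles the G row, making G sites twice
  as mutable and G→A the predominant single substitution. The hotspot is a
  step multiplier (default 5×) on plasmid coordinates within 750 bp of
  ori; with the default insert offset (292) the whole insert is inside the
  window, so the default is effectively neutral after normalization, but
  constructs straddling the boundary redistribute as expected. Indels are
  off by default (substitutions dominate this mutagenesis chemistry); when
  enabled they are rare single-base events applied per copy after the
  substitution rounds. An optional event log records every substitution
  (copy, round, position, from, to); spectrum estimates should use it,
  since end-state comparisons are biased by multi-hit sites (≈ 0.796
  apparent transition fraction at rate 0.01×4 rounds versus the true 0.8).
* **Selection** samples exactly `n_events` (default 706) copies with
  replacement, probability ∝ copy count × affinity weight — FACS events
  are independent observations of an abundant phage pool, hence
  with-replacement sampling.
* **Sequencing** emits `depth` read pairs (forward = first 300 nt, reverse
  = reverse complement of the last 300 nt), substitution errors i.i.d. at
  `substitution_error_rate` (default 10⁻³, uniform over the three
  alternative bases, independent of the reported quality — a
  simplification; real errors correlate with quality), and qualities drawn
  from a per-cycle mean profile (default Q37 decaying to Q30) plus
  Gaussian noise, clipped to [2, 41]. A truth table maps each read to its
  source clone.

What the generator does *not* emulate: PCR chimeras and index hopping,
quality-dependent error rates, display-efficiency or helper-phage biology,
and real basecaller `N`s. Passing tests therefore demonstrate the
correctness of the analysis operations and the recoverability of the
modeled parameters, not robustness to every artifact of real MiSeq runs.

All three operations are bitwise reproducible under fixed seeds.

## Problem sizes and numerical choices

The test suite and acceptance script use scaled-down pool sizes chosen as
representative working points: mutagenesis spectrum recovery at 10,000
copies (~1.5×10⁵ events), error-rate recovery at >10⁶ sequenced bases,
noiseless round-trip at 1000 pairs, and a full pipeline pass at 3000/6000
read pairs against the study-scale 14k/40k raw reads. Binomial
confidence intervals are exact (Clopper–Pearson at 99 %). Percentages are
rounded half-up (`decimal`), matching how the reproduced tables round.
Fold enrichments are kept at full precision internally and rounded to two
decimals for reporting.

## Known limitations

* Exact-equality clustering treats a single `N` as a distinct sequence,
  slightly inflating nucleotide cluster counts on noisy data (as any
  literal deduplication does).
* The merger considers a single best overlap; amplicons shorter than the
  minimum overlap, or pairs whose true overlap is dominated by errors,
  come out unmerged rather than error-corrected.
* Positional profiles exclude gapped/length-deviant regions rather than
  realigning them; with ≤ ~4 % length deviants this loses little.
* The significance rule is a threshold, not a statistical test — by
  design, mirroring the error-rate floor convention it reproduces.
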