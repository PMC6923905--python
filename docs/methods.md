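# Methods

## Model and assumptions

The corrector assumes two datasets from the same sample: short reads with
low, substitution-dominated error (~1%) at high coverage (tens of x), and
long reads with high, indel-dominated error (~13%). Because every k-mer of
an error-free long-read region was also sampled by many short reads, the
short-read k-mer spectrum separates cleanly into *solid* k-mers (counts
near the sequencing depth) and *error* k-mers (counts near 1). Two signals
drive the two correction phases:

1. **Coverage collapse marks indels.** A single error corrupts the k
   overlapping k-mers, so a run of below-threshold ("weak") windows in a
   long read localizes an error region, and its flanking solid k-mers
   anchor a local assembly in the de Bruijn graph. Among all graph paths
   between the anchors, the true sequence is the one least likely to
   contain any low-coverage k-mer, hence the **widest (maximum-bottleneck)
   path** criterion: maximize the minimum vertex coverage along the path.
   An erroneous path may contain high-coverage stretches, but it almost
   always traverses at least one poorly-supported k-mer that caps its
   bottleneck.
2. **Coverage skew marks substitutions.** Within a short-read-sized
   fragment of a long read, k-mer abundances are expected to be homogeneous
   (the fragment derives from one genomic locus). A fragment that is mostly
   high-coverage with a few low-coverage outliers is carrying isolated
   substitution errors; its Pearson median skew 3·(mean − median)/σ is
   pushed away from zero while the median — robust to a few outliers and
   only weakly dependent on k — stays at the local depth. Fragments with
   near-zero skew, or with a median far below the spectrum median (genuine
   low-coverage loci), are accepted as correct. This is what protects true
   low-coverage regions that count-threshold methods misclassify.

Both phases operate per read and are order-independent, so correction
parallelizes trivially (the `workers` option maps reads over a fork-based
process pool with results identical to serial execution).

## Parameters

| parameter | default | units / range | rationale |
|---|---|---|---|
| `k` | 21 | bases | large enough that 4^k vastly exceeds desk-scale genome sizes (k-mers are locus-specific), small enough that an error-free k-mer window is still common at 13% error |
| `canonical` | true | — | short reads sample both strands; merging a k-mer with its reverse complement restores full effective coverage. `--no-canonical` gives literal single-strand counting |
| `tau` | 3 | count | weak/strong threshold; at ~40x effective k-mer depth with 1% short-read errors, error k-mers have counts 1–2 while solid ones sit near depth, so any small cutoff separates them |
| `max_len_factor` | 2.0 | — | path search is capped at ceil(factor·(weak span + 2)) vertices; a replacement should have roughly the span of the region it replaces, and an unbounded bottleneck search in a cyclic graph does not terminate usefully |
| `b` | 100 | vertices | greedy traversal backtracks after this many successive vertices |
| `frag_len` | 100 | bases | fragment length for substitution statistics; matches the short-read length, the scale at which k-mer abundances are expected homogeneous |
| `skew_low`, `skew_high` | −0.3, +0.3 | — | accepted skew interval; a symmetric near-zero band. One zero-coverage outlier among n windows alone contributes ≈ −3/√(n−1) ≈ −0.34 at n = 80, so the band rejects even single-error fragments while tolerating ordinary sampling noise |
| `low_median_factor` | 0.5 | — | a fragment is "mostly low-coverage" (protected) when its median is below half the spectrum median. Sampling noise places the medians of ordinary fragments *at* the spectrum median, so a protection cutoff at the median itself would randomly absorb genuine error fragments; half-depth is far below the typical-depth distribution but far above error-k-mer counts |
| `tau_low` | = `tau` | count | error-window cutoff inside flagged fragments |
| `thresh_high` | max(`tau`, ⌈median/4⌉) | count | voting acceptance threshold in high-coverage areas. The spectrum median itself would reject the true base whenever a window's sampled coverage dips below the median (half the windows); a quarter of the median keeps ≥4σ margin below typical depth and above error counts |
| `thresh_low` | = `tau` | count | voting threshold in low-coverage areas |
| `spectrum_stat` | instances | — | the spectrum median used for classification and thresholds weights each k-mer by its count. The median over *distinct* k-mers collapses to 1 whenever error k-mers outnumber genomic ones (they do at 1% short-read error), which would erase the high/low-coverage distinction; both modes are exposed on `DeBruijnGraph.spectrum_median` |

## Numerical and algorithmic choices

- **Widest path.** Best-first search ordered by (width desc, length asc,
  path lex), the bottleneck analogue of Dijkstra, with Pareto pruning of
  (width, length) labels per vertex. A walk's width never increases as it
  grows, so dominated prefixes can be discarded without losing optimality,
  and cycles never help (they cannot raise width and always add length),
  so the returned path is optimal among all walks within the length bound.
  Ties resolve to the shorter path, then lexicographically, making results
  deterministic and independent of insertion order.
- **Path width** is defined over vertex coverages including both endpoints;
  counts live on vertices, not edges.
- **Splice arithmetic.** A weak region spanning k-mer indices [ws, we)
  replaces read bases [ws−1, we+k) — both boundary k-mers included verbatim
  — so strong-region bases are preserved byte-identically. Replacements are
  applied right-to-left; adjacent replacements may overlap inside a short
  shared strong region, but the overlapping bases are boundary k-mers that
  both the read and every spelled path contain verbatim, so the splices
  agree. Weak regions at read tips (one anchor only) are left unchanged.
- **Alignment.** `global_align` is an exact Needleman–Wunsch with linear
  gaps and deterministic tie-breaking (match/mismatch over deletion over
  insertion), vectorized row-wise with the running-max trick for the
  serial in-row dependency. For long reads, error-set extraction and
  identity default to edlib's unit-cost aligner for speed; its occasional
  cost-equal representation of adjacent substitutions as an indel pair is
  gain-neutral (it swaps an FN for a TP+FP pair, leaving (TP−FP)/(TP+FN)
  unchanged). Indel gap runs are normalized by maximal left-shifting before
  set comparison.
- **Gain edge case.** When a read carries no real errors (TP+FN = 0) the
  gain is undefined; it is reported as 1.0 if FP = 0 and −1.0 otherwise,
  flagged `degenerate`.
- **Even-length medians** are the arithmetic mean of the two middle values;
  skew uses the population (not sample) standard deviation — the fragment's
  windows are the whole population of interest.
- **Degenerate inputs.** Reads shorter than k pass through indel correction
  untouched (reported, never dropped); reads shorter than one fragment are
  skipped by substitution correction; windows containing non-ACGT characters
  are excluded from counting and have coverage 0.

## What the simulator emulates — and what it does not

`simulate` generates an i.i.d. random reference (optional exact repeat
injection to force graph branching), short reads with uniform i.i.d.
substitutions from both strands, and long reads with i.i.d. per-base
insertion/deletion/substitution events (defaults 6%/5%/2% ≈ 13% total,
drawn categorically so each type's marginal rate is exactly nominal).
Every read carries an edit log that replays exactly onto its reference
interval, so ground-truth error sets are exact and no mapper is needed.

Deliberately not modeled: homopolymer-biased indels, position-dependent
error rates, quality values, chimeric reads, coverage biases (GC, mappability)
and genome-scale repeat structure. Passing tests therefore demonstrate the
correction logic under the stated coverage/error model, not performance on
real instrument data, where clustered errors and repeats make anchors
scarcer and local assembly more ambiguous.

## Problem sizes used by tests and the acceptance script

Unit tests run on a 2 kb reference; the end-to-end suite and
`scripts/acceptance.py` use a 50 kb reference with 50x short reads and 10x
long reads of mean 5 kb (100 reads), with three replicate seeds where
averages are reported — sizes chosen so the full coverage/error regime of
the method is exercised while a complete run stays within a minute or two
on one CPU.

## Known limitations

- Substitutions within ~7 bases of a fragment boundary are covered by only
  3–4 windows that lie fully inside the fragment; their skew signature is
  statistically indistinguishable from coverage noise and they can evade
  detection. (Fragment statistics are intentionally computed from fully
  contained windows only.)
- Weak regions at read tips are not corrected by default: with a single
  anchor the assembly problem is one-sided and unbounded.
- In exact repeats longer than k, the widest path can legitimately prefer
  the wrong repeat copy (both are genomic and well covered); the gain
  ordering of traversal strategies still holds on repeat-bearing
  simulations, but absolute gain degrades with repeat content.
- The graph is held exactly (no approximate counting); memory is ~100 bytes
  per distinct k-mer, appropriate for desk-scale genomes (tens of Mb), not
  for mammalian-scale spectra.
- Correction never trims: a read whose errors cannot be repaired is
  returned unchanged rather than shortened, by design (depth preservation
  over alignment-rate cosmetics).
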