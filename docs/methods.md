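# Methods

## Clone identity and functionality

A clone is the pair (TRBV gene call with the `*NN` allele suffix
stripped, CDR3 nucleotide sequence). Nucleotide-level identity is
required because the pipeline matches the *same physical clone* across
platforms, tissues and timepoints; amino-acid identity would pool
convergent rearrangements. An amino-acid key (`make_clone_key_aa`) is
provided for analyses that want that pooling.

A junction is *functional* when it is in-frame (length a multiple of 3),
its translation contains no stop codon, and the translation carries the
conserved anchors (starts with Cys, ends with Phe or Trp). The anchor
requirement follows community convention for productive rearrangements
and can be relaxed (`require_anchors=False`). All frequency denominators
in the package are totals over functional reads or cells only;
non-productive clonotypes never enter any denominator.

Counts are raw read duplicates (bulk) or cell counts (single-cell); no
UMI handling is attempted, matching pre-UMI 5′-RACE protocols.

## Expansion statistics

* `call_ecs`: an expanded clone has frequency **strictly greater** than
  the threshold ("more than 0.2%" is read as a strict inequality, so a
  boundary clone is excluded); the EC rate is cumulative EC reads over
  functional reads.
* `shared_clone_rate`: the shared set is the key intersection; each
  sample gets its own rate (shared reads over that sample's functional
  total). The per-sample denominator was chosen over a pooled one
  because the quantity is a property of each sorted subset.
* `compare_groups`: classical pooled-variance Student's t-test
  (two-sided) by default, Welch via `equal_var=False`. Zero-variance
  degenerate inputs are resolved explicitly (equal means → t = 0,
  p = 1; separated means → infinite t, p = 0) instead of returning NaN.

## FACS-size-corrected subset distribution

For a clone and a sorted subset *s*, the corrected contribution is
`f_s × φ_s`, where `f_s` is the clone's frequency among the subset's
functional reads and `φ_s` the flow-cytometry fraction of that subset
within all CD4⁺ T cells. Contributions are reported raw (fractions of
all CD4⁺ cells) *and* normalized to shares summing to 1; the normalized
form is the default for plotting since stacked proportion figures do not
distinguish the two. The four memory helper subsets are not forced to
partition the memory gate (the CXCR3⁺CCR6⁺ double-positive gate is
absent from the scheme), only bounded by it. A clone detected in no
subset yields an all-zero distribution with a warning — dropout at low
depth is expected, not an error.

## Tracking and persistence

Two expansion definitions coexist: bulk (frequency threshold, default
0.2%) and single-cell (observed in more than one cell, the natural
criterion when only ~10² cells are sampled). They are never mixed
implicitly: each sample is judged by its own platform. A clone is
*persistent* when it meets the EC criterion at ≥2 distinct timepoints
within one compartment (tissue + subset) — mere presence is not enough.
Persistent clones receive IDs `Ci.j` with `i` the subject index (parsed
from trailing digits of the subject label, overridable) and `j` ranking
by mean frequency across all tracked samples, ties broken
lexicographically by clone key, making labels stable under sample
reordering. The mEC of a single-cell sample is the unique maximal EC;
a tie leaves the mEC undesignated rather than broken arbitrarily.
Cross-tissue intersection uses presence ≥1 functional read — the most
permissive reading of "detected" — and is configurable upstream by
filtering inputs.

## Error correction and platform concordance

The correction stage is a deliberately simple, fully specified
absorption rule: a child clonotype with the same stripped V call, a
CDR3 of equal length at Hamming distance 1 from a parent, and count
≤ `ratio_threshold` × parent count is merged into the parent. Parents
are processed in descending count order (ties by lexicographic CDR3);
each child is absorbed at most once, by its largest eligible parent.
The procedure is deterministic, conserves total reads exactly, never
creates new keys, and runs *before* functional filtering because a
substitution can toggle productivity. It does not model indels or
quality scores and is not a reimplementation of any published
corrector; its accuracy is measured, not assumed, via the simulator's
provenance channel (`evaluate_correction`): spurious clonotypes =
observed keys matching no true clone; misassigned reads = reads filed
under a true clone other than their own; ρ to truth = Spearman
correlation between observed and true frequencies over true clones.

Concordance treats the single-cell sample as gold standard: each
single-cell clone's frequency is paired with its bulk frequency (0 when
undetected) and summarized by Spearman ρ (average-rank ties) plus
detection sensitivity. When a paired vector is constant there is no
rank information and ρ is reported as 0 with p = 1 rather than NaN.

## Synthetic repertoire generator

The generator emulates the latent structure the analyses are built to
detect, not any particular dataset:

* **Clone-size law** — discrete power law `rank^(−a)`; default
  `a = 1.0` (classic Zipf), the accepted heavy-tail stylization of
  repertoires. No richness calibration is claimed: the study setting
  provides none, so `n_clones` and depth defaults are declared
  arbitrary.
* **Designated persistent clones** — `n_dominant` clones pinned at
  fixed frequencies (default halving ladder 0.10, 0.05, …) in every
  memory-side compartment at every timepoint; they are strictly
  memory-phenotype, always present in the synovium, and homed to the
  non-Th1/Th17/Tfh subset when helper leaves are simulated.
* **Subset placement** — each other clone has a home subset among the
  gates actually simulated; a compartment holds the clones its gate
  covers, with log-normal jitter (sd 0.3) across compartments. A
  fraction `cross_subset_share = 0.05` of clones straddles phenotype
  gates, producing small but nonzero naive/memory sharing; a fraction
  `synovium_share = 0.1` seeds the synovium. These values are single
  realistic choices, not fits.
* **Bulk noise** — one log-normal per-clone PCR amplification factor
  (sd `pcr_bias_sd`, typical 0.5) applied before a multinomial read
  draw, then i.i.d. per-base substitutions (rate typical 1e-3; no
  indels, errors confined to the CDR3, V call inherited) with reads
  re-aggregated into observed clonotypes. Substitution and bias at 0
  reduce exactly to multinomial sampling of truth. The per-read error
  count is drawn as Binomial(L, rate) conditioned on ≥1 for the
  error-bearing reads, which is distributionally identical to mutating
  every base of every read independently.
* **Single-cell sampling** — an error-free multinomial draw of cells
  (default cap 102 per sample, the operational limit of the emulated
  protocol), the gold-standard arm.
* **Provenance** — every sample carries a hidden map from observed
  clone keys to true-clone read counts; truth-based evaluations consume
  it, analyses never do.

What the generator does *not* emulate: germline V(D)J recombination
statistics (CDR3s are random stop-free C…F sequences), indels, UMI
structure, alpha chains, read-level quality, or library-size variation.
Passing tests therefore demonstrate correctness of the statistics and
of noise handling under this model, not performance on any real
sequencing run.

## Problem sizes in the shipped studies

The test suite and `scripts/acceptance.py` run at sizes chosen to make
the statistical properties measurable while keeping full runs fast on a
single CPU: bulk depth 5×10⁴–10⁵ reads (inside the 10⁴–10⁶ band typical
of the emulated platform), 100–5000 true clones, 102-cell single-cell
samples, 20–100 seed replicates per property. The acceptance script's
cohort study uses 4 "expanded" subjects (5 dominant clones) vs 4
"control" subjects (none) over a diverse background
(`n_clones = 5000`, `a = 0.5`), which yields memory EC rates around
0.25 vs 0.11 and naive/memory sharing below 10% — qualitatively the
regime the analyses target.

## Known limitations

* The power to call a persistent clone from 102-cell samples falls
  steeply below ~5% true frequency: a 2% clone is seen ≥2 times in one
  sample with probability ≈0.61 only, so persistence calls near that
  size are unreliable by design of the single-cell EC criterion, not by
  implementation.
* The Hamming-1 corrector cannot rescue reads with ≥2 substitutions or
  children of parents too small for the ratio gate; residual spurious
  clonotypes after correction are expected at roughly the multi-error
  read rate.
* Clone identity ignores J calls and out-of-junction variation; two
  rearrangements differing only outside the junction collapse.
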