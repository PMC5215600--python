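# Methods

## Model and assumptions

The toolkit treats stochastic labeling as a balls-in-bins occupancy
process: each of N template molecules independently draws one tag from a
uniform space of C = 4^L sequences. Three consequences drive everything
else:

1. **Forward occupancy.** The expected number of distinct incorporated
   tags is E[H] = C(1 − (1 − 1/C)^N). Collisions (two molecules sharing a
   tag) are why raw unique-tag counts under-count molecules.
2. **Collision correction.** Inverting the Poisson approximation gives
   N̂ = −C ln(1 − S/C) for an observed unique-tag count S. The exact
   round trip through the forward model recovers N·(−C ln(1 − 1/C)), a
   multiplicative bias of 1 + 1/(2C) + O(C⁻²) — below 0.001% for
   C = 65,536, which is why the continuous estimate is reported un-rounded.
3. **Tag discovery vs depth.** Conditional on H incorporated tags, reads
   are modeled as uniform with-replacement draws from those tags (equal
   post-labeling abundances). The expected discovery increment at read n
   is r^(n−1) with r = (H−1)/H, and the expected distinct-tag count after
   n reads is the geometric sum H(1 − r^n). The uniform-draw sampling
   model is an explicit modeling choice: it ignores amplification noise
   among molecules of the same taxon, which is acceptable because depth
   planning only needs the expectation's saturation behavior.

Assumptions inherited from the protocol: tags are incorporated exactly
once per molecule before any exponential amplification; tag synthesis is
uniform over the 4^L space (no synthesis bias); molecules of different
taxa are distinguishable by their amplicon sequence, so tag identity is
scoped within taxon.

## Parameters that matter

| Parameter | Default | Meaning / rationale |
|---|---|---|
| `tag_length` L | 8 | Octamer tags, C = 65,536. L = 9 extends the upper quantification limit ~4×. |
| saturation threshold | 0.8 occupancy | Warn when S/C > 0.8: the estimator's sensitivity d ln N̂ / d ln S ≈ (S/C)/((1−S/C) ln(1/(1−S/C))) grows without bound near saturation. The underlying protocol degrades above ~10⁵ copies for C = 65,536 but names no cutoff; 0.8 is this package's choice. |
| `reads_multiplier` | 10 | Ten reads per template copy: enough to saturate tag discovery (1 − e⁻¹⁰ of tags seen in expectation) while limiting error-derived spurious tags. |
| `per_base_error` | 5×10⁻⁴ | Typical Illumina substitution rate; corrupts a tag with probability 1 − (1−p)^L ≈ 0.4%, the dominant upward bias at 10× depth. |
| `labeling_efficiency` | 1.0 | Fraction of templates tagged during primer extension. Sub-unit efficiency scales estimates down proportionally; no measured value exists, so it is a free knob. |
| primer `max_mismatches` | 0 | Conservative exact IUPAC matching; configurable. |
| search window | adapter + L + 4 | The construct fixes the primer position; bounding the window prevents spurious internal matches. |
| `min_identity` | 0.97 | Conventional species-level identity threshold for reference binning. |
| `subsample_n` | none | Fixed per-sample read budget, drawn without replacement with a recorded seed. Exposed per sample (not per taxon): the read budget in practice is a property of the sequencing run. |
| bootstrap replicates | 1,000 | Percentile interval over read-resampling. |

## What the simulator emulates — and what it does not

The generator reproduces: uniform stochastic labeling; per-taxon
amplification bias (default: taxon-level read-share weights, since tags
are fixed before PCR and only the read-sampling distribution reaches the
estimator; optionally a per-molecule Galton–Watson doubling model over
`pcr_cycles` cycles); uniform substitution errors (error counts drawn
binomially per read block, positions uniform); per-taxon concrete
realizations of the degenerate primers; and constant Q37 qualities.

It does **not** emulate: indels, chimeras, polymerase-specific error
spectra, quality-score profiles, tag-synthesis bias, paired-end structure,
or real 16S sequence divergence — the bundled six "mock" references are
synthetic random 250-mers (pairwise ~25% identity), named after the roles
the mock species play, not their sequences. Passing tests therefore show
that the estimator chain is correct *under the stated generative model*;
they do not show robustness to indel-rich platforms, to closely related
taxa near the 0.97 identity boundary, or to non-uniform tag chemistry.

## Numerical choices

- All logarithms natural; `log1p`/`expm1` forms throughout
  (−C·log1p(−S/C), H·(−expm1(n·log1p(−1/H)))) keep precision at both
  occupancy extremes and for large H.
- S ≥ C raises a typed saturation error; per-taxon saturation inside a
  multi-taxon run produces a warning row (infinite estimate) instead of
  aborting, and infinite rows are excluded from relative abundances.
- H = 1 is handled as an exact special case (r = 0, with 0⁰ ≡ 1 at n = 1).
- `required_reads` computes ⌈ln(1−f)/ln(r)⌉ and then enforces the defining
  inequalities directly to absorb floating-point edge cases.
- Extraction rejections are data (categorized counts that partition total
  reads), not exceptions. Ties in reference binning go to the first
  reference in input order, deterministically.
- Binning identity is edit-distance-based global alignment
  (1 − d/max length); reads are first trimmed of their terminal
  reverse-primer match so the compared region is the bare inter-primer
  amplicon. Identical amplicon strings are aligned once and cached.
- Subsampling uses numpy's seeded Generator, without replacement; the seed
  is recorded in every output row.

## Design choices where the design was open

- **Hamming-1 tag collapse is off by default.** The default mitigation for
  error-derived tags is depth limitation (use no more reads than needed),
  which matches how the protocol is operated; clustering-style collapse is
  available as an explicit extension flag.
- **The bootstrap CI quantifies read-sampling variability only.** At 10×
  depth nearly all estimator variability comes from the labeling process
  itself (which realized H the molecules drew), which resampling reads
  cannot see; the interval is deliberately labeled as an extension and
  should not be read as a credible interval for N. Empirically its width
  is an order of magnitude smaller than labeling noise.
- **Relative abundances are computed from collision-corrected estimates**,
  never from raw read shares — the whole point of tagging is that read
  shares are bias-contaminated.
- **Per-taxon amplification as read-share weights** rather than explicit
  cycle branching by default: the estimator only ever sees the read
  distribution, so the lighter model is sufficient for every supported
  analysis; the cycle-level mode exists for studying amplification
  variance itself.

## Problem sizes used in validation

The test suite and the acceptance script run the full chain at 5×10³–5×10⁴
templates with 10× reads (up to 5×10⁵ reads per run, three seeds), the
saturated regime at 5×10⁵ templates with a 2×10⁵-read budget, a
6×3,333-copy equimolar community, and a 1:3-biased two-taxon community —
sizes chosen to exercise the accurate band, the saturation regime, and the
bias-immunity contrast at full scale on a single CPU in about a minute
each.

## Known limitations

- The estimator assumes uniform tag usage; synthesis bias in degenerate
  oligos would shrink the effective C and bias estimates upward.
- Sequencing errors inflate S by roughly p·L·(read multiplier)·(1 − S/C)⁻¹
  percent; at default settings this is a ~1–5% upward bias, visible in the
  validation numbers. Error collapse (off by default) trades this for
  possible merging of genuinely distinct tags.
- Reference binning is nearest-reference assignment, suitable for mock and
  simulated communities with divergent references — not a general-purpose
  taxonomic classifier.
- Sub-unit labeling efficiency is indistinguishable from a proportionally
  smaller template pool; the toolkit exposes the knob but cannot infer it.
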