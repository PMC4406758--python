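# Methods

This note records the models, conventions and numerical choices behind
`ampliqc`, in the spirit of a methods appendix: what each computation
assumes, which knobs matter, and what the synthetic data does and does
not emulate.

## Read model and orientation

A read is a DNA string with a Phred+33 quality string of equal length
plus provenance annotations (true sample/taxon for simulated reads,
assigned sample after demultiplexing). Tags and primers are stored in
the samplesheet in their synthesis (5'→3') orientation; a forward read
is laid out as

```
tag_f + primer_f + insert + revcomp(primer_r) + revcomp(tag_r)
```

reflecting single-direction sequencing of a dual-indexed amplicon. All
matching against the 3' end therefore uses the reverse complement of
the manifest entries (IUPAC-aware complementation). A
reverse-complement rescue pass is deliberately absent: reads are
assumed already in forward orientation.

## Synthetic libraries

The generator is the source of ground truth for every downstream test.
Its components:

- **Reference panel.** `random_panel(n, L, min_divergence)` builds one
  uniform-random L-mer and derives each further taxon by substituting
  `ceil(min_divergence·L)` positions spread evenly along the length at
  disjoint per-taxon offsets. Spreading matters: isolated substitutions
  cannot be re-registered by gap pairs under the default alignment
  scoring (mismatch −1 vs. gap −2), so the nominal divergence equals the
  aligned divergence. Any-vs-any divergence is ≥ `min_divergence` (the
  base) or ≥ 2·`min_divergence` (two derived taxa). The default 250 bp
  emulates a short mitochondrial 12S-type marker.
- **Template bottleneck.** Each sample's taxon mixture is realized in
  two stages: a multinomial draw of
  `template_copies · (1 − inhibition_factor)` effective template
  molecules fixes the template pool, and reads are resampled from that
  pool. With few effective templates, rare taxa receive zero templates
  in some replicates — reproducing the replicate dropout seen when
  inhibited or low-template extracts are sequenced. Inhibition is
  modelled purely as this effective-template reduction; full inhibition
  (factor 1) raises an error rather than emitting an empty library.
- **Error process.** Independent per-base substitution, insertion and
  deletion probabilities; indel rates are multiplied by
  `homopolymer_multiplier` inside base runs of length ≥ 3 and for 2
  bases downstream (low quality extends beyond the homopolymer itself);
  positional substitution overrides create hotspots at amplicon
  coordinates; a `run_multiplier` scales everything to emulate
  run-to-run variation (default 1 — no particular value is claimed).
- **Quality model.** Q = round(−10·log₁₀ p) + N(0, sd), clamped to
  [2, 41], where p is the per-position total error probability of the
  model and sd defaults to 2; an error-free base reports the cap (41).
  Because Q derives from the *rate* rather than the realized errors,
  per-read expected error (EE) is nearly constant within a library.
  One practical consequence, visible in the sensitivity grid: at an
  Ion-Torrent-like 0.5% uniform error a ~300-base read has EE ≈ 1.8 and
  a maxee-0.5 filter removes essentially every read, whereas at a
  good-run 0.1% (EE ≈ 0.3) the maxee cells stay populated. Real
  platforms show strong read-to-read quality variation that this model
  does not reproduce, so passing tests demonstrate the correctness of
  the filtering arithmetic, not platform-realistic retention rates.
- **Artefacts.** `inject_chimeras` replaces a seeded binomial fraction
  of reads with two-parent recombinants (single breakpoint, uniform in
  the interior, decoration preserved; the replacement read's quality is
  flattened to the original's mean Q, which no downstream stage
  consults before filtering). `inject_tag_carryover` re-tags a fraction
  of reads with decoy tag pairs generated deterministically and
  disjoint from the manifest. Contaminants displace true-taxon reads at
  fixed per-read rates and are labelled as such.

Degenerate IUPAC bases in primers are expanded uniformly at synthesis
time, per read. Identical inputs and seed give byte-identical FASTQ
output.

Not emulated (out of scope by design): platform flowgram/signal
simulation, paired-end reads, PCR-cycle-by-cycle amplification bias,
and quality miscalibration.

## Demultiplexing and auditing

Tag matching is anchored (5' prefix, 3' suffix) and always exact — no
mismatch in length or base composition; only the template-specific
primers take a 0/1/2-substitution allowance, IUPAC-aware and without
indels. Reads containing any non-ACGT call are discarded up front.
Reads shorter than tags + primers + 1 are unassigned, not an error.
Every input read lands in exactly one of assigned / unassigned /
discarded, and this partition is asserted.

The audit classifies the observed (tag_f, tag_r) of unassignable reads:
both tags known but never paired → cross combination (within-run tag
jumping); at least one tag unknown → foreign (cross-run carry-over).
`foreign_fraction` is the foreign-read percentage of the whole pool.
Note that under sequencing error an exact-tag audit also counts
error-corrupted tags as foreign; the carry-over tests therefore run at
zero sequencing error so that the injected rate is the only source of
foreign tags.

## Filtering

- maxee: keep iff EE = Σ 10^(−Q/10) ≤ threshold (default 0.5). An empty
  read has EE 0 and is kept.
- MIN_Q_PERCENT(q, p): keep iff ≥ p% of bases have Q ≥ q.
- MEAN_Q(q̄): keep iff mean Q ≥ q̄.
- Abundance: DROP_SINGLETONS removes count 1; FRACTION removes uniques
  strictly below f × denominator. "Below 1% of the total number of
  unique sequences" is ambiguous between an abundance reading (1% of
  reads) and a richness reading (1% of the number of uniques); both are
  implemented, defaulting to reads. Strict `<` throughout: ties are
  kept.

The four shipped quality presets (QFM1 none, QFM2 all-bases-Q15, QFM3
mean-Q20 with 2 primer mismatches, QFM4 maxee 0.5) span the common
definitions of a "high-quality sequence"; only QFM2 forbids individual
bases below Q15. They are plain `QFMSpec` values and fully
config-overridable.

## Clustering

Dereplication is exact full-length string identity with counts and
member ids retained; output order is (count desc, sequence asc), which
is also the clustering scan order. Identity is computed from a global
alignment (match +1, mismatch −1, gap −2, terminal gaps penalized) as
matches / alignment columns including gap columns — full-length
dereplication upstream implies length differences are meaningful.
Centroid joining is **first-fit** in abundance order (a unique joins the
first centroid reached at ≥ 97%), with centroid-creation order breaking
ties; a best-fit tool can assign borderline uniques differently, which
is why the suite pins the exact first-fit semantics against an
independent oracle. Among co-optimal alignments of near-identical
sequences the identity fraction is unique; for unrelated sequences it
is not, but no threshold decision in the pipeline depends on that
regime.

The chimera check is a minimal de-novo bimera detector: a unique is
flagged iff two distinct uniques, each with count ≥ `min_fold` (2.0) ×
its own, admit a breakpoint where left-from-A + right-from-B mismatches
undercut the best single parent by ≥ `min_improve` (3). The fold and
improvement defaults are this package's choices. Parents are never
flagged (no improvement over themselves is possible), and a candidate
more abundant than its putative parents fails the fold rule.

## Error spectrum

25 subsamples of 1,000 reads are drawn without replacement,
independently across subsamples. Each subsample is dereplicated; its
most abundant unique (lexicographic tie-break) is the reference. Every
read is globally aligned to the reference with a unit-cost
edit-distance aligner, and each reference position accumulates the
percentage of reads whose aligned symbol differs there — a gap (base
deleted in the read) counts as a difference; read insertions are not
scored, keeping the profile anchored on reference coordinates. The
original field procedure builds one multiple alignment per subsample;
per-read pairwise alignment is equivalent at low indel rates,
deterministic, and has no tool dependency — a documented deviation.
Per-subsample error is the positional mean; the overall rate is the
mean (and sd) over subsamples; 5-bp non-overlapping windows and a >1%
single-base hotspot rule summarize the profile. The aggregate per-base
vector averages the subsamples sharing the modal reference (references
are identical in practice for single-source data).

For uniform per-base error p estimated from a pool of `n_pool` reads of
length L, the overall mean concentrates on the pool's realized error
fraction (SE √(p(1−p)/(n_pool·L))); subsampling adds at most the
variance of depth·reps independent reads. The recovery tests use
SE = √(p(1−p)·(1/(n_pool·L) + 1/(depth·reps·L))) and a 3-SE band,
which held with margin across seeds during development at
p ∈ {0.001, 0.005, 0.02}.

## DTU collapse

Centroid p-distance is mismatches / compared columns with gap-containing
columns excluded (pairwise deletion); two sequences with no comparable
columns get distance 1. The collapse connects OTUs with distance
strictly below 3% and takes connected components (single linkage) —
inferred from the pairwise-threshold description of the original
in-house procedure; average linkage (UPGMA cut just below the
threshold) is offered since the linkage is not intrinsic to the rule.
Exactly 0.03 does not merge. DTU count ≤ OTU count always; threshold 0
returns the OTUs unchanged.

## Controls and assignment

"Present in a control" defaults to ≥97% centroid identity to any
control sequence (contaminant reads acquire sequencing errors too);
exact equality is available. The drop percentage is computed on OTU
counts, with a read-weighted variant (`read_weighted_drop_pct`)
emitted alongside. Subtraction is idempotent and partitions the input.
Panel assignment is best identity with first-record tie-break and
genus ≥ 97% / family ≥ 95% rank thresholds. The detection table
reports per-replicate percentage abundance and presence, with an
optional minimum-replicate criterion that flags (rather than silently
drops) taxa detected in fewer replicates — the reporting convention
that can exclude genuinely present low-template taxa.

## qPCR screening

Expected ΔCT across a fold-dilution r at efficiency E is
ln(r)/ln(1+E) — additive in log dilution, log₂10 ≈ 3.3219 cycles per
decade at E = 1. A series is *inhibited* when any consecutive observed
shift falls more than `tol` (default 1.0 cycle) short of expectation —
dilution relieving suppression, including diluted points amplifying
earlier than neat. Otherwise it is *low template* if no point amplifies
below `ct_low_template` (default 35; no-amplification is treated as
CT = +∞), else *ok* with the least-diluted usable point as the working
dilution. The two thresholds are this package's defaults — the
underlying assessment is traditionally done by reading curves — and are
exposed in the API and config. Melt-curve analysis is out of scope.
Architecture comparison is plain arithmetic: mean CT per primer
architecture minus the non-fusion baseline mean, with replicate sd.

## Pipeline and sensitivity grid

The default stage order is demux → quality filter → dereplicate →
abundance filter → chimera removal → 97% OTU → (optional DTU, control
subtraction, panel assignment), with the abundance filter relocatable
to after clustering, since the order of filtering steps is itself one
of the parameters whose impact the grid measures. The grid executes
the full cross-product of quality filters × abundance filters ×
{OTU, DTU} and reports per-cell unit counts plus min/max per method.
No monotonicity of unit counts in filter stringency is assumed
(removing an abundant centroid can re-partition its members); the suite
checks consistency and determinism instead, and verifies specific
monotone cases empirically per seed. Reports embed a config hash and
the seed.

## Problem sizes

The test suite and the acceptance script run entirely on generated
data: 25,000-read single-source libraries for error-spectrum recovery,
a million-read pool for the foreign-tag audit (injection rate 2×10⁻⁴),
3,000-read clean libraries for end-to-end recovery, 100-instance oracle
sweeps for clustering and DTU collapse, 1,000 random quality strings
for maxee, and a 1,500-read four-taxon library (one taxon at 0.8%
abundance, 3% chimeras) for the sensitivity grid. These sizes give the
statistical checks 3-SE resolution while keeping a full run in the
tens of seconds on one CPU.

## Known limitations

- Per-read EE is nearly deterministic given the error model (see
  quality model above), so maxee retention is all-or-nothing per
  library rather than read-selective as on real platforms.
- The first-fit centroid rule and pairwise (rather than MSA-based)
  distances can differ from the original external tools on borderline
  clusters; both conventions are pinned by oracle tests and documented
  rather than hidden.
- The exact-tag audit conflates sequencing errors in tags with foreign
  tags when error rates are non-zero.
- Chimera detection considers two-parent single-breakpoint recombinants
  only; multi-parent or multi-breakpoint artefacts are out of scope.
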