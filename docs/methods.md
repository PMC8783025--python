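# Methods

`valveseq` measures transcriptional valves — modifier + core-terminator
cassettes that split RNA polymerase flux into a terminated and a read-through
transcript isoform — from pooled direct RNA sequencing (dRNA-seq) data. This
note documents the models, conventions and numerical choices behind each
stage, and what the synthetic-data experiments do and do not demonstrate.

## The measurement model

For a design with valve interval `[x_s, x_e)` (0-based, half-open; `x_s` is
the start of the modifier, or of the terminator when no modifier is present,
and `x_e` is the end of the terminator), the termination efficiency is

    Te = (R(x_s) - R(x_e)) / R(x_s)

where `R(x)` is the read depth at reference position `x`. Depth is
pileup-style span coverage: a mapped read contributes 1 to every position in
its alignment span `[rs, re)`. Because every read is 5'-anchored at the
transcript start (unless truncated), depth is non-increasing along the
reference and `Te` is exactly the fraction of polymerases that halted inside
the valve.

The normalized profile is `N(x) = R(x)/R(x_s)` and the Δ (drop) profile is
`D(x) = N(x-1) - N(x)`. Summing `D` over `(x_s, x_e]` telescopes exactly to
`Te`; this identity is asserted to machine precision in the tests and is the
consistency contract between the profile and measurement stages.

**Coordinate conventions.** A terminated read is the reference prefix
`reference[:p]`; its termination position `p` is an exclusive end, so the
final transcribed nucleotide is `p - 1` and the depth at that base includes
the base itself. Valid termination positions therefore satisfy
`terminator_start < p <= x_e`. Called termination points from the Δ-profile
land on the same scale: a drop at `x` means reads ended covering `x - 1`.
The U-tract count reads the 8 bases ending at the final transcribed
nucleotide inclusive (`reference[p-8:p]`); an exclusive mode shifts the
window one base upstream.

## Demultiplexing by intrinsic barcodes

Every read contains its design's sequence (at the 3' end if terminated,
internally if read-through), so reads are assigned by best local alignment
against the design cassette references (never a plasmid backbone). Scoring is
BLASTN-like: match +2, mismatch −3, affine gaps costing `5 + 2k` for a gap of
length `k`, word size 4. Ranking uses the raw local-alignment score: at fixed
scoring parameters the bitscore is a fixed affine transform of the raw score
(`(λS − ln K)/ln 2`), so best-hit ranking and tie detection are identical and
no Karlin–Altschul parameter estimation is needed. E-value gating is replaced
by a raw `min_score` threshold (default 30 ≈ 15 matched nt). Reads with no
hit reaching `min_score` are `unassigned_no_hit`; reads whose maximum score
is achieved by two or more designs are `unassigned_tie` and excluded, which
makes assignment invariant to design order. Only the forward strand is
searched by default (dRNA-seq is strand-specific).

Two aligners back this up:

- `local_align_dp` — the exact affine-gap local DP (Gotoh), used as the
  oracle and for small inputs. Alignment starts are propagated through the DP
  (no traceback matrix); score ties break toward the lowest reference start,
  then the lowest query start.
- `seeded_align` — exact word-size seeds, diagonals clustered (gap ≤ band
  half-width, default 16), each cluster extended with a banded version of the
  same DP, overlapping hits merged keeping the higher score. A banded run
  only removes alignment paths, so its score is a genuine alignment score and
  can never exceed the exact optimum; on seed-containing instances it almost
  always equals it (asserted ≥ 95% on random pairs sharing an 8-mer).

At pool scale (thousands of reads × hundreds of designs) the demultiplexer
screens designs per read by their densest seed-diagonal window and extends
only the top candidates (default 8) with the banded DP — the count threshold
includes ties, so exactly duplicated designs are always extended together and
their tie is always detected. This is the standard seed-and-extend trade:
a design outside the screened set could in principle hold the best alignment,
but a design that outscores all others while sharing fewer seed words than
eight of them is not observed in practice at the error rates considered.

## The read simulator

The simulator is the package's synthetic-data generator and defines the
conditions under which the pipeline is validated:

- Per design, a read is terminated with probability `true_te`, ending at a
  position drawn from the design's termination-weight map; otherwise it spans
  the full reference. Default weights put a single position at the middle of
  the terminator's 3' half; multimodal maps are supported.
- A poly(A) tail (default 30 nt) is appended — the library-prep
  polyadenylation step.
- Substitution errors are applied independently per base (default rate 0.15,
  the error level the demultiplexer was tuned against); a substituted base
  becomes one of the other three uniformly. The error model is
  substitution-only by design; insertions/deletions and homopolymer-specific
  error rates are not modelled.
- Optional 5' truncation: with probability `truncation_prob` a read loses a
  uniform-length 5' prefix (at least `min_keep` = 50 nt survive, which also
  guarantees the cut never lands in the poly(A) tail). This is the forward
  model for the deviation correction.
- Each design draws from an RNG substream keyed on `(seed, design id)`:
  output is bit-reproducible and independent of design iteration order.

Synthetic parts: spacers are random 33-mers ending in the stop codon TAA
(composition uniform by default; an approximate coding-region preset exists);
modifiers are random 30-mers; synthetic terminators are 48 nt — an 8-nt stem,
4-nt loop, reverse-complement stem hairpin followed by an 8-U U-tract and a
random 3' pad — so the default termination position falls exactly at the end
of the U-tract, more than 20 nt into the terminator (deep enough to survive
the truncation filter).

**What the simulator does not emulate:** indels, basecaller artifacts,
homopolymer compression, signal-level noise, carrier RNA, or biological
variation in termination position between contexts. Passing tests therefore
demonstrate correctness of the estimator and pipeline under a
substitution-only error model, not end-to-end performance on real nanopore
reads.

## Read filtering

A mapped read is removed iff it does **not** contain the full design cassette
(span covering the cassette within a 5-nt end slack) **and** its end position
falls in `[spacer_start, terminator_start + 20)`. Reads ending there are
indistinguishable from 5'-intact truncation artifacts; genuine terminations
end deeper in the terminator and read-through reads span the whole design, so
both isoform classes are retained. The margin (20 nt) and window ends are
configurable; on an error-free, truncation-free pool the filter removes
nothing.

## Deviation correction

Library preparation distorts profiles: a truncated read-through read starts
downstream of `x_s` but still covers `x_e`, deflating `R(x_s)` and biasing
measured Te downward (at `true_te = 0` the measured value is negative). The
correction is a forward-simulation model: for each true Te on a grid (default
0, 0.05, …, 1) pools are simulated under the configured distortion and pushed
through the full measurement pipeline (mapping by alignment, filtering,
profiling); the mean measured Te per grid point defines a measured-vs-true
map. Demultiplexing is skipped during fitting — reads are mapped to their
generating design — because the deviation being modelled is a profile
artifact, not an assignment artifact.

Correction inverts the fitted map by monotone linear interpolation
(`te_corrected = clamp(interp(te_raw, measured, true), 0, 1)`); a
non-monotone fit is rejected with an error (refit with more reads per point).
Inverting the map is equivalent to subtracting the predicted deviation at
small deviations and better behaved at large ones. With no distortion
configured the pipeline is exact and the deviation is identically zero. Raw
Te is reported unclamped (negative values are diagnostic); only the corrected
value is clamped.

The shipped recovery experiment fits on a 21-point grid (2–4 designs × 1500
reads per point) and evaluates on an 11-point grid with disjoint seeds,
comparing per-grid-point means (which is what the model predicts); at 20%
truncation the corrected mean error is ~7× smaller than the raw error.

## Termination-point calling

The dominant position is the argmax of the Δ-profile over `(x_s, x_e]`
(ties break 5'-ward); secondary points are local maxima reaching at least
`secondary_fraction` (default 0.25) of the maximum drop. Weights are the drop
values renormalized over called points. An all-non-positive window yields an
empty call list with the dominant position undefined.

## gRNA arrays

An array is `unit_1 valve_1 unit_2 valve_2 … unit_k`; a polymerase passes
valves 5'→3' and terminates at valve `j` with probability `Te_j`, so unit `i`
accumulates to `∏_{j<i} (1 − Te_j)` relative to unit 1. The measured
counterpart applies `compute_te` at each valve of the array's depth profile
and feeds the (clamped) values through the same product rule.

## Group-level metrics

- **Percentage deviation** of a design's Te from its core-terminator group
  median `m`, normalized by the maximum attainable deviation in that
  direction: `100 (te − m)/(1 − m)` upward, `100 (te − m)/m` downward, with
  0/0 → 0. The normalization direction rule is this package's choice; a
  symmetric alternative would divide by `max(m, 1 − m)`.
- **CV across spacers** uses the sample (n−1) standard deviation over the
  mean; it quantifies insulation of a modifier–terminator combination from
  upstream context.
- **Replicate agreement** reports squared Pearson correlation and the
  fraction of designs with |ΔTe| below a threshold (default 0.05); zero
  variance in either replicate makes r² undefined and it is reported as such.
- **Frequency deviation** is `|measured − predicted|/predicted × 100` per
  design with a configurable flag cutoff (default 20%); designs with zero
  predicted frequency are flagged `unpredicted` and excluded from
  percentages.

## Problem sizes and reproducibility

The simulation-study harness and acceptance checks use a 50-design library
(5 spacers × 5 modifiers × 2 terminators) at 500 reads per design for Te
recovery under 15% substitutions, a 100-design library at 20 reads per design
for error-free demultiplexing, 2000 reads for array stoichiometry, and the
grid sizes above for the correction experiment. These sizes put Monte-Carlo
noise well inside the asserted tolerances (binomial SE at n = 500 is ≤ 0.022)
while keeping each experiment to a few minutes on one CPU; the full printed
library (7 × 13 × 13 = 1183 designs) is enumerated and frequency-checked but
not sequenced at depth in the default suite. All randomness flows from
explicit seeds through per-design substreams, so every experiment is
bit-reproducible.

## Known limitations

- The structure filter for padding sequences is a minimal-hairpin surrogate
  (two disjoint reverse-complementary ≥4-mers separated by ≥3 nt), not a
  thermodynamic folding prediction; it is deterministic and configurable but
  will not reproduce an energy-based filter's exact accept set.
- The deviation model corrects the distortions present in its forward model
  (5' truncation by default). Real dRNA-seq artifacts it does not model —
  3'-end trimming, adapter chimeras, pore stalls — are outside its reach.
- The seeded aligner is a heuristic: scores are lower bounds on the exact DP
  optimum, with equality asserted statistically, not universally.
- Reverse-complement search and indel simulation exist as flags but are off
  by default and not exercised by the acceptance experiments.
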