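# valveseq

Pooled characterization of **transcriptional valves** from nanopore direct RNA
sequencing (dRNA-seq).

A transcriptional valve is a modifier + core-terminator cassette placed inside
a transcription unit. Because intrinsic termination is stochastic, a fraction
`Te` of polymerases halt at the valve (producing the short isoform) while the
rest read through (the long isoform) — so a valve sets transcript-isoform
stoichiometry purely at the transcription level. Libraries of valves can be
characterized *in one pot*: every read contains its design's own sequence as
an **intrinsic barcode**, so a single pooled dRNA-seq run can be demultiplexed
into per-design read-depth profiles and measured at nucleotide resolution.

`valveseq` implements that entire computational pipeline as a library, for
bioengineers and sequencing-methods developers:

- **Library design** — combinatorial enumeration of spacer × modifier ×
  terminator designs, spacer/padding sequence generation under homopolymer,
  restriction-site and structure filters, and design-frequency prediction
  from part frequencies (FASTA/GFF3 I/O).
- **Read simulation** — synthetic dRNA-seq pools with ground truth: per-design
  mixtures of terminated and read-through transcripts, poly(A) tails, random
  substitutions (default 15%), optional 5' truncation.
- **Demultiplexing** — seeded local alignment with affine gaps (match +2,
  mismatch −3, gap `5 + 2k`, word size 4), best-score assignment with tie
  exclusion, backed by an exact DP oracle.
- **Profiling & measurement** — truncation-artifact filtering, depth /
  normalized / Δ profiles, `Te = (R(x_s) − R(x_e))/R(x_s)`, termination-point
  calling, U-tract counts, deviation-model correction of measured Te.
- **Metrics & stoichiometry** — tunability and insulation metrics, replicate
  agreement, frequency-deviation reports, gRNA-array stoichiometries, and an
  end-to-end simulation-study harness.

## Worked example

```python
import valveseq as vs

designs = vs.synthetic_design_library(1, 1, 1, seed=3)
d = designs[0]
model = vs.default_truth_model(d, true_te=0.65)
cfg = vs.SimulationConfig(substitution_rate=0.15, reads_per_design=800, seed=4)
reads, truth = vs.simulate_pool([d], {d.id: model}, cfg)

mapped = [m for m in (vs.map_read(r.id, r.sequence, d) for r in reads) if m]
kept, removed = vs.filter_reads(mapped, d)
profile = vs.build_depth_profile(kept, len(d.reference_sequence), d.id)
m = vs.measure_valve(profile, d)
print(m.te_raw, m.dominant_position, m.u_count)
```

Running `python examples/03_termination_profile.py` (the same computation)
prints:

```
design S1_M1_T1: 800 reads kept, 0 removed by the filter
true Te = 0.65; empirical terminated fraction = 0.6275
measured Te (raw) = 0.6275  [depth 800 at valve start -> 298 at valve end]
dominant termination position = 149 (truth: 149)
called points (position: weight): 149:1.00
U residues in the 8-nt U-tract at the dominant position: 8
terminated:read-through isoform ratio = 1.68:1
```

The measured Te equals the simulated pool's terminated-read fraction exactly
(the estimator is exact up to mapping error), the called termination position
matches the simulator's truth, and the 8-U U-tract of the synthetic terminator
is recovered at the point of termination.

The other scripts in `examples/` each demonstrate one capability: library
enumeration and frequency prediction (`01`), pooled simulation and
demultiplexing at 15% substitutions (`02`), deviation-model correction of
truncation bias (`04`), and gRNA-array stoichiometry (`05`).

A thin CLI wraps the same stages for shell pipelines:

```bash
valveseq design-library --parts parts.fa --flank5 ... --flank3 ... --out designs.fa --gff designs.gff3
valveseq simulate --designs designs.fa --gff designs.gff3 --rate 0.15 --n 100 --seed 42 --out reads.fastq
valveseq demux --reads reads.fastq --designs designs.fa --out assign.tsv
valveseq measure --assign assign.tsv --reads reads.fastq --designs designs.fa --gff designs.gff3 --out te.tsv
```

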