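# tracepure

Electropherogram-based screening of algal culture purity from single
Sanger reads.

## The problem

Establishing unialgal cultures from environmental samples requires a fast
check of whether a picked colony really contains one strain.  Sequencing
the V4 region of the 18S rRNA gene — the most variable part of the
eukaryotic small subunit — directly from a boiled culture gives one Sanger
chromatogram per culture.  If the culture is mixed, templates from
different strains carry different bases at divergent positions, so the
trace shows two rival peaks there.  The basecaller detects this as a
biased uncalled/called peak ratio, which raises the per-base error
probability `Pe` and depresses the Phred quality value

```
QV = -10 · log10(Pe)
```

so QV 20 means a 1% chance the call is wrong.  `tracepure` turns this into
an objective decision rule:

1. **Trim** the read on its QV profile:
   * 5' — after skipping the first 25 bases, keep from the first 20-base
     window in which every QV is strictly above 20;
   * 3' — scanning only after 350 bases past the 5' trim point (so every
     passing read keeps a floor-length segment), cut before the first
     20-base window containing more than one call strictly below QV 20.
2. **Classify**: the culture is *unialgal* iff strictly fewer than 1% of
   the retained basecalls fall below QV 20; *mixed* otherwise;
   *indeterminate* when no clean 5' window exists.

The package also provides ABIF (`.ab1`) reading and writing, FASTA+QUAL
I/O, degenerate-primer in-silico PCR with the built-in V4 primer pair
TAReuk454FWD1 (`CCAGCASCYGCGGTAATTCC`) / TAReukREV3 (`ACTTTCGTTCTTGATYRA`),
and a mixed-template chromatogram simulator with ground truth, so the
whole pipeline is testable without instrument data.

## Worked example

```sh
python examples/simulate_and_screen.py
```

simulates three single-template traces and two 50:50 mixtures (10%
sequence divergence), writes them as `.ab1`, and screens them:

```
     id  status  start  end  retained_length  n_subthreshold  percent_subthreshold classification
sim_000 trimmed     26  560              535               0                  0.00       unialgal
sim_001 trimmed     26  559              534               0                  0.00       unialgal
sim_002 trimmed     26  562              537               0                  0.00       unialgal
sim_003 trimmed     42  391              350              32                  9.14          mixed
sim_004 trimmed     59  408              350              38                 10.86          mixed

classification matches simulation ground truth: True
```

`start`/`end` are 1-based inclusive trim coordinates;
`percent_subthreshold` is the percentage of retained calls below QV 20.
The clean traces retain ~535 bases at 0% sub-QV20; the mixtures are cut at
the 350-base assessment floor and carry ~9-11% sub-QV20 calls — far over
the 1% bound — because every divergent position shows two near-equal
peaks.

The same pipeline is available from the shell:

```sh
tracepure simulate sim.yaml out/       # render traces from a YAML config
tracepure screen out/*.ab1             # TSV purity report to stdout
tracepure trim out/*.ab1 --out-fasta t.fasta --out-qual t.qual
tracepure pcr templates.fasta          # predict V4 amplicons
```

See also `examples/trim_walkthrough.py` (the two trimming rules on a
constructed QV profile) and `examples/insilico_pcr_v4.py` (a 421 bp V4
amplicon prediction).

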