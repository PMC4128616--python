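# Methods

## Decision rule

A culture is screened from a single Sanger read of its V4 18S rDNA
amplicon.  Per-base Phred quality values (QV = −10·log10(Pe), with Pe the
basecall error probability) drive both steps:

1. **Trimming.**  (a) After skipping the first `head_skip` bases
   (default 25), the 5' trim point is the first position from which a
   `window`-long run (default 20) of consecutive calls is strictly above
   `qv_threshold` (default 20).  (b) Scanning only window offsets of at
   least `tail_scan_start` bases (default 350) from the 5' trim point,
   the 3' cut falls immediately before the first full window containing
   strictly more than `max_bad_in_window` (default 1) calls strictly
   below the threshold.  All comparisons are strict: QV exactly 20 is
   neither good for rule (a) nor bad for rule (b).
2. **Classification.**  On the retained interval, the read is *unialgal*
   iff the fraction of calls strictly below QV 20 is strictly smaller
   than `max_bad_fraction` (default 1%), *mixed* otherwise, and
   *indeterminate* when rule (a) finds no window (such reads are flagged,
   never silently classified).

Rule (b)'s offset is counted from the 5' trim point, so every read that
passes trimming retains at least 350 bases — enough sequence for the
purity fraction (and any later taxonomic use) to be meaningful.  When
quality never degrades, rule (b) keeps the read to its end: the rule
describes where to cut when degradation occurs, not a mandatory cut.

Boundary behaviour of rule (a): the scan window is truncated at the read
end, so a clean run that ends exactly at the read end qualifies (a
30-base all-QV40 read trims to [25, 30)); a read shorter than
`head_skip`, or with no clean run at all, fails.  Rule (b) evaluates only
full windows; a read too short for the scan to begin is kept whole.

## Quality model

Basecallers derive Pe from chromatogram features; the features named by
convention are peak spacing, the uncalled/called peak ratio, and peak
resolution.  `tracepure` uses the simplest monotone model over exactly
those features:

```
Pe_i = clip( w_ratio · secondary_i/primary_i
           + w_res   · (1 − resolution_i)
           + w_space · spacing_dev_i,  pe_floor, pe_ceiling )
```

with defaults `w_ratio = 0.5`, `w_res = 0.3`, `w_space = 0.2`,
`pe_floor = 1e-4` (QV 40 cap), `pe_ceiling = 0.75`.  A base with equal
called and uncalled peaks (ratio 1, the signature of a 50:50 mixed base)
gets Pe ≥ 0.5 — effectively uncallable, QV ≤ 3 — while a clean,
well-resolved, evenly spaced base sits at the floor.  A linear form was
chosen over a logistic one because monotonicity in each feature is the
only property the pipeline relies on; the weights are plumbing, exposed
in the config.  No attempt is made to reproduce any instrument vendor's
calibration tables; numeric agreement with a real basecaller's QVs would
be coincidental.  What matters — and what the tests pin — is the
calibration *requirement*: clean simulated traces yield trimmed median
QV ≥ 30 with a sub-QV20 fraction far below 1%, and every divergent
position of a 50:50 mixture falls below QV 20.

Feature measurement from a trace (`measure_features`): `primary` is the
called channel's intensity at the peak scan and `secondary` the tallest
other channel there; `resolution` is one minus the deeper flanking valley
of the summed four-channel signal relative to the summed peak height
(well-separated peaks score near 1); `spacing_dev` is the relative
deviation of the flanking peak gaps from the mean gap.

## Chromatogram simulator

The simulator is the package's ground-truth data source.  Channels are
sums of Gaussian peaks: at base *i*, template *t* contributes a peak of
height `peak_amplitude · proportion_t` on the channel of its own base
(after its indel offset), at a centre `peak_spacing_mean` scans after the
previous base.  Basecalls take the tallest channel at each peak; QVs come
from the quality model applied to features measured from the finished
trace, exactly as for a file read from disk.  All randomness derives from
one `numpy` generator seeded with the config seed, so identical configs
give byte-identical `.ab1` files.

Defaults and what they emulate:

| parameter | default | role |
|---|---|---|
| `n_bases` | 600 | read length; long enough to exercise the 350-base floor |
| `peak_spacing_mean` | 12 scans/base | typical processed-trace spacing |
| `peak_sigma` | 1.1 scans | initial peak width |
| `resolution_decay` | 1.6e-3 /base | linear peak broadening; drives QVs below 20 from roughly base 470, giving rule (b) something to cut |
| `head_ramp_len` | 25 bases | 5' low-quality ramp: a decaying spurious peak on a random wrong channel, giving rule (a)'s skip something to skip |
| `noise_sd` | 4 intensity units | additive detector noise (amplitude 10000) |
| `spacing_jitter_sd` | 0 scans | peak-centre jitter; default off so spacing deviations reflect only quantisation |

`peak_sigma` and `resolution_decay` were set together so that the
valley-fill between broadening peaks pushes Pe past 1% (QV < 20) near
base 470 under the defaults: late enough that the trimmed body of a clean
read has median QV ≥ 30, early enough that the 3' rule is exercised on
every default-length read.

Mixtures: a divergent position splits the amplitude between two channels
in proportion to the mixing weights, so a 50:50 mixture produces
near-equal double peaks (ratio ≈ 1) and a 5% contaminant already yields
ratio ≈ 0.05/0.95 ≈ 0.053, i.e. Pe ≈ 0.026 — below QV 20.  The purity
statistic is therefore sensitive to small contaminations at divergent
sites, and its dose-response in the minor proportion rises steeply and
then plateaus.  Indel offsets model interspecific length polymorphism:
a one-base offset between templates makes essentially every downstream
position divergent ("one base shift scrambles the read"), which only
sharpens the mixed signal.

What the simulator does *not* model: dye blobs, mobility shifts,
polymerase slippage, chimeric amplicons, or any real instrument's noise
spectrum.  Passing tests show the decision rule behaves correctly on
traces whose noise structure matches the model's assumptions (linear dye
response, Gaussian peaks and noise); they do not certify performance on
real instrument files, whose Pe calibration differs.

## In-silico PCR

Primer matching is purely combinatorial: a template position matches a
degenerate IUPAC primer position at zero cost when their code sets
intersect; `max_mismatch` substitutions are tolerated (default 0, since
the screening amplification yields clean single bands).  Products are
primer-inclusive — what a gel sizes — and both template orientations are
searched, so amplifying a reverse-complemented template yields the same
product lengths.  No melting temperature or 3'-anchor weighting is
modelled.

## Numerical and interface choices

* Internal coordinates are 0-based half-open; reports print 1-based
  inclusive positions.  Percentages are reported to two decimals.
* QVs are stored as integers in [0, 93]; out-of-range values are rejected
  rather than clamped, to fail loudly on corrupt data.
* The ABIF writer emits the minimal tag set this pipeline and common
  third-party parsers need (DATA9-12, PLOC, PBAS, PCON, FWO_, sample and
  instrument strings), in both tag-number-1 and tag-number-2 variants as
  real basecallers do; the reader prefers 1 and falls back to 2.
* Batch screening isolates per-file failures as indeterminate report rows
  instead of aborting; mixed or indeterminate outcomes are results, not
  process errors, so the CLI exits 0 whenever the batch itself ran.

## Problem sizes used in the checks

The repeated-simulation checks (end-to-end discrimination and the
dose-response trend) use 100 seeded replicates per condition with
600-base reads, and the trimming scans are verified against a brute-force
window scanner on 10,000 random QV arrays of length up to 1000 — sizes at
which every property examined is stable from run to run.

## Known limitations

* The quality model is uncalibrated against real basecallers; absolute
  QVs on real `.ab1` files will differ even where the classification
  logic would agree.
* The 25-35 base head-skip latitude seen in practice is collapsed to a
  single configurable default (25).
* Only substitution divergence and rigid indel offsets are simulated;
  within-read indel events are not.
* SCF/ZTR trace formats and raw (unprocessed) channel data are out of
  scope.
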