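"""Synthetic Sanger chromatograms with known ground truth.

The generative model builds the four dye channels of a capillary trace as
sums of Gaussian peaks, one per basecall position, and supports template
mixtures: at base ``i`` each template contributes a peak whose height is
proportional to its mixing proportion, placed on the channel of its own
base at that position (after any per-template indel offset).  A divergent
position in a 50:50 mixture therefore carries two near-equal peaks on
different channels — the double-peak signature a mixed culture leaves in a
real electropherogram — while a single template yields one dominant peak
per position.

Three further features mimic real capillary reads:

* a 5' low-quality ramp (``head_ramp_len`` bases receive a decaying
  spurious peak on a random wrong channel), the reason trimming skips the
  first ~25 bases;
* 3' resolution decay (peak width grows linearly along the read, filling
  the valleys between peaks), which the 3' trimming rule cuts away;
* additive Gaussian detector noise on every channel.

Basecalls take the tallest channel at each peak; QVs come from
:func:`tracepure.quality.assign_qualities` applied to features measured
from the finished trace, exactly as for a file read back from disk.
Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .quality import PeakFeatures, QualityModelParams, assign_qualities
from .trace_io import BASES, TraceRecord, write_abif

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_trace",
    "generate_dataset",
    "measure_features",
    "random_template",
    "diverge_template",
]


@dataclass
class SimConfig:
    """Configuration of one simulated trace.

    Defaults are calibrated so that a single clean template trims at the
    head ramp, degrades past ~base 470, and classifies unialgal, while a
    50:50 mixture diverging at 10% of positions fails the 1% sub-QV20 rule.

    Parameters
    ----------
    templates : list of str
        One or more ACGT template sequences (e.g. V4 amplicons).
    proportions : list of float, optional
        Mixing weights, summing to 1; equal weights when omitted.
    n_bases : int, optional
        Read length; defaults to 600 or the longest length every template
        can support, whichever is smaller.
    peak_spacing_mean : float
        Scans per base (default 12).
    peak_sigma : float
        Gaussian peak width in scans at the read start (default 1.1).
    spacing_jitter_sd : float
        Standard deviation of peak-centre jitter in scans (default 0).
    noise_sd : float
        Additive channel noise, intensity units (default 4).
    peak_amplitude : float
        Height of a pure-template peak (default 10000).
    resolution_decay : float
        Per-base relative growth of peak width toward the 3' end
        (default 1.6e-3: width roughly doubles over 600 bases).
    head_ramp_len : int
        Number of initial bases receiving the 5' spurious-peak ramp
        (default 25).
    indel_offsets : list of int, optional
        Per-template base offsets modelling interspecific length
        polymorphism; template ``t`` reads its base for position ``i``
        from ``templates[t][i + offset[t]]``.  A one-base offset between
        two templates scrambles every downstream call.
    seed : int
        Root seed for all randomness in this trace.
    """

    templates: list[str]
    proportions: list[float] | None = None
    n_bases: int | None = None
    peak_spacing_mean: float = 12.0
    peak_sigma: float = 1.1
    spacing_jitter_sd: float = 0.0
    noise_sd: float = 4.0
    peak_amplitude: float = 10000.0
    resolution_decay: float = 1.6e-3
    head_ramp_len: int = 25
    indel_offsets: list[int] | None = None
    seed: int = 0
    quality_model: QualityModelParams = field(default_factory=QualityModelParams)

    def validate(self) -> None:
        if not self.templates:
            raise ValueError("at least one template is required")
        for t in self.templates:
            if not t or set(t.upper()) - set(BASES):
                raise ValueError("templates must be non-empty ACGT strings")
        props = self.effective_proportions()
        if len(props) != len(self.templates):
            raise ValueError("proportions and templates differ in length")
        if min(props) < 0:
            raise ValueError("proportions must be non-negative")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        offs = self.effective_offsets()
        if len(offs) != len(self.templates):
            raise ValueError("indel_offsets and templates differ in length")
        if min(offs) < 0:
            raise ValueError("indel_offsets must be >= 0")
        for scale in (self.peak_spacing_mean, self.peak_sigma, self.peak_amplitude):
            if scale <= 0:
                raise ValueError("spacing, peak width and amplitude must be > 0")
        for rate in (self.noise_sd, self.resolution_decay, self.spacing_jitter_sd):
            if rate < 0:
                raise ValueError("noise and decay rates must be >= 0")
        if self.head_ramp_len < 0:
            raise ValueError("head_ramp_len must be >= 0")
        if self.effective_n_bases() < 1:
            raise ValueError("templates too short for the requested read length")

    def effective_proportions(self) -> list[float]:
        if self.proportions is None:
            k = len(self.templates)
            return [1.0 / k] * k
        return list(self.proportions)

    def effective_offsets(self) -> list[int]:
        if self.indel_offsets is None:
            return [0] * len(self.templates)
        return list(self.indel_offsets)

    def effective_n_bases(self) -> int:
        limit = min(len(t) - o for t, o in zip(self.templates,
                                               self.effective_offsets()))
        return min(self.n_bases, limit) if self.n_bases is not None else min(600, limit)


@dataclass
class SimTruth:
    """Ground truth of one simulated trace."""

    config: SimConfig
    consensus_length: int
    divergent_positions: list[int]
    is_mixture: bool


_PAD = 30  # scans of margin before the first and after the last peak


def simulate_trace(config: SimConfig) -> tuple[TraceRecord, SimTruth]:
    """Render one chromatogram and its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    props = np.asarray(config.effective_proportions())
    offsets = config.effective_offsets()
    templates = [t.upper() for t in config.templates]
    L = config.effective_n_bases()

    active = np.flatnonzero(props > 0)
    base_matrix = [[templates[t][i + offsets[t]] for t in range(len(templates))]
                   for i in range(L)]
    divergent = [i for i in range(L)
                 if len({base_matrix[i][t] for t in active}) > 1]

    # peak centres: regular spacing plus optional jitter, kept strictly increasing
    centres = (_PAD + np.arange(L) * config.peak_spacing_mean
               + rng.normal(0.0, config.spacing_jitter_sd, L))
    pos = np.rint(centres).astype(np.int64)
    for i in range(1, L):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    n_scans = int(pos[-1]) + _PAD if L else 2 * _PAD

    widths = config.peak_sigma * (1.0 + config.resolution_decay * np.arange(L))
    x = np.arange(n_scans, dtype=float)
    chan = {b: np.zeros(n_scans) for b in BASES}

    for i in range(L):
        w = widths[i]
        lo = max(0, int(pos[i] - 5 * w))
        hi = min(n_scans, int(pos[i] + 5 * w) + 1)
        shape = np.exp(-0.5 * ((x[lo:hi] - pos[i]) / w) ** 2)
        for t in range(len(templates)):
            if props[t] <= 0:
                continue
            b = base_matrix[i][t]
            chan[b][lo:hi] += config.peak_amplitude * props[t] * shape
        if i < config.head_ramp_len:
            # 5' ramp: decaying spurious peak on a random wrong channel
            major = base_matrix[i][int(active[np.argmax(props[active])])]
            others = [b for b in BASES if b != major]
            wrong = others[rng.integers(len(others))]
            frac = np.sqrt((config.head_ramp_len - i) / config.head_ramp_len)
            h = config.peak_amplitude * frac * rng.uniform(0.6, 1.0)
            chan[wrong][lo:hi] += h * shape

    for b in BASES:
        chan[b] += rng.normal(0.0, config.noise_sd, n_scans)
        chan[b] = np.clip(np.rint(chan[b]), 0, 32767).astype(np.int64)

    stack = np.stack([chan[b] for b in BASES])
    calls = "".join(BASES[int(np.argmax(stack[:, p]))] for p in pos)

    record = TraceRecord(channels=chan, channel_order="GATC",
                         peak_positions=pos, basecalls=calls,
                         qualities=np.zeros(L, dtype=np.int64),
                         name=f"sim-seed{config.seed}",
                         instrument="tracepure chromatogram simulator")
    record.qualities = assign_qualities(measure_features(record),
                                        config.quality_model)
    record.validate()
    truth = SimTruth(config=config, consensus_length=L,
                     divergent_positions=divergent,
                     is_mixture=len(active) >= 2)
    return record, truth


def measure_features(record: TraceRecord) -> PeakFeatures:
    """Measure per-base peak features from a chromatogram.

    * ``primary``: called-channel intensity at the peak scan;
    * ``secondary``: tallest other channel at the same scan — the
      uncalled/called ratio numerator;
    * ``resolution``: one minus the deeper of the two flanking valleys of
      the summed signal relative to the summed peak height, clipped to
      [0, 1] — well-separated peaks score near 1;
    * ``spacing_dev``: relative deviation of the flanking peak gaps from
      the mean gap.
    """
    L = record.n_bases
    if L == 0:
        z = np.zeros(0)
        return PeakFeatures(primary=z, secondary=z, resolution=z, spacing_dev=z)
    stack = np.stack([record.channels[b] for b in BASES]).astype(float)
    total = stack.sum(axis=0)
    pos = record.peak_positions
    base_idx = {b: k for k, b in enumerate(BASES)}

    primary = np.empty(L)
    secondary = np.empty(L)
    for i in range(L):
        col = stack[:, pos[i]]
        k = base_idx.get(record.basecalls[i])
        if k is None:  # ambiguity call from elsewhere: no dedicated channel
            primary[i] = 0.0
            secondary[i] = col.max()
        else:
            primary[i] = col[k]
            secondary[i] = np.delete(col, k).max()

    resolution = np.ones(L)
    peak_total = total[pos]
    valley = np.zeros(L - 1) if L > 1 else np.zeros(0)
    for i in range(L - 1):
        valley[i] = total[pos[i]: pos[i + 1] + 1].min()
    for i in range(L):
        vs = []
        if i > 0:
            vs.append(valley[i - 1])
        if i < L - 1:
            vs.append(valley[i])
        if not vs or peak_total[i] <= 0:
            resolution[i] = 0.0 if peak_total[i] <= 0 else 1.0
            continue
        resolution[i] = float(np.clip(1.0 - max(vs) / peak_total[i], 0.0, 1.0))

    if L > 1:
        gaps = np.diff(pos).astype(float)
        mean_gap = gaps.mean()
        gap_dev = np.abs(gaps - mean_gap) / mean_gap if mean_gap > 0 \
            else np.zeros_like(gaps)
        spacing_dev = np.empty(L)
        spacing_dev[0] = gap_dev[0]
        spacing_dev[-1] = gap_dev[-1]
        for i in range(1, L - 1):
            spacing_dev[i] = 0.5 * (gap_dev[i - 1] + gap_dev[i])
    else:
        spacing_dev = np.zeros(L)

    return PeakFeatures(primary=primary, secondary=secondary,
                        resolution=resolution, spacing_dev=spacing_dev)


# ---------------------------------------------------------------------------
# template helpers

def random_template(length: int, seed: int | np.random.Generator = 0) -> str:
    """A uniform random ACGT template of the given length."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return "".join(np.array(list(BASES))[rng.integers(0, 4, length)])


def diverge_template(template: str, divergence: float,
                     seed: int | np.random.Generator = 0) -> tuple[str, list[int]]:
    """Mutate a fixed fraction of positions to a different base.

    Returns the mutated template and the sorted list of mutated positions;
    models the interspecific substitution divergence of the V4 region.
    """
    if not (0 <= divergence <= 1):
        raise ValueError("divergence must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n_mut = int(round(divergence * len(template)))
    sites = sorted(rng.choice(len(template), size=n_mut, replace=False))
    seq = list(template.upper())
    for i in sites:
        choices = [b for b in BASES if b != seq[i]]
        seq[i] = choices[rng.integers(3)]
    return "".join(seq), [int(i) for i in sites]


def generate_dataset(configs: list[SimConfig], outdir) -> pd.DataFrame:
    """Render a set of configs to ``.ab1`` files plus a TSV truth table.

    Files are named ``sim_000.ab1``, ``sim_001.ab1``, ... in config order;
    the table (also written to ``truth.tsv``) records id, mixture status,
    template count, proportions and seed.  Re-running with identical
    configs reproduces byte-identical files.
    """
    outdir = Path(outdir)
    for config in configs:
        config.validate()
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, config in enumerate(configs):
        record, truth = simulate_trace(config)
        name = f"sim_{i:03d}"
        record.name = name
        write_abif(record, outdir / f"{name}.ab1")
        rows.append({
            "id": name,
            "is_mixture": truth.is_mixture,
            "n_templates": len(config.templates),
            "proportions": ",".join("%g" % p for p in
                                    config.effective_proportions()),
            "n_divergent": len(truth.divergent_positions),
            "seed": config.seed,
        })
    table = pd.DataFrame(rows, columns=["id", "is_mixture", "n_templates",
                                        "proportions", "n_divergent", "seed"])
    table.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return table
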