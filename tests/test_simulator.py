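"""The chromatogram simulator: determinism, feature behaviour, ground truth."""

import hashlib

import numpy as np
import pytest

from tracepure import (SimConfig, classify, diverge_template,
                       generate_dataset, measure_features, random_template,
                       simulate_trace, to_read, trim_read)
from tracepure.screening import MIXED, UNIALGAL


def test_determinism():
    config = SimConfig(templates=[random_template(650, 1)], seed=5)
    a, _ = simulate_trace(config)
    b, _ = simulate_trace(config)
    assert a.basecalls == b.basecalls
    assert np.array_equal(a.qualities, b.qualities)
    for base in "ACGT":
        assert np.array_equal(a.channels[base], b.channels[base])


def test_different_seeds_differ():
    template = random_template(650, 1)
    a, _ = simulate_trace(SimConfig(templates=[template], seed=5))
    b, _ = simulate_trace(SimConfig(templates=[template], seed=6))
    assert any(not np.array_equal(a.channels[c], b.channels[c]) for c in "ACGT")


def test_single_template_truth(pure_trace):
    record, truth = pure_trace
    assert not truth.is_mixture
    assert truth.divergent_positions == []
    assert truth.consensus_length == 600
    assert record.n_bases == 600


def test_pure_trace_classifies_unialgal(pure_trace):
    record, _ = pure_trace
    result = classify(trim_read(to_read(record)))
    assert result.classification == UNIALGAL


def test_pure_trace_calibration(pure_trace):
    """A clean default-noise trace: trimmed median QV >= 30, sub-QV20 < 1%."""
    record, _ = pure_trace
    trim = trim_read(to_read(record))
    assert trim.status == "trimmed"
    q = trim.read.qualities
    assert np.median(q) >= 30
    assert (q < 20).mean() < 0.01


def test_basecalls_recover_template(pure_trace):
    """Away from the 5' ramp, the max-channel caller reads the template."""
    record, truth = pure_trace
    template = truth.config.templates[0]
    ramp = truth.config.head_ramp_len
    called = record.basecalls[ramp:600]
    assert called == template[ramp:600]


def test_mixture_divergent_positions_are_low_quality(mixed_trace):
    """Every divergent position in a 50:50 mixture carries near-equal top
    channels, hence QV < 20."""
    record, truth, sites = mixed_trace
    assert truth.is_mixture
    assert truth.divergent_positions == [i for i in sites if i < 600]
    features = measure_features(record)
    ramp = truth.config.head_ramp_len
    for i in truth.divergent_positions:
        assert record.qualities[i] < 20
        if i >= ramp:  # inside the ramp the spurious 5' peak skews the ratio
            assert 0.8 <= features.secondary[i] / features.primary[i] <= 1.0


def test_mixture_classifies_mixed(mixed_trace):
    record, _, _ = mixed_trace
    assert classify(trim_read(to_read(record))).classification == MIXED


def test_clean_trace_features(pure_trace):
    record, truth = pure_trace
    features = measure_features(record)
    ramp = truth.config.head_ramp_len
    mid = slice(ramp, 400)
    ratio = features.secondary[mid] / features.primary[mid]
    assert ratio.max() < 0.1
    assert features.resolution[mid].min() > 0.9
    # integer-spaced peaks: spacing deviations essentially zero
    assert features.spacing_dev.max() < 0.05


def test_indel_offset_scrambles_downstream():
    """A one-base length polymorphism makes (nearly) every position
    divergent: the read is scrambled from the start."""
    template = random_template(650, 3)
    config = SimConfig(templates=[template, template], indel_offsets=[0, 1],
                       proportions=[0.5, 0.5], seed=2)
    record, truth = simulate_trace(config)
    assert len(truth.divergent_positions) > 0.7 * truth.consensus_length
    result = classify(trim_read(to_read(record)))
    assert result.classification != UNIALGAL


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(templates=[]).validate()
    with pytest.raises(ValueError):
        SimConfig(templates=["ACGT"], proportions=[0.5, 0.5]).validate()
    with pytest.raises(ValueError):
        SimConfig(templates=["ACGT" * 200], proportions=[0.9]).validate()
    with pytest.raises(ValueError):
        SimConfig(templates=["ACGT" * 200], noise_sd=-1).validate()


def test_diverge_template_fraction():
    template = random_template(500, 4)
    mutated, sites = diverge_template(template, 0.10, seed=5)
    assert len(sites) == 50
    assert all(template[i] != mutated[i] for i in sites)
    assert all(template[i] == mutated[i]
               for i in set(range(500)) - set(sites))


# ---------------------------------------------------------------------------
# dataset generation

def _dataset_configs():
    template = random_template(650, 21)
    other, _ = diverge_template(template, 0.1, 22)
    return [SimConfig(templates=[template], seed=1),
            SimConfig(templates=[template, other],
                      proportions=[0.5, 0.5], seed=2)]


def test_generate_dataset(tmp_path):
    table = generate_dataset(_dataset_configs(), tmp_path / "out")
    assert len(table) == 2
    assert list(table["is_mixture"]) == [False, True]
    assert sorted(p.name for p in (tmp_path / "out").glob("*.ab1")) == \
        ["sim_000.ab1", "sim_001.ab1"]
    assert (tmp_path / "out" / "truth.tsv").exists()


def test_generate_dataset_byte_identical(tmp_path):
    def digest(d):
        return [hashlib.sha256((d / f"sim_{i:03d}.ab1").read_bytes()).hexdigest()
                for i in range(2)]

    generate_dataset(_dataset_configs(), tmp_path / "a")
    generate_dataset(_dataset_configs(), tmp_path / "b")
    assert digest(tmp_path / "a") == digest(tmp_path / "b")


def test_generate_dataset_empty(tmp_path):
    table = generate_dataset([], tmp_path / "out")
    assert len(table) == 0
    assert list((tmp_path / "out").glob("*.ab1")) == []
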