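import numpy as np
import pytest

import ramanscreen as rs
from ramanscreen.synth import DEFAULT_GRID, EffectConfig


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID.copy()


def clean_effects(**overrides) -> EffectConfig:
    """EffectConfig with every nuisance off: noiseless, flat, spike-free,
    no between-sample variation, no class effect."""
    base = dict(
        amplitude_ratios={},
        amplitude_sigma=0.0,
        noise_sd=0.0,
        baseline_scale=(0.0, 0.0),
        spike_prob=0.0,
    )
    base.update(overrides)
    return EffectConfig(**base)


def quick_feature_cohort(n_per_class, seed, effects=None):
    """Feature table from single-trace noiseless spectra with only the
    per-sample amplitude variation on: the fast path for statistical
    calibration checks of the downstream harness."""
    effects = effects or EffectConfig(
        noise_sd=0.0, baseline_scale=(0.0, 0.0), spike_prob=0.0
    )
    spectra, truths = rs.generate_cohort_spectra(
        n_per_class, effects, seed=seed, maps_per_sample=1, spectra_per_map=1
    )
    samples = [traces[0] for traces in spectra.values()]
    labels = [truths[s.sample_id].label for s in samples]
    return rs.select_nonredundant(rs.build_feature_table(samples, labels))


@pytest.fixture(scope="session")
def processed_cohort():
    """A small fully-preprocessed effect-on cohort shared across tests:
    6 samples per class, 2 maps x 2 spectra each, default effects."""
    spectra, truths = rs.generate_cohort_spectra(
        6, EffectConfig(), seed=11, maps_per_sample=2, spectra_per_map=2
    )
    samples, labels = [], []
    for sid, traces in spectra.items():
        done = [rs.preprocess_spectrum(t) for t in traces]
        samples.append(rs.aggregate_sample(done))
        labels.append(truths[sid].label)
    table = rs.build_feature_table(samples, labels)
    return samples, labels, table, truths
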