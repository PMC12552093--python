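"""Shared fixtures: tiny simulated datasets and models sized for fast tests."""

from __future__ import annotations

import numpy as np
import pytest

from smrtkin.simdata import SimConfig, simulate_dataset, STRONG_6MA_PRESET
from smrtkin.kinetics_io import NormalizationSpec, normalize_table
from smrtkin import windows as win
from smrtkin.baseline_regressor import (RegressorConfig, train_regressor,
                                        regression_training_data)

NORM = NormalizationSpec()


@pytest.fixture(scope="session")
def tiny_native_cfg() -> SimConfig:
    return SimConfig(genome_length=20000, motif="GATC", mod_offset=1,
                     methyl_fraction=1.0, context_k=5, seed=42,
                     chemistry_seed=7,
                     ipd_shift=STRONG_6MA_PRESET["ipd"],
                     pw_shift=STRONG_6MA_PRESET["pw"])


@pytest.fixture(scope="session")
def tiny_native(tiny_native_cfg):
    """(cfg, seq, truth, kinetics) of a small strongly-methylated genome."""
    seq, truth, kin = simulate_dataset(tiny_native_cfg)
    return tiny_native_cfg, seq, truth, kin


@pytest.fixture(scope="session")
def tiny_wga(tiny_native_cfg):
    cfg = SimConfig(**{**tiny_native_cfg.to_dict(), "methyl_fraction": 0.0,
                       "seed": 43})
    seq, truth, kin = simulate_dataset(cfg)
    return cfg, seq, truth, kin


@pytest.fixture(scope="session")
def tiny_native_ds(tiny_native) -> win.KineticDataset:
    cfg, seq, truth, kin = tiny_native
    return win.KineticDataset({cfg.contig: seq},
                              normalize_table(kin.to_table(), NORM), truth)


@pytest.fixture(scope="session")
def tiny_wga_ds(tiny_wga) -> win.KineticDataset:
    cfg, seq, _, kin = tiny_wga
    return win.KineticDataset({cfg.contig: seq},
                              normalize_table(kin.to_table(), NORM), None)


@pytest.fixture(scope="session")
def tiny_regressor(tiny_wga_ds):
    """A small frozen baseline regressor trained on the tiny WGA data."""
    windows = win.random_windows(tiny_wga_ds, 1200, seed=3)
    seqs, targets = regression_training_data(windows)
    cfg = RegressorConfig(epochs=12, gru_hidden=16, seed=3, min_samples=50,
                          dropout=0.0)
    return train_regressor(seqs, targets, cfg)


@pytest.fixture(scope="session")
def tiny_sample_sets(tiny_native_ds, tiny_wga_ds, tiny_native_cfg):
    """(train_windows, test_windows) from the tiny strong-signal genome."""
    truth = tiny_native_ds.truth
    tr_pos, te_pos = win.split_sites(truth.sites, 0.6, 5)
    train_set = win.build_training_set(
        tiny_native_ds, tiny_wga_ds, tiny_native_cfg.motif,
        tiny_native_cfg.mod_offset, win.SamplingPlan(seed=5),
        positive_sites=tr_pos)
    test_set = win.build_test_set(
        tiny_native_ds, tiny_native_cfg.motif, tiny_native_cfg.mod_offset,
        win.SamplingPlan(mode="test", negative_source="random_non_motif", seed=6),
        positive_sites=te_pos)
    return train_set, test_set
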