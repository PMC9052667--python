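"""Shared fixtures: simulated separable-pore-model datasets and trained models.

All data is generated at test time by the simulator; the session-scoped
heterozygous CAG dataset (alleles 18/40) and its trained classifier are
shared across classifier, caller, and acceptance tests to keep the suite
fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from squigstr import events, imaging, network, simulate

HET_ALLELES = (18, 40)
HET_FRACTIONS = (0.6, 0.4)
FLANK_LEN = 120
N_READS = 100


def make_het_dataset(seed: int = 7, n_reads: int = N_READS) -> simulate.SimDataset:
    """Heterozygous CAG locus with the separable pore-model preset."""
    rng = np.random.default_rng(42)
    spec = simulate.SimLocusSpec(
        unit="CAG",
        left_flank=simulate.random_flank(rng, FLANK_LEN),
        right_flank=simulate.random_flank(rng, FLANK_LEN),
        alleles=HET_ALLELES,
        fractions=HET_FRACTIONS,
        n_reads=n_reads,
        jitter_sd=1.0,
        seed=seed,
    )
    return simulate.simulate_locus_dataset(spec)


def bin_dataset(ds: simulate.SimDataset) -> dict[str, np.ndarray]:
    return {raw.read_id: events.prepare_bins(raw, table)[0] for raw, table in ds.reads}


def maps_of(ds: simulate.SimDataset) -> dict[str, imaging.AlignedBaseMap]:
    return {a.query_name: imaging.aligned_base_map(a) for a in ds.alignments}


@pytest.fixture(scope="session")
def het_dataset() -> simulate.SimDataset:
    return make_het_dataset()


@pytest.fixture(scope="session")
def het_binned(het_dataset) -> dict[str, np.ndarray]:
    return bin_dataset(het_dataset)


@pytest.fixture(scope="session")
def het_training_set(het_dataset, het_binned) -> imaging.TrainingSet:
    return imaging.generate_training_set(
        het_binned,
        maps_of(het_dataset),
        [het_dataset.region],
        het_dataset.region.group,
        max_images=5000,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_training_set(het_dataset, het_binned) -> imaging.TrainingSet:
    """A 1,200-image subset for fast training-behavior tests."""
    return imaging.generate_training_set(
        het_binned,
        maps_of(het_dataset),
        [het_dataset.region],
        het_dataset.region.group,
        max_images=1200,
        seed=2,
    )


@pytest.fixture(scope="session")
def trained(het_training_set) -> tuple[network.ConvNet, network.TrainHistory]:
    model, _ = network.build_model(3, seed=3)
    config = network.TrainingConfig(epochs=30, seed=3, validation_fraction=0.2)
    history = network.train(model, het_training_set, config)
    return model, history
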