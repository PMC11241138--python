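import numpy as np
import pytest

from tfmirnet.pipeline import run_integration
from tfmirnet.synthetic_data import SimulationConfig, simulate


@pytest.fixture(scope="session")
def strong_bundle():
    """Noise-free regime: large effects, low dispersion, no decoys."""
    return simulate(SimulationConfig.strong_signal(seed=1))


@pytest.fixture(scope="session")
def default_bundle():
    """Realistic regime: decoy peaks, decoy target pairs, extra bound promoters."""
    return simulate(SimulationConfig(seed=7))


def integrate(bundle, **overrides):
    kwargs = dict(
        tss=bundle.tss,
        chrom_sizes=bundle.chrom_sizes,
        matures=bundle.matures,
        gene_lengths=bundle.gene_lengths,
        tf_peaks=bundle.tf_peaks,
        gene_counts=bundle.gene_counts,
        gene_condition=bundle.gene_condition,
        arm_counts=bundle.arm_counts,
        mirna_condition=bundle.mirna_condition,
        target_map=bundle.target_map,
        h3k27ac_peaks=bundle.h3k27ac_peaks,
        h3k4me3_peaks=bundle.h3k4me3_peaks,
        promoter_seqs=bundle.mirna_promoter_seqs,
        pfm=bundle.pfm,
    )
    kwargs.update(overrides)
    return run_integration(**kwargs)


@pytest.fixture(scope="session")
def strong_result(strong_bundle):
    return integrate(strong_bundle)


@pytest.fixture(scope="session")
def default_result(default_bundle):
    return integrate(default_bundle)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240628)
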