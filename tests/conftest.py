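"""Shared fixtures: one small synthetic study reused across test modules."""

import numpy as np
import pytest

from adipotf import simulate as sim


@pytest.fixture(scope="session")
def small_config():
    return sim.SyntheticConfig(
        seed=11, n_chrom=2, chrom_len=200_000, n_genes=40, n_peaks=200
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """Complete in-memory synthetic study (genome, peaks, counts, screen)."""
    rng = np.random.default_rng(small_config.seed)
    layout, genes, sequences = sim.generate_genome(small_config, rng)
    peaks_by_tp, all_regions, truth, second = sim.generate_peak_timecourse(
        small_config, layout, rng
    )
    sequences, motif_truth = sim.plant_motifs(
        sequences, all_regions, rate=small_config.motif_plant_rate, rng=rng
    )
    design = sim.timecourse_design()
    matrix = sim.generate_counts(
        sim.timecourse_means(truth), design,
        dispersion=small_config.nb_dispersion, rng=rng,
    )
    return {
        "config": small_config,
        "layout": layout,
        "genes": genes,
        "sequences": sequences,
        "peaks_by_timepoint": peaks_by_tp,
        "all_regions": all_regions,
        "truth": truth,
        "second_factor": second,
        "counts": matrix,
        "motif_truth": motif_truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
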