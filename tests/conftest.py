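import numpy as np
import pytest

from atacprog import (
    PeakInterval,
    PeakSet,
    SimulationConfig,
    build_atlas,
    reproducible_peaks,
    simulate_cohort,
    simulate_counts_and_motifs,
    simulate_peak_sets,
)


def iv(start, end, chrom="chrS"):
    return PeakInterval(chrom, start, end)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 8+8 cohort with planted differential peaks, shared per session."""
    config = SimulationConfig(
        seed=11, n_patients=16, frac_recurrent=0.5, n_atlas_peaks=400,
        n_diff_open_recurrent=30, n_diff_open_nonrecurrent=30,
    )
    truth = simulate_cohort(config)
    peak_sets = simulate_peak_sets(truth, config)
    rep = [reproducible_peaks(r1, r2) for r1, r2 in peak_sets.values()]
    atlas = build_atlas(rep)
    counts, metadata, motifs, directions = simulate_counts_and_motifs(
        truth, atlas, config
    )
    return {
        "config": config,
        "truth": truth,
        "atlas": atlas,
        "counts": counts,
        "metadata": metadata,
        "motifs": motifs,
        "directions": directions,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
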