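import numpy as np
import pytest

import vwmgeom as vg


@pytest.fixture(scope="session")
def noiseless_exp1():
    """Exp1 dataset with zero noise: patterns equal the planted means."""
    params = vg.GeometryParams(theta_deg=0.0, noise_sd=0.0, seed=42,
                               n_vertices=60)
    means = vg.plant_geometry(params, "exp1")
    ds = vg.sample_patterns(means, experiment="exp1", noise_sd=0.0, seed=7)
    return params, means, ds


@pytest.fixture(scope="session")
def noisy_exp1():
    """Calibrated-default Exp1 dataset (within-decoding around .75)."""
    return vg.generate_dataset(vg.GeometryParams(theta_deg=0.0, seed=11),
                               "exp1")


@pytest.fixture(scope="session")
def noisy_exp2():
    return vg.generate_dataset(vg.GeometryParams(theta_deg=0.0, seed=12),
                               "exp2")


@pytest.fixture(scope="session")
def small_glm_run():
    """Small GLM problem: 4 runs per split, 30 vertices, mild noise.

    Fewer runs than the protocol's 6-7 leave too few distinct trial
    alignments for a full-rank FIR design, so 4 is the floor here.
    """
    params = vg.GeometryParams(seed=5, n_vertices=30, noise_sd=0.2)
    means = vg.plant_geometry(params, "exp1")
    design = vg.build_design("exp1", 4, seed=9)
    ds = vg.sample_patterns(means, design, noise_sd=0.2, seed=3,
                            timeseries=True, ts_noise_sd=0.2)
    fir = vg.build_fir_design(design)
    subsets = {s: vg.enumerate_run_combinations(
        [r.run_id for r in design if r.split == s], allow_any_size=True)
        for s in range(1, 5)}
    betas = vg.estimate_betas(ds.timeseries, fir, subsets)
    return ds, fir, betas
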