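import numpy as np
import pytest

import pymbms as pm


def toy_spectrum(values: dict[int, float], sample_id="toy", replicate_id="1",
                 state="raw") -> pm.MassSpectrum:
    """MassSpectrum with the given {m/z: intensity} entries, zeros elsewhere."""
    vec = np.zeros(pm.N_CHANNELS)
    for mz, v in values.items():
        vec[pm.mz_index(mz)] = v
    return pm.MassSpectrum(sample_id, replicate_id, vec, state)


@pytest.fixture(scope="session")
def natural_set():
    """Default synthetic natural-variant study: 500 samples in duplicate,
    TIC-normalized and replicate-averaged, with truth and noisy reference."""
    cfg = pm.GeneratorConfig()  # module defaults, seed 0
    rng = np.random.default_rng(cfg.seed)
    truths = pm.sample_compositions(500, cfg, rng=rng)
    spectra = []
    for i, t in enumerate(truths):
        for rep in range(cfg.n_replicates):
            spectra.append(
                pm.compose_spectrum(t, cfg, rng=rng, sample_id=f"NV{i:04d}",
                                    replicate_id=str(rep + 1))
            )
    matrix = pm.average_replicates(spectra)
    ref = pm.nmr_measure(truths, cfg, rng=rng)
    return {
        "config": cfg,
        "truths": truths,
        "matrix": matrix,
        "reference": ref,
        "glucose_true": np.array([t.glucose_dw_pct for t in truths]),
        "xylose_true": np.array([t.xylose_dw_pct for t in truths]),
    }


@pytest.fixture(scope="session")
def small_pedigree_trial():
    """Small clonally replicated trial with spectra, for pipeline tests."""
    pcfg = pm.PedigreeSimConfig(progeny_per_family=2, ramets_per_genotype=3,
                                grid_rows=20, grid_cols=20, seed=4)
    return pm.simulate_pedigree(pcfg, include_spectra=True), pcfg
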