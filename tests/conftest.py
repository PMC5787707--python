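import numpy as np
import pytest

import hetscore as hs

# Scaled-down classifier settings for multi-well suites: fewer bootstraps,
# folds and penalty-grid points than the screen-scale defaults, chosen for
# desk-scale runtimes while keeping the CV structure intact.
FAST = dict(n_boot=4, n_per_class=150, n_folds=5, Cs=tuple(np.logspace(-2, 1, 6)))


@pytest.fixture(scope="session")
def small_screen():
    """8-well screen: 1 control + 7 targeting wells, 3-SD effect, penetrance 0.6."""
    cfg = hs.SimulationConfig(wells_per_plate=8, cells_per_well=600, n_features=8, seed=11)
    cells, pmap, truth = hs.generate_screen(cfg)
    return cfg, cells, pmap, truth


@pytest.fixture(scope="session")
def small_screen_classified(small_screen):
    """The small screen run through QC, standardization and classification."""
    cfg, cells, pmap, truth = small_screen
    retained, _ = hs.qc_wells(cells, min_tpos=100, min_tneg=50)
    std = hs.standardize_within_well(retained)
    wells, pvs, model = hs.classify_screen(std, pca_k=6, seed=cfg.seed, **FAST)
    return std, pmap, truth, wells, pvs, model
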