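import numpy as np
import pandas as pd
import pytest

from phosphopipe.io import SiteRecord, StudyDesign
from phosphopipe.preprocess import QuantMatrix
from phosphopipe.simulate import SimulationConfig, generate_experiment


def make_design(groups=("caput", "cauda"), n_reps=5) -> StudyDesign:
    channels, group_of, replicate_of = [], {}, {}
    for g in groups:
        for r in range(1, n_reps + 1):
            ch = f"{g}_{r}"
            channels.append(ch)
            group_of[ch] = g
            replicate_of[ch] = r
    return StudyDesign(channels, group_of, replicate_of)


def make_site(acc="P00001", pos=10, res="S", lp=0.95, window=None, intensities=None):
    if window is None:
        window = "AAAAAAA" + res + "AAAAAAA"
    return SiteRecord(acc, pos, res, lp, window, intensities or {})


def make_diff_matrix(spec, design, jitter=(-0.002, -0.001, 0.0, 0.001, 0.002)):
    """Build a two-group QuantMatrix with exact group-mean fold changes.

    ``spec`` is a list of (site_id, fc) pairs; within-group values are
    m*(1+eps) with zero-sum jitter, so group means (and hence FC) are exact
    and the t-test p is ~0 for fc != 1 and exactly 1 for fc == 1.
    """
    eps = np.asarray(jitter)
    assert abs(eps.sum()) < 1e-15
    ga = design.channels_for(design.groups[0])
    gb = design.channels_for(design.groups[-1])
    assert len(ga) == len(eps) and len(gb) == len(eps)
    rows, ids = [], []
    for site_id, fc in spec:
        ids.append(site_id)
        rows.append(np.concatenate([1.0 * (1 + eps), fc * (1 + eps)]))
    data = pd.DataFrame(rows, index=ids, columns=ga + gb)
    return QuantMatrix(data, "calibrated")


@pytest.fixture(scope="session")
def two_group_design():
    return make_design()


@pytest.fixture(scope="session")
def small_experiment():
    """A seeded planted experiment shared across tests (read-only)."""
    cfg = SimulationConfig(n_sites=400, n_proteins=80, seed=11)
    return cfg, generate_experiment(cfg)
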