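import numpy as np
import pytest

import calciumpeaks as cp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quiet_sim():
    """Small low-noise recording with well-resolved transients."""
    cfg = cp.SimConfig(n_roi=6, n_frames=400, noise_sd=0.02,
                       trend=cp.TrendSpec("none", 0.0), seed=5)
    ts, truth = cp.simulate(cfg)
    return cfg, ts, truth


def write_wide_csv(path, time, columns):
    """columns: dict label -> list of cell strings (may contain blanks)."""
    labels = list(columns)
    lines = ["time," + ",".join(labels)]
    for k, t in enumerate(time):
        lines.append(",".join([str(t)] + [str(columns[lab][k]) for lab in labels]))
    path.write_text("\n".join(lines) + "\n")
    return path
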