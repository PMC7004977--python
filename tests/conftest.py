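import numpy as np
import pytest

from wildens import closed_cr, synth


def simulate_mb_history(N, p, c, K, rng):
    """Behavioral-response capture history; individuals never seen drop out."""
    m = np.zeros((N, K), dtype=int)
    u = rng.uniform(size=(N, K))
    for i in range(N):
        caught = False
        for t in range(K):
            pr = c if caught else p
            if u[i, t] < pr:
                m[i, t] = 1
                caught = True
    return m[m.sum(axis=1) > 0]


@pytest.fixture(scope="session")
def mb_history():
    rng = np.random.default_rng(123)
    m = simulate_mb_history(120, 0.3, 0.2, 6, rng)
    return closed_cr.CaptureHistory("sim", m, 6)


@pytest.fixture(scope="session")
def camera_dataset():
    """One synthetic camera session with decent sample size (CSR population)."""
    scn = synth.SyntheticScenario(
        seed=5, true_density=3.0, mean_cluster_size=1.0, extent_km=(9.0, 8.0)
    )
    rng = scn.rng()
    truth = synth.gen_population(scn, rng)
    cam, _ = synth.gen_camera(scn, truth, rng=rng)
    return scn, truth, cam


@pytest.fixture(scope="session")
def fecal_detections():
    """Truth-labelled long detections table for bootstrap reduction tests."""
    scn = synth.SyntheticScenario(
        seed=4, deposition_rate=0.8, genotyping_success=0.5, extent_km=(6.0, 5.0)
    )
    rng = scn.rng()
    truth = synth.gen_population(scn, rng)
    samples, tmap = synth.gen_fecal(scn, truth, rng=rng)
    return synth.detections_frame(samples, tmap)
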