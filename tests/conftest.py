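import numpy as np
import pandas as pd
import pytest

from braingp import Recording, SessionData, SimSpec, make_ground_truth, simulate_dataset


def electrode_table(locations, prefix="e"):
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    return pd.DataFrame({
        "electrode_id": [f"{prefix}{i}" for i in range(len(locations))],
        "x": locations[:, 0], "y": locations[:, 1], "z": locations[:, 2],
    })


def make_recording(voltages, locations, samplerate=250.0, patient_id="p0",
                   session_ids=None):
    """Recording from one or more timepoints x electrodes matrices."""
    if isinstance(voltages, np.ndarray):
        voltages = [voltages]
    session_ids = session_ids or [f"ses{k}" for k in range(len(voltages))]
    sessions = [SessionData(v, samplerate, sid) for v, sid in zip(voltages, session_ids)]
    return Recording(patient_id, sessions, electrode_table(locations))


def correlated_pair(r, T, rng):
    """Two series whose sample Pearson correlation is exactly r (to float)."""
    x = rng.standard_normal(T)
    e = rng.standard_normal(T)
    x = x - x.mean()
    e = e - e.mean()
    e = e - (e @ x) / (x @ x) * x
    x /= x.std()
    e /= e.std()
    return x, r * x + np.sqrt(1.0 - r**2) * e


@pytest.fixture(scope="session")
def small_cohort():
    """Default synthetic study: 8 patients sharing one smooth ground truth."""
    gt = make_ground_truth(seed=42)
    recs, manifest = simulate_dataset(gt, SimSpec(seed=42))
    return gt, recs, manifest


# -- independent brute-force oracles ----------------------------------------

def rbf_scalar(a, b, lam):
    return float(np.exp(-np.sum((np.asarray(a, float) - np.asarray(b, float)) ** 2) / lam))


def expand_brute_force(corr_matrix, electrode_locs, targets, lam):
    """Literal nested-loop expansion over unordered electrode pairs j < i."""
    n = len(electrode_locs)
    m = len(targets)
    num = np.zeros((m, m))
    den = np.zeros((m, m))
    for x in range(m):
        for y in range(m):
            for i in range(n):
                for j in range(i):
                    wxi = rbf_scalar(targets[x], electrode_locs[i], lam)
                    wyj = rbf_scalar(targets[y], electrode_locs[j], lam)
                    z = np.arctanh(np.clip(corr_matrix[i, j], -1 + 1e-6, 1 - 1e-6))
                    num[x, y] += wxi * wyj * z
                    den[x, y] += wxi * wyj
    # symmetrize by accumulating both (x, y) and (y, x) terms
    num = num + num.T
    den = den + den.T
    np.fill_diagonal(num, 0.0)
    np.fill_diagonal(den, 0.0)
    return num, den


def reconstruct_brute_force(K, alpha, beta, y_alpha):
    """Per-timepoint linear-system solution of the conditional expectation."""
    k_aa = K[np.ix_(alpha, alpha)]
    k_ab = K[np.ix_(alpha, beta)]
    out = np.empty((y_alpha.shape[0], len(beta)))
    for t in range(y_alpha.shape[0]):
        w = np.linalg.solve(k_aa, y_alpha[t])
        out[t] = k_ab.T @ w
    return out
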