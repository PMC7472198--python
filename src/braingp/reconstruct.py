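"""Gaussian-process conditional reconstruction at unobserved locations.

With a full-brain correlation matrix K over model locations, the
observed-electrode indices alpha, and unobserved indices beta, the
expected z-scored activity at beta given observations Y_alpha is

    Y_beta_hat = (K_ba @ K_aa^-1 @ Y_alpha.T).T

evaluated per timepoint, so it can be computed piecewise over time in
chunks of any size with identical results. K_aa is inverted via a
Cholesky solve after a PSD floor + ridge conditioning step, never
explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

from .io import Recording
from .model import FullCorrelationMatrix


@dataclass
class IndexPartition:
    """Split of model locations into observed (alpha) and unobserved (beta).

    ``electrode_to_alpha[i]`` is the position within ``observed`` of the
    recording's i-th electrode, so voltage columns can be mapped onto
    alpha order regardless of row order in the model.
    """

    observed: np.ndarray            # alpha: indices into model locations
    unobserved: np.ndarray          # beta: the complement
    electrode_to_alpha: np.ndarray  # per electrode, index into `observed`

    @property
    def n_model(self) -> int:
        return self.observed.size + self.unobserved.size


def partition(model: FullCorrelationMatrix, electrode_locs: np.ndarray,
              tolerance: float = 0.5) -> IndexPartition:
    """Match electrodes to model rows within ``tolerance`` mm.

    Every electrode must match a model location (they normally originate
    from the same table, so matches are near-exact); an unmatched
    electrode raises with the nearest model location and its distance.
    """
    electrode_locs = np.atleast_2d(np.asarray(electrode_locs, dtype=float))
    d = cdist(electrode_locs, model.locations)
    nearest = d.argmin(axis=1)
    dist = d[np.arange(len(electrode_locs)), nearest]
    misses = np.flatnonzero(dist > tolerance)
    if misses.size:
        i = misses[0]
        raise ValueError(
            f"electrode at {electrode_locs[i]} matches no model location within "
            f"{tolerance} mm (nearest is {model.locations[nearest[i]]} at "
            f"{dist[i]:.3f} mm)"
        )
    alpha, inverse = np.unique(nearest, return_inverse=True)
    beta = np.setdiff1d(np.arange(model.n_locations), alpha)
    return IndexPartition(alpha, beta, inverse)


def condition_matrix(K: FullCorrelationMatrix, ridge: float = 1e-5) -> FullCorrelationMatrix:
    """Make K safely invertible while keeping it a correlation matrix.

    Negative eigenvalues (the z-space weighted average does not guarantee
    positive semi-definiteness) are floored at zero and the diagonal
    renormalized to 1; then ``K <- (K + ridge*I) / (1 + ridge)``, which
    keeps the unit diagonal and bounds the smallest eigenvalue below by
    ``ridge / (1 + ridge)``. With ``ridge=0`` a PSD input passes through
    unchanged.
    """
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    mat = np.asarray(K.matrix, dtype=float)
    mat = (mat + mat.T) / 2.0
    w, v = np.linalg.eigh(mat)
    if w[0] < 0:
        mat = (v * np.maximum(w, 0.0)) @ v.T
        d = np.sqrt(np.clip(np.diag(mat), 1e-12, None))
        mat = mat / np.outer(d, d)
        mat = (mat + mat.T) / 2.0
        np.fill_diagonal(mat, 1.0)
    if ridge > 0:
        mat = (mat + ridge * np.eye(mat.shape[0])) / (1.0 + ridge)
    return FullCorrelationMatrix(K.locations.copy(), mat)


@dataclass
class Reconstruction:
    """Per-session reconstructed (and passed-through) z-scored activity.

    ``values[k]`` is the timepoints x M matrix for session k: observed
    columns equal the input exactly, unobserved columns hold the
    conditional expectation.
    """

    locations: np.ndarray
    session_ids: list[str]
    values: list[np.ndarray]
    observed_mask: np.ndarray
    chunk_log: list = field(default_factory=list)

    def session(self, k: int = 0) -> np.ndarray:
        return self.values[k]


def reconstruct_timeseries(
    rec: Recording,
    model: FullCorrelationMatrix,
    part: IndexPartition,
    chunk_size: int = 10_000,
) -> Reconstruction:
    """Fill in activity at unobserved model locations, session by session.

    ``rec`` must already be z-scored per session. The linear map
    ``A = K_aa^-1 K_ab`` is formed once per recording via a Cholesky
    solve; each time chunk then contributes ``Y_alpha[chunk] @ A``. The
    result is exactly independent of ``chunk_size``.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    alpha, beta = part.observed, part.unobserved
    k_aa = model.matrix[np.ix_(alpha, alpha)]
    k_ab = model.matrix[np.ix_(alpha, beta)]
    try:
        factor = cho_factor(k_aa)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "observed-block correlation matrix is singular; condition the model "
            "with a larger ridge before reconstructing"
        ) from err
    a_map = cho_solve(factor, k_ab) if beta.size else np.zeros((alpha.size, 0))

    m = model.n_locations
    out_values = []
    chunk_log = []
    for ses in rec.sessions:
        y_alpha = np.empty((ses.n_timepoints, alpha.size))
        # map voltage columns (electrode order) onto alpha order
        y_alpha[:, part.electrode_to_alpha] = ses.voltages
        out = np.empty((ses.n_timepoints, m))
        out[:, alpha] = y_alpha
        for start in range(0, ses.n_timepoints, chunk_size):
            stop = min(start + chunk_size, ses.n_timepoints)
            out[start:stop, beta] = y_alpha[start:stop] @ a_map
            chunk_log.append({"session_id": ses.session_id, "start": start, "stop": stop})
        if not np.isfinite(out).all():
            raise FloatingPointError(
                f"session {ses.session_id}: non-finite values in reconstruction"
            )
        out_values.append(out)
    observed_mask = np.zeros(m, dtype=bool)
    observed_mask[alpha] = True
    return Reconstruction(model.locations.copy(), [s.session_id for s in rec.sessions],
                          out_values, observed_mask, chunk_log)


def theoretical_accuracy(K: np.ndarray, alpha: np.ndarray, b: int) -> float:
    """Closed-form best-case reconstruction accuracy under the model.

    If activity is jointly Gaussian with correlation K, the correlation
    between the true series at location ``b`` and its conditional
    expectation from the locations ``alpha`` is
    ``sqrt(K_ba K_aa^-1 K_ab / K_bb)``.
    """
    K = np.asarray(K, dtype=float)
    alpha = np.asarray(alpha, dtype=int)
    k_aa = K[np.ix_(alpha, alpha)]
    k_ab = K[alpha, b]
    explained = float(k_ab @ np.linalg.solve(k_aa, k_ab))
    return float(np.sqrt(max(explained, 0.0) / K[b, b]))
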