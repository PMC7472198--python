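"""The full-brain correlation model.

Each patient contributes a session-averaged interelectrode correlation
matrix. An RBF weight matrix spreads those pairwise correlations (in
Fisher z space) over an arbitrary set of model locations, producing a
per-patient numerator/denominator pair; summing the pairs across
patients and taking the weighted average yields the merged full-brain
correlation matrix K-hat. Because the merge is a sum, it is exactly
associative and commutative, and patients can be added or held out by
adding or subtracting their pair.

The statsmodels-style front door is :class:`CorrelationModel` /
:class:`CorrelationModelResults`; the functional layer underneath is
usable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Recording, load_model, save_model
from .kernels import CLIP_EPS, RbfKernelSpec, fisher_z, fisher_z_inv, rbf_weights


@dataclass
class PatientCorrelation:
    """Session-averaged interelectrode correlations for one patient.

    ``matrix`` is symmetric with unit diagonal; off-diagonal entries are
    the inverse-Fisher mean of the per-session Pearson correlations.
    """

    electrodes: np.ndarray  # (N, 3) MNI mm
    matrix: np.ndarray      # (N, N)
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.electrodes = np.atleast_2d(np.asarray(self.electrodes, dtype=float))
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.electrodes.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("correlation matrix shape does not match electrode count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")


def session_average_correlations(rec: Recording) -> PatientCorrelation:
    """Average each electrode pair's per-session Pearson correlation in z space.

    For sessions ``k = 1..n`` with correlation matrices ``C_k``, returns
    ``r(mean_k z(C_k))`` with the diagonal forced to 1. Requires >= 2
    electrodes and >= 3 timepoints per session.
    """
    if rec.n_electrodes < 2:
        raise ValueError(f"patient {rec.patient_id}: need >= 2 electrodes for correlations")
    z_sum = np.zeros((rec.n_electrodes, rec.n_electrodes))
    for ses in rec.sessions:
        if ses.n_timepoints < 3:
            raise ValueError(
                f"patient {rec.patient_id}, session {ses.session_id}: need >= 3 timepoints"
            )
        sd = ses.voltages.std(axis=0)
        if np.any(sd == 0):
            bad = [rec.electrode_ids[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(
                f"patient {rec.patient_id}, session {ses.session_id}: "
                f"zero-variance electrode(s) {bad}"
            )
        c = np.corrcoef(ses.voltages.T)
        z_sum += fisher_z(c)
    mat = np.asarray(fisher_z_inv(z_sum / len(rec.sessions)))
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 1.0)
    return PatientCorrelation(rec.locations, mat, rec.patient_id)


def expand_patient(
    corr: PatientCorrelation,
    targets: np.ndarray,
    kernel: RbfKernelSpec = RbfKernelSpec(),
) -> tuple[np.ndarray, np.ndarray]:
    """Spread one patient's correlations over the model locations.

    For each target pair (x, y) the numerator sums
    ``W(x,i) * W(y,j) * z(C(i,j))`` over unordered electrode pairs j < i
    and the denominator the same sum without the z term; both are then
    symmetrized over (x, y) so the downstream ratio is a symmetric
    z-space weighted average. Diagonals are zeroed: the model's diagonal
    is fixed to 1 at materialization and never read from these sums.
    """
    w = rbf_weights(targets, corr.electrodes, kernel).weights
    n = corr.electrodes.shape[0]
    z = np.asarray(fisher_z(corr.matrix))
    np.fill_diagonal(z, 0.0)
    pair_mask = 1.0 - np.eye(n)
    # W tril(Z) W^T + its transpose == W Z0 W^T because Z0 is symmetric
    # with zero diagonal; same for the weight-only denominator.
    num = w @ z @ w.T
    den = w @ pair_mask @ w.T
    num = (num + num.T) / 2.0
    den = (den + den.T) / 2.0
    np.fill_diagonal(num, 0.0)
    np.fill_diagonal(den, 0.0)
    return num, den


@dataclass
class ModelAccumulator:
    """Running numerator/denominator sums of the merged correlation model.

    Fields mirror what is persisted: model locations, the two M x M sums,
    the number of merged patients, the kernel, and a provenance log with
    one entry per merged patient.
    """

    locations: np.ndarray
    numerator: np.ndarray
    denominator: np.ndarray
    n_patients: int = 0
    kernel: RbfKernelSpec = field(default_factory=RbfKernelSpec)
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.locations = np.atleast_2d(np.asarray(self.locations, dtype=float))
        m = self.locations.shape[0]
        self.numerator = np.asarray(self.numerator, dtype=float)
        self.denominator = np.asarray(self.denominator, dtype=float)
        if self.numerator.shape != (m, m) or self.denominator.shape != (m, m):
            raise ValueError("numerator/denominator must be M x M for M locations")

    @classmethod
    def empty(cls, locations: np.ndarray,
              kernel: RbfKernelSpec = RbfKernelSpec()) -> "ModelAccumulator":
        locations = np.atleast_2d(np.asarray(locations, dtype=float))
        m = locations.shape[0]
        return cls(locations, np.zeros((m, m)), np.zeros((m, m)), 0, kernel, [])

    def add_patient(self, num: np.ndarray, den: np.ndarray,
                    patient_id: str = "", n_electrodes: int | None = None) -> None:
        """Merge one patient's numerator/denominator pair in place."""
        if num.shape != self.numerator.shape:
            raise ValueError("patient term shape does not match model locations")
        self.numerator += num
        self.denominator += den
        self.n_patients += 1
        self.log.append({"patient_id": patient_id, "n_electrodes": n_electrodes})

    def merge(self, other: "ModelAccumulator") -> "ModelAccumulator":
        """Combine two accumulators over identical locations (order-invariant)."""
        if self.locations.shape != other.locations.shape or not np.allclose(
            self.locations, other.locations, atol=1e-9
        ):
            raise ValueError("cannot merge models with different locations")
        if self.kernel.lambda_width != other.kernel.lambda_width:
            raise ValueError("cannot merge models with different kernel widths")
        return ModelAccumulator(
            self.locations.copy(),
            self.numerator + other.numerator,
            self.denominator + other.denominator,
            self.n_patients + other.n_patients,
            self.kernel,
            list(self.log) + list(other.log),
        )

    def save(self, path) -> None:
        save_model(self, path)

    @classmethod
    def load(cls, path) -> "ModelAccumulator":
        return load_model(path)


def merge_patients(
    parts: list[tuple[np.ndarray, np.ndarray]],
    locations: np.ndarray,
    kernel: RbfKernelSpec = RbfKernelSpec(),
    patient_ids: list[str] | None = None,
) -> ModelAccumulator:
    """Sum per-patient (numerator, denominator) pairs into one accumulator."""
    acc = ModelAccumulator.empty(locations, kernel)
    for i, (num, den) in enumerate(parts):
        pid = patient_ids[i] if patient_ids else f"patient{i}"
        acc.add_patient(num, den, pid)
    return acc


@dataclass
class FullCorrelationMatrix:
    """Materialized K-hat: symmetric, unit diagonal, off-diagonal in (-1, 1)."""

    locations: np.ndarray
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.locations = np.atleast_2d(np.asarray(self.locations, dtype=float))
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.locations.shape[0]
        if self.matrix.shape != (m, m):
            raise ValueError("matrix shape does not match locations")

    @property
    def n_locations(self) -> int:
        return self.locations.shape[0]


def materialize(model: ModelAccumulator) -> FullCorrelationMatrix:
    """Turn accumulated sums into the merged correlation matrix.

    Off-diagonal entries are ``fisher_z_inv(numerator / denominator)``
    clipped into the open interval (-1, 1); the diagonal is exactly 1.
    A zero denominator off the diagonal means no patient's electrode
    pair carries any weight for that location pair, and is an error.
    """
    if model.n_patients < 1:
        raise ValueError("cannot materialize a model with 0 patients")
    m = model.locations.shape[0]
    off = ~np.eye(m, dtype=bool)
    den = model.denominator
    bad = off & (den <= 0.0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            "zero denominator: no electrode pair covers location pair "
            f"({model.locations[i]}, {model.locations[j]}); "
            "add patients with coverage there or increase lambda"
        )
    ratio = np.zeros((m, m))
    ratio[off] = model.numerator[off] / den[off]
    mat = np.asarray(fisher_z_inv(ratio))
    mat = np.clip(mat, -1.0 + CLIP_EPS, 1.0 - CLIP_EPS)
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 1.0)
    return FullCorrelationMatrix(model.locations.copy(), mat)


def union_locations(
    location_sets: list[np.ndarray], tol: float = 1e-6
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Union of location sets, collapsing duplicates closer than ``tol`` mm.

    Returns the (M, 3) union (in first-appearance order) and, per input
    set, the index of each of its rows in the union.
    """
    union: list[np.ndarray] = []
    index_maps = []
    for locs in location_sets:
        locs = np.atleast_2d(np.asarray(locs, dtype=float))
        idx = np.empty(locs.shape[0], dtype=int)
        for i, p in enumerate(locs):
            hit = -1
            if union:
                d = np.linalg.norm(np.asarray(union) - p, axis=1)
                j = int(np.argmin(d))
                if d[j] <= tol:
                    hit = j
            if hit < 0:
                union.append(p)
                hit = len(union) - 1
            idx[i] = hit
        index_maps.append(idx)
    return np.asarray(union), index_maps


# ---------------------------------------------------------------------------
# Front door: Model / Results
# ---------------------------------------------------------------------------

class CorrelationModel:
    """Full-brain correlation model over a cohort of recordings.

    Parameters
    ----------
    recordings : list of Recording
        Preprocessed (cleaned, z-scored or raw; correlations are scale
        invariant) patient recordings.
    targets : (M, 3) array, 'union', or None
        Model locations. ``'union'`` (default) uses the union of all
        patients' electrode locations; an explicit array is appended to
        that union so arbitrary query points can be reconstructed.
    kernel : RbfKernelSpec
        RBF smoothing kernel (default width 20 mm^2).

    Examples
    --------
    >>> model = CorrelationModel(recordings)
    >>> res = model.fit()
    >>> print(res.summary())
    >>> recon = res.predict(new_recording)
    """

    def __init__(self, recordings: list[Recording], targets="union",
                 kernel: RbfKernelSpec = RbfKernelSpec()):
        if not recordings:
            raise ValueError("need at least one recording")
        self.recordings = list(recordings)
        self.kernel = kernel
        sets = [rec.locations for rec in self.recordings]
        extra = None
        if isinstance(targets, str):
            if targets != "union":
                raise ValueError("targets must be 'union', None, or an (M, 3) array")
        elif targets is not None:
            extra = np.atleast_2d(np.asarray(targets, dtype=float))
            sets = sets + [extra]
        self.locations, self._index_maps = union_locations(sets)

    def fit(self, ridge: float = 1e-5) -> "CorrelationModelResults":
        """Estimate K-hat; ``ridge`` conditions it for later inversion."""
        acc = ModelAccumulator.empty(self.locations, self.kernel)
        parts = []
        for rec in self.recordings:
            corr = session_average_correlations(rec)
            num, den = expand_patient(corr, self.locations, self.kernel)
            acc.add_patient(num, den, rec.patient_id, rec.n_electrodes)
            parts.append((num, den))
        return CorrelationModelResults(self, acc, ridge, parts)


class CorrelationModelResults:
    """Fitted full-brain correlation model.

    Attributes
    ----------
    accumulator : ModelAccumulator
        Mergeable numerator/denominator sums with provenance log.
    correlation : FullCorrelationMatrix
        Materialized K-hat (unconditioned).
    conditioned : FullCorrelationMatrix
        K-hat after the PSD floor and ridge renormalization; this is
        what :meth:`predict` inverts.
    """

    def __init__(self, model: CorrelationModel, accumulator: ModelAccumulator,
                 ridge: float, parts=None):
        from .reconstruct import condition_matrix

        self.model = model
        self.accumulator = accumulator
        self.ridge = float(ridge)
        self.patient_parts = parts
        self.correlation = materialize(accumulator)
        self.conditioned = condition_matrix(self.correlation, ridge)

    @property
    def locations(self) -> np.ndarray:
        return self.accumulator.locations

    @property
    def n_patients(self) -> int:
        return self.accumulator.n_patients

    def predict(self, rec: Recording, chunk_size: int = 10_000,
                tolerance: float = 0.5, zscore: bool = True):
        """Reconstruct z-scored activity at every model location.

        Observed electrode columns pass through unchanged; unobserved
        locations get the Gaussian-process conditional expectation
        ``K_ba K_aa^-1 y`` computed chunkwise over time.
        """
        from .preprocess import zscore_sessions
        from .reconstruct import partition, reconstruct_timeseries

        if zscore:
            rec = zscore_sessions(rec)
        part = partition(self.conditioned, rec.locations, tolerance=tolerance)
        return reconstruct_timeseries(rec, self.conditioned, part, chunk_size=chunk_size)

    def save(self, path) -> None:
        self.accumulator.save(path)

    def summary(self) -> str:
        k = self.correlation.matrix
        off = k[~np.eye(k.shape[0], dtype=bool)]
        eig = np.linalg.eigvalsh(self.conditioned.matrix)
        lines = [
            "Full-brain correlation model",
            "=" * 46,
            f"{'Patients merged':<30}{self.n_patients:>16d}",
            f"{'Model locations (M)':<30}{self.locations.shape[0]:>16d}",
            f"{'RBF width lambda (mm^2)':<30}{self.accumulator.kernel.lambda_width:>16.3g}",
            f"{'Ridge':<30}{self.ridge:>16.3g}",
            f"{'Mean |off-diag correlation|':<30}{np.mean(np.abs(off)):>16.4f}",
            f"{'Off-diag range':<30}{off.min():>8.3f}{off.max():>8.3f}",
            f"{'Conditioned eigenvalue range':<30}{eig.min():>8.1e}{eig.max():>8.1e}",
            "=" * 46,
        ]
        return "\n".join(lines)
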