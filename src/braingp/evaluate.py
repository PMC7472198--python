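"""Cross-validated reconstruction accuracy and voxelwise brain maps.

Accuracy is measured by leave-one-electrode-out reconstruction: each
electrode is held out in turn and reconstructed from the patient's
remaining electrodes, using a correlation model learned either from all
*other* patients (across-patient mode; the held-out patient's data never
enters the model sums) or from the held-out patient's own remaining
electrodes (within-patient mode). Per-session correlations between the
reconstructed and observed traces are averaged in Fisher z space.

Voxel maps on the 4-mm MNI grid summarize electrode sampling density and
per-voxel "information scores" (the weighted average reconstruction
accuracy of patients with electrodes near each voxel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

from .io import Recording, VoxelMap
from .kernels import RbfKernelSpec, fisher_z, fisher_z_inv
from .model import (
    ModelAccumulator,
    expand_patient,
    materialize,
    session_average_correlations,
    union_locations,
)
from .reconstruct import condition_matrix

ACROSS = "across_patient"
WITHIN = "within_patient"


@dataclass
class AccuracyRecord:
    """Reconstruction accuracy for one held-out electrode."""

    patient_id: str
    electrode_id: str
    location: np.ndarray
    per_session_r: list[float]
    mode: str

    @property
    def aggregate_r(self) -> float:
        """Session-averaged correlation (averaged in Fisher z space)."""
        return float(fisher_z_inv(np.mean([fisher_z(r) for r in self.per_session_r])))


@dataclass
class EvaluationSummary:
    """All accuracy records from one cross-validation run."""

    records: list[AccuracyRecord] = field(default_factory=list)
    model_log: dict = field(default_factory=dict)  # mode -> {held-out patient: merged ids}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{
            "patient_id": r.patient_id, "electrode_id": r.electrode_id,
            "x": r.location[0], "y": r.location[1], "z": r.location[2],
            "mode": r.mode, "n_sessions": len(r.per_session_r),
            "aggregate_r": r.aggregate_r,
        } for r in self.records]
        return pd.DataFrame(rows)

    def mean_r(self, mode: str) -> float:
        vals = [r.aggregate_r for r in self.records if r.mode == mode]
        if not vals:
            raise ValueError(f"no records for mode {mode!r}")
        return float(np.mean(vals))

    def per_patient_mean_z(self, mode: str) -> pd.Series:
        """Per patient, the mean z-transformed electrode accuracy."""
        df = self.to_dataframe()
        df = df[df["mode"] == mode]
        if df.empty:
            raise ValueError(f"no records for mode {mode!r}")
        return df.groupby("patient_id")["aggregate_r"].apply(
            lambda v: float(np.mean(fisher_z(v.to_numpy())))
        )


def _session_corr(y_true: np.ndarray, y_hat: np.ndarray) -> float:
    if y_hat.std() == 0 or y_true.std() == 0:
        return 0.0
    return float(np.corrcoef(y_true, y_hat)[0, 1])


def _holdout_accuracy(rec: Recording, K: np.ndarray, alpha_model: np.ndarray,
                      b_model: int, elec: int, others: np.ndarray) -> list[float]:
    """Per-session correlation between electrode ``elec`` and its reconstruction.

    ``alpha_model``/``b_model`` index the model matrix ``K``; ``others``
    are the voltage columns corresponding (in order) to ``alpha_model``.
    """
    k_aa = K[np.ix_(alpha_model, alpha_model)]
    k_ab = K[alpha_model, b_model]
    weights = cho_solve(cho_factor(k_aa), k_ab)
    out = []
    for ses in rec.sessions:
        y_hat = ses.voltages[:, others] @ weights
        out.append(_session_corr(ses.voltages[:, elec], y_hat))
    return out


def loo_accuracy(
    patients: list[Recording],
    mode: str = ACROSS,
    kernel: RbfKernelSpec = RbfKernelSpec(),
    ridge: float = 1e-5,
) -> EvaluationSummary:
    """Leave-one-electrode-out cross-validated reconstruction accuracy.

    ``mode='across_patient'`` trains the correlation model on all other
    patients; ``mode='within_patient'`` trains it on the held-out
    patient's remaining electrodes only. In both modes the held-out
    electrode is reconstructed from the same observed set: the patient's
    other electrodes.
    """
    if mode not in (ACROSS, WITHIN):
        raise ValueError(f"mode must be {ACROSS!r} or {WITHIN!r}")
    summary = EvaluationSummary(model_log={mode: {}})
    if mode == ACROSS:
        if len(patients) < 2:
            raise ValueError("across-patient mode needs >= 2 patients")
        targets, index_maps = union_locations([r.locations for r in patients])
        parts = []
        for rec in patients:
            corr = session_average_correlations(rec)
            parts.append(expand_patient(corr, targets, kernel))
        for s, rec in enumerate(patients):
            acc = ModelAccumulator.empty(targets, kernel)
            for o, other in enumerate(patients):
                if o == s:
                    continue
                acc.add_patient(*parts[o], other.patient_id, other.n_electrodes)
            held_ids = [e["patient_id"] for e in acc.log]
            assert rec.patient_id not in held_ids, "held-out patient leaked into model"
            summary.model_log[mode][rec.patient_id] = held_ids
            K = condition_matrix(materialize(acc), ridge).matrix
            idx = index_maps[s]
            for e in range(rec.n_electrodes):
                others = np.array([i for i in range(rec.n_electrodes)
                                   if i != e and idx[i] != idx[e]])
                if others.size == 0:
                    continue
                rs = _holdout_accuracy(rec, K, idx[others], int(idx[e]), e, others)
                summary.records.append(AccuracyRecord(
                    rec.patient_id, rec.electrode_ids[e], rec.locations[e], rs, mode))
    else:
        for rec in patients:
            if rec.n_electrodes < 3:
                raise ValueError(
                    f"patient {rec.patient_id}: within-patient mode needs >= 3 electrodes"
                )
            summary.model_log[mode][rec.patient_id] = [rec.patient_id]
            for e in range(rec.n_electrodes):
                others = np.array([i for i in range(rec.n_electrodes) if i != e])
                corr = session_average_correlations(rec.subset_electrodes(others))
                num, den = expand_patient(corr, rec.locations, kernel)
                acc = ModelAccumulator.empty(rec.locations, kernel)
                acc.add_patient(num, den, rec.patient_id, others.size)
                K = condition_matrix(materialize(acc), ridge).matrix
                rs = _holdout_accuracy(rec, K, others, e, e, others)
                summary.records.append(AccuracyRecord(
                    rec.patient_id, rec.electrode_ids[e], rec.locations[e], rs, mode))
    return summary


@dataclass
class ModeComparison:
    """Group statistics over per-patient mean z-transformed accuracies."""

    one_sample: dict      # mode -> (t, df, p) against 0
    paired_t: float | None = None
    paired_df: int | None = None
    paired_p: float | None = None
    mean_r: dict = field(default_factory=dict)


def compare_modes(summary: EvaluationSummary) -> ModeComparison:
    """One-sample and paired t-tests on z-transformed per-patient accuracies."""
    modes = sorted({r.mode for r in summary.records})
    one_sample = {}
    means = {}
    series = {}
    for mode in modes:
        z = summary.per_patient_mean_z(mode)
        if len(z) < 2:
            raise ValueError("need >= 2 patients for group statistics")
        t, p = stats.ttest_1samp(z.to_numpy(), 0.0)
        one_sample[mode] = (float(t), len(z) - 1, float(p))
        means[mode] = summary.mean_r(mode)
        series[mode] = z
    comp = ModeComparison(one_sample=one_sample, mean_r=means)
    if len(modes) == 2:
        a, b = (series[m] for m in modes)
        joined = pd.concat([a, b], axis=1, keys=modes).dropna()
        if len(joined) < 2:
            raise ValueError("paired comparison needs >= 2 patients present in both modes")
        diff = joined[modes[0]] - joined[modes[1]]
        if np.allclose(diff, 0.0):
            comp.paired_t, comp.paired_p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(joined[modes[0]], joined[modes[1]])
            comp.paired_t, comp.paired_p = float(t), float(p)
        comp.paired_df = len(joined) - 1
    return comp


# ---------------------------------------------------------------------------
# Voxel maps
# ---------------------------------------------------------------------------

def density_map(electrode_locs: np.ndarray, grid: VoxelMap,
                radius: float = 20.0) -> VoxelMap:
    """Per voxel, the proportion of electrodes within ``radius`` mm (closed ball)."""
    electrode_locs = np.atleast_2d(np.asarray(electrode_locs, dtype=float))
    if electrode_locs.shape[0] < 1:
        raise ValueError("need at least one electrode")
    centers = grid.voxel_centers()
    within = cdist(centers, electrode_locs) <= radius
    return grid.with_values(within.mean(axis=1))


def electrode_density(location: np.ndarray, other_electrodes: np.ndarray,
                      radius: float = 20.0) -> float:
    """Proportion of a comparison electrode set within ``radius`` of a point.

    The comparison set should already exclude the electrode's own
    patient's electrodes.
    """
    other_electrodes = np.atleast_2d(np.asarray(other_electrodes, dtype=float))
    if other_electrodes.shape[0] == 0:
        raise ValueError("comparison electrode set is empty")
    d = np.linalg.norm(other_electrodes - np.asarray(location, dtype=float), axis=1)
    return float((d <= radius).mean())


def information_scores(summary: EvaluationSummary, grid: VoxelMap,
                       radius: float = 20.0, mode: str = ACROSS) -> VoxelMap:
    """Per-voxel weighted average reconstruction accuracy.

    Every electrode inherits its patient's mean accuracy; a voxel's score
    is the mean over all electrodes within ``radius``, so patients with
    more electrodes near a voxel weigh proportionally more. Voxels with
    no nearby electrode are missing (NaN).
    """
    df = summary.to_dataframe()
    df = df[df["mode"] == mode]
    if df.empty:
        raise ValueError(f"no records for mode {mode!r}")
    patient_mean = df.groupby("patient_id")["aggregate_r"].mean()
    locs = df[["x", "y", "z"]].to_numpy(dtype=float)
    inherited = df["patient_id"].map(patient_mean).to_numpy(dtype=float)
    centers = grid.voxel_centers()
    within = cdist(centers, locs) <= radius
    counts = within.sum(axis=1)
    vals = np.full(centers.shape[0], np.nan)
    has = counts > 0
    vals[has] = (within[has] @ inherited) / counts[has]
    return grid.with_values(vals)


def _check_same_grid(a: VoxelMap, b: VoxelMap) -> None:
    if (a.shape != b.shape or a.grid_spacing != b.grid_spacing
            or not np.allclose(a.origin, b.origin) or not (a.mask == b.mask).all()):
        raise ValueError("voxel maps are not on the same grid/mask")


def top_fraction_intersection(map_a: VoxelMap, map_b: VoxelMap,
                              fraction: float = 0.1) -> VoxelMap:
    """Boolean map of voxels in the top ``fraction`` of BOTH maps.

    The cutoff is the k-th largest defined value (k = ceil(fraction * n));
    ties at the cutoff are included, so the top set may slightly exceed
    the nominal fraction, deterministically.
    """
    _check_same_grid(map_a, map_b)
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")

    def top_set(m: VoxelMap) -> np.ndarray:
        vals = m.in_mask_values()
        defined = np.isfinite(vals)
        n = int(defined.sum())
        if n == 0:
            raise ValueError("map has no defined voxels")
        k = max(1, int(np.ceil(fraction * n)))
        cutoff = np.sort(vals[defined])[::-1][k - 1]
        return defined & (vals >= cutoff)

    both = top_set(map_a) & top_set(map_b)
    return map_a.with_values(both.astype(float))


def correlate_maps(map_a: VoxelMap, map_b: VoxelMap) -> tuple[float, int]:
    """Pearson correlation over the voxels defined in both maps."""
    _check_same_grid(map_a, map_b)
    a, b = map_a.in_mask_values(), map_b.in_mask_values()
    shared = np.isfinite(a) & np.isfinite(b)
    n = int(shared.sum())
    if n < 3:
        raise ValueError(f"need >= 3 shared defined voxels, have {n}")
    r = float(np.corrcoef(a[shared], b[shared])[0, 1])
    return r, n
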