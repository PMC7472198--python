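"""Data containers and on-disk formats.

A :class:`Recording` bundles one patient's multi-session voltage
matrices with the MNI coordinates of the electrodes that produced them.
A :class:`VoxelMap` is a scalar field on an axis-aligned MNI lattice
(electrode density, information scores, ...). Recordings round-trip
through a CSV pair or a single HDF5 file; voxel maps are NIfTI-1;
correlation models are HDF5 (see :func:`save_model`).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


class FormatError(ValueError):
    """Raised when an on-disk artifact does not match its declared format."""


@dataclass
class SessionData:
    """One recording session: a timepoints x electrodes voltage matrix.

    Voltages are raw microvolts before preprocessing and z-units after
    :func:`braingp.preprocess.zscore_sessions`.
    """

    voltages: np.ndarray
    samplerate: float
    session_id: str = "ses0"

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.voltages.ndim != 2:
            raise ValueError(f"session {self.session_id}: voltages must be 2-D")
        if self.voltages.shape[0] < 2:
            raise ValueError(f"session {self.session_id}: need >= 2 timepoints")
        if self.samplerate <= 0:
            raise ValueError(f"session {self.session_id}: samplerate must be > 0")

    @property
    def n_timepoints(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.voltages.shape[1]


@dataclass
class Recording:
    """One patient's sessions plus the shared electrode coordinate table.

    Parameters
    ----------
    patient_id : str
    sessions : list of SessionData
        All sessions share the electrode table (same column order).
    electrodes : pandas.DataFrame
        Columns ``electrode_id, x, y, z`` with MNI152 coordinates in mm.
        Row order defines voltage column order and is never reordered.
    """

    patient_id: str
    sessions: list[SessionData]
    electrodes: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = ["electrode_id", "x", "y", "z"]
        missing = [c for c in required if c not in self.electrodes.columns]
        if missing:
            raise ValueError(f"electrode table missing columns {missing}")
        if len(self.electrodes) < 1:
            raise ValueError("need at least one electrode")
        locs = self.electrodes[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.isfinite(locs).all():
            raise ValueError(f"patient {self.patient_id}: non-finite electrode coordinates")
        if not self.sessions:
            raise ValueError(f"patient {self.patient_id}: need at least one session")
        n = len(self.electrodes)
        rates = set()
        for ses in self.sessions:
            if ses.n_electrodes != n:
                raise ValueError(
                    f"patient {self.patient_id}, session {ses.session_id}: "
                    f"{ses.n_electrodes} voltage columns but {n} electrode rows"
                )
            rates.add(float(ses.samplerate))
        if len(rates) > 1:
            raise ValueError(
                f"patient {self.patient_id}: sessions disagree on samplerate {sorted(rates)}"
            )

    @property
    def n_electrodes(self) -> int:
        return len(self.electrodes)

    @property
    def locations(self) -> np.ndarray:
        """(N, 3) MNI coordinates in electrode-table order."""
        return self.electrodes[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def samplerate(self) -> float:
        return float(self.sessions[0].samplerate)

    @property
    def electrode_ids(self) -> list[str]:
        return [str(e) for e in self.electrodes["electrode_id"]]

    def with_sessions(self, sessions: list[SessionData]) -> "Recording":
        """Copy of this recording with replaced session data (same electrodes)."""
        return Recording(self.patient_id, sessions, self.electrodes.copy(), dict(self.meta))

    def subset_electrodes(self, keep: np.ndarray) -> "Recording":
        """Copy retaining the electrodes at boolean/integer index ``keep``."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        table = self.electrodes.iloc[keep].reset_index(drop=True)
        sessions = [
            SessionData(s.voltages[:, keep], s.samplerate, s.session_id) for s in self.sessions
        ]
        return Recording(self.patient_id, sessions, table, dict(self.meta))


def _check_finite(voltages: np.ndarray, session_id: str, drop_nan_rows: bool) -> np.ndarray:
    bad = ~np.isfinite(voltages).all(axis=1)
    if not bad.any():
        return voltages
    if drop_nan_rows:
        logger.warning("session %s: dropped %d non-finite rows", session_id, int(bad.sum()))
        out = voltages[~bad]
        if out.shape[0] < 2:
            raise FormatError(f"session {session_id}: fewer than 2 finite timepoints remain")
        return out
    raise FormatError(
        f"session {session_id}: {int(bad.sum())} rows contain NaN/Inf "
        "(pass drop_nan_rows=True to drop them)"
    )


def write_recording(rec: Recording, path: str | Path, format: str = "csv_pair") -> None:
    """Serialize a recording as a CSV pair (``path`` is the name prefix) or HDF5."""
    path = Path(path)
    if format == "csv_pair":
        path.parent.mkdir(parents=True, exist_ok=True)
        # %.17g round-trips float64 exactly
        rec.electrodes.to_csv(f"{path}_locs.csv", index=False, float_format="%.17g")
        for k, ses in enumerate(rec.sessions):
            pd.DataFrame(ses.voltages, columns=rec.electrode_ids).to_csv(
                f"{path}_ses{k}.csv", index=False, float_format="%.17g"
            )
        meta = {
            "patient_id": rec.patient_id,
            "samplerate": rec.samplerate,
            "session_ids": [s.session_id for s in rec.sessions],
            **rec.meta,
        }
        Path(f"{path}_meta.json").write_text(json.dumps(meta, indent=1))
    elif format == "hdf5":
        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w") as f:
            f.attrs["patient_id"] = rec.patient_id
            f.attrs["samplerate"] = rec.samplerate
            f.create_dataset("locations", data=rec.locations)
            ids = f.create_dataset(
                "electrode_ids", data=np.array(rec.electrode_ids, dtype=object),
                dtype=h5py.string_dtype(),
            )
            del ids
            grp = f.create_group("sessions")
            for k, ses in enumerate(rec.sessions):
                g = grp.create_group(f"{k:04d}")
                g.attrs["session_id"] = ses.session_id
                g.create_dataset("voltages", data=ses.voltages)
    else:
        raise ValueError(f"unknown format {format!r}")


def load_recording(
    path: str | Path, format: str = "csv_pair", drop_nan_rows: bool = False
) -> Recording:
    """Load and validate a recording written by :func:`write_recording`.

    ``format='csv_pair'`` expects ``<path>_locs.csv``, ``<path>_ses<k>.csv``
    and ``<path>_meta.json``; ``format='hdf5'`` expects a single file.
    Non-finite samples abort the load unless ``drop_nan_rows`` is set, in
    which case offending rows are dropped with a logged count.
    """
    path = Path(path)
    if format == "csv_pair":
        locs_file = Path(f"{path}_locs.csv")
        if not locs_file.exists():
            raise FileNotFoundError(locs_file)
        electrodes = pd.read_csv(locs_file, float_precision="round_trip")
        meta = json.loads(Path(f"{path}_meta.json").read_text())
        samplerate = float(meta["samplerate"])
        session_ids = meta.get("session_ids")
        sessions = []
        k = 0
        while Path(f"{path}_ses{k}.csv").exists():
            v = pd.read_csv(f"{path}_ses{k}.csv", float_precision="round_trip").to_numpy(dtype=float)
            sid = session_ids[k] if session_ids else f"ses{k}"
            if v.shape[1] != len(electrodes):
                raise FormatError(
                    f"session {sid}: data has {v.shape[1]} columns "
                    f"but location table has {len(electrodes)} rows"
                )
            v = _check_finite(v, sid, drop_nan_rows)
            sessions.append(SessionData(v, samplerate, sid))
            k += 1
        if not sessions:
            raise FileNotFoundError(f"no session files found for prefix {path}")
        extra = {k2: v2 for k2, v2 in meta.items()
                 if k2 not in ("patient_id", "samplerate", "session_ids")}
        return Recording(str(meta.get("patient_id", path.name)), sessions, electrodes, extra)
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            locs = np.asarray(f["locations"], dtype=float)
            ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["electrode_ids"][()]]
            electrodes = pd.DataFrame(
                {"electrode_id": ids, "x": locs[:, 0], "y": locs[:, 1], "z": locs[:, 2]}
            )
            samplerate = float(f.attrs["samplerate"])
            sessions = []
            for key in sorted(f["sessions"]):
                g = f["sessions"][key]
                sid = str(g.attrs.get("session_id", key))
                v = np.asarray(g["voltages"], dtype=float)
                if v.shape[1] != len(electrodes):
                    raise FormatError(
                        f"session {sid}: data has {v.shape[1]} columns "
                        f"but location table has {len(electrodes)} rows"
                    )
                v = _check_finite(v, sid, drop_nan_rows)
                sessions.append(SessionData(v, samplerate, sid))
            return Recording(str(f.attrs["patient_id"]), sessions, electrodes)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Voxel maps
# ---------------------------------------------------------------------------

@dataclass
class VoxelMap:
    """Scalar field on an axis-aligned MNI lattice.

    Voxel centers sit at ``origin + spacing * index``. ``values`` is
    defined (non-NaN) only where ``mask`` is true; in-mask voxels with no
    defined value carry NaN and count as "missing".
    """

    grid_spacing: float
    origin: np.ndarray  # (3,) mm, center of voxel (0, 0, 0)
    values: np.ndarray  # 3-D float array
    mask: np.ndarray    # 3-D bool array, same shape

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape or self.values.ndim != 3:
            raise ValueError("values and mask must be 3-D arrays of identical shape")
        self.values = np.where(self.mask, self.values, np.nan)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.eye(3) * self.grid_spacing
        aff[:3, 3] = self.origin
        return aff

    def voxel_centers(self, in_mask_only: bool = True) -> np.ndarray:
        """(n, 3) MNI coordinates of voxel centers (in scan order)."""
        idx = np.argwhere(self.mask) if in_mask_only else np.argwhere(np.ones(self.shape, bool))
        return self.origin + self.grid_spacing * idx

    def in_mask_values(self) -> np.ndarray:
        return self.values[self.mask]

    def with_values(self, flat_values: np.ndarray) -> "VoxelMap":
        """New map assigning ``flat_values`` to in-mask voxels in scan order."""
        out = np.full(self.shape, np.nan)
        out[self.mask] = flat_values
        return VoxelMap(self.grid_spacing, self.origin, out, self.mask.copy())

    @classmethod
    def box(cls, origin=(-40.0, -40.0, -40.0), shape=(21, 21, 21),
            spacing: float = 4.0) -> "VoxelMap":
        """Rectangular fully unmasked grid, used by tests and synthetic runs."""
        shape = tuple(int(s) for s in shape)
        return cls(spacing, np.asarray(origin, float),
                   np.full(shape, np.nan), np.ones(shape, bool))

    @classmethod
    def mni152(cls, spacing: float = 4.0) -> "VoxelMap":
        """Grid template over the MNI152 brain mask bundled with nilearn."""
        from nilearn.datasets import load_mni152_brain_mask

        img = load_mni152_brain_mask(resolution=int(spacing))
        mask = np.asarray(img.dataobj).astype(bool)
        aff = img.affine
        if not np.allclose(aff[:3, :3], np.eye(3) * spacing):
            raise FormatError("MNI template affine is not axis-aligned at requested spacing")
        return cls(spacing, aff[:3, 3].copy(), np.full(mask.shape, np.nan), mask)


def write_voxel_map(vmap: VoxelMap, path: str | Path) -> None:
    """Write as NIfTI-1 with the 4-mm (or given) MNI-aligned affine.

    Masked-out voxels are written as NaN.
    """
    if not vmap.mask.any():
        warnings.warn("writing a voxel map with an empty mask (all NaN volume)")
    data = np.where(vmap.mask, vmap.values, np.nan).astype(np.float64)
    img = nib.Nifti1Image(data, vmap.affine)
    nib.save(img, str(path))


def read_voxel_map(path: str | Path) -> VoxelMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    aff = img.affine
    spacing = float(aff[0, 0])
    if not np.allclose(aff[:3, :3], np.eye(3) * spacing):
        raise FormatError("voxel map affine must be axis-aligned isotropic")
    mask = np.isfinite(data)
    return VoxelMap(spacing, aff[:3, 3].copy(), data, mask)


# ---------------------------------------------------------------------------
# Model persistence (the accumulator of the full-brain correlation model)
# ---------------------------------------------------------------------------

def save_model(model, path: str | Path) -> None:
    """Persist a ModelAccumulator to HDF5 (exact round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = MODEL_FORMAT_VERSION
        f.attrs["n_patients"] = int(model.n_patients)
        f.attrs["lambda_width"] = float(model.kernel.lambda_width)
        f.attrs["log"] = json.dumps(model.log)
        f.create_dataset("locations", data=model.locations)
        f.create_dataset("numerator", data=model.numerator)
        f.create_dataset("denominator", data=model.denominator)


def load_model(path: str | Path):
    """Load a ModelAccumulator saved by :func:`save_model`."""
    from .kernels import RbfKernelSpec
    from .model import ModelAccumulator

    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", -1))
        if version != MODEL_FORMAT_VERSION:
            raise FormatError(
                f"model file format version {version} unsupported "
                f"(expected {MODEL_FORMAT_VERSION})"
            )
        for key in ("locations", "numerator", "denominator"):
            if key not in f:
                raise FormatError(f"model file is missing dataset {key!r}")
        acc = ModelAccumulator(
            locations=np.asarray(f["locations"], dtype=float),
            numerator=np.asarray(f["numerator"], dtype=float),
            denominator=np.asarray(f["denominator"], dtype=float),
            n_patients=int(f.attrs["n_patients"]),
            kernel=RbfKernelSpec(float(f.attrs["lambda_width"])),
            log=json.loads(str(f.attrs["log"])),
        )
    if acc.n_patients == 0:
        logger.warning("loaded a model with 0 patients: unusable for prediction")
    return acc
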