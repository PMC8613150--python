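"""Reading, validating and writing fixation tables and serialized models.

Fixation data come in as delimited text with one row per fixation
(``subject,stimulus,trial,fix_index,x,y``; extra columns ignored). Models
(single HMMs, subject×stimulus grids of HMMs, and co-clustering results) are
stored in a versioned HDF5 archive: numeric arrays in datasets plus a JSON
metadata block carrying IDs, a format version and a checksum of the arrays.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .model import Hmm

__all__ = [
    "FixationSequence",
    "FixationDataset",
    "FormatError",
    "IntegrityError",
    "read_fixation_table",
    "write_fixation_table",
    "split_dataset",
    "write_model",
    "read_model",
]

FORMAT_VERSION = 1
REQUIRED_COLUMNS = ("subject", "stimulus", "trial", "fix_index", "x", "y")


class FormatError(ValueError):
    """The input table does not conform to the fixation-table format."""


class IntegrityError(RuntimeError):
    """A model archive is corrupt, truncated or of an unknown version."""


@dataclass(frozen=True)
class FixationSequence:
    """Ordered fixation locations for one trial (one subject, one stimulus).

    ``points`` is a (T, 2) float array of pixel coordinates, origin at the
    top-left of the stimulus, y increasing downward, in the order fixated.
    """

    subject_id: str
    stimulus_id: str
    trial_id: str
    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
            raise ValueError("points must be a non-empty (T, 2) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("fixation coordinates must be finite")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class FixationDataset:
    """A collection of fixation sequences indexed by subject and stimulus."""

    sequences: list[FixationSequence]
    subjects: list[str] = field(default_factory=list)
    stimuli: list[str] = field(default_factory=list)
    stimulus_size: dict[str, tuple[float, float]] = field(default_factory=dict)
    stimulus_label: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.subjects:
            self.subjects = sorted({s.subject_id for s in self.sequences})
        if not self.stimuli:
            self.stimuli = sorted({s.stimulus_id for s in self.sequences})
        subj, stim = set(self.subjects), set(self.stimuli)
        for s in self.sequences:
            if s.subject_id not in subj or s.stimulus_id not in stim:
                raise ValueError(
                    f"sequence ({s.subject_id},{s.stimulus_id}) missing from indices")
        self._index: dict[tuple[str, str], list[FixationSequence]] = {}
        for s in self.sequences:
            self._index.setdefault((s.subject_id, s.stimulus_id), []).append(s)

    def get(self, subject: str, stimulus: str) -> list[FixationSequence]:
        """All trials for one (subject, stimulus) pair, in file order."""
        return list(self._index.get((subject, stimulus), []))

    def subject_sequences(self, subject: str) -> list[FixationSequence]:
        return [s for s in self.sequences if s.subject_id == subject]

    def restrict_stimuli(self, stimuli: list[str]) -> "FixationDataset":
        keep = set(stimuli)
        return FixationDataset(
            sequences=[s for s in self.sequences if s.stimulus_id in keep],
            subjects=list(self.subjects),
            stimuli=[s for s in self.stimuli if s in keep],
            stimulus_size={k: v for k, v in self.stimulus_size.items() if k in keep},
            stimulus_label={k: v for k, v in self.stimulus_label.items() if k in keep},
        )

    def __len__(self) -> int:
        return len(self.sequences)


def read_fixation_table(path, dialect: dict | None = None,
                        stimulus_meta=None,
                        drop_out_of_bounds: bool = False) -> FixationDataset:
    """Read a delimited fixation table into a :class:`FixationDataset`.

    Rows are grouped into sequences by (subject, stimulus, trial) and ordered by
    ``fix_index`` within each trial, so row order on disk does not matter.

    Parameters
    ----------
    path : path-like
        Delimited text file with a header containing at least the columns
        ``subject, stimulus, trial, fix_index, x, y``.
    dialect : dict, optional
        Extra keyword arguments for :func:`pandas.read_csv` (e.g. ``sep``).
    stimulus_meta : path-like, optional
        CSV with columns ``stimulus,width,height[,label]``.
    drop_out_of_bounds : bool
        If stimulus sizes are known, drop fixations outside the bounds instead
        of keeping them with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, **(dialect or {}))
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty fixation table: {path}") from exc
    if df.empty:
        raise FormatError(f"fixation table has no rows: {path}")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    for col in ("x", "y", "fix_index"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0]) + 2  # 1-based, after header
            raise FormatError(f"non-numeric value in column {col!r} at line {row}")
        if coerced.isna().any():
            row = int(df.index[coerced.isna()][0]) + 2
            raise FormatError(f"missing value in column {col!r} at line {row}")
        df[col] = coerced

    sizes: dict[str, tuple[float, float]] = {}
    labels: dict[str, str] = {}
    if stimulus_meta is not None:
        meta = pd.read_csv(stimulus_meta)
        for col in ("stimulus", "width", "height"):
            if col not in meta.columns:
                raise FormatError(f"missing column {col!r} in stimulus metadata")
        for _, r in meta.iterrows():
            sizes[str(r["stimulus"])] = (float(r["width"]), float(r["height"]))
            if "label" in meta.columns and pd.notna(r.get("label")):
                labels[str(r["stimulus"])] = str(r["label"])

    sequences = []
    n_oob = 0
    for (subj, stim, trial), g in df.groupby(["subject", "stimulus", "trial"],
                                             sort=True):
        g = g.sort_values("fix_index", kind="stable")
        pts = g[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(pts)):
            raise FormatError(
                f"non-finite coordinate for subject {subj}, stimulus {stim}")
        stim = str(stim)
        if stim in sizes:
            w, h = sizes[stim]
            oob = (pts[:, 0] < 0) | (pts[:, 0] > w) | (pts[:, 1] < 0) | (pts[:, 1] > h)
            n_oob += int(oob.sum())
            if drop_out_of_bounds:
                pts = pts[~oob]
                if pts.shape[0] == 0:
                    continue
        sequences.append(FixationSequence(str(subj), stim, str(trial), pts))
    if n_oob and not drop_out_of_bounds:
        warnings.warn(f"{n_oob} fixations fall outside stimulus bounds; kept "
                      "(Gaussian emissions tolerate them)", stacklevel=2)
    return FixationDataset(sequences=sequences, stimulus_size=sizes,
                           stimulus_label=labels)


def write_fixation_table(dataset: FixationDataset, path) -> None:
    """Write a dataset back to the canonical CSV format."""
    rows = []
    for s in dataset.sequences:
        for i, (x, y) in enumerate(s.points, start=1):
            rows.append((s.subject_id, s.stimulus_id, s.trial_id, i, x, y))
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)


def split_dataset(dataset: FixationDataset, scheme: str = "alternating",
                  seed: int = 0) -> tuple[FixationDataset, FixationDataset]:
    """Partition the stimulus set into two halves; subjects keep their data.

    Schemes: ``alternating`` (stimuli 1,3,5,... vs 2,4,6,... in index order),
    ``random`` (seeded permutation; stratified by stimulus label when labels are
    present, so each half gets half of each label), ``by_stimulus_label``
    (one label set per half; requires exactly two labels).
    """
    stimuli = list(dataset.stimuli)
    if len(stimuli) < 2:
        raise ValueError("cannot split a dataset with fewer than 2 stimuli")
    if scheme == "alternating":
        half_a, half_b = stimuli[0::2], stimuli[1::2]
    elif scheme == "random":
        rng = np.random.default_rng(seed)
        labels = dataset.stimulus_label
        half_a, half_b = [], []
        if labels and all(s in labels for s in stimuli):
            groups: dict[str, list[str]] = {}
            for s in stimuli:
                groups.setdefault(labels[s], []).append(s)
            strata = [groups[k] for k in sorted(groups)]
        else:
            strata = [stimuli]
        for stratum in strata:
            perm = rng.permutation(len(stratum))
            half = len(stratum) // 2
            half_a.extend(stratum[i] for i in sorted(perm[:half]))
            half_b.extend(stratum[i] for i in sorted(perm[half:]))
    elif scheme == "by_stimulus_label":
        labels = dataset.stimulus_label
        uniq = sorted({labels.get(s, "") for s in stimuli})
        if len(uniq) != 2:
            raise ValueError(f"by_stimulus_label needs exactly 2 labels, got {uniq}")
        half_a = [s for s in stimuli if labels.get(s, "") == uniq[0]]
        half_b = [s for s in stimuli if labels.get(s, "") == uniq[1]]
    else:
        raise ValueError(f"unknown split scheme {scheme!r}")
    return dataset.restrict_stimuli(half_a), dataset.restrict_stimuli(half_b)


# ---------------------------------------------------------------------------
# Model archives
# ---------------------------------------------------------------------------

def _hmm_to_group(h5group: h5py.Group, hmm: Hmm, hasher) -> None:
    for name, arr in (("prior", hmm.prior), ("transition", hmm.transition),
                      ("means", hmm.means), ("covariances", hmm.covariances)):
        arr = np.ascontiguousarray(arr, dtype=np.float64)
        h5group.create_dataset(name, data=arr)
        hasher.update(arr.tobytes())


def _arrays_from_group(h5group: h5py.Group, hasher) -> dict:
    arrs = {}
    for name in ("prior", "transition", "means", "covariances"):
        if name not in h5group:
            raise IntegrityError(f"model archive missing array {h5group.name}/{name}")
        arr = np.asarray(h5group[name], dtype=np.float64)
        hasher.update(np.ascontiguousarray(arr).tobytes())
        arrs[name] = arr
    return arrs


def _hmm_from_arrays(arrs: dict) -> Hmm:
    return Hmm.from_arrays(arrs["prior"], arrs["transition"],
                           arrs["means"], arrs["covariances"])


def write_model(model, path, extra_meta: dict | None = None) -> None:
    """Serialize an Hmm, HmmGrid or CoClusterModel to a versioned HDF5 archive.

    The archive stores all parameters as float64 datasets plus a JSON metadata
    attribute with the format version and a sha256 checksum over the arrays, so
    round-trips are bit-exact and truncation is detectable.
    """
    from .cocluster import CoClusterModel, HmmGrid  # local import, avoids cycle

    hasher = hashlib.sha256()
    meta: dict = {"format_version": FORMAT_VERSION}
    if extra_meta:
        meta["extra"] = extra_meta
    with h5py.File(path, "w") as f:
        if isinstance(model, Hmm):
            meta["kind"] = "hmm"
            _hmm_to_group(f.create_group("hmm"), model, hasher)
        elif isinstance(model, HmmGrid):
            meta["kind"] = "hmm_grid"
            meta["subjects"] = list(model.subjects)
            meta["stimuli"] = list(model.stimuli)
            meta["n_sequences"] = {f"{s}|{t}": int(v)
                                   for (s, t), v in model.n_sequences.items()}
            meta["median_length"] = {f"{s}|{t}": float(v)
                                     for (s, t), v in model.median_length.items()}
            grids = f.create_group("grid")
            for (subj, stim), hmm in sorted(model.hmms.items()):
                _hmm_to_group(grids.create_group(f"{subj}|{stim}"), hmm, hasher)
        elif isinstance(model, CoClusterModel):
            meta["kind"] = "cocluster"
            meta["subjects"] = list(model.subjects)
            meta["stimuli"] = list(model.stimuli)
            meta["n_groups"] = int(model.n_groups)
            meta["assignments"] = {s: int(g) for s, g in model.assignments.items()}
            meta["objective"] = float(model.objective)
            resp = np.ascontiguousarray(model.responsibilities, dtype=np.float64)
            f.create_dataset("responsibilities", data=resp)
            hasher.update(resp.tobytes())
            w = np.ascontiguousarray(model.group_weights, dtype=np.float64)
            f.create_dataset("group_weights", data=w)
            hasher.update(w.tobytes())
            groups = f.create_group("group_hmms")
            for (g, stim), hmm in sorted(model.group_hmms.items()):
                _hmm_to_group(groups.create_group(f"{g}|{stim}"), hmm, hasher)
        else:
            raise TypeError(f"cannot serialize {type(model).__name__}")
        meta["checksum"] = hasher.hexdigest()
        f.attrs["metadata"] = json.dumps(meta)


def read_model(path):
    """Read a model archive written by :func:`write_model`; verifies version
    and checksum and raises :class:`IntegrityError` on mismatch."""
    from .cocluster import CoClusterModel, HmmGrid

    with h5py.File(path, "r") as f:
        if "metadata" not in f.attrs:
            raise IntegrityError(f"{path}: not a model archive (no metadata)")
        meta = json.loads(f.attrs["metadata"])
        if meta.get("format_version") != FORMAT_VERSION:
            raise IntegrityError(
                f"{path}: unsupported format version {meta.get('format_version')}")
        hasher = hashlib.sha256()
        kind = meta.get("kind")
        # hash all arrays first so corruption is reported as an integrity
        # failure rather than a downstream validation error
        if kind == "hmm":
            raw = _arrays_from_group(f["hmm"], hasher)
            _check(path, meta, hasher)
            return _hmm_from_arrays(raw)
        if kind == "hmm_grid":
            raw = {key: _arrays_from_group(f["grid"][key], hasher)
                   for key in sorted(f["grid"])}
            _check(path, meta, hasher)
            hmms = {tuple(key.split("|", 1)): _hmm_from_arrays(a)
                    for key, a in raw.items()}
            n_seq = {tuple(k.split("|", 1)): int(v)
                     for k, v in meta.get("n_sequences", {}).items()}
            med = {tuple(k.split("|", 1)): float(v)
                   for k, v in meta.get("median_length", {}).items()}
            return HmmGrid(hmms=hmms, subjects=list(meta["subjects"]),
                           stimuli=list(meta["stimuli"]),
                           n_sequences=n_seq, median_length=med)
        if kind == "cocluster":
            resp = np.asarray(f["responsibilities"], dtype=np.float64)
            hasher.update(np.ascontiguousarray(resp).tobytes())
            weights = np.asarray(f["group_weights"], dtype=np.float64)
            hasher.update(np.ascontiguousarray(weights).tobytes())
            raw = {key: _arrays_from_group(f["group_hmms"][key], hasher)
                   for key in sorted(f["group_hmms"])}
            _check(path, meta, hasher)
            group_hmms = {}
            for key, a in raw.items():
                g, stim = key.split("|", 1)
                group_hmms[(int(g), stim)] = _hmm_from_arrays(a)
            return CoClusterModel(
                n_groups=int(meta["n_groups"]),
                subjects=list(meta["subjects"]),
                stimuli=list(meta["stimuli"]),
                assignments={s: int(g) for s, g in meta["assignments"].items()},
                responsibilities=resp,
                group_hmms=group_hmms,
                group_weights=weights,
                objective=float(meta["objective"]),
            )
        raise IntegrityError(f"{path}: unknown model kind {kind!r}")


def _check(path, meta, hasher) -> None:
    if meta.get("checksum") != hasher.hexdigest():
        raise IntegrityError(f"{path}: checksum mismatch (corrupt archive)")
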