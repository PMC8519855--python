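"""Readers, writers and assembly for subject-level vertex maps and labels.

Supported formats:

* GIFTI functional / label files (``.func.gii``, ``.label.gii``) via nibabel;
* FreeSurfer per-vertex morphometry ("curv" binary) and ``.annot`` via
  ``nibabel.freesurfer.io``;
* delimited text: one value per line (maps, masks, labels).

Location indexing is 0-based and file order defines location identity; both
modalities must already live in the same surface space (no resampling is
performed here).  A small fixture generator writes synthetic files in every
supported format so the full I/O surface is testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import nibabel as nib
from nibabel.freesurfer import io as fsio

from .core import ModalityDataset

__all__ = [
    "MAP_FORMATS",
    "LABEL_FORMATS",
    "RegionLabels",
    "read_subject_map",
    "write_subject_map",
    "assemble_dataset",
    "read_labels",
    "write_labels",
    "read_mask",
    "read_subject_matrix",
    "make_fixtures",
]

MAP_FORMATS = ("gifti_func", "freesurfer_morph", "delimited")
LABEL_FORMATS = ("gifti_label", "freesurfer_annot", "delimited")


@dataclass
class RegionLabels:
    """Per-location integer labels mapping locations to parcels/networks.

    Label 0 is the unassigned/medial-wall sentinel; every nonzero label must
    have an entry in ``names``.
    """

    labels: np.ndarray
    names: Mapping[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D integer vector")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(int)
            if not np.array_equal(as_int, self.labels):
                raise ValueError("labels must be integers")
            self.labels = as_int
        self.names = dict(self.names)
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from names")

    @property
    def n_locations(self) -> int:
        return self.labels.size

    def region_mask(self, label: int) -> np.ndarray:
        if label != 0 and label not in self.names:
            raise KeyError(f"unknown region label {label}")
        return self.labels == label

    def present_labels(self) -> list[int]:
        return sorted(set(np.unique(self.labels)) - {0})


# ---------------------------------------------------------------------------
# subject maps


def _read_delimited_vector(path: Path) -> np.ndarray:
    text = Path(path).read_text().strip()
    if not text:
        raise ValueError(f"{path}: empty delimited file")
    tokens = text.replace(",", "\n").split()
    try:
        return np.array([float(t) for t in tokens])
    except ValueError as exc:
        raise ValueError(f"{path}: could not parse delimited values") from exc


def read_subject_map(path, format: str = "delimited") -> np.ndarray:
    """Read one per-location map, returning values in file order.

    Non-finite values are preserved (masking happens downstream, at
    dataset assembly).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited":
        return _read_delimited_vector(path)
    if format == "freesurfer_morph":
        return np.asarray(fsio.read_morph_data(str(path)), dtype=float)
    if format == "gifti_func":
        img = nib.load(str(path))
        if not isinstance(img, nib.gifti.GiftiImage):
            raise ValueError(f"{path}: not a GIFTI file")
        if len(img.darrays) != 1:
            raise ValueError(
                f"{path}: expected a single map data array, "
                f"found {len(img.darrays)}"
            )
        return np.asarray(img.darrays[0].data, dtype=float).ravel()
    raise ValueError(f"unknown map format {format!r}; expected {MAP_FORMATS}")


def write_subject_map(vector: np.ndarray, path, format: str = "delimited") -> None:
    """Write one per-location map in the requested format.

    GIFTI and the FreeSurfer curv format store 32-bit floats, so values
    round-trip only to single precision.
    """
    vector = np.asarray(vector, dtype=float).ravel()
    path = Path(path)
    if format == "delimited":
        np.savetxt(path, vector, fmt="%.17g")
    elif format == "freesurfer_morph":
        fsio.write_morph_data(str(path), vector.astype(np.float32))
    elif format == "gifti_func":
        darr = nib.gifti.GiftiDataArray(
            vector.astype(np.float32), intent="NIFTI_INTENT_NONE"
        )
        nib.save(nib.gifti.GiftiImage(darrays=[darr]), str(path))
    else:
        raise ValueError(
            f"unknown map format {format!r}; expected {MAP_FORMATS}"
        )


def assemble_dataset(
    x_paths: Sequence,
    y_paths: Sequence,
    subject_ids: Optional[Sequence] = None,
    mask: Optional[np.ndarray] = None,
    format: str = "delimited",
) -> ModalityDataset:
    """Read aligned per-subject map files into a validated ModalityDataset.

    Subject order is defined by input list order; ``x_paths[i]`` and
    ``y_paths[i]`` must belong to the same subject.  Any map whose length
    disagrees with the first is reported by path.
    """
    x_paths = list(x_paths)
    y_paths = list(y_paths)
    if len(x_paths) != len(y_paths):
        raise ValueError(
            f"{len(x_paths)} x maps but {len(y_paths)} y maps; the two "
            "modality lists must pair up subject-by-subject"
        )
    if len(x_paths) < 2:
        raise ValueError("need at least 2 subjects")
    rows_x, rows_y = [], []
    v = None
    for path, rows in [(p, rows_x) for p in x_paths] + [
        (p, rows_y) for p in y_paths
    ]:
        vec = read_subject_map(path, format)
        if v is None:
            v = vec.size
        elif vec.size != v:
            raise ValueError(
                f"{path}: has {vec.size} locations but previous maps have {v}"
            )
        rows.append(vec)
    return ModalityDataset(
        np.vstack(rows_x), np.vstack(rows_y), subject_ids, mask
    )


def read_subject_matrix(path, sep: str = "\t") -> tuple[list, np.ndarray]:
    """Read a subjects-as-rows delimited matrix with a header line.

    The first column holds subject identifiers; remaining columns are
    per-location values in location order.  Returns (subject_ids, matrix).
    """
    import pandas as pd

    frame = pd.read_csv(path, sep=sep, index_col=0)
    if frame.shape[1] < 3:
        raise ValueError(f"{path}: matrix has fewer than 3 locations")
    return list(frame.index), frame.to_numpy(dtype=float)


def read_mask(path) -> np.ndarray:
    """Boolean location mask from a delimited file of 0/1 values."""
    values = _read_delimited_vector(Path(path))
    if not np.isin(values, (0.0, 1.0)).all():
        raise ValueError(f"{path}: mask entries must be 0 or 1")
    return values.astype(bool)


# ---------------------------------------------------------------------------
# region labels


def read_labels(
    path,
    format: str = "delimited",
    names: Optional[Mapping[int, str]] = None,
) -> RegionLabels:
    """Read per-location integer region labels plus a name table.

    For delimited files the name table may be supplied via ``names``;
    otherwise names default to ``region_<k>``.  GIFTI label tables and
    annot color tables provide names directly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited":
        values = _read_delimited_vector(path)
        labels = values.astype(int)
        if not np.array_equal(labels, values):
            raise ValueError(f"{path}: labels must be integers")
        if names is None:
            names = {
                int(k): f"region_{int(k)}" for k in np.unique(labels) if k != 0
            }
        return RegionLabels(labels, names)
    if format == "gifti_label":
        img = nib.load(str(path))
        if len(img.darrays) != 1:
            raise ValueError(f"{path}: expected a single label array")
        labels = np.asarray(img.darrays[0].data).astype(int)
        table = {
            int(lab.key): lab.label
            for lab in img.labeltable.labels
            if lab.key != 0
        }
        if not table:
            table = {
                int(k): f"region_{int(k)}" for k in np.unique(labels) if k != 0
            }
        return RegionLabels(labels, table)
    if format == "freesurfer_annot":
        annot_labels, _, annot_names = fsio.read_annot(str(path))
        labels = np.asarray(annot_labels).astype(int)
        labels[labels < 0] = 0  # vertices without a table entry
        table = {
            i: (nm.decode() if isinstance(nm, bytes) else str(nm))
            for i, nm in enumerate(annot_names)
            if i != 0
        }
        return RegionLabels(labels, table)
    raise ValueError(
        f"unknown label format {format!r}; expected {LABEL_FORMATS}"
    )


def write_labels(labels: RegionLabels, path, format: str = "delimited") -> None:
    """Write region labels in the requested format (fixture support)."""
    path = Path(path)
    if format == "delimited":
        np.savetxt(path, labels.labels, fmt="%d")
    elif format == "gifti_label":
        darr = nib.gifti.GiftiDataArray(
            labels.labels.astype(np.int32), intent="NIFTI_INTENT_LABEL"
        )
        table = nib.gifti.GiftiLabelTable()
        zero = nib.gifti.GiftiLabel(key=0)
        zero.label = "unassigned"
        table.labels.append(zero)
        for key, name in sorted(labels.names.items()):
            lab = nib.gifti.GiftiLabel(key=int(key))
            lab.label = name
            table.labels.append(lab)
        img = nib.gifti.GiftiImage(darrays=[darr], labeltable=table)
        nib.save(img, str(path))
    elif format == "freesurfer_annot":
        keys = sorted(labels.names)
        # annot stores indices into its color table; index 0 = unassigned
        lut = {0: 0}
        lut.update({k: i + 1 for i, k in enumerate(keys)})
        idx = np.array([lut[int(v)] for v in labels.labels], dtype=np.int32)
        n_entries = len(keys) + 1
        ctab = np.zeros((n_entries, 5), dtype=np.int32)
        for i in range(n_entries):  # distinct colors -> distinct annot ids
            ctab[i, :3] = (i * 37 % 256, i * 91 % 256, i * 151 % 256)
            ctab[i, 4] = (
                ctab[i, 0] + ctab[i, 1] * 256 + ctab[i, 2] * 256**2
            )
        annot_names = ["unassigned"] + [labels.names[k] for k in keys]
        fsio.write_annot(str(path), idx, ctab, annot_names, fill_ctab=False)
    else:
        raise ValueError(
            f"unknown label format {format!r}; expected {LABEL_FORMATS}"
        )


# ---------------------------------------------------------------------------
# fixtures


def make_fixtures(
    out_dir,
    n_subjects: int = 30,
    n_locations: int = 300,
    sigma_a_sq: float = 3.0,
    sigma_e_sq: float = 0.5,
    rho: float = -0.15,
    seed: int = 0,
    format: str = "delimited",
) -> dict:
    """Write a small synthetic strongly-coupled bi-modal dataset to disk.

    Produces per-subject map files for both modalities, list files
    enumerating them, a mask (all-true except the first 5 locations, a toy
    "medial wall"), and a two-region label file splitting the locations in
    half.  Returns a manifest of the written paths.
    """
    from .simulation import SimulationConfig, make_mean_maps, simulate_dataset

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    maps = make_mean_maps(n_locations, rho, seed=seed)
    cfg = SimulationConfig(
        n=n_subjects,
        sigma_a_sq=sigma_a_sq,
        sigma_e_sq=sigma_e_sq,
        mean_maps=maps,
        seed=seed,
    )
    data = simulate_dataset(cfg)
    ext = {"delimited": "txt", "gifti_func": "func.gii", "freesurfer_morph": "curv"}[
        format
    ]
    x_paths, y_paths = [], []
    for i in range(n_subjects):
        xp = out / f"sub-{i:03d}_modX.{ext}"
        yp = out / f"sub-{i:03d}_modY.{ext}"
        write_subject_map(data.x[i], xp, format)
        write_subject_map(data.y[i], yp, format)
        x_paths.append(xp)
        y_paths.append(yp)
    x_list = out / "x_maps.txt"
    y_list = out / "y_maps.txt"
    x_list.write_text("\n".join(str(p) for p in x_paths) + "\n")
    y_list.write_text("\n".join(str(p) for p in y_paths) + "\n")
    mask = np.ones(n_locations, dtype=int)
    mask[:5] = 0
    mask_path = out / "mask.txt"
    np.savetxt(mask_path, mask, fmt="%d")
    labels = np.where(np.arange(n_locations) < n_locations // 2, 1, 2)
    region_labels = RegionLabels(labels, {1: "anterior", 2: "posterior"})
    labels_path = out / "labels.txt"
    write_labels(region_labels, labels_path, "delimited")
    return {
        "x_list": x_list,
        "y_list": y_list,
        "x_paths": x_paths,
        "y_paths": y_paths,
        "mask": mask_path,
        "labels": labels_path,
        "format": format,
    }
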