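"""Intermodal similarity across locations and the mean within-subject statistic.

Two aligned modalities are represented as ``n x V`` matrices (subjects by
surface locations).  The intermodal similarity :math:`\\psi(x, y)` between a
pair of length-``V`` maps is a correlation across locations — sample Pearson
by default, or Spearman (average-rank ties) as a rank-based alternative.
The observed test statistic is

.. math:: A_0 = \\frac{1}{n} \\sum_{i=1}^n \\hat\\psi(X_{i\\cdot}, Y_{i\\cdot}),

the mean within-subject similarity, which the permutation engine compares
against its distribution under random relabeling of the Y maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "DegenerateInputError",
    "ModalityDataset",
    "MEASURES",
    "similarity",
    "mean_within_subject_statistic",
    "cross_similarity_matrix",
]

#: Supported similarity measures.  Both are correlations over masked-in
#: locations: symmetric, shift-invariant, and bounded in [-1, 1].
MEASURES = ("pearson", "spearman")


class DegenerateInputError(ValueError):
    """A similarity computation received an input with no usable variation
    (zero variance over masked-in locations, too few locations, or
    non-finite values inside the mask)."""


def _check_measure(measure: str) -> str:
    if measure not in MEASURES:
        raise ValueError(
            f"unknown similarity measure {measure!r}; expected one of {MEASURES}"
        )
    return measure


@dataclass
class ModalityDataset:
    """Aligned subject-by-location intensity matrices for two modalities.

    Parameters
    ----------
    x, y : ndarray, shape (n, V)
        Intensities for modality X and modality Y.  Row ``i`` of both
        matrices belongs to the same subject.
    subject_ids : sequence of length n
        Opaque subject identifiers; must be unique (duplicates would
        corrupt the permutation null).
    mask : ndarray of bool, shape (V,), optional
        True marks locations included in every similarity computation
        (e.g. cortex, excluding the medial wall).  Default: all included.
    """

    x: np.ndarray
    y: np.ndarray
    subject_ids: Sequence = field(default=None)  # type: ignore[assignment]
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 2 or self.y.ndim != 2:
            raise ValueError("x and y must be 2-D (subjects x locations)")
        if self.x.shape != self.y.shape:
            raise ValueError(
                f"x and y shapes differ: {self.x.shape} vs {self.y.shape}"
            )
        n, v = self.x.shape
        if n < 2:
            raise ValueError(f"need at least 2 subjects, got {n}")
        if self.subject_ids is None:
            self.subject_ids = [f"sub-{i:04d}" for i in range(n)]
        self.subject_ids = list(self.subject_ids)
        if len(self.subject_ids) != n:
            raise ValueError(
                f"{len(self.subject_ids)} subject_ids for {n} subjects"
            )
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject_ids")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (v,):
                raise ValueError(
                    f"mask length {self.mask.shape} does not match V={v}"
                )
        if self.n_effective_locations < 3:
            raise ValueError(
                "fewer than 3 masked-in locations; correlation is undefined"
            )
        # Non-finite values inside the mask are an error rather than being
        # silently dropped: dropping per-subject would compare modalities
        # over different location sets.
        xm = self.x[:, self._mask_index()]
        ym = self.y[:, self._mask_index()]
        for name, arr in (("x", xm), ("y", ym)):
            bad = ~np.isfinite(arr)
            if bad.any():
                i = int(np.argwhere(bad.any(axis=1))[0, 0])
                raise DegenerateInputError(
                    f"non-finite values inside the mask in modality {name}, "
                    f"subject {self.subject_ids[i]!r}"
                )

    def _mask_index(self):
        return slice(None) if self.mask is None else self.mask

    @property
    def n_subjects(self) -> int:
        return self.x.shape[0]

    @property
    def n_locations(self) -> int:
        return self.x.shape[1]

    @property
    def n_effective_locations(self) -> int:
        return self.x.shape[1] if self.mask is None else int(self.mask.sum())

    def masked(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) restricted to masked-in locations."""
        idx = self._mask_index()
        return self.x[:, idx], self.y[:, idx]

    def restrict(self, locations: np.ndarray) -> "ModalityDataset":
        """A new dataset keeping only the given boolean location selection
        (combined with any existing mask)."""
        locations = np.asarray(locations, dtype=bool)
        if locations.shape != (self.n_locations,):
            raise ValueError("location selector length does not match V")
        keep = locations if self.mask is None else (locations & self.mask)
        if keep.all():  # avoid a copy so results stay bitwise identical
            x, y = self.x, self.y
        else:
            x, y = self.x[:, keep], self.y[:, keep]
        return ModalityDataset(x, y, list(self.subject_ids), None)


def _prepare_vector(v: np.ndarray, name: str, measure: str) -> np.ndarray:
    """Validate and standardize one map: z-score (of ranks, for Spearman)."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if v.size < 3:
        raise DegenerateInputError(
            f"{name} has {v.size} masked-in locations; need at least 3"
        )
    if not np.isfinite(v).all():
        raise DegenerateInputError(f"non-finite values inside the mask in {name}")
    if measure == "spearman":
        v = rankdata(v)  # average ranks on ties
    sd = v.std()
    if sd == 0:
        raise DegenerateInputError(
            f"zero variance over masked-in locations in {name}"
        )
    return (v - v.mean()) / sd


def similarity(
    x_map: np.ndarray,
    y_map: np.ndarray,
    measure: str = "pearson",
    mask: Optional[np.ndarray] = None,
) -> float:
    """Intermodal similarity between two maps over masked-in locations.

    Pearson: the ordinary sample correlation coefficient across the V
    masked-in locations.  Spearman: the same applied to average ranks.

    Raises
    ------
    DegenerateInputError
        If either map has zero variance, non-finite values, or fewer than
        3 masked-in locations.
    """
    _check_measure(measure)
    x_map = np.asarray(x_map, dtype=float)
    y_map = np.asarray(y_map, dtype=float)
    if x_map.shape != y_map.shape:
        raise ValueError("x_map and y_map lengths differ")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != x_map.shape:
            raise ValueError("mask length does not match maps")
        if not mask.any():
            raise DegenerateInputError("mask excludes every location")
        x_map = x_map[mask]
        y_map = y_map[mask]
    zx = _prepare_vector(x_map, "x_map", measure)
    zy = _prepare_vector(y_map, "y_map", measure)
    # Sample correlation as the mean product of z-scores (population-sd
    # normalization cancels).  Clip guards tiny FP overshoot past +/-1.
    r = float(np.clip(zx @ zy / zx.size, -1.0, 1.0))
    return r


def _standardized_rows(
    mat: np.ndarray, measure: str, modality: str, subject_ids: Sequence
) -> np.ndarray:
    if measure == "spearman":
        mat = rankdata(mat, axis=1)
    sd = mat.std(axis=1)
    bad = sd == 0
    if bad.any():
        i = int(np.argmax(bad))
        raise DegenerateInputError(
            f"zero variance over masked-in locations in modality {modality}, "
            f"subject {subject_ids[i]!r}"
        )
    return (mat - mat.mean(axis=1, keepdims=True)) / sd[:, None]


def cross_similarity_matrix(
    data: ModalityDataset, measure: str = "pearson"
) -> np.ndarray:
    """The n x n matrix ``C[i, j] = psi(X_i, Y_j)`` over masked-in locations.

    Its diagonal holds the within-subject similarities; off-diagonal entries
    are between-subject.  The permutation engine scores every relabeling of
    the Y maps by gathering from this matrix, so it is computed once.
    """
    _check_measure(measure)
    xm, ym = data.masked()
    zx = _standardized_rows(xm, measure, "x", data.subject_ids)
    zy = _standardized_rows(ym, measure, "y", data.subject_ids)
    c = zx @ zy.T / xm.shape[1]
    return np.clip(c, -1.0, 1.0)


def mean_within_subject_statistic(
    data: ModalityDataset, measure: str = "pearson"
) -> float:
    """The observed statistic ``A0``: mean over subjects of the
    within-subject similarity ``psi(X_i, Y_i)``."""
    c = cross_similarity_matrix(data, measure)
    n = data.n_subjects
    return float(c[np.arange(n), np.arange(n)].mean())
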