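"""Permutation null distribution and p-value for the SPICE test.

The null hypothesis is that a subject's two maps correspond no more strongly
than maps from two different subjects: psi(X_i, Y_i) =d psi(X_i, Y_j), i != j.
Shuffling the Y maps across subjects leaves that null distribution intact, so
re-computing the mean within-subject statistic A_k on K random relabelings
yields draws from the null distribution of A0.  The p-value counts how often
the permuted statistic matches or exceeds the observed one in magnitude,

    p = ( 1 + #{ k : |A0| <= |A_k| } ) / (K + 1),

where the leading 1 is the identity permutation's self-comparison (always
true), bounding p below by 1/(K+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    ModalityDataset,
    _check_measure,
    cross_similarity_matrix,
)

__all__ = ["SpiceResult", "permute_and_score", "spice_p_value", "spice_test"]

SIDEDNESS = ("two_sided", "greater")


@dataclass
class SpiceResult:
    """Outcome of one SPICE test."""

    a0: float
    null_stats: np.ndarray
    k_permutations: int
    p_value: float
    seed: int
    measure_name: str
    n_subjects: int
    n_locations: int
    sidedness: str = "two_sided"

    def __post_init__(self) -> None:
        self.null_stats = np.asarray(self.null_stats, dtype=float)
        assert self.null_stats.shape == (self.k_permutations,)
        assert 1.0 / (self.k_permutations + 1) <= self.p_value <= 1.0
        assert abs(self.a0) <= 1.0 and np.abs(self.null_stats).max() <= 1.0

    def to_dict(self) -> dict:
        """JSON-serializable summary (null statistics excluded)."""
        return {
            "a0": self.a0,
            "p_value": self.p_value,
            "k_permutations": self.k_permutations,
            "seed": self.seed,
            "measure": self.measure_name,
            "sided": self.sidedness,
            "n_subjects": self.n_subjects,
            "n_locations": self.n_locations,
        }


def _sample_permutations(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """K uniformly random row orders of size n, with replacement across k
    (the identity may be re-drawn by chance; no derangement restriction)."""
    return np.argsort(rng.random((k, n)), axis=1)


def _score_permutations(c: np.ndarray, perms: np.ndarray) -> np.ndarray:
    rows = np.arange(c.shape[0])
    return c[rows[None, :], perms].mean(axis=1)


def permute_and_score(
    data: ModalityDataset,
    measure: str = "pearson",
    k: int = 999,
    seed: int = 0,
) -> np.ndarray:
    """Null statistics A_1..A_k from k random relabelings of the Y maps.

    Each relabeling permutes the row order of ``y`` (``x`` fixed) and scores
    the permuted pairing with the mean within-subject similarity.  The whole
    stream is determined by ``seed``; re-running reproduces it bitwise.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    c = cross_similarity_matrix(data, measure)
    rng = np.random.default_rng(seed)
    perms = _sample_permutations(data.n_subjects, k, rng)
    return _score_permutations(c, perms)


def spice_p_value(
    a0: float, null_stats: np.ndarray, sidedness: str = "two_sided"
) -> float:
    """Permutation p-value with the identity-permutation correction.

    two_sided compares magnitudes, greater compares signed values; ties
    (exact floating-point equality) count toward the numerator.
    """
    null_stats = np.asarray(null_stats, dtype=float)
    if null_stats.size == 0:
        raise ValueError("null_stats is empty")
    if sidedness not in SIDEDNESS:
        raise ValueError(f"sidedness must be one of {SIDEDNESS}")
    if sidedness == "two_sided":
        hits = np.abs(a0) <= np.abs(null_stats)
    else:
        hits = a0 <= null_stats
    k = null_stats.size
    return float((1 + int(hits.sum())) / (k + 1))


def spice_test(
    data: ModalityDataset,
    measure: str = "pearson",
    k: int = 999,
    seed: int = 0,
    sidedness: str = "two_sided",
) -> SpiceResult:
    """Run the full SPICE test: observed A0, K permutation statistics, and
    the permutation p-value.

    Parameters
    ----------
    data : ModalityDataset
        Aligned subject-level maps for the two modalities.
    measure : {"pearson", "spearman"}
        Similarity measure across locations.
    k : int
        Number of random permutations (default 999).
    seed : int
        Seed for the permutation stream; the result is reproducible from it.
    sidedness : {"two_sided", "greater"}
        Two-sided compares |A0| with |A_k|; "greater" tests specifically for
        within-subject similarity exceeding the null.
    """
    _check_measure(measure)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    c = cross_similarity_matrix(data, measure)
    n = data.n_subjects
    rows = np.arange(n)
    a0 = float(c[rows, rows].mean())
    rng = np.random.default_rng(seed)
    perms = _sample_permutations(n, k, rng)
    null_stats = _score_permutations(c, perms)
    p = spice_p_value(a0, null_stats, sidedness)
    return SpiceResult(
        a0=a0,
        null_stats=null_stats,
        k_permutations=k,
        p_value=p,
        seed=int(seed),
        measure_name=measure,
        n_subjects=n,
        n_locations=data.n_effective_locations,
        sidedness=sidedness,
    )
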