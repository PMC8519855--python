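"""Region/network-stratified SPICE testing with Bonferroni correction.

Each selected region (e.g. a Yeo functional network or a parcel) restricts
both modalities to that region's locations and runs the global test there.
Every region gets its own deterministic permutation stream spawned from the
master seed, so regions can be run selectively and remain individually
reproducible.  Multiple-comparison control follows the threshold form of
Bonferroni: raw p-values are reported alongside alpha/m, never inflated.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import ModalityDataset
from .io_maps import RegionLabels
from .permutation import spice_test

__all__ = [
    "bonferroni_threshold",
    "region_seed",
    "spice_by_region",
    "STRATIFIED_COLUMNS",
]

STRATIFIED_COLUMNS = [
    "region",
    "label",
    "n_locations",
    "a0",
    "p_value",
    "threshold",
    "k_permutations",
    "seed",
    "skipped",
    "reason",
]


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-adjusted significance threshold alpha/m.

    Kept at full precision internally (0.05/16 = 0.003125); rounding is a
    display concern only.  Callers compare raw p-values against it.
    """
    if m < 1:
        raise ValueError(f"comparison count m must be >= 1, got {m}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return alpha / m


def region_seed(master_seed: int, label: int) -> int:
    """Deterministic per-region permutation seed spawned from the master
    seed; below 2**31 so it can be logged and replayed anywhere."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(int(label),))
    return int(ss.generate_state(1, np.uint64)[0] % (2**31))


def spice_by_region(
    data: ModalityDataset,
    labels: RegionLabels,
    regions: Optional[Sequence[int]] = None,
    k: int = 999,
    seed: int = 0,
    measure: str = "pearson",
    alpha: float = 0.05,
    m_comparisons: Optional[int] = None,
    sidedness: str = "two_sided",
) -> pd.DataFrame:
    """Run the SPICE test within each requested region.

    Parameters
    ----------
    regions : sequence of int, optional
        Label values to test; default every nonzero label present.  An
        unknown label raises.  Regions with fewer than 3 masked-in
        locations are reported as skipped rows, never silently dropped.
    m_comparisons : int, optional
        Declared comparison count for the Bonferroni threshold; defaults
        to the number of regions actually tested (not skipped).  The
        multiplicity declaration is a study-design choice, so it is the
        caller's to make.

    Returns
    -------
    DataFrame with one row per requested region: name, label, size, A0,
    raw p-value, Bonferroni threshold, K, and the per-region seed.
    """
    if labels.n_locations != data.n_locations:
        raise ValueError(
            f"labels length {labels.n_locations} does not match dataset "
            f"V={data.n_locations}"
        )
    if regions is None:
        regions = labels.present_labels()
        if not regions:
            raise ValueError("no nonzero regions present in labels")
    regions = list(regions)
    for lab in regions:
        if lab == 0 or lab not in labels.names:
            raise KeyError(f"unknown region label {lab}")

    rows = []
    for lab in regions:
        sel = labels.region_mask(lab)
        in_mask = sel if data.mask is None else (sel & data.mask)
        size = int(in_mask.sum())
        row = {
            "region": labels.names[lab],
            "label": int(lab),
            "n_locations": size,
            "k_permutations": k,
            "seed": region_seed(seed, lab),
        }
        if size < 3:
            row.update(
                a0=np.nan,
                p_value=np.nan,
                skipped=True,
                reason=f"empty region: {size} masked-in locations (< 3)",
            )
        else:
            sub = data.restrict(sel)
            res = spice_test(
                sub,
                measure=measure,
                k=k,
                seed=row["seed"],
                sidedness=sidedness,
            )
            row.update(
                a0=res.a0, p_value=res.p_value, skipped=False, reason=""
            )
        rows.append(row)

    m = m_comparisons
    if m is None:
        m = sum(1 for r in rows if not r["skipped"])
        m = max(m, 1)
    thr = bonferroni_threshold(alpha, m)
    for r in rows:
        r["threshold"] = thr
    return pd.DataFrame(rows, columns=STRATIFIED_COLUMNS)
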