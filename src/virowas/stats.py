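"""Community diversity statistics.

Alpha diversity (observed richness and natural-log Shannon index) on the
full profile or on its eukaryotic/prokaryotic subsets, square-root
Bray-Curtis beta diversity, classical PCoA (Gower centering), one-way
permutation PERMANOVA with the adonis sums-of-squares decomposition, and
Spearman correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from ._rng import child_rng

__all__ = [
    "PermanovaResult",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "permanova",
    "spearman",
]


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_perm: int


def alpha_diversity(
    row: pd.Series | Mapping[str, float],
    kingdoms: Mapping[str, str] | None = None,
    subset: str = "all",
) -> tuple[int, float]:
    """Observed richness and Shannon index (nats) for one sample.

    With subset 'eukaryotic' or 'prokaryotic' the profile is restricted to
    vOTUs of that kingdom and renormalized within the subset before the
    Shannon index is computed. Observed = count of nonzero vOTUs. An empty
    or all-zero subset yields (0, 0.0).
    """
    series = pd.Series(row, dtype=float)
    if subset not in ("all", "eukaryotic", "prokaryotic"):
        raise ValueError(f"unknown subset {subset!r}")
    if subset != "all":
        if kingdoms is None:
            raise ValueError("kingdom map required for subset diversity")
        keep = [v for v in series.index if kingdoms.get(v) == subset]
        series = series.loc[keep]
    values = series.to_numpy()
    if np.any(values < 0):
        raise ValueError("negative abundance")
    nonzero = values[values > 0]
    if nonzero.size == 0:
        return 0, 0.0
    p = nonzero / nonzero.sum()
    return int(nonzero.size), float(-(p * np.log(p)).sum())


def bray_curtis(profile: pd.DataFrame, transform: str | None = "sqrt") -> pd.DataFrame:
    """Pairwise Bray-Curtis distances after an element-wise transform.

    The default square-root transform damps the dominance of the most
    abundant vOTUs. Pairs of all-zero samples get distance 0 (with a
    warning), so degenerate samples do not poison the matrix.
    """
    values = profile.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("negative abundance")
    if transform == "sqrt":
        values = np.sqrt(values)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    zero_rows = values.sum(axis=1) == 0
    if zero_rows.sum() >= 2:
        warnings.warn("all-zero samples present; their mutual distance set to 0", stacklevel=2)
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(values, metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=profile.index, columns=profile.index)


def pcoa(distance: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical principal coordinate analysis.

    Gower-centers -D^2/2, eigendecomposes, and returns coordinates scaled
    by sqrt(eigenvalue) for the positive eigenvalues, ordered by
    decreasing eigenvalue, plus the explained-variance fractions
    (eigenvalue over the sum of positive eigenvalues).
    """
    d = distance.to_numpy(dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10, 1e-10 * abs(eigval[0])) if eigval.size else 0.0
    positive = eigval > tol
    lams = eigval[positive]
    coords = eigvec[:, positive] * np.sqrt(lams)
    explained = lams / lams.sum()
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=distance.index, columns=axes), explained


def _ss_within(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    total = 0.0
    for g in groups:
        mask = labels == g
        n_g = int(mask.sum())
        total += d2[np.ix_(mask, mask)].sum() / 2.0 / n_g
    return total


def permanova(
    distance: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA (adonis decomposition) with label permutations.

    SS_total = sum_{i<j} d_ij^2 / N over all pairs; SS_within sums the
    analogous per-group terms; R^2 = 1 - SS_within/SS_total and
    pseudo-F = (SS_between/(k-1)) / (SS_within/(N-k)). The permutation
    p-value is (1 + #{F_perm >= F_obs}) / (1 + n_perm). The permutation
    stream is keyed to the sorted sample ids, so sample order does not
    change the result.
    """
    ids = sorted(distance.index)
    d = distance.loc[ids, ids].to_numpy(dtype=float)
    labels = np.asarray([pd.Series(groups)[i] for i in ids])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if counts.min() < 2:
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    n, k = len(ids), len(uniq)
    d2 = d**2
    ss_total = d2.sum() / 2.0 / n
    ss_within = _ss_within(d2, labels, uniq)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (k - 1)) / (ss_within / (n - k))
    r2 = ss_between / ss_total

    rng = child_rng(seed, "permanova", *ids)
    exceed = 0
    for _ in range(n_perm):
        perm = labels[rng.permutation(n)]
        ss_w = _ss_within(d2, perm, uniq)
        f_perm = ((ss_total - ss_w) / (k - 1)) / (ss_w / (n - k))
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(pseudo_F=float(f_obs), R2=float(r2), p_value=float(p), n_perm=n_perm)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks; p via scipy."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        warnings.warn("constant input: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
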