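"""vOTU abundance profiling.

Implements the three-step relative-abundance model: (1) the per-vOTU
sequencing depth is the trimmed mean of its per-base depths, discarding
the lowest and highest 10% of positions (robust against island coverage
from shared regions); (2) depths are zeroed for vOTUs with no classifier-
confirmed reads; (3) depths are closed to relative abundances per sample.
Family-level profiles sum member vOTU abundances; the virus-to-bacterium
ratio compares genome-length-normalized read counts ("cell counts").
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "trimmed_depth",
    "apply_confirmation",
    "relative_abundance",
    "build_profile",
    "aggregate_family",
    "virus_bacterium_ratio",
]


def trimmed_depth(depths: Sequence[int] | np.ndarray) -> float:
    """Mean per-base depth after trimming floor(0.1*L) positions per end.

    Positions are ranked by depth (stable sort, ties broken by position);
    vectors shorter than 10 positions are not trimmed at all.
    """
    arr = np.asarray(depths)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("depth vector must be nonempty and one-dimensional")
    if np.any(arr < 0):
        raise ValueError("negative depth")
    k = arr.size // 10
    ordered = np.sort(arr, kind="stable")
    if k:
        ordered = ordered[k:-k]
    return float(ordered.mean())


def apply_confirmation(
    depth_by_votu: Mapping[str, float], confirmed_counts: Mapping[str, int]
) -> dict[str, float]:
    """Zero the depth of any vOTU without classifier-confirmed reads."""
    missing = sorted(set(depth_by_votu) ^ set(confirmed_counts))
    if missing:
        raise ValueError(f"vOTU key mismatch between depths and counts: {missing}")
    out = {}
    for votu, depth in depth_by_votu.items():
        count = confirmed_counts[votu]
        if count < 0:
            raise ValueError(f"negative confirmation count for {votu!r}")
        out[votu] = 0.0 if count == 0 else float(depth)
    return out


def relative_abundance(depth_by_votu: Mapping[str, float]) -> dict[str, float]:
    """Close depths to relative abundances; an all-zero sample stays zero."""
    values = np.array([depth_by_votu[k] for k in depth_by_votu], dtype=float)
    if np.any(values < 0):
        raise ValueError("negative depth")
    total = values.sum()
    if total == 0:
        warnings.warn("no viral signal: all depths zero", stacklevel=2)
        return {k: 0.0 for k in depth_by_votu}
    return {k: float(v / total) for k, v in zip(depth_by_votu, values)}


def build_profile(
    depth_store: Mapping[tuple[str, str], np.ndarray],
    confirm_counts: Mapping[tuple[str, str], int],
    samples: Sequence[str],
    votus: Sequence[str],
) -> pd.DataFrame:
    """Sample x vOTU relative-abundance matrix from per-base depth vectors.

    A (sample, vOTU) pair absent from the depth store contributes depth 0.
    All-zero rows are retained so sample sets stay aligned across
    modalities.
    """
    rows = []
    for sample in samples:
        depths = {
            v: trimmed_depth(depth_store[(sample, v)])
            if (sample, v) in depth_store
            else 0.0
            for v in votus
        }
        counts = {v: confirm_counts.get((sample, v), 0) for v in votus}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows.append(relative_abundance(apply_confirmation(depths, counts)))
    return pd.DataFrame(rows, index=list(samples), columns=list(votus)).fillna(0.0)


def aggregate_family(profile: pd.DataFrame, family_map: Mapping[str, str]) -> pd.DataFrame:
    """Aggregate a vOTU profile to family level; row sums are preserved.

    Every vOTU must map to a family name (use 'unclassified' for vOTUs
    without family-level annotation).
    """
    unmapped = sorted(set(profile.columns) - set(family_map))
    if unmapped:
        raise ValueError(f"vOTUs without family mapping: {unmapped}")
    fams = pd.Index([family_map[v] for v in profile.columns], name="family")
    out = profile.T.groupby(fams).sum().T
    return out


def virus_bacterium_ratio(
    read_counts: Mapping[str, float],
    genome_lengths: Mapping[str, int],
    kingdom_labels: Mapping[str, str],
) -> float:
    """Virus-to-bacterium "cell count" ratio for one sample.

    cell_count(entity) = mapped reads / genome length; the ratio is the sum
    of viral cell counts over the sum of bacterial cell counts. Returns 0.0
    with no viral reads and +inf (with a warning) with no bacterial reads.
    """
    viral = bacterial = 0.0
    for entity, reads in read_counts.items():
        length = genome_lengths[entity]
        if length <= 0:
            raise ValueError(f"nonpositive genome length for {entity!r}")
        kingdom = kingdom_labels[entity]
        if kingdom == "virus":
            viral += reads / length
        elif kingdom == "bacterium":
            bacterial += reads / length
        else:
            raise ValueError(f"unknown kingdom label {kingdom!r} for {entity!r}")
    if bacterial == 0:
        warnings.warn("no bacterial signal: virus-to-bacterium ratio undefined", stacklevel=2)
        return float("inf") if viral > 0 else float("nan")
    return viral / bacterial
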