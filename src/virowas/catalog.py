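"""vOTU catalog construction.

Viral sequences are dereplicated into species-level clusters (vOTUs) at
95% nucleotide identity over 70% coverage of the shorter sequence, using
greedy longest-first centroid clustering. Clusters made up entirely of
external-catalog genomes are dropped, so the catalog stays anchored to the
study's own assemblies; each cluster is represented by its longest member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AlignmentSegment",
    "VotuCatalog",
    "pair_similarity",
    "cluster_votus",
    "integrate_external",
    "quality_tier",
]


@dataclass(frozen=True)
class AlignmentSegment:
    """One local alignment between a (query, subject) pair, 1-based inclusive."""

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    percent_identity: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(f"{self.query_id}: q_start > q_end")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent_identity outside [0, 100]")


@dataclass
class VotuCatalog:
    """Clustered viral reference set.

    clusters maps representative id -> list of member ids (representative
    included); source labels each member 'study' or 'external'; tier maps
    representatives to a CheckV-style quality tier.
    """

    clusters: dict[str, list[str]]
    lengths: dict[str, int]
    source: dict[str, str] = field(default_factory=dict)
    tier: dict[str, str] = field(default_factory=dict)

    @property
    def representatives(self) -> list[str]:
        return sorted(self.clusters)

    @property
    def members(self) -> list[str]:
        return sorted(m for ms in self.clusters.values() for m in ms)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rep in sorted(self.clusters):
            for member in self.clusters[rep]:
                rows.append(
                    {
                        "representative": rep,
                        "member": member,
                        "length": self.lengths.get(member),
                        "source": self.source.get(member, "study"),
                        "tier": self.tier.get(rep, ""),
                    }
                )
        return pd.DataFrame(rows)


def _merged_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of 1-based inclusive intervals."""
    ivs = sorted((s, e) for s, e in intervals)
    total = 0
    cur_s, cur_e = None, None
    for s, e in ivs:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return total


def pair_similarity(
    segments: Sequence[AlignmentSegment], len_query: int, len_subject: int
) -> tuple[float, float]:
    """Aggregate segment alignments for one ordered pair.

    Coverage is the union of aligned intervals projected on the *shorter*
    sequence, divided by the shorter length (the permissive convention in
    viral dereplication). Identity is the alignment-length-weighted mean of
    per-segment identities, with pre-merge segment lengths as weights.

    Returns (identity percent, coverage fraction); no segments -> (0, 0).
    """
    if not segments:
        return 0.0, 0.0
    pairs = {(s.query_id, s.subject_id) for s in segments}
    if len(pairs) > 1:
        raise ValueError(f"segments span multiple pairs: {sorted(pairs)}")
    if len_query <= len_subject:
        intervals = [(s.q_start, s.q_end) for s in segments]
        shorter = len_query
    else:
        intervals = [(min(s.s_start, s.s_end), max(s.s_start, s.s_end)) for s in segments]
        shorter = len_subject
    coverage = _merged_length(intervals) / shorter
    weights = [s.q_end - s.q_start + 1 for s in segments]
    identity = sum(w * s.percent_identity for w, s in zip(weights, segments)) / sum(weights)
    return identity, min(coverage, 1.0)


def cluster_votus(
    lengths: Mapping[str, int],
    similarities: Mapping[tuple[str, str], tuple[float, float]],
    id_threshold: float = 95.0,
    cov_threshold: float = 0.70,
    strict: bool = False,
) -> VotuCatalog:
    """Greedy longest-first centroid clustering.

    Sequences are visited by descending length (ties broken by id); each
    joins the first existing centroid meeting both thresholds (identity
    >= id_threshold and coverage >= cov_threshold; strictly greater when
    ``strict``), else founds a new cluster. The centroid is by construction
    the longest member, hence the cluster representative.

    similarities maps ordered (a, b) pairs to (identity percent, coverage
    fraction); lookups are symmetrized by taking the elementwise max over
    both orientations.
    """
    for a, b in similarities:
        for key in (a, b):
            if key not in lengths:
                raise ValueError(f"unknown sequence id in similarity table: {key!r}")
    for sid, length in lengths.items():
        if length <= 0:
            raise ValueError(f"nonpositive length for {sid!r}")

    def sim(a: str, b: str) -> tuple[float, float]:
        i1, c1 = similarities.get((a, b), (0.0, 0.0))
        i2, c2 = similarities.get((b, a), (0.0, 0.0))
        return max(i1, i2), max(c1, c2)

    def passes(identity: float, coverage: float) -> bool:
        if strict:
            return identity > id_threshold and coverage > cov_threshold
        return identity >= id_threshold and coverage >= cov_threshold

    order = sorted(lengths, key=lambda s: (-lengths[s], s))
    centroids: list[str] = []
    clusters: dict[str, list[str]] = {}
    for seq in order:
        for cent in centroids:
            identity, coverage = sim(seq, cent)
            if passes(identity, coverage):
                clusters[cent].append(seq)
                break
        else:
            centroids.append(seq)
            clusters[seq] = [seq]
    return VotuCatalog(clusters=clusters, lengths=dict(lengths))


def integrate_external(catalog: VotuCatalog, source: Mapping[str, str]) -> VotuCatalog:
    """Drop clusters whose members are all external-catalog genomes.

    Clusters containing at least one study genome are retained unchanged.
    Every member must carry a source label in {'study', 'external'}.
    """
    missing = [m for ms in catalog.clusters.values() for m in ms if m not in source]
    if missing:
        raise ValueError(f"members without source label: {sorted(missing)}")
    bad = {v for v in source.values()} - {"study", "external"}
    if bad:
        raise ValueError(f"unknown source labels: {sorted(bad)}")
    kept = {
        rep: list(members)
        for rep, members in catalog.clusters.items()
        if any(source[m] == "study" for m in members)
    }
    kept_members = {m for ms in kept.values() for m in ms}
    return VotuCatalog(
        clusters=kept,
        lengths={m: catalog.lengths[m] for m in kept_members},
        source={m: source[m] for m in kept_members},
        tier=dict(catalog.tier),
    )


def quality_tier(completeness: float, contamination: float) -> tuple[str, bool]:
    """CheckV-style quality tier and a low-contamination flag.

    complete (=100%), high (>=90%), medium (>=50%), low otherwise;
    low-contamination means contamination < 10%.
    """
    if not (0.0 <= completeness <= 100.0):
        raise ValueError("completeness outside [0, 100]")
    if not (0.0 <= contamination <= 100.0):
        raise ValueError("contamination outside [0, 100]")
    if completeness == 100.0:
        tier = "complete"
    elif completeness >= 90.0:
        tier = "high"
    elif completeness >= 50.0:
        tier = "medium"
    else:
        tier = "low"
    return tier, contamination < 10.0
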