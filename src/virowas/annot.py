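"""Taxonomic annotation and host prediction for vOTUs.

Family assignment follows a protein-voting rule over filtered homology
hits: a small genome (< 30 genes) is assigned to the family matching more
than one-fifth of its proteins; a large genome (>= 30 genes) needs at
least 10 matching proteins. Hosts are predicted from CRISPR-spacer matches
(bit score >= 45) and whole-genome alignments (>= 90% identity over
>= 30% of the viral genome). Families map to a eukaryotic/prokaryotic
kingdom through a fixed lookup used by the diversity analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ProteinHit",
    "HostEvidence",
    "KINGDOM_BY_FAMILY",
    "kingdom_of",
    "filter_hits",
    "assign_family",
    "assign_hosts",
    "annotate_votus",
]

# Fixed family -> kingdom lookup covering the families the analyses track.
# Families absent from the table map to 'unknown' (never an error).
KINGDOM_BY_FAMILY: dict[str, str] = {
    "Siphoviridae": "prokaryotic",
    "Myoviridae": "prokaryotic",
    "Microviridae": "prokaryotic",
    "Podoviridae": "prokaryotic",
    "crAss-like": "prokaryotic",
    "Quimbyviridae": "prokaryotic",
    "Inoviridae": "prokaryotic",
    "Salasmaviridae": "prokaryotic",
    "Autographiviridae": "prokaryotic",
    "Gratiaviridae": "prokaryotic",
    "Anelloviridae": "eukaryotic",
    "Adenoviridae": "eukaryotic",
    "Retroviridae": "eukaryotic",
    "Genomoviridae": "eukaryotic",
    "Hepadnaviridae": "eukaryotic",
}


def kingdom_of(family: str) -> str:
    if family == "unclassified":
        return "unknown"
    return KINGDOM_BY_FAMILY.get(family, "unknown")


@dataclass(frozen=True)
class ProteinHit:
    """One protein-vs-reference homology hit."""

    protein_id: str
    votu_id: str
    target_family: str
    percent_identity: float
    query_coverage: float
    subject_coverage: float
    bit_score: float


@dataclass(frozen=True)
class HostEvidence:
    """One piece of virus-host evidence.

    kind 'crispr_spacer' carries a bit_score; kind 'genome_alignment'
    carries percent_identity and viral_coverage (fraction of the viral
    genome aligned to the host genome).
    """

    votu_id: str
    host_genome_id: str
    kind: str
    bit_score: float | None = None
    percent_identity: float | None = None
    viral_coverage: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "crispr_spacer":
            if self.bit_score is None:
                raise ValueError(f"spacer evidence for {self.votu_id} lacks bit_score")
        elif self.kind == "genome_alignment":
            if self.percent_identity is None or self.viral_coverage is None:
                raise ValueError(
                    f"alignment evidence for {self.votu_id} lacks identity/coverage"
                )
        else:
            raise ValueError(f"unknown evidence kind {self.kind!r} for {self.votu_id}")


def filter_hits(hits: Iterable[ProteinHit]) -> list[ProteinHit]:
    """Retain hits meeting the homology-search thresholds (all inclusive):
    identity >= 30, query coverage >= 50, subject coverage >= 50,
    bit score >= 50."""
    return [
        h
        for h in hits
        if h.percent_identity >= 30.0
        and h.query_coverage >= 50.0
        and h.subject_coverage >= 50.0
        and h.bit_score >= 50.0
    ]


def assign_family(total_genes: int, family_counts: Mapping[str, int]) -> str:
    """Vote a family from per-family matched-protein counts.

    Genomes with fewer than 30 genes are assigned to the top family iff its
    count exceeds one-fifth of the gene total; genomes with 30 or more
    genes need at least 10 matched proteins. A tie for the best family is
    conservative: 'unclassified'.
    """
    if total_genes == 0:
        warnings.warn("vOTU with zero predicted genes cannot be classified", stacklevel=2)
        return "unclassified"
    counts = {f: c for f, c in family_counts.items() if c > 0}
    if not counts:
        return "unclassified"
    best = max(counts.values())
    winners = sorted(f for f, c in counts.items() if c == best)
    if len(winners) != 1:
        return "unclassified"
    if total_genes < 30:
        return winners[0] if best * 5 > total_genes else "unclassified"
    return winners[0] if best >= 10 else "unclassified"


def assign_hosts(evidence: Iterable[HostEvidence]) -> dict[str, set[str]]:
    """Predicted host set per vOTU from spacer and alignment evidence.

    Spacer matches assign at bit score >= 45; genome alignments assign at
    identity >= 90% over >= 30% of the viral genome. A vOTU may gain
    several hosts; vOTUs with no qualifying evidence are absent.
    """
    hosts: dict[str, set[str]] = {}
    for ev in evidence:
        if ev.kind == "crispr_spacer":
            assigned = ev.bit_score >= 45.0
        else:
            assigned = ev.percent_identity >= 90.0 and ev.viral_coverage >= 0.30
        if assigned:
            hosts.setdefault(ev.votu_id, set()).add(ev.host_genome_id)
    return hosts


def annotate_votus(
    protein_hits: Iterable[ProteinHit],
    gene_counts: Mapping[str, int],
    host_evidence: Iterable[HostEvidence] = (),
) -> pd.DataFrame:
    """Full annotation table: family, kingdom, and hosts per vOTU.

    Family votes count distinct proteins per family (a protein hitting one
    family several times votes once), computed over filtered hits only.
    Every vOTU in gene_counts appears in the output.
    """
    kept = filter_hits(protein_hits)
    votes: dict[str, dict[str, set[str]]] = {}
    for h in kept:
        votes.setdefault(h.votu_id, {}).setdefault(h.target_family, set()).add(h.protein_id)
    hosts = assign_hosts(host_evidence)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for votu in sorted(gene_counts):
            fam_counts = {f: len(ps) for f, ps in votes.get(votu, {}).items()}
            family = assign_family(gene_counts[votu], fam_counts)
            rows.append(
                {
                    "votu_id": votu,
                    "family": family,
                    "kingdom": kingdom_of(family),
                    "hosts": ";".join(sorted(hosts.get(votu, set()))),
                }
            )
    return pd.DataFrame(rows)
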