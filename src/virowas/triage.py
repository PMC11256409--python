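"""Viral contig triage.

Classifies assembled contigs as viral or not from per-contig evidence
summaries produced by upstream detectors (CheckV-style gene counts and
completeness, DeepVirFinder-style score/p-value, VIBRANT-style flag, and
BUSCO counts). Rules are applied in a fixed order:

1. length screen (keep contigs longer than 2 kb),
2. host-like exclusion (more than 10 host genes and more than five times
   the viral gene count),
3. candidate-viral criteria (any of: more viral than host genes; detector
   score > 0.90 with p < 0.01; flagged viral by the annotator),
4. bacterial-contamination removal (BUSCO ratio of at least 5%),
5. completeness filter (estimated completeness must exceed 50%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable

import pandas as pd

__all__ = [
    "ContigFeatures",
    "TriageDecision",
    "screen_length",
    "hostlike_exclusion",
    "is_candidate_viral",
    "busco_ratio",
    "triage_contigs",
    "VERDICTS",
]

VERDICTS = (
    "viral",
    "excluded_hostlike",
    "rejected_busco",
    "rejected_completeness",
    "nonviral",
    "too_short",
)

#: column order expected in contig_features.tsv
FEATURE_COLUMNS = [
    "contig_id",
    "length",
    "viral_gene_count",
    "host_gene_count",
    "total_gene_count",
    "dvf_score",
    "dvf_pvalue",
    "vibrant_viral",
    "busco_count",
    "completeness",
    "contamination",
]


@dataclass(frozen=True)
class ContigFeatures:
    """Per-contig evidence summary driving triage."""

    contig_id: str
    length: int
    viral_gene_count: int
    host_gene_count: int
    total_gene_count: int
    dvf_score: float
    dvf_pvalue: float
    vibrant_viral: bool
    busco_count: int
    completeness: float
    contamination: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.dvf_score <= 1.0):
            raise ValueError(
                f"{self.contig_id}: dvf_score {self.dvf_score} outside [0, 1]"
            )
        if self.busco_count > self.total_gene_count:
            raise ValueError(
                f"{self.contig_id}: busco_count exceeds total_gene_count"
            )
        if self.viral_gene_count + self.host_gene_count > self.total_gene_count:
            raise ValueError(
                f"{self.contig_id}: viral + host gene counts exceed total"
            )


@dataclass(frozen=True)
class TriageDecision:
    contig_id: str
    verdict: str
    fired_rules: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def screen_length(length: int) -> bool:
    """True iff the contig strictly exceeds 2000 bp."""
    if length < 0:
        raise ValueError("negative contig length")
    return length > 2000


def hostlike_exclusion(viral_gene_count: int, host_gene_count: int) -> bool:
    """True (exclude) iff host genes > 10 and > 5x the viral gene count."""
    if viral_gene_count < 0 or host_gene_count < 0:
        raise ValueError("gene counts must be nonnegative")
    return host_gene_count > 10 and host_gene_count > 5 * viral_gene_count

def is_candidate_viral(features: ContigFeatures) -> tuple[bool, tuple[str, ...]]:
    """Evaluate the three candidate-viral criteria; returns all that fire.

    A contig is a viral candidate if it has strictly more viral than host
    genes, or a detector score > 0.90 with p-value < 0.01, or is flagged
    viral by the annotation tool. Boundaries are strict where the criteria
    say "higher" / ">".
    """
    fired: list[str] = []
    if features.viral_gene_count > features.host_gene_count:
        fired.append("gene_rule")
    if features.dvf_score > 0.90 and features.dvf_pvalue < 0.01:
        fired.append("dvf_rule")
    if features.vibrant_viral:
        fired.append("vibrant_rule")
    return bool(fired), tuple(fired)


def busco_ratio(busco_count: int, total_gene_count: int) -> Fraction:
    """BUSCO-to-total gene ratio, as an exact fraction in [0, 1].

    Returned as a :class:`fractions.Fraction` so the >= 5% removal
    threshold is an exact rational comparison (1/20 triggers removal).
    """
    if total_gene_count == 0:
        raise ValueError("no predicted genes")
    if total_gene_count < 0 or busco_count < 0:
        raise ValueError("counts must be nonnegative")
    return Fraction(busco_count, total_gene_count)


_BUSCO_THRESHOLD = Fraction(1, 20)


def _decide_one(f: ContigFeatures) -> TriageDecision:
    if not screen_length(f.length):
        return TriageDecision(f.contig_id, "too_short", ("length_screen",))
    if hostlike_exclusion(f.viral_gene_count, f.host_gene_count):
        return TriageDecision(f.contig_id, "excluded_hostlike", ("hostlike_rule",))
    ok, fired = is_candidate_viral(f)
    if not ok:
        return TriageDecision(f.contig_id, "nonviral", ())
    if f.total_gene_count > 0 and busco_ratio(f.busco_count, f.total_gene_count) >= _BUSCO_THRESHOLD:
        return TriageDecision(f.contig_id, "rejected_busco", fired + ("busco_rule",))
    if not f.completeness > 50.0:
        return TriageDecision(
            f.contig_id, "rejected_completeness", fired + ("completeness_rule",)
        )
    return TriageDecision(f.contig_id, "viral", fired)


def triage_contigs(
    features: Iterable[ContigFeatures] | pd.DataFrame,
) -> list[TriageDecision]:
    """Apply the full rule cascade to a table of contigs.

    Each contig receives exactly one verdict. Duplicate contig ids are an
    error. A contig with zero predicted genes cannot be assessed for BUSCO
    contamination and skips that rule.
    """
    if isinstance(features, pd.DataFrame):
        rows = [
            ContigFeatures(
                contig_id=str(r.contig_id),
                length=int(r.length),
                viral_gene_count=int(r.viral_gene_count),
                host_gene_count=int(r.host_gene_count),
                total_gene_count=int(r.total_gene_count),
                dvf_score=float(r.dvf_score),
                dvf_pvalue=float(r.dvf_pvalue),
                vibrant_viral=bool(r.vibrant_viral),
                busco_count=int(r.busco_count),
                completeness=float(r.completeness),
                contamination=float(r.contamination),
            )
            for r in features.itertuples(index=False)
        ]
    else:
        rows = list(features)
    if not rows:
        raise ValueError("empty contig feature table")
    ids = [f.contig_id for f in rows]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate contig ids: {dupes}")
    return [_decide_one(f) for f in rows]


def decisions_frame(decisions: Iterable[TriageDecision]) -> pd.DataFrame:
    """Decisions as a tidy frame (fired rules semicolon-joined)."""
    return pd.DataFrame(
        {
            "contig_id": [d.contig_id for d in decisions],
            "verdict": [d.verdict for d in decisions],
            "fired_rules": [";".join(d.fired_rules) for d in decisions],
        }
    )
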