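"""Dual-modality differential-abundance signature calling.

A vOTU is an IBD-associated signature only if it is significant after
Benjamini-Hochberg adjustment in *both* the VLP and the bulk dataset and
shifts in the same direction in both — the conjunction makes the call
robust to modality-specific capture bias. Cross-dataset agreement of the
per-modality differential sets is quantified with Fisher's exact test,
and functional occurrence is compared between the case- and
control-enriched signature groups the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SignatureResult",
    "ConcordanceResult",
    "FunctionOccurrence",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "fisher_exact_2x2",
    "call_signatures",
    "functional_enrichment",
]

#: pseudocount used only when reporting fold changes
FOLD_EPS = 1e-9


@dataclass(frozen=True)
class SignatureResult:
    votu_id: str
    p_vlp: float
    q_vlp: float
    p_bulk: float
    q_bulk: float
    direction_vlp: str
    direction_bulk: str
    fold_vlp: float
    fold_bulk: float
    status: str


@dataclass(frozen=True)
class ConcordanceResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float


@dataclass(frozen=True)
class FunctionOccurrence:
    function_id: str
    count_case_votus: int
    count_control_votus: int
    n_case_votus: int
    n_control_votus: int
    odds_ratio: float
    p: float
    q: float
    significant: bool


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact by enumeration for small tie-free samples (n1 + n2 <= 12), else
    the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Fisher's exact test for a 2x2 table: (odds ratio, two-sided p).

    The p-value sums hypergeometric probabilities (margins fixed) of every
    table at most as probable as the observed one, with 1e-12 relative
    slack for ties. The odds ratio is the sample cross-product (a*d)/(b*c),
    +inf when b*c = 0 with a*d > 0. A zero margin makes the table
    degenerate: p = 1 and the odds ratio undefined (nan, with a warning).
    """
    (a, b), (c, d) = table
    cells = np.array([a, b, c, d])
    if np.any(cells < 0) or not np.issubdtype(cells.dtype, np.integer):
        raise ValueError("cells must be nonnegative integers")
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        warnings.warn("degenerate 2x2 table (zero margin): p = 1, OR undefined", stacklevel=2)
        return float("nan"), 1.0
    if b * c == 0:
        oratio = float("inf") if a * d > 0 else float("nan")
    else:
        oratio = (a * d) / (b * c)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[support == a][0]
    included = pmf <= p_obs * (1 + 1e-12)
    if included.all():
        return oratio, 1.0
    p = float(pmf[included].sum())
    return oratio, min(p, 1.0)


def _direction(case: np.ndarray, control: np.ndarray) -> str:
    diff = case.mean() - control.mean()
    if diff > 0:
        return "case_up"
    if diff < 0:
        return "control_up"
    return "flat"


def _test_modality(
    profile: pd.DataFrame,
    case_samples: list[str],
    control_samples: list[str],
    min_prevalence: float,
) -> pd.DataFrame:
    """Per-vOTU Wilcoxon + BH within one modality.

    Only vOTUs nonzero in at least ``min_prevalence`` of the modality's
    samples are tested; the rest are reported untested (q = NaN).
    """
    n = len(case_samples) + len(control_samples)
    sub = profile.loc[case_samples + control_samples]
    prevalence = (sub > 0).sum(axis=0) / n
    tested = prevalence[prevalence >= min_prevalence].index
    rows = {}
    for votu in profile.columns:
        case = profile.loc[case_samples, votu].to_numpy()
        control = profile.loc[control_samples, votu].to_numpy()
        fold = (case.mean() + FOLD_EPS) / (control.mean() + FOLD_EPS)
        if votu in tested:
            p = wilcoxon_rank_sum(case, control)
        else:
            p = np.nan
        rows[votu] = {"p": p, "direction": _direction(case, control), "fold": fold}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out["q"] = np.nan
    mask = out["p"].notna()
    if mask.any():
        out.loc[mask, "q"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    return out


def call_signatures(
    profile_vlp: pd.DataFrame,
    profile_bulk: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    alpha: float = 0.05,
    min_prevalence: float = 0.10,
) -> tuple[list[SignatureResult], ConcordanceResult]:
    """Call dual-modality differential-abundance signatures.

    Per modality, each sufficiently prevalent vOTU is tested case vs
    control with the Wilcoxon rank-sum test and BH-adjusted across vOTUs
    within that modality. A vOTU is case_enriched (control_enriched) iff
    q < alpha in both modalities with direction case_up (control_up) in
    both. vOTUs untested in either modality get status 'not_tested'.

    The concordance test is Fisher's exact test on the 2x2 cross-
    classification of {differential in VLP} x {differential in bulk}
    membership over all vOTUs tested in both modalities.
    """
    if set(profile_vlp.columns) != set(profile_bulk.columns):
        raise ValueError("vOTU sets differ between VLP and bulk profiles")
    groups = pd.Series(groups)

    def split(profile: pd.DataFrame) -> tuple[list[str], list[str]]:
        labels = groups.loc[profile.index]
        case = [s for s in profile.index if labels[s] == "IBD"]
        control = [s for s in profile.index if labels[s] == "control"]
        if not case or not control:
            raise ValueError("both groups must be present in each modality")
        return case, control

    vlp = _test_modality(profile_vlp, *split(profile_vlp), min_prevalence)
    bulk = _test_modality(
        profile_bulk[profile_vlp.columns], *split(profile_bulk), min_prevalence
    )

    results = []
    for votu in profile_vlp.columns:
        rv, rb = vlp.loc[votu], bulk.loc[votu]
        if np.isnan(rv["p"]) or np.isnan(rb["p"]):
            status = "not_tested"
        elif (
            rv["q"] < alpha
            and rb["q"] < alpha
            and rv["direction"] == rb["direction"] == "case_up"
        ):
            status = "case_enriched"
        elif (
            rv["q"] < alpha
            and rb["q"] < alpha
            and rv["direction"] == rb["direction"] == "control_up"
        ):
            status = "control_enriched"
        else:
            status = "not_significant"
        results.append(
            SignatureResult(
                votu_id=votu,
                p_vlp=float(rv["p"]),
                q_vlp=float(rv["q"]),
                p_bulk=float(rb["p"]),
                q_bulk=float(rb["q"]),
                direction_vlp=rv["direction"],
                direction_bulk=rb["direction"],
                fold_vlp=float(rv["fold"]),
                fold_bulk=float(rb["fold"]),
                status=status,
            )
        )

    both = [r for r in results if r.status != "not_tested"]
    a = sum(1 for r in both if r.q_vlp < alpha and r.q_bulk < alpha)
    b = sum(1 for r in both if r.q_vlp < alpha and not r.q_bulk < alpha)
    c = sum(1 for r in both if not r.q_vlp < alpha and r.q_bulk < alpha)
    d = len(both) - a - b - c
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        oratio, p = fisher_exact_2x2([[a, b], [c, d]])
    concordance = ConcordanceResult(table=((a, b), (c, d)), odds_ratio=oratio, p_value=p)
    return results, concordance


def signatures_frame(results: Sequence[SignatureResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def functional_enrichment(
    presence: pd.DataFrame,
    signature_groups: Mapping[str, str],
    alpha: float = 0.05,
) -> list[FunctionOccurrence]:
    """Compare function occurrence between signature groups.

    ``presence`` is a function x vOTU boolean matrix; signature_groups maps
    a subset of its vOTU columns to 'case_enriched' or 'control_enriched'.
    Per function, a 2x2 table (possessing vs not x group) is tested with
    Fisher's exact test, BH-adjusted across functions.
    """
    case = sorted(v for v, g in signature_groups.items() if g == "case_enriched")
    control = sorted(v for v, g in signature_groups.items() if g == "control_enriched")
    if not case or not control:
        raise ValueError("both signature groups must be nonempty")
    missing = sorted((set(case) | set(control)) - set(presence.columns))
    if missing:
        raise ValueError(f"vOTUs missing from presence matrix: {missing}")

    stats_rows = []
    for fn in presence.index:
        a = int(presence.loc[fn, case].sum())
        c = int(presence.loc[fn, control].sum())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            oratio, p = fisher_exact_2x2([[a, len(case) - a], [c, len(control) - c]])
        stats_rows.append((fn, a, c, oratio, p))
    qs = bh_adjust([r[4] for r in stats_rows])
    return [
        FunctionOccurrence(
            function_id=fn,
            count_case_votus=a,
            count_control_votus=c,
            n_case_votus=len(case),
            n_control_votus=len(control),
            odds_ratio=oratio,
            p=p,
            q=float(q),
            significant=bool(q < alpha),
        )
        for (fn, a, c, oratio, p), q in zip(stats_rows, qs)
    ]
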