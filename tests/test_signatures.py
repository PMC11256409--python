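"""Exact tests and the dual-modality signature-calling rule."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from virowas.signatures import (
    bh_adjust,
    call_signatures,
    fisher_exact_2x2,
    functional_enrichment,
    wilcoxon_rank_sum,
)


def wilcoxon_oracle(x, y):
    """Two-sided exact p by enumerating every rank assignment."""
    pooled = sorted(list(x) + list(y))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # tie-free inputs only
    w_obs = sum(ranks[v] for v in x)
    n = len(pooled)
    dist = [sum(c) for c in itertools.combinations(range(1, n + 1), len(x))]
    total = len(dist)
    le = sum(1 for w in dist if w <= w_obs)
    ge = sum(1 for w in dist if w >= w_obs)
    return min(1.0, 2 * min(le, ge) / total)


class TestWilcoxon:
    def test_fully_separated_triples(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_separated_pairs(self):
        assert wilcoxon_rank_sum([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_matches_enumeration_oracle_small_n(self):
        """Exact p equals full rank-assignment enumeration, all n1+n2 <= 8."""
        rng = np.random.default_rng(5)
        for n in range(2, 9):
            for n1 in range(1, n):
                values = list(rng.permutation(np.arange(1, n + 1, dtype=float)))
                for x_idx in itertools.combinations(range(n), n1):
                    x = [values[i] for i in x_idx]
                    y = [values[i] for i in range(n) if i not in x_idx]
                    assert wilcoxon_rank_sum(x, y) == pytest.approx(
                        wilcoxon_oracle(x, y), abs=1e-12
                    )


def bh_oracle(ps):
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, ps[i] * m / rank_from_top)
        q[i] = prev
    return q


class TestBH:
    def test_single_p(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_equal_scaled_sequence(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_two_values(self):
        assert bh_adjust([0.001, 1.0]) == pytest.approx([0.002, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    def test_matches_step_up_oracle(self, rng):
        for _ in range(50):
            ps = rng.uniform(size=int(rng.integers(1, 40))).tolist()
            assert bh_adjust(ps) == pytest.approx(bh_oracle(ps), abs=1e-12)

    def test_q_at_least_p_and_rank_monotone(self, rng):
        ps = rng.uniform(size=30)
        qs = bh_adjust(ps)
        assert np.all(qs >= ps - 1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(qs[order]) >= -1e-15)


def fisher_oracle(a, b, c, d):
    """Exact two-sided p with rational arithmetic."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    probs = {
        x: Fraction(math.comb(r1, x) * math.comb(n - r1, c1 - x), denom)
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestFisher:
    def test_worked_example(self):
        oratio, p = fisher_exact_2x2([[3, 1], [1, 3]])
        assert p == pytest.approx(34 / 70)
        assert oratio == pytest.approx(9.0)

    def test_perfect_separation(self):
        oratio, p = fisher_exact_2x2([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / math.comb(20, 10))
        assert oratio == float("inf")

    def test_symmetric_table(self):
        oratio, p = fisher_exact_2x2([[1, 1], [1, 1]])
        assert (oratio, p) == (1.0, 1.0)

    def test_degenerate_margin(self):
        with pytest.warns(UserWarning, match="degenerate"):
            oratio, p = fisher_exact_2x2([[0, 0], [3, 4]])
        assert p == 1.0 and np.isnan(oratio)

    def test_matches_rational_enumeration_oracle(self, rng):
        for _ in range(200):
            cells = rng.integers(0, 12, size=4)
            a, b, c, d = (int(v) for v in cells)
            if (a + b) * (c + d) * (a + c) * (b + d) == 0:
                continue
            _, p = fisher_exact_2x2([[a, b], [c, d]])
            assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)


def _two_modality_profiles(rng, effect_in=("VLP", "bulk"), opposite=False):
    """Tiny synthetic paired profiles with one differential vOTU ('hit')."""
    n = 20
    samples = [f"s{i:02d}" for i in range(n)]
    groups = pd.Series(["IBD"] * (n // 2) + ["control"] * (n // 2), index=samples)
    profiles = {}
    for modality in ("VLP", "bulk"):
        base = rng.lognormal(0, 0.2, size=(n, 4))
        if modality in effect_in:
            shift = 8.0 if not (opposite and modality == "bulk") else 1 / 8.0
            base[: n // 2, 0] *= shift
        base = base / base.sum(axis=1, keepdims=True)
        profiles[modality] = pd.DataFrame(
            base, index=samples, columns=["hit", "v1", "v2", "v3"]
        )
    return profiles, groups


class TestCallSignatures:
    def test_recovers_concordant_hit(self, rng):
        profiles, groups = _two_modality_profiles(rng)
        results, concordance = call_signatures(profiles["VLP"], profiles["bulk"], groups)
        by_id = {r.votu_id: r for r in results}
        assert by_id["hit"].status == "case_enriched"
        assert by_id["hit"].direction_vlp == by_id["hit"].direction_bulk == "case_up"

    def test_single_modality_hit_not_called(self, rng):
        profiles, groups = _two_modality_profiles(rng, effect_in=("VLP",))
        results, _ = call_signatures(profiles["VLP"], profiles["bulk"], groups)
        by_id = {r.votu_id: r for r in results}
        assert by_id["hit"].status == "not_significant"

    def test_opposite_directions_not_called(self, rng):
        profiles, groups = _two_modality_profiles(rng, opposite=True)
        results, _ = call_signatures(profiles["VLP"], profiles["bulk"], groups)
        by_id = {r.votu_id: r for r in results}
        assert by_id["hit"].status == "not_significant"
        assert by_id["hit"].direction_vlp != by_id["hit"].direction_bulk

    def test_votu_mismatch_rejected(self, rng):
        profiles, groups = _two_modality_profiles(rng)
        with pytest.raises(ValueError, match="vOTU sets differ"):
            call_signatures(
                profiles["VLP"], profiles["bulk"].drop(columns="v3"), groups
            )

    def test_status_partition_on_generated_study(self, small_study, small_profiles):
        results, _ = call_signatures(
            small_profiles["VLP"], small_profiles["bulk"], small_study.groups()
        )
        counts = pd.Series([r.status for r in results]).value_counts()
        assert counts.sum() == len(small_study.votus)
        allowed = {"case_enriched", "control_enriched", "not_significant", "not_tested"}
        assert set(counts.index) <= allowed


class TestFunctionalEnrichment:
    def _presence(self, pattern):
        votus = [f"c{i}" for i in range(10)] + [f"h{i}" for i in range(10)]
        return pd.DataFrame([pattern], index=["fn"], columns=votus).astype(bool)

    def _groups(self):
        groups = {f"c{i}": "case_enriched" for i in range(10)}
        groups.update({f"h{i}": "control_enriched" for i in range(10)})
        return groups

    def test_all_case_function(self):
        presence = self._presence([True] * 10 + [False] * 10)
        (occ,) = functional_enrichment(presence, self._groups())
        assert occ.odds_ratio == float("inf")
        assert occ.p == pytest.approx(2 / math.comb(20, 10))
        assert occ.count_case_votus == 10 and occ.count_control_votus == 0

    def test_absent_function_degenerate(self):
        presence = self._presence([False] * 20)
        (occ,) = functional_enrichment(presence, self._groups())
        assert occ.p == 1.0 and not occ.significant

    def test_occurrence_ratio_semantics(self):
        assert 5 / 39 == pytest.approx(0.1282, abs=5e-5)

    def test_empty_group_rejected(self):
        presence = self._presence([True] * 20)
        with pytest.raises(ValueError, match="nonempty"):
            functional_enrichment(presence, {"c0": "case_enriched"})
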