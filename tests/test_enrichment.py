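"""Hypergeometric/EASE over-representation: exactness and behaviour."""

from math import comb

import numpy as np
import pytest
from scipy import stats

from mirgrn.enrichment import ease_p, enrich_mirna, hypergeometric_p
from mirgrn.io_formats import GeneSet, GeneSetCollection, ValidationError
from mirgrn.targets import VerifiedTargetSet


def tail_oracle(k, K, n, N):
    """Exact tail by integer enumeration over the hypergeometric support."""
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / comb(N, n)


class TestHypergeometricP:
    def test_zero_overlap_is_one(self):
        assert hypergeometric_p(0, 5, 5, 20) == 1.0

    def test_single_favourable_draw(self):
        # all 5 drawn genes inside the 5-gene set: 1 / C(20,5)
        assert hypergeometric_p(5, 5, 5, 20) == pytest.approx(1 / 15504, rel=1e-9)

    def test_matches_fisher_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            N = int(rng.integers(5, 30))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            table = [[k, K - k], [n - k, N - K - (n - k)]]
            if min(min(row) for row in table) < 0:
                continue
            _, p_fisher = stats.fisher_exact(table, alternative="greater")
            assert hypergeometric_p(k, K, n, N) == pytest.approx(p_fisher, abs=1e-10)

    def test_matches_enumeration_oracle_spot_grid(self):
        for N in (10, 17, 25):
            for K in range(0, N + 1, 4):
                for n in range(0, N + 1, 5):
                    for k in range(0, min(K, n) + 1):
                        assert hypergeometric_p(k, K, n, N) == pytest.approx(
                            tail_oracle(k, K, n, N), abs=1e-10
                        )

    def test_non_increasing_in_k(self):
        ps = [hypergeometric_p(k, 20, 15, 100) for k in range(0, 16)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValidationError):
            hypergeometric_p(3, 2, 5, 10)
        with pytest.raises(ValidationError):
            hypergeometric_p(0, 11, 5, 10)

    def test_large_universe_stable(self):
        p = hypergeometric_p(50, 200, 300, 100_000)
        assert 0.0 < p < 1e-30  # far tail, still a clean positive float


class TestEase:
    def test_k1_reduces_to_one(self):
        assert ease_p(1, 10, 10, 100) == 1.0

    def test_k0_is_one(self):
        assert ease_p(0, 10, 10, 100) == 1.0

    def test_decrement_definition(self):
        assert ease_p(6, 10, 10, 100) == hypergeometric_p(5, 10, 10, 100)

    def test_conservative_vs_fisher(self):
        for k in range(1, 10):
            assert ease_p(k, 10, 10, 100) >= hypergeometric_p(k, 10, 10, 100)


def _vts(genes, eligible=True, mirna="m1"):
    return VerifiedTargetSet(
        mirna=mirna, direction="up", comparison="P09-P04",
        verified=frozenset(genes), eligible=eligible,
    )


class TestEnrichMirna:
    def _universe(self, n=400):
        return frozenset(f"G{i:04d}" for i in range(n))

    def test_planted_set_ranks_first(self):
        rng = np.random.default_rng(1)
        universe = sorted(self._universe())
        planted_members = universe[:50]
        query = planted_members[:45]
        sets = [GeneSet("S:planted", "planted", "GO_BP", frozenset(planted_members))]
        for i in range(50):
            members = rng.choice(universe, size=40, replace=False)
            sets.append(GeneSet(f"S:bg{i}", f"bg {i}", "GO_BP", frozenset(members)))
        records = enrich_mirna(_vts(query), GeneSetCollection(tuple(sets)), self._universe())
        assert records[0].set_id == "S:planted"
        assert records[0].significant

    def test_disjoint_query_all_p_one(self):
        sets = GeneSetCollection(
            (GeneSet("S:1", "s", "GO_BP", frozenset({"G0001", "G0002"})),)
        )
        records = enrich_mirna(_vts(["G0100", "G0101"]), sets, self._universe())
        assert all(r.pvalue == 1.0 for r in records)
        assert not any(r.significant for r in records)

    def test_ineligible_set_rejected(self):
        sets = GeneSetCollection((GeneSet("S:1", "s", "GO_BP", frozenset({"G0001"})),))
        with pytest.raises(ValidationError, match="filter_min_targets"):
            enrich_mirna(_vts(["G0001"], eligible=False), sets, self._universe())

    def test_null_pvalues_stochastically_above_uniform(self):
        # random queries from the universe: P(p <= x) must not exceed x by
        # more than sampling noise (one-sided, conservative by discreteness)
        rng = np.random.default_rng(9)
        universe = sorted(self._universe(200))
        gs = GeneSetCollection(
            (GeneSet("S:0", "s", "GO_BP", frozenset(universe[:30])),)
        )
        pvals = []
        for _ in range(300):
            q = rng.choice(universe, size=40, replace=False)
            recs = enrich_mirna(_vts(q), gs, frozenset(universe))
            pvals.append(recs[0].pvalue)
        pvals = np.sort(pvals)
        ecdf = np.arange(1, len(pvals) + 1) / len(pvals)
        assert np.all(ecdf - pvals <= 0.08)

    def test_query_outside_universe_dropped(self):
        sets = GeneSetCollection((GeneSet("S:1", "s", "GO_BP", frozenset({"G0001"})),))
        records = enrich_mirna(
            _vts(["G0001", "NOT_IN_UNIVERSE"]), sets, self._universe()
        )
        assert records[0].n == 1
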