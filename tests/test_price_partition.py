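import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import isonich as iso
from isonich.price_partition import (
    link_contributions_env,
    price_partition,
    relative_contributions,
    timeseries_partition,
)


def snap(date, entries, period="mixing"):
    return iso.CommunitySnapshot(dt.date.fromordinal(date), period, tuple(entries))


def random_pair(rng, max_taxa=10):
    """Two snapshots over a random taxon pool with random sharing."""
    pool = [f"t{i}" for i in range(rng.integers(1, max_taxa + 1))]
    taxa1 = [t for t in pool if rng.random() < 0.7] or [pool[0]]
    taxa2 = [t for t in pool if rng.random() < 0.7] or [pool[-1]]
    q1 = rng.dirichlet(np.ones(len(taxa1)))
    q2 = rng.dirichlet(np.ones(len(taxa2)))
    z1 = rng.normal(0, 3, len(taxa1))
    z2 = rng.normal(0, 3, len(taxa2))
    c1 = snap(1, [(t, float(q), float(z)) for t, q, z in zip(taxa1, q1, z1)])
    c2 = snap(2, [(t, float(q), float(z)) for t, q, z in zip(taxa2, q2, z2)])
    return c1, c2


class TestPricePartition:
    def test_identical_snapshots_give_zero(self):
        c = snap(1, [("a", 0.5, 1.0), ("b", 0.5, 3.0)])
        p = price_partition(c, c)
        assert (p.delta_total, p.TS, p.ITV, p.TT) == (0, 0, 0, 0)
        assert p.degenerate

    def test_shared_only_hand_arithmetic(self):
        # delta = (0.25*2 + 0.75*4) - (0.5*1 + 0.5*3) = 3.5 - 2 = 1.5
        # TS = 1*(0.25-0.5) + 3*(0.75-0.5) = 0.5
        # ITV = 0.25*(2-1) + 0.75*(4-3) = 1.0
        c1 = snap(1, [("a", 0.5, 1.0), ("b", 0.5, 3.0)])
        c2 = snap(2, [("a", 0.25, 2.0), ("b", 0.75, 4.0)])
        p = price_partition(c1, c2)
        assert p.delta_total == pytest.approx(1.5)
        assert p.TS == pytest.approx(0.5)
        assert p.ITV == pytest.approx(1.0)
        assert p.TT == 0.0

    def test_disjoint_taxa_all_turnover(self):
        c1 = snap(1, [("a", 1.0, 2.0)])
        c2 = snap(2, [("b", 1.0, 5.0)])
        p = price_partition(c1, c2)
        assert p.TS == 0 and p.ITV == 0
        assert p.TT == pytest.approx(p.delta_total) == pytest.approx(3.0)

    def test_conservation_on_random_pairs(self, rng):
        for _ in range(1000):
            c1, c2 = random_pair(rng)
            for mode in ("telescoping", "three_term"):
                p = price_partition(c1, c2, mode=mode)
                total = p.TS + p.ITV + p.TT + (p.COV or 0.0)
                scale = max(abs(p.delta_total), 1.0)
                assert abs(total - p.delta_total) / scale < 1e-12

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        q1=st.lists(st.floats(0.05, 1.0), min_size=2, max_size=6),
        q2=st.lists(st.floats(0.05, 1.0), min_size=2, max_size=6),
        z=st.lists(st.floats(-50, 50), min_size=12, max_size=12),
        c=st.floats(-5, 5),
    )
    def test_linearity_in_traits(self, q1, q2, z, c):
        """Scaling every trait by c scales every component by c."""
        k = min(len(q1), len(q2))
        q1 = np.array(q1[:k]) / sum(q1[:k])
        q2 = np.array(q2[:k]) / sum(q2[:k])
        z1, z2 = z[:k], z[6 : 6 + k]
        c1 = snap(1, [(f"t{i}", q1[i], z1[i]) for i in range(k)])
        c2 = snap(2, [(f"t{i}", q2[i], z2[i]) for i in range(k)])
        c1s = snap(1, [(f"t{i}", q1[i], c * z1[i]) for i in range(k)])
        c2s = snap(2, [(f"t{i}", q2[i], c * z2[i]) for i in range(k)])
        p, ps = price_partition(c1, c2), price_partition(c1s, c2s)
        assert ps.TS == pytest.approx(c * p.TS, abs=1e-8)
        assert ps.ITV == pytest.approx(c * p.ITV, abs=1e-8)
        assert ps.delta_total == pytest.approx(c * p.delta_total, abs=1e-8)

    def test_swap_negates_delta(self, rng):
        c1, c2 = random_pair(rng)
        assert price_partition(c1, c2).delta_total == pytest.approx(
            -price_partition(c2, c1).delta_total
        )

    def test_rarity_threshold_routes_rare_taxa_to_turnover(self):
        c1 = snap(1, [("a", 0.98, 1.0), ("rare", 0.02, 10.0)])
        c2 = snap(2, [("a", 0.98, 1.0), ("rare", 0.02, 10.0)])
        default = price_partition(c1, c2)
        routed = price_partition(
            snap(1, [("a", 0.98, 1.0), ("rare", 0.02, 10.0)]),
            snap(2, [("a", 0.98, 1.0), ("other", 0.02, 10.0)]),
            rarity_threshold=0.03,
        )
        assert default.TT == 0.0
        assert routed.TT == 0.0  # both rare taxa dropped from both sides
        assert routed.delta_total == pytest.approx(0.0)

    def test_missing_trait_names_taxon(self):
        c1 = snap(1, [("a", 1.0, float("nan"))])
        c2 = snap(2, [("a", 1.0, 2.0)])
        with pytest.raises(iso.ValidationError, match="a"):
            price_partition(c1, c2)


class TestRelativeContributions:
    def test_hand_arithmetic(self):
        p = iso.PricePartition(1.5, TS=0.5, ITV=1.0, TT=0.0)
        r = relative_contributions(p)
        assert r.rel_TS == pytest.approx(100 / 3)
        assert r.rel_ITV == pytest.approx(200 / 3)
        assert r.rel_TT == 0.0

    def test_single_component_gets_all(self):
        r = relative_contributions(iso.PricePartition(2.0, TS=0.0, ITV=0.0, TT=2.0))
        assert r.rel_TT == 100.0

    def test_signs_ignored(self):
        r = relative_contributions(iso.PricePartition(0.0, TS=-1.0, ITV=1.0, TT=0.0))
        assert r.rel_TS == 50.0 and r.rel_ITV == 50.0

    def test_all_zero_flags_degenerate(self):
        r = relative_contributions(iso.PricePartition(0.0, TS=0.0, ITV=0.0, TT=0.0))
        assert r.degenerate and r.rel_TS is None

    def test_shares_sum_to_100(self, rng):
        for _ in range(50):
            c1, c2 = random_pair(rng)
            p = price_partition(c1, c2)
            if not p.degenerate:
                assert p.rel_TS + p.rel_ITV + p.rel_TT == pytest.approx(100.0, abs=1e-9)


class TestTimeseries:
    def test_partition_count(self, default_bundle):
        parts = timeseries_partition(default_bundle.snapshots)
        assert len(parts) == 20

    def test_constant_community_all_zero(self):
        snaps = [snap(i, [("a", 0.4, 1.0), ("b", 0.6, 2.0)]) for i in (1, 2, 3)]
        parts = timeseries_partition(snaps)
        assert all(p.delta_total == 0 for p in parts)

    def test_non_monotone_dates_rejected(self):
        s1 = snap(5, [("a", 1.0, 1.0)])
        s2 = snap(3, [("a", 1.0, 1.0)])
        with pytest.raises(iso.ValidationError, match="increasing"):
            timeseries_partition([s1, s2])

    def test_each_pair_conserves(self, default_bundle):
        for p in timeseries_partition(default_bundle.snapshots):
            assert p.TS + p.ITV + p.TT == pytest.approx(p.delta_total, abs=1e-12)


class TestEnvLinkage:
    def _series(self, values, traits):
        env = [
            iso.EnvRecord(dt.date.fromordinal(i + 1), {"temperature": float(v)})
            for i, v in enumerate(values)
        ]
        snaps = [
            snap(i + 1, [("a", 0.6, float(t)), ("b", 0.4, 1.0)])
            for i, t in enumerate(traits)
        ]
        return timeseries_partition(snaps), env

    def test_perfect_monotone_correlation(self, rng):
        # construct shares that decrease monotonically with the temp change
        n = 9
        dtemp = np.arange(1.0, n + 1)  # increasing positive deltas
        temps = np.concatenate([[0.0], np.cumsum(dtemp)])
        parts = []
        for i, d in enumerate(dtemp):
            itv = 10.0 - i  # monotone decreasing ITV magnitude
            parts.append(
                relative_contributions(
                    iso.PricePartition(d, TS=1.0, ITV=itv, TT=0.0)
                )
            )
        env = [
            iso.EnvRecord(dt.date.fromordinal(i + 1), {"temperature": float(t)})
            for i, t in enumerate(temps)
        ]
        table = link_contributions_env(parts, env)
        assert table[("rel_ITV", "temperature")]["rho"] == pytest.approx(-1.0)

    def test_matches_rank_oracle_with_ties(self, rng):
        from scipy.stats import rankdata

        n = 8
        shares = rng.integers(0, 4, n).astype(float) * 10
        denv = rng.integers(0, 3, n).astype(float)
        parts = [
            relative_contributions(
                iso.PricePartition(1.0, TS=s, ITV=100 - s, TT=0.0)
            )
            for s in shares
        ]
        env_vals = np.concatenate([[0.0], np.cumsum(denv)])
        env = [
            iso.EnvRecord(dt.date.fromordinal(i + 1), {"x": float(v)})
            for i, v in enumerate(env_vals)
        ]
        table = link_contributions_env(parts, env)
        got = table[("rel_TS", "x")]["rho"]
        rel_ts = np.array([p.rel_TS for p in parts])
        ra, rb = rankdata(rel_ts), rankdata(denv)
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert got == pytest.approx(oracle, abs=1e-12)

    def test_constant_share_vector_flagged(self):
        parts = [
            relative_contributions(iso.PricePartition(1.0, TS=1.0, ITV=1.0, TT=0.0))
            for _ in range(6)
        ]
        env = [
            iso.EnvRecord(dt.date.fromordinal(i + 1), {"x": float(i * i)})
            for i in range(7)
        ]
        table = link_contributions_env(parts, env)
        cell = table[("rel_TS", "x")]
        assert cell["insufficient"] and cell["rho"] is None

    def test_too_few_pairs_flagged(self):
        parts = [
            relative_contributions(iso.PricePartition(1.0, TS=float(i), ITV=1.0, TT=0.0))
            for i in range(3)
        ]
        env = [
            iso.EnvRecord(dt.date.fromordinal(i + 1), {"x": float(i)}) for i in range(4)
        ]
        table = link_contributions_env(parts, env)
        assert table[("rel_TS", "x")]["insufficient"]
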