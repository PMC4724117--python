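"""Pair labelling, partitioning, dN binning and robustness subsets."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from dupfates import (
    DEFAULT_DN_BINS,
    ParalogPair,
    assign_dn_bin,
    label_pairs,
    partition_gene_sets,
    select_closest_pairs,
    split_ssd_by_age,
)
from dupfates.assembly import mirror_pairs


class TestLabelPairs:
    def test_wgd_reference_overrides_identity(self):
        """A pair on the ohnolog list is WGD even below the identity threshold."""
        cand = [ParalogPair("a", "b", identity_pct=30.0)]
        res = label_pairs(cand, {("a", "b")}, min_identity_pct=50.0)
        assert res.pairs[0].origin == "WGD"
        assert res.counts["wgd"] == 1

    def test_identity_threshold_is_inclusive(self):
        cand = [ParalogPair("a", "b", identity_pct=49.9),
                ParalogPair("c", "d", identity_pct=50.0)]
        res = label_pairs(cand, set(), min_identity_pct=50.0)
        assert [p.origin for p in res.pairs] == ["SSD"]
        assert res.pairs[0].key == ("c", "d")
        assert res.counts["excluded_low_identity"] == 1

    def test_missing_identity_excluded_with_reason(self):
        res = label_pairs([ParalogPair("a", "b")], set())
        assert res.pairs == []
        assert res.counts["excluded_missing_identity"] == 1

    def test_reference_orientation_irrelevant(self):
        cand = [ParalogPair("b", "a", identity_pct=90.0)]
        res = label_pairs(cand, {("b", "a")})
        assert res.pairs[0].origin == "WGD"

    def test_idempotent_and_order_independent(self):
        cand = [ParalogPair("a", "b", identity_pct=70.0),
                ParalogPair("c", "d", identity_pct=30.0),
                ParalogPair("e", "f", identity_pct=55.0)]
        ref = {("e", "f")}
        res1 = label_pairs(cand, ref)
        res2 = label_pairs(list(reversed(cand)), ref)
        assert sorted((p.key, p.origin) for p in res1.pairs) == \
               sorted((p.key, p.origin) for p in res2.pairs)
        again = label_pairs(res1.pairs, ref)
        assert sorted((p.key, p.origin) for p in again.pairs) == \
               sorted((p.key, p.origin) for p in res1.pairs)


class TestPartition:
    def test_examples(self):
        pairs = [ParalogPair("g", "x", origin="SSD", dn=0.1),
                 ParalogPair("g", "y", origin="WGD", dn=0.2),
                 ParalogPair("s", "t", origin="SSD", dn=0.1)]
        part = partition_gene_sets(pairs)
        assert "g" in part.both
        assert {"s", "t", "x"} <= part.ssd_only
        assert part.wgd_only == {"y"}

    @given(st.lists(st.tuples(st.integers(0, 12), st.integers(0, 12),
                              st.sampled_from(["SSD", "WGD"])), max_size=40))
    def test_sets_disjoint_and_cover_all_pair_genes(self, raw):
        pairs = [ParalogPair(f"g{a}", f"g{b}", origin=o, dn=0.1)
                 for a, b, o in raw if a != b]
        part = partition_gene_sets(pairs)
        assert part.ssd_only.isdisjoint(part.wgd_only)
        assert part.ssd_only.isdisjoint(part.both)
        assert part.wgd_only.isdisjoint(part.both)
        all_genes = {g for p in pairs for g in p.key}
        assert part.ssd_only | part.wgd_only | part.both == all_genes


class TestDnBins:
    @pytest.mark.parametrize("dn,label", [
        (0.05, "0.0-0.1"),
        (0.1, "0.1-0.2"),   # half-open boundary: 0.1 belongs to the next bin
        (0.73, ">0.4"),
        (0.0, "0.0-0.1"),
        (0.4, ">0.4"),
    ])
    def test_bin_assignment(self, dn, label):
        assert assign_dn_bin(dn) == label

    def test_bins_partition_conservation(self):
        rng = random.Random(0)
        dns = [rng.uniform(0, 1.2) for _ in range(500)]
        counts = {b.label: 0 for b in DEFAULT_DN_BINS}
        for dn in dns:
            counts[assign_dn_bin(dn)] += 1
        assert sum(counts.values()) == len(dns)


def _brute_force_closest(pairs):
    """Oracle: a pair survives iff it is minimal for >= 1 member (with tie-breaks)."""
    def rank(p, g):
        partner = p.gene_b if g == p.gene_a else p.gene_a
        ident = p.identity_pct if p.identity_pct is not None else -1.0
        return (p.dn, -ident, partner)

    keep = set()
    genes = {g for p in pairs for g in p.key}
    for g in genes:
        for origin in ("SSD", "WGD"):
            mine = [p for p in pairs if g in p.key and p.origin == origin
                    and p.dn is not None]
            if mine:
                best = min(mine, key=lambda p: rank(p, g))
                keep.add(id(best))
    return [p for p in pairs if id(p) in keep]


class TestClosestPairs:
    def test_minimum_dn_retained(self):
        # (g,x) at dN 0.3 is not the closest pair of g, nor of x (x has a
        # closer pair with w), so it is the only pair dropped
        pairs = [ParalogPair("g", "x", origin="SSD", dn=0.3, identity_pct=60),
                 ParalogPair("g", "y", origin="SSD", dn=0.1, identity_pct=55),
                 ParalogPair("w", "x", origin="SSD", dn=0.05, identity_pct=70)]
        kept = select_closest_pairs(pairs)
        assert sorted(p.key for p in kept) == [("g", "y"), ("w", "x")]

    def test_single_pair_survives(self):
        pairs = [ParalogPair("a", "b", origin="WGD", dn=0.5)]
        assert select_closest_pairs(pairs) == pairs

    def test_tie_breaks_on_identity(self):
        # g's two pairs tie on dN; the higher-identity one wins for g, and
        # (g,x) is dropped because x's own closest pair is (w,x)
        pairs = [ParalogPair("g", "x", origin="SSD", dn=0.2, identity_pct=55),
                 ParalogPair("g", "y", origin="SSD", dn=0.2, identity_pct=60),
                 ParalogPair("w", "x", origin="SSD", dn=0.05, identity_pct=70)]
        kept = select_closest_pairs(pairs)
        assert sorted(p.key for p in kept) == [("g", "y"), ("w", "x")]

    def test_matches_brute_force_on_random_fixtures(self):
        rng = random.Random(42)
        for _ in range(25):
            genes = [f"g{i}" for i in range(rng.randint(3, 12))]
            pairs = []
            seen = set()
            for _ in range(rng.randint(1, 50)):
                a, b = rng.sample(genes, 2)
                key = tuple(sorted((a, b)))
                origin = rng.choice(["SSD", "WGD"])
                if (key, origin) in seen:
                    continue
                seen.add((key, origin))
                pairs.append(ParalogPair(a, b, origin=origin,
                                         dn=round(rng.uniform(0, 0.6), 2),
                                         identity_pct=rng.choice([50, 60, 70])))
            kept = select_closest_pairs(pairs)
            expected = _brute_force_closest(pairs)
            assert sorted((p.key, p.origin) for p in kept) == \
                   sorted((p.key, p.origin) for p in expected)
            assert len(kept) <= len(pairs)


class TestAgeSplit:
    def test_examples(self):
        pairs = [ParalogPair("a", "b", origin="SSD", dn=0.1),
                 ParalogPair("c", "d", origin="SSD", dn=0.1),
                 ParalogPair("e", "f", origin="SSD", dn=0.1)]
        ranks = {"a": 1, "b": 1, "c": 15, "d": 15, "e": 12}
        young, old, missing = split_ssd_by_age(pairs, ranks, young_threshold=10)
        assert [p.key for p in old] == [("a", "b")]
        assert [p.key for p in young] == [("c", "d")]
        assert missing == 1  # gene f has no rank

    def test_mixed_rank_pair_is_old(self):
        pairs = [ParalogPair("a", "b", origin="SSD", dn=0.1)]
        young, old, _ = split_ssd_by_age(pairs, {"a": 15, "b": 2}, 10)
        assert old == pairs and young == []


def test_mirror_pairs_doubles():
    pairs = [ParalogPair("a", "b", origin="SSD", dn=0.1)]
    assert len(mirror_pairs(pairs)) == 2
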