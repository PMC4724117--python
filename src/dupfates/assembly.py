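"""Pair labelling, filtering, gene partitioning and dN stratification.

Duplication origin is assigned from a compiled whole-genome-duplication
(ohnolog) reference list; every other candidate paralog pair passing the
sequence-identity threshold is a small-scale duplicate. Pairs are then
stratified into dN bins for the SSD-vs-WGD comparisons, and genes are
partitioned into SSD-only / WGD-only / both for gene-level analyses.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .model import SSD, WGD, GenePartition, ParalogPair


@dataclass(frozen=True)
class DnBin:
    """Half-open dN stratum [lower, upper); ``upper=None`` means unbounded."""

    label: str
    lower: float
    upper: float | None

    def contains(self, dn: float) -> bool:
        return dn >= self.lower and (self.upper is None or dn < self.upper)


#: The five default strata partitioning [0, inf).
DEFAULT_DN_BINS: tuple[DnBin, ...] = (
    DnBin("0.0-0.1", 0.0, 0.1),
    DnBin("0.1-0.2", 0.1, 0.2),
    DnBin("0.2-0.3", 0.2, 0.3),
    DnBin("0.3-0.4", 0.3, 0.4),
    DnBin(">0.4", 0.4, None),
)


@dataclass
class LabelResult:
    """Origin-labelled pairs plus disposition counts for the exclusion log."""

    pairs: list[ParalogPair]
    counts: Counter = field(default_factory=Counter)


def label_pairs(
    candidate_pairs: list[ParalogPair],
    wgd_reference_pairs: set[tuple[str, str]],
    min_identity_pct: float = 50.0,
) -> LabelResult:
    """Label candidate pairs by duplication origin.

    Pairs on the WGD reference list are WGD regardless of identity (the list
    is compiled independently of the identity rule); remaining pairs with
    ``identity_pct >= min_identity_pct`` (inclusive) are SSD; everything else
    is excluded with a counted reason.
    """
    reference = {tuple(sorted(k)) for k in wgd_reference_pairs}
    result = LabelResult(pairs=[])
    for pair in candidate_pairs:
        if pair.key in reference:
            result.pairs.append(ParalogPair(
                pair.gene_a, pair.gene_b, origin=WGD, dn=pair.dn, ds=pair.ds,
                identity_pct=pair.identity_pct,
            ))
            result.counts["wgd"] += 1
        elif pair.identity_pct is None:
            result.counts["excluded_missing_identity"] += 1
        elif pair.identity_pct >= min_identity_pct:
            result.pairs.append(ParalogPair(
                pair.gene_a, pair.gene_b, origin=SSD, dn=pair.dn, ds=pair.ds,
                identity_pct=pair.identity_pct,
            ))
            result.counts["ssd"] += 1
        else:
            result.counts["excluded_low_identity"] += 1
    return result


def partition_gene_sets(pairs: list[ParalogPair]) -> GenePartition:
    """Split genes by the origin classes of their labelled pairs."""
    origins: dict[str, set[str]] = defaultdict(set)
    for pair in pairs:
        if pair.origin is None:
            continue
        origins[pair.gene_a].add(pair.origin)
        origins[pair.gene_b].add(pair.origin)
    ssd_only, wgd_only, both = set(), set(), set()
    for gene, origin_set in origins.items():
        if origin_set == {SSD}:
            ssd_only.add(gene)
        elif origin_set == {WGD}:
            wgd_only.add(gene)
        else:
            both.add(gene)
    return GenePartition(frozenset(ssd_only), frozenset(wgd_only), frozenset(both))


def assign_dn_bin(dn: float, bins: tuple[DnBin, ...] = DEFAULT_DN_BINS) -> str:
    """Return the label of the unique half-open bin containing ``dn``."""
    for b in bins:
        if b.contains(dn):
            return b.label
    raise ValueError(f"dn={dn} falls outside every bin")


def select_closest_pairs(pairs: list[ParalogPair]) -> list[ParalogPair]:
    """Keep, per gene and per origin class, only its minimum-dN pair.

    A pair survives if it is the closest pair of at least one of its members.
    Ties on dN break toward higher identity, then lexicographically smaller
    partner id. Pairs without dN cannot be ranked and are dropped.
    """
    def sort_key(pair: ParalogPair, gene: str):
        partner = pair.gene_b if gene == pair.gene_a else pair.gene_a
        identity = pair.identity_pct if pair.identity_pct is not None else -1.0
        return (pair.dn, -identity, partner)

    best: dict[tuple[str, str | None], ParalogPair] = {}
    for pair in pairs:
        if pair.dn is None:
            continue
        for gene in pair.key:
            slot = (gene, pair.origin)
            cur = best.get(slot)
            if cur is None or sort_key(pair, gene) < sort_key(cur, gene):
                best[slot] = pair
    keep = {id(p) for p in best.values()}
    return [p for p in pairs if id(p) in keep]


def split_ssd_by_age(
    ssd_pairs: list[ParalogPair],
    gene_age_ranks: dict[str, int],
    young_threshold: int,
) -> tuple[list[ParalogPair], list[ParalogPair], int]:
    """Split SSD pairs into young and old by phylostratum rank.

    A pair is young when both members' rank exceeds ``young_threshold``
    (arose in a recent phylostratum; rank 1 = oldest), else old. Pairs with a
    missing rank are excluded; the third return value counts them.
    """
    young: list[ParalogPair] = []
    old: list[ParalogPair] = []
    n_excluded = 0
    for pair in ssd_pairs:
        ranks = [gene_age_ranks.get(g) for g in pair.key]
        if any(r is None for r in ranks):
            n_excluded += 1
        elif all(r > young_threshold for r in ranks):
            young.append(pair)
        else:
            old.append(pair)
    return young, old, n_excluded


def mirror_pairs(pairs: list[ParalogPair]) -> list[ParalogPair]:
    """Duplicate every pair, emulating counting each orientation separately."""
    return [p for pair in pairs for p in (pair, pair)]
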