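"""Gene-level analyses on the SSD-only and WGD-only sets.

Evolutionary rate uses per-gene dN and dN/dS against outgroup orthologs
(e.g. mouse, chimpanzee), with mutational saturation controlled by discarding
records with dS >= 3. Multifunctionality is proxied by the number of unique
GO biological-process terms and by Pfam domain counts. Importance is the
proportion of essential / disease-associated genes per group.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .errors import TabulationError
from .model import Dataset, GenePartition, GeneRecord, OrthologRate

#: dS at or above this value is treated as mutationally saturated.
DS_SATURATION = 3.0


@dataclass(frozen=True)
class GeneRateRow:
    """One gene's rate against one outgroup; dnds absent when dS is 0."""

    gene_id: str
    group: str  # SSD_only | WGD_only
    outgroup: str
    dn: float
    dnds: float | None


def ortholog_rate_table(
    ortholog_rates: list[OrthologRate],
    partition: GenePartition,
    ds_max: float = DS_SATURATION,
) -> tuple[list[GeneRateRow], Counter]:
    """Build the per-gene rate table for SSD-only vs WGD-only comparisons.

    Genes with paralogs from both duplication classes are excluded, as are
    saturated records (ds >= ds_max). A record with ds == 0 keeps its dN but
    contributes no dN/dS. Returns the rows plus exclusion counts
    (conservation: rows + exclusions == input records).
    """
    rows: list[GeneRateRow] = []
    excluded: Counter = Counter()
    for rec in ortholog_rates:
        group = partition.group_of(rec.gene_id)
        if group == "both":
            excluded["gene_in_both_classes"] += 1
            continue
        if group is None:
            excluded["gene_not_in_any_pair"] += 1
            continue
        if rec.ds >= ds_max:
            excluded["ds_saturated"] += 1
            continue
        dnds = rec.dn / rec.ds if rec.ds > 0 else None
        rows.append(GeneRateRow(
            gene_id=rec.gene_id, group=group, outgroup=rec.outgroup,
            dn=rec.dn, dnds=dnds,
        ))
    return rows, excluded


@dataclass(frozen=True)
class MultifunctionalityRow:
    gene_id: str
    group: str
    bp_term_count: int
    pfam_domain_count: int | None


def multifunctionality_counts(
    genes: dict[str, GeneRecord], partition: GenePartition
) -> list[MultifunctionalityRow]:
    """Unique GO-BP term count and Pfam domain count per single-class gene.

    Annotation sets already collapse duplicate rows, so the count is invariant
    to repeated annotations; a gene without BP annotation counts 0.
    """
    rows = []
    for gid in sorted(partition.ssd_only | partition.wgd_only):
        gene = genes[gid]
        rows.append(MultifunctionalityRow(
            gene_id=gid,
            group=partition.group_of(gid),
            bp_term_count=len(gene.go_bp),
            pfam_domain_count=gene.pfam_domain_count,
        ))
    return rows


@dataclass(frozen=True)
class GroupFlagCounts:
    group: str
    flagged_n: int
    total_n: int

    @property
    def proportion(self) -> float:
        return self.flagged_n / self.total_n


def importance_tabulation(
    genes: dict[str, GeneRecord],
    partition: GenePartition,
    flag: str,
) -> dict[str, GroupFlagCounts]:
    """2x2 tabulation of an importance flag ("essential" or "disease").

    Genes with an absent flag are ignored; proportions are flagged / total
    flag-bearing genes per group. A group with zero flag-bearing genes raises
    :class:`TabulationError` naming the group.
    """
    if flag not in ("essential", "disease"):
        raise ValueError(f"unknown flag {flag!r}")
    out: dict[str, GroupFlagCounts] = {}
    for group, members in (("SSD_only", partition.ssd_only),
                           ("WGD_only", partition.wgd_only)):
        flagged = total = 0
        for gid in members:
            value = getattr(genes[gid], flag)
            if value is None:
                continue
            total += 1
            flagged += int(value)
        if total == 0:
            raise TabulationError(f"group {group} has no genes with a {flag} flag")
        out[group] = GroupFlagCounts(group=group, flagged_n=flagged, total_n=total)
    return out


def dataset_age_ranks(dataset: Dataset) -> dict[str, int]:
    """Convenience: gene_id -> phylostratum rank for genes that have one."""
    return {
        gid: g.age_rank for gid, g in dataset.genes.items() if g.age_rank is not None
    }
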