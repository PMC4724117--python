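"""Core data model: genes, paralog pairs, ortholog rates and the Dataset container.

The container mirrors a Biomart-style extraction: a gene table with importance
flags, a pair table with per-pair divergence measures (dN, dS, percent
identity), GO annotation sets split by domain (biological process, molecular
function, cellular component), an expression matrix over named tissues, and
per-gene ortholog substitution rates against outgroup species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import IntegrityError, TableValueError

SSD = "SSD"
WGD = "WGD"
ORIGINS = (SSD, WGD)

GO_DOMAINS = ("BP", "MF", "CC")


@dataclass
class GeneRecord:
    """One gene with its annotation sets, expression profile and flags.

    ``expression`` is an array aligned with ``Dataset.tissue_names``; ``None``
    means the gene was absent from the expression table (absence of evidence,
    not zero expression). ``essential`` / ``disease`` are tri-state: True,
    False, or unknown (``None``). ``age_rank`` is a phylostratum rank with
    1 = oldest.
    """

    gene_id: str
    go_bp: frozenset[str] = frozenset()
    go_mf: frozenset[str] = frozenset()
    go_cc: frozenset[str] = frozenset()
    expression: np.ndarray | None = None
    essential: bool | None = None
    disease: bool | None = None
    pfam_domain_count: int | None = None
    age_rank: int | None = None

    def __post_init__(self) -> None:
        if self.expression is not None:
            arr = np.asarray(self.expression, dtype=float)
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise TableValueError(
                    f"gene {self.gene_id}: expression values must be finite and >= 0"
                )
            self.expression = arr
        if self.pfam_domain_count is not None and self.pfam_domain_count < 0:
            raise TableValueError(f"gene {self.gene_id}: pfam_domain_count < 0")

    def go_terms(self, domain: str) -> frozenset[str]:
        return {"BP": self.go_bp, "MF": self.go_mf, "CC": self.go_cc}[domain]

    def equals(self, other: "GeneRecord") -> bool:
        if (
            self.gene_id != other.gene_id
            or self.go_bp != other.go_bp
            or self.go_mf != other.go_mf
            or self.go_cc != other.go_cc
            or self.essential != other.essential
            or self.disease != other.disease
            or self.pfam_domain_count != other.pfam_domain_count
            or self.age_rank != other.age_rank
        ):
            return False
        if (self.expression is None) != (other.expression is None):
            return False
        if self.expression is not None:
            return np.array_equal(self.expression, other.expression)
        return True


@dataclass
class ParalogPair:
    """An unordered duplicate pair with origin label and divergence measures.

    Gene ids are canonicalised to lexicographic order so (a, b) == (b, a).
    """

    gene_a: str
    gene_b: str
    origin: str | None = None
    dn: float | None = None
    ds: float | None = None
    identity_pct: float | None = None

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise IntegrityError(f"self-pair: {self.gene_a}")
        if self.gene_b < self.gene_a:
            self.gene_a, self.gene_b = self.gene_b, self.gene_a
        if self.origin is not None and self.origin not in ORIGINS:
            raise TableValueError(f"unknown origin {self.origin!r}")
        if self.dn is not None and self.dn < 0:
            raise TableValueError(f"pair {self.key}: dn < 0")
        if self.ds is not None and self.ds < 0:
            raise TableValueError(f"pair {self.key}: ds < 0")
        if self.identity_pct is not None and not (0 <= self.identity_pct <= 100):
            raise TableValueError(f"pair {self.key}: identity_pct outside [0, 100]")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass
class OrthologRate:
    """Per-gene dN and dS against one outgroup species (e.g. mouse, chimp)."""

    gene_id: str
    outgroup: str
    dn: float
    ds: float

    def __post_init__(self) -> None:
        if self.dn < 0 or self.ds < 0:
            raise TableValueError(f"ortholog {self.gene_id}/{self.outgroup}: negative rate")


@dataclass
class Dataset:
    """Validated in-memory form of the five input tables."""

    genes: dict[str, GeneRecord] = field(default_factory=dict)
    pairs: list[ParalogPair] = field(default_factory=list)
    ortholog_rates: list[OrthologRate] = field(default_factory=list)
    tissue_names: list[str] = field(default_factory=list)

    def validate(self) -> "Dataset":
        if len(set(self.tissue_names)) != len(self.tissue_names):
            raise IntegrityError("duplicate tissue names")
        n_tissues = len(self.tissue_names)
        for gene in self.genes.values():
            if gene.expression is not None and len(gene.expression) != n_tissues:
                raise IntegrityError(
                    f"gene {gene.gene_id}: expression length {len(gene.expression)}"
                    f" != {n_tissues} tissues"
                )
        for pair in self.pairs:
            for gid in pair.key:
                if gid not in self.genes:
                    raise IntegrityError(f"pair references unknown gene {gid!r}")
        for rec in self.ortholog_rates:
            if rec.gene_id not in self.genes:
                raise IntegrityError(f"ortholog table references unknown gene {rec.gene_id!r}")
        return self

    def equals(self, other: "Dataset") -> bool:
        """Structural equality (used for round-trip checks)."""
        if self.tissue_names != other.tissue_names:
            return False
        if set(self.genes) != set(other.genes):
            return False
        if any(not g.equals(other.genes[gid]) for gid, g in self.genes.items()):
            return False

        def pair_key(p: ParalogPair):
            return (p.gene_a, p.gene_b, p.origin or "")

        sp, op = sorted(self.pairs, key=pair_key), sorted(other.pairs, key=pair_key)
        if len(sp) != len(op):
            return False
        for a, b in zip(sp, op):
            if (a.key, a.origin, a.dn, a.ds, a.identity_pct) != (
                b.key, b.origin, b.dn, b.ds, b.identity_pct,
            ):
                return False

        def orth_key(r: OrthologRate):
            return (r.gene_id, r.outgroup)

        so, oo = sorted(self.ortholog_rates, key=orth_key), sorted(other.ortholog_rates, key=orth_key)
        return all(
            (a.gene_id, a.outgroup, a.dn, a.ds) == (b.gene_id, b.outgroup, b.dn, b.ds)
            for a, b in zip(so, oo)
        ) and len(so) == len(oo)


@dataclass(frozen=True)
class GenePartition:
    """Genes split by the origin classes of their pairs.

    ``both`` holds genes with at least one SSD and one WGD pair; those are
    excluded from all gene-level analyses downstream.
    """

    ssd_only: frozenset[str]
    wgd_only: frozenset[str]
    both: frozenset[str]

    def group_of(self, gene_id: str) -> str | None:
        if gene_id in self.ssd_only:
            return "SSD_only"
        if gene_id in self.wgd_only:
            return "WGD_only"
        if gene_id in self.both:
            return "both"
        return None


@dataclass(frozen=True)
class PairScore:
    """One pairwise divergence score.

    ``n_basis`` is the number of annotation terms (|A| + |B|) for similarity
    metrics, or the number of tissues for the expression correlation.
    """

    gene_a: str
    gene_b: str
    origin: str | None
    dn: float | None
    metric: str
    value: float
    n_basis: int
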