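"""Synthetic dataset generator with origin-dependent divergence structure.

Emulates the statistical structure of a Biomart-style extraction of human
paralogs: small-scale duplicate (SSD) pairs share more GO annotation and are
more strongly co-expressed than whole-genome duplicate (WGD/ohnolog) pairs,
WGD pairs sit at higher dN (the 2R events are ancient), WGD genes evolve more
slowly against outgroup orthologs, and carry higher essentiality and
disease-association rates. Effect-size defaults follow the group means and
proportions reported for the human SSD/WGD comparison; dispersions are free
parameters (see docs/methods.md).

Annotation sharing is generated by a hypergeometric-style construction: term
set sizes are drawn per gene, the pair is resampled until the target shared
count is feasible, and the shared count is binomial with mean chosen so the
expected Dice similarity equals the per-origin target exactly. Expression
profiles are correlated bivariate normals per tissue, shifted well above zero
and clamped, with a small-sample bias correction on the latent correlation so
the mean recovered Pearson r matches the target.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .model import SSD, WGD, Dataset, GeneRecord, OrthologRate, ParalogPair

#: The 27 normal-tissue labels of the default expression panel.
DEFAULT_TISSUES = (
    "adipose tissue", "adrenal gland", "appendix", "bone marrow",
    "cerebral cortex", "colon", "duodenum", "oesophagus", "gallbladder",
    "heart muscle", "kidney", "liver", "lung", "lymph node", "ovary",
    "pancreas", "placenta", "prostate", "salivary gland", "skin",
    "small intestine", "spleen", "stomach", "testis", "thyroid gland",
    "urinary bladder", "uterus",
)

_RESAMPLE_ROUNDS = 500


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults reproduce the study's group structure.

    ``dice_target`` and ``terms_per_gene`` are keyed origin -> GO domain;
    rate-like fields are keyed by origin. ``dn_distribution`` maps origin to
    (gamma shape, mean) for per-pair dN; ``ds_over_dn`` is (offset, shape,
    mean excess) of the shifted-gamma multiplier giving dS from dN (support
    >= offset, so dS >= dN whenever offset >= 1). ``ortholog_dn`` /
    ``ortholog_dnds`` give per-origin, per-outgroup means for gene-level
    rates. ``frac_both`` is the fraction of SSD genes additionally drawn into
    a WGD pair (genes of mixed duplication history).
    """

    n_pairs_ssd: int = 5000
    n_pairs_wgd: int = 5000
    dice_target: dict = field(default_factory=lambda: {
        SSD: {"BP": 0.710, "MF": 0.840, "CC": 0.782},
        WGD: {"BP": 0.415, "MF": 0.659, "CC": 0.541},
    })
    terms_per_gene: dict = field(default_factory=lambda: {
        SSD: {"BP": 5.0, "MF": 4.0, "CC": 6.0},
        WGD: {"BP": 10.0, "MF": 4.0, "CC": 6.0},
    })
    expr_r_target: dict = field(default_factory=lambda: {SSD: 0.403, WGD: 0.193})
    n_tissues: int = 27
    dn_distribution: dict = field(default_factory=lambda: {
        SSD: (1.2, 0.18), WGD: (2.0, 0.35),
    })
    ds_over_dn: tuple = (1.0, 2.0, 2.0)
    essential_rate: dict = field(default_factory=lambda: {SSD: 0.04601, WGD: 0.11344})
    disease_rate: dict = field(default_factory=lambda: {SSD: 0.2789, WGD: 0.6146})
    ortholog_dn: dict = field(default_factory=lambda: {
        SSD: {"mouse": 0.089, "chimp": 0.012},
        WGD: {"mouse": 0.062, "chimp": 0.006},
    })
    ortholog_dnds: dict = field(default_factory=lambda: {
        SSD: {"mouse": 0.135, "chimp": 0.480},
        WGD: {"mouse": 0.101, "chimp": 0.257},
    })
    ortholog_availability: dict = field(default_factory=lambda: {
        "mouse": 0.90, "chimp": 0.85,
    })
    pfam_mean: dict = field(default_factory=lambda: {SSD: 1.61, WGD: 2.02})
    identity_range: dict = field(default_factory=lambda: {
        SSD: (50.0, 99.0), WGD: (25.0, 90.0),
    })
    annotation_missing_rate: float = 0.02
    expression_missing_rate: float = 0.03
    age_geometric_p: float = 0.35
    age_max_rank: int = 20
    frac_both: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs_ssd < 1 or self.n_pairs_wgd < 1:
            raise ConfigurationError("pair counts must be >= 1")
        if self.n_tissues < 1:
            raise ConfigurationError("n_tissues must be >= 1")
        for origin in (SSD, WGD):
            for domain, t in self.dice_target[origin].items():
                _check_prob(f"dice_target[{origin}][{domain}]", t)
            for domain, m in self.terms_per_gene[origin].items():
                if m < 1:
                    raise ConfigurationError(
                        f"terms_per_gene[{origin}][{domain}] must be >= 1")
            r = self.expr_r_target[origin]
            if not (-1.0 < r < 1.0):
                raise ConfigurationError(f"expr_r_target[{origin}] outside (-1, 1)")
            _check_prob(f"essential_rate[{origin}]", self.essential_rate[origin])
            _check_prob(f"disease_rate[{origin}]", self.disease_rate[origin])
        _check_prob("annotation_missing_rate", self.annotation_missing_rate)
        _check_prob("expression_missing_rate", self.expression_missing_rate)
        _check_prob("frac_both", self.frac_both)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ds_over_dn"] = list(self.ds_over_dn)
        for origin in (SSD, WGD):
            d["dn_distribution"][origin] = list(self.dn_distribution[origin])
            d["identity_range"][origin] = list(self.identity_range[origin])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticConfig":
        data = dict(data)
        if "ds_over_dn" in data:
            data["ds_over_dn"] = tuple(data["ds_over_dn"])
        for key in ("dn_distribution", "identity_range"):
            if key in data:
                data[key] = {o: tuple(v) for o, v in data[key].items()}
        return cls(**data)


def paper_like_config(**overrides) -> SyntheticConfig:
    """The shipped default configuration (study-like effect sizes)."""
    return SyntheticConfig(**overrides)


def null_config(n_pairs: int = 800, seed: int = 0, **overrides) -> SyntheticConfig:
    """A no-effect configuration: WGD parameters copied from SSD.

    dN distributions are also equalised so the two groups are exchangeable
    within every bin; used for type-I-error calibration.
    """
    cfg = SyntheticConfig(n_pairs_ssd=n_pairs, n_pairs_wgd=n_pairs, seed=seed,
                          **overrides)
    for attr in ("dice_target", "terms_per_gene", "expr_r_target",
                 "dn_distribution", "essential_rate", "disease_rate",
                 "ortholog_dn", "ortholog_dnds", "pfam_mean", "identity_range"):
        mapping = getattr(cfg, attr)
        mapping[WGD] = mapping[SSD]
    return cfg


def _feasible_sizes(rng, mean_a: float, mean_b: float, target: float, n: int):
    """Draw term-set size pairs (na, nb) with target*(na+nb)/2 <= min(na, nb).

    Sizes are 1 + Poisson(mean - 1); infeasible pairs (too asymmetric for the
    requested Dice target) are jointly redrawn. Conditional on the accepted
    sizes the expected Dice of the binomial shared count equals the target
    exactly, so group means are unbiased.
    """
    na = 1 + rng.poisson(mean_a - 1.0, n)
    nb = 1 + rng.poisson(mean_b - 1.0, n)
    for _ in range(_RESAMPLE_ROUNDS):
        bad = target * (na + nb) / 2.0 > np.minimum(na, nb) + 1e-9
        if not bad.any():
            return na, nb
        k = int(bad.sum())
        na[bad] = 1 + rng.poisson(mean_a - 1.0, k)
        nb[bad] = 1 + rng.poisson(mean_b - 1.0, k)
    raise ConfigurationError(
        f"cannot draw term-set sizes feasible for dice_target={target} "
        f"with means ({mean_a}, {mean_b})"
    )


def _shared_counts(rng, na, nb, target: float):
    smax = np.minimum(na, nb)
    p = np.clip(target * (na + nb) / (2.0 * smax), 0.0, 1.0)
    return rng.binomial(smax, p)


def _latent_rho(target: float, n_tissues: int) -> float:
    # Correct the small-sample bias E[r] ~= rho(1 - (1 - rho^2)/(2(N-1))).
    rho = target * (1.0 + (1.0 - target * target) / (2.0 * (n_tissues - 1)))
    return float(np.clip(rho, -0.999, 0.999))


_EXPR_MU = 5.0
_EXPR_SD = 1.0


def _correlated_profiles(rng, rho: float, n_pairs: int, n_tissues: int):
    z1 = rng.standard_normal((n_pairs, n_tissues))
    z2 = rng.standard_normal((n_pairs, n_tissues))
    x = _EXPR_MU + _EXPR_SD * z1
    y = _EXPR_MU + _EXPR_SD * (rho * z1 + np.sqrt(1.0 - rho * rho) * z2)
    return np.clip(x, 0.0, None), np.clip(y, 0.0, None)


def _partner_profile(rng, x: np.ndarray, rho: float) -> np.ndarray:
    eps = rng.standard_normal(x.shape)
    y = _EXPR_MU + rho * (x - _EXPR_MU) + _EXPR_SD * np.sqrt(1.0 - rho * rho) * eps
    return np.clip(y, 0.0, None)


def _term_ids(domain: str, tag: str, kind: str, count: int) -> frozenset[str]:
    return frozenset(f"GO:{domain}:{tag}:{kind}{k}" for k in range(count))


def generate_dataset(config: SyntheticConfig) -> Dataset:
    """Generate a :class:`Dataset`; a pure function of the config (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    tissues = list(DEFAULT_TISSUES[: config.n_tissues])
    tissues += [f"tissue_{i + 1}" for i in range(len(tissues), config.n_tissues)]

    dataset = Dataset(tissue_names=tissues)
    off, sh, mexc = config.ds_over_dn

    def new_gene(gid: str, origin: str, expression: np.ndarray | None) -> GeneRecord:
        age = 1 + min(int(rng.geometric(config.age_geometric_p)) - 1,
                      config.age_max_rank - 1)
        gene = GeneRecord(
            gene_id=gid,
            expression=expression,
            essential=bool(rng.random() < config.essential_rate[origin]),
            disease=bool(rng.random() < config.disease_rate[origin]),
            pfam_domain_count=1 + int(rng.poisson(config.pfam_mean[origin] - 1.0)),
            age_rank=age,
        )
        dataset.genes[gid] = gene
        return gene

    def add_orthologs(gid: str, origin: str) -> None:
        for outgroup, avail in sorted(config.ortholog_availability.items()):
            if rng.random() >= avail:
                continue
            mean_dn = config.ortholog_dn[origin][outgroup]
            mean_w = config.ortholog_dnds[origin][outgroup]
            dn = float(rng.gamma(2.0, mean_dn / 2.0))
            omega = float(rng.gamma(2.0, mean_w / 2.0))
            ds = dn / omega if omega > 0 else 0.0
            dataset.ortholog_rates.append(
                OrthologRate(gene_id=gid, outgroup=outgroup, dn=dn, ds=ds))

    def domain_sets(origin: str, tag: str):
        """Per-domain (terms_a, terms_b) with the origin's Dice structure."""
        out = {}
        for domain in ("BP", "MF", "CC"):
            t = config.dice_target[origin][domain]
            mean = config.terms_per_gene[origin][domain]
            na, nb = _feasible_sizes(rng, mean, mean, t, 1)
            s = int(_shared_counts(rng, na, nb, t)[0])
            shared = _term_ids(domain, tag, "S", s)
            a_only = _term_ids(domain, tag, "A", int(na[0]) - s)
            b_only = _term_ids(domain, tag, "B", int(nb[0]) - s)
            out[domain] = (shared | a_only, shared | b_only)
        return out

    for origin, n_pairs in ((SSD, config.n_pairs_ssd), (WGD, config.n_pairs_wgd)):
        dn = rng.gamma(*_gamma_params(config.dn_distribution[origin]), n_pairs)
        ds = dn * (off + rng.gamma(sh, mexc / sh, n_pairs))
        lo, hi = config.identity_range[origin]
        identity = rng.uniform(lo, hi, n_pairs)
        rho = _latent_rho(config.expr_r_target[origin], config.n_tissues)
        expr_a, expr_b = _correlated_profiles(rng, rho, n_pairs, config.n_tissues)
        miss_a = rng.random(n_pairs) < config.expression_missing_rate
        miss_b = rng.random(n_pairs) < config.expression_missing_rate
        for i in range(n_pairs):
            tag = f"{origin}{i:05d}"
            ga = new_gene(f"{tag}_A", origin, None if miss_a[i] else expr_a[i])
            gb = new_gene(f"{tag}_B", origin, None if miss_b[i] else expr_b[i])
            sets = domain_sets(origin, tag)
            for gene, side in ((ga, 0), (gb, 1)):
                gene.go_bp = sets["BP"][side]
                gene.go_mf = sets["MF"][side]
                gene.go_cc = sets["CC"][side]
            for gene in (ga, gb):
                for attr in ("go_bp", "go_mf", "go_cc"):
                    if rng.random() < config.annotation_missing_rate:
                        setattr(gene, attr, frozenset())
                add_orthologs(gene.gene_id, origin)
            dataset.pairs.append(ParalogPair(
                ga.gene_id, gb.gene_id, origin=origin, dn=float(dn[i]),
                ds=float(ds[i]), identity_pct=float(identity[i]),
            ))

    _add_mixed_origin_pairs(dataset, config, rng)
    return dataset.validate()


def _gamma_params(shape_mean: tuple[float, float]) -> tuple[float, float]:
    shape, mean = shape_mean
    return shape, mean / shape


def _add_mixed_origin_pairs(dataset: Dataset, config: SyntheticConfig, rng) -> None:
    """Give a fraction of SSD genes an additional WGD pair (mixed history)."""
    n_bridge = int(round(config.frac_both * config.n_pairs_ssd))
    if n_bridge == 0:
        return
    off, sh, mexc = config.ds_over_dn
    shape, scale = _gamma_params(config.dn_distribution[WGD])
    lo, hi = config.identity_range[WGD]
    rho = _latent_rho(config.expr_r_target[WGD], config.n_tissues)

    for i in range(n_bridge):
        anchor = dataset.genes[f"SSD{i:05d}_A"]
        tag = f"MIX{i:05d}"
        pid = f"{tag}_P"
        if anchor.expression is not None:
            expr = _partner_profile(rng, anchor.expression, rho)
        elif rng.random() < config.expression_missing_rate:
            expr = None
        else:
            expr = np.clip(
                _EXPR_MU + _EXPR_SD * rng.standard_normal(config.n_tissues), 0.0, None)
        partner = GeneRecord(gene_id=pid, expression=expr,
                             essential=bool(rng.random() < config.essential_rate[WGD]),
                             disease=bool(rng.random() < config.disease_rate[WGD]),
                             pfam_domain_count=1 + int(rng.poisson(config.pfam_mean[WGD] - 1.0)),
                             age_rank=1 + min(int(rng.geometric(config.age_geometric_p)) - 1,
                                              config.age_max_rank - 1))
        dataset.genes[pid] = partner
        for domain, attr in (("BP", "go_bp"), ("MF", "go_mf"), ("CC", "go_cc")):
            anchor_terms = sorted(getattr(anchor, attr))
            t = config.dice_target[WGD][domain]
            mean = config.terms_per_gene[WGD][domain]
            if not anchor_terms:
                setattr(partner, attr,
                        _term_ids(domain, tag, "P", 1 + int(rng.poisson(mean - 1.0))))
                continue
            na = len(anchor_terms)
            nb = na  # fallback; prefer a fresh feasible draw for the partner
            for _ in range(_RESAMPLE_ROUNDS):
                cand = 1 + int(rng.poisson(mean - 1.0))
                if t * (na + cand) / 2.0 <= min(na, cand) + 1e-9:
                    nb = cand
                    break
            s = int(_shared_counts(rng, np.array([na]), np.array([nb]), t)[0])
            shared = frozenset(rng.choice(anchor_terms, size=s, replace=False))
            setattr(partner, attr, shared | _term_ids(domain, tag, "P", nb - s))
        for outgroup, avail in sorted(config.ortholog_availability.items()):
            if rng.random() >= avail:
                continue
            dn_o = float(rng.gamma(2.0, config.ortholog_dn[WGD][outgroup] / 2.0))
            omega = float(rng.gamma(2.0, config.ortholog_dnds[WGD][outgroup] / 2.0))
            dataset.ortholog_rates.append(OrthologRate(
                gene_id=pid, outgroup=outgroup, dn=dn_o,
                ds=dn_o / omega if omega > 0 else 0.0))
        dn = float(rng.gamma(shape, scale))
        dataset.pairs.append(ParalogPair(
            anchor.gene_id, pid, origin=WGD, dn=dn,
            ds=dn * float(off + rng.gamma(sh, mexc / sh)),
            identity_pct=float(rng.uniform(lo, hi)),
        ))
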