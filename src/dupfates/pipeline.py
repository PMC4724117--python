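"""End-to-end analysis: filter -> partition -> bin -> score -> compare -> report.

The analysis path is deterministic and seed-free; all randomness lives in the
synthetic generator. Stages are independently skippable so partial datasets
(no expression table, no Pfam counts, no flags) still produce the remaining
tables, with each skip and exclusion logged.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assembly, metrics, rates, stats
from .assembly import DEFAULT_DN_BINS, DnBin
from .errors import TabulationError
from .model import SSD, WGD, Dataset, ParalogPair


@dataclass
class AnalysisConfig:
    """Knobs of the analysis path (not of the data generator)."""

    min_identity_pct: float = 50.0
    bins: tuple[DnBin, ...] = DEFAULT_DN_BINS
    ds_max: float = rates.DS_SATURATION
    closest_only: bool = False
    mirror_pairs: bool = False
    #: phylostratum rank above which both members make an SSD pair "young";
    #: None disables the young/old robustness split.
    age_threshold: int | None = None
    #: extra identity thresholds for the robustness sweep (empty = off).
    identity_sweep: tuple[float, ...] = ()
    #: display-only floor for reported p-values.
    p_floor: float = 1e-6

    def to_dict(self) -> dict:
        return {
            "min_identity_pct": self.min_identity_pct,
            "bins": [[b.label, b.lower, b.upper] for b in self.bins],
            "ds_max": self.ds_max,
            "closest_only": self.closest_only,
            "mirror_pairs": self.mirror_pairs,
            "age_threshold": self.age_threshold,
            "identity_sweep": list(self.identity_sweep),
            "p_floor": self.p_floor,
        }


@dataclass
class AnalysisReport:
    """All result tables of one run, plus exclusion log and provenance."""

    binned: pd.DataFrame
    rates: pd.DataFrame
    multifunctionality: pd.DataFrame
    proportions: pd.DataFrame
    variants: dict[str, pd.DataFrame] = field(default_factory=dict)
    exclusions: pd.DataFrame = field(default_factory=pd.DataFrame)
    skipped: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _binned_frame(rows: list[stats.BinnedComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "bin": r.bin_label, "metric": r.metric,
        "mean_ssd": r.mean_ssd, "n_ssd": r.n_ssd,
        "mean_wgd": r.mean_wgd, "n_wgd": r.n_wgd,
        "u_statistic": r.u_statistic, "p_value": r.p_two_tailed,
        "applicable": r.applicable,
    } for r in rows])


def _filter_pairs(
    pairs: list[ParalogPair], min_identity_pct: float, log: Counter
) -> list[ParalogPair]:
    """Re-apply the labelling rules to origin-labelled pairs.

    WGD pairs are kept regardless of identity (the reference list overrides
    the identity rule); SSD pairs must meet the threshold.
    """
    kept = []
    for p in pairs:
        if p.origin == WGD:
            kept.append(p)
        elif p.origin == SSD:
            if p.identity_pct is not None and p.identity_pct < min_identity_pct:
                log["pair_below_identity_threshold"] += 1
            else:
                kept.append(p)
        else:
            log["pair_without_origin"] += 1
    return kept


def _score_and_compare(
    dataset: Dataset,
    pairs: list[ParalogPair],
    config: AnalysisConfig,
    log: Counter | None = None,
    prefix: str = "",
) -> pd.DataFrame:
    sub = Dataset(genes=dataset.genes, pairs=pairs,
                  ortholog_rates=dataset.ortholog_rates,
                  tissue_names=dataset.tissue_names)
    all_scores = []
    for metric in metrics.METRICS:
        scores, excl = metrics.score_all_pairs(sub, metric)
        if config.mirror_pairs:
            scores = [s for sc in scores for s in (sc, sc)]
        all_scores.extend(scores)
        if log is not None:
            for reason, n in excl.items():
                log[f"{prefix}{metric}:{reason}"] += n
            log[f"{prefix}{metric}:scored"] += len(scores)
    return _binned_frame(stats.binned_metric_comparison(all_scores, config.bins))


def run_full_analysis(
    dataset: Dataset, config: AnalysisConfig | None = None
) -> AnalysisReport:
    """Run every enabled stage on a validated dataset.

    Deterministic given (dataset, config); missing inputs skip their stage
    with a logged reason rather than aborting the run.
    """
    config = config or AnalysisConfig()
    log: Counter = Counter()
    skipped: dict[str, str] = {}

    pairs = _filter_pairs(dataset.pairs, config.min_identity_pct, log)
    if config.closest_only:
        before = len(pairs)
        pairs = assembly.select_closest_pairs(pairs)
        log["closest_only_removed"] += before - len(pairs)
    partition = assembly.partition_gene_sets(pairs)
    log["genes_ssd_only"] = len(partition.ssd_only)
    log["genes_wgd_only"] = len(partition.wgd_only)
    log["genes_both_excluded"] = len(partition.both)

    binned = _score_and_compare(dataset, pairs, config, log)

    # --- gene-level rate comparison, stratified by outgroup -----------------
    rate_records = []
    if dataset.ortholog_rates:
        rows, excl = rates.ortholog_rate_table(
            dataset.ortholog_rates, partition, config.ds_max)
        for reason, n in excl.items():
            log[f"rates:{reason}"] += n
        for outgroup in sorted({r.outgroup for r in rows}):
            by_group = {
                g: [r for r in rows if r.outgroup == outgroup and r.group == g]
                for g in ("SSD_only", "WGD_only")
            }
            if not by_group["SSD_only"] or not by_group["WGD_only"]:
                continue
            dn = {g: [r.dn for r in rs] for g, rs in by_group.items()}
            dnds = {g: [r.dnds for r in rs if r.dnds is not None]
                    for g, rs in by_group.items()}
            _, p_dn = stats.mann_whitney_two_tailed(dn["SSD_only"], dn["WGD_only"])
            p_dnds = None
            if dnds["SSD_only"] and dnds["WGD_only"]:
                _, p_dnds = stats.mann_whitney_two_tailed(
                    dnds["SSD_only"], dnds["WGD_only"])
            for g in ("SSD_only", "WGD_only"):
                rate_records.append({
                    "outgroup": outgroup, "group": g, "n": len(dn[g]),
                    "mean_dn": float(np.mean(dn[g])),
                    "mean_dnds": float(np.mean(dnds[g])) if dnds[g] else None,
                    "p_value_dn": p_dn, "p_value_dnds": p_dnds,
                })
    else:
        skipped["rate_comparison"] = "no ortholog rate table"
    rate_df = pd.DataFrame(rate_records)

    # --- multifunctionality -------------------------------------------------
    multi_records = []
    mf_rows = rates.multifunctionality_counts(dataset.genes, partition)
    by_group = {g: [r for r in mf_rows if r.group == g]
                for g in ("SSD_only", "WGD_only")}
    if by_group["SSD_only"] and by_group["WGD_only"]:
        bp = {g: [r.bp_term_count for r in rs] for g, rs in by_group.items()}
        _, p_bp = stats.mann_whitney_two_tailed(bp["SSD_only"], bp["WGD_only"])
        pfam = {g: [r.pfam_domain_count for r in rs
                    if r.pfam_domain_count is not None]
                for g, rs in by_group.items()}
        p_pfam = None
        if pfam["SSD_only"] and pfam["WGD_only"]:
            _, p_pfam = stats.mann_whitney_two_tailed(
                pfam["SSD_only"], pfam["WGD_only"])
        elif not pfam["SSD_only"] and not pfam["WGD_only"]:
            skipped["multifunctionality_pfam"] = "no Pfam domain counts"
        for g in ("SSD_only", "WGD_only"):
            multi_records.append({
                "group": g,
                "n": len(bp[g]),
                "mean_bp_terms": float(np.mean(bp[g])),
                "p_value_bp": p_bp,
                "mean_pfam_domains": float(np.mean(pfam[g])) if pfam[g] else None,
                "n_pfam": len(pfam[g]),
                "p_value_pfam": p_pfam,
            })
    else:
        skipped["multifunctionality"] = "a partition group is empty"
    multi_df = pd.DataFrame(multi_records)

    # --- essentiality / disease proportions ---------------------------------
    prop_records = []
    for flag in ("essential", "disease"):
        try:
            tab = rates.importance_tabulation(dataset.genes, partition, flag)
        except TabulationError as exc:
            skipped[f"proportions_{flag}"] = str(exc)
            continue
        ssd_t, wgd_t = tab["SSD_only"], tab["WGD_only"]
        try:
            res = stats.two_proportion_z_from_counts(
                ssd_t.flagged_n, ssd_t.total_n, wgd_t.flagged_n, wgd_t.total_n)
        except Exception as exc:  # degenerate pooled proportion
            skipped[f"proportions_{flag}"] = str(exc)
            continue
        prop_records.append({
            "flag": flag,
            "proportion_ssd": res.p1, "n_ssd": res.n1,
            "proportion_wgd": res.p2, "n_wgd": res.n2,
            "pooled_p": res.pooled_p, "z": res.z_statistic,
            "p_value": res.p_two_tailed,
            "confidence_level": res.confidence_level,
        })
    prop_df = pd.DataFrame(prop_records)

    # --- robustness variants -------------------------------------------------
    variants: dict[str, pd.DataFrame] = {}
    if not config.closest_only:
        closest = assembly.select_closest_pairs(pairs)
        variants["closest_pair_only"] = _score_and_compare(
            dataset, closest, config, log, prefix="closest:")
    for threshold in config.identity_sweep:
        sub_log: Counter = Counter()
        sub = _filter_pairs(dataset.pairs, threshold, sub_log)
        variants[f"identity_ge_{threshold:g}"] = _score_and_compare(
            dataset, sub, config)
    if config.age_threshold is not None:
        age_ranks = rates.dataset_age_ranks(dataset)
        ssd_pairs = [p for p in pairs if p.origin == SSD]
        young, old, n_missing = assembly.split_ssd_by_age(
            ssd_pairs, age_ranks, config.age_threshold)
        log["age_split_missing_rank"] += n_missing
        log["ssd_young_pairs"] = len(young)
        log["ssd_old_pairs"] = len(old)
        wgd_pairs = [p for p in pairs if p.origin == WGD]
        if old:
            variants["old_ssd_vs_wgd"] = _score_and_compare(
                dataset, old + wgd_pairs, config)
        if young:
            variants["young_ssd_vs_wgd"] = _score_and_compare(
                dataset, young + wgd_pairs, config)

    if not dataset.tissue_names:
        skipped["expression_stage"] = "no expression table"

    exclusions = pd.DataFrame(
        sorted(log.items()), columns=["event", "count"])
    provenance = {
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:16],
        "n_genes": len(dataset.genes),
        "n_pairs_input": len(dataset.pairs),
        "n_pairs_analyzed": len(pairs),
        "n_ortholog_records": len(dataset.ortholog_rates),
        "n_tissues": len(dataset.tissue_names),
    }
    return AnalysisReport(
        binned=binned, rates=rate_df, multifunctionality=multi_df,
        proportions=prop_df, variants=variants, exclusions=exclusions,
        skipped=skipped, provenance=provenance,
    )
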