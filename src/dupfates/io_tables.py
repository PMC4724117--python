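"""Reading and writing the five tab-separated input tables and result reports.

Tables follow the Biomart-export convention: UTF-8, tab-separated, one header
row, missing optional values as empty fields.

  genes.tsv       gene_id, essential (0/1/empty), disease, pfam_domain_count, age_rank
  pairs.tsv       gene_a, gene_b, origin (SSD|WGD), dn, ds, identity_pct
  go.tsv          gene_id, go_domain (BP|MF|CC), term_id
  expression.tsv  gene_id followed by one column per tissue
  orthologs.tsv   gene_id, outgroup, dn, ds
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError, TableValueError
from .model import Dataset, GeneRecord, OrthologRate, ParalogPair

GENE_COLUMNS = ["gene_id", "essential", "disease", "pfam_domain_count", "age_rank"]
PAIR_COLUMNS = ["gene_a", "gene_b", "origin", "dn", "ds", "identity_pct"]
GO_COLUMNS = ["gene_id", "go_domain", "term_id"]
ORTHOLOG_COLUMNS = ["gene_id", "outgroup", "dn", "ds"]


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{Path(path).name}: missing required column {col!r}")
    return df


def _opt_bool(cell: str, ctx: str) -> bool | None:
    if cell == "":
        return None
    if cell in ("0", "1"):
        return cell == "1"
    raise TableValueError(f"{ctx}: flag must be 0, 1 or empty, got {cell!r}")


def _opt_int(cell: str, ctx: str) -> int | None:
    if cell == "":
        return None
    try:
        return int(cell)
    except ValueError as exc:
        raise TableValueError(f"{ctx}: not an integer: {cell!r}") from exc


def _opt_float(cell: str, ctx: str) -> float | None:
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise TableValueError(f"{ctx}: not a number: {cell!r}") from exc


def load_dataset(
    gene_table_path: str | Path,
    pair_table_path: str | Path,
    go_table_path: str | Path,
    expression_table_path: str | Path | None = None,
    ortholog_table_path: str | Path | None = None,
) -> Dataset:
    """Read and cross-validate the input tables into a :class:`Dataset`.

    Rows in the pair/GO/expression/ortholog tables that reference a gene id
    absent from the gene table raise :class:`IntegrityError` — they are never
    silently dropped. Out-of-range values raise :class:`TableValueError`
    naming the offending row (1-based data row number).
    """
    genes: dict[str, GeneRecord] = {}
    gdf = _read_tsv(gene_table_path, GENE_COLUMNS)
    for i, row in enumerate(gdf.itertuples(index=False), start=1):
        gid = row.gene_id
        if gid in genes:
            raise IntegrityError(f"genes.tsv row {i}: duplicate gene id {gid!r}")
        ctx = f"genes.tsv row {i}"
        pfam = _opt_int(row.pfam_domain_count, ctx)
        if pfam is not None and pfam < 0:
            raise TableValueError(f"{ctx}: pfam_domain_count < 0")
        age = _opt_int(row.age_rank, ctx)
        if age is not None and age < 1:
            raise TableValueError(f"{ctx}: age_rank must be >= 1")
        genes[gid] = GeneRecord(
            gene_id=gid,
            essential=_opt_bool(row.essential, ctx),
            disease=_opt_bool(row.disease, ctx),
            pfam_domain_count=pfam,
            age_rank=age,
        )

    go_df = _read_tsv(go_table_path, GO_COLUMNS)
    go_sets: dict[tuple[str, str], set[str]] = {}
    for i, row in enumerate(go_df.itertuples(index=False), start=1):
        if row.gene_id not in genes:
            raise IntegrityError(f"go.tsv row {i}: unknown gene id {row.gene_id!r}")
        if row.go_domain not in ("BP", "MF", "CC"):
            raise TableValueError(f"go.tsv row {i}: go_domain must be BP, MF or CC")
        # duplicate (gene, domain, term) rows collapse into the set silently
        go_sets.setdefault((row.gene_id, row.go_domain), set()).add(row.term_id)
    for (gid, domain), terms in go_sets.items():
        setattr(genes[gid], {"BP": "go_bp", "MF": "go_mf", "CC": "go_cc"}[domain], frozenset(terms))

    tissue_names: list[str] = []
    if expression_table_path is not None:
        edf = _read_tsv(expression_table_path, ["gene_id"])
        tissue_names = [c for c in edf.columns if c != "gene_id"]
        if len(set(tissue_names)) != len(tissue_names):
            raise SchemaError("expression.tsv: duplicate tissue column names")
        for i, row in enumerate(edf.itertuples(index=False), start=1):
            gid = row.gene_id
            if gid not in genes:
                raise IntegrityError(f"expression.tsv row {i}: unknown gene id {gid!r}")
            ctx = f"expression.tsv row {i}"
            values = [_opt_float(v, ctx) for v in row[1:]]
            if any(v is None for v in values):
                raise TableValueError(f"{ctx}: empty expression cell")
            arr = np.array(values, dtype=float)
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise TableValueError(f"{ctx}: expression values must be finite and >= 0")
            genes[gid].expression = arr

    pairs: list[ParalogPair] = []
    pdf = _read_tsv(pair_table_path, PAIR_COLUMNS)
    for i, row in enumerate(pdf.itertuples(index=False), start=1):
        ctx = f"pairs.tsv row {i}"
        for gid in (row.gene_a, row.gene_b):
            if gid not in genes:
                raise IntegrityError(f"{ctx}: unknown gene id {gid!r}")
        dn = _opt_float(row.dn, ctx)
        if dn is not None and dn < 0:
            raise TableValueError(f"{ctx}: dn < 0")
        ds = _opt_float(row.ds, ctx)
        if ds is not None and ds < 0:
            raise TableValueError(f"{ctx}: ds < 0")
        origin = row.origin if row.origin != "" else None
        try:
            pairs.append(
                ParalogPair(
                    gene_a=row.gene_a,
                    gene_b=row.gene_b,
                    origin=origin,
                    dn=dn,
                    ds=ds,
                    identity_pct=_opt_float(row.identity_pct, ctx),
                )
            )
        except TableValueError as exc:
            raise TableValueError(f"{ctx}: {exc}") from exc

    rates: list[OrthologRate] = []
    if ortholog_table_path is not None:
        odf = _read_tsv(ortholog_table_path, ORTHOLOG_COLUMNS)
        for i, row in enumerate(odf.itertuples(index=False), start=1):
            ctx = f"orthologs.tsv row {i}"
            if row.gene_id not in genes:
                raise IntegrityError(f"{ctx}: unknown gene id {row.gene_id!r}")
            dn = _opt_float(row.dn, ctx)
            ds = _opt_float(row.ds, ctx)
            if dn is None or ds is None:
                raise TableValueError(f"{ctx}: dn and ds are required")
            if dn < 0 or ds < 0:
                raise TableValueError(f"{ctx}: negative dn/ds")
            rates.append(OrthologRate(gene_id=row.gene_id, outgroup=row.outgroup, dn=dn, ds=ds))

    return Dataset(
        genes=genes, pairs=pairs, ortholog_rates=rates, tissue_names=tissue_names
    ).validate()


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_dataset(dataset: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a Dataset to the five TSV tables; the inverse of :func:`load_dataset`.

    Output is deterministic (rows sorted by id) so identical datasets produce
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.tsv" for name in
             ("genes", "pairs", "go", "expression", "orthologs")}

    gene_ids = sorted(dataset.genes)
    with open(paths["genes"], "w", encoding="utf-8") as fh:
        fh.write("\t".join(GENE_COLUMNS) + "\n")
        for gid in gene_ids:
            g = dataset.genes[gid]
            fh.write("\t".join([
                gid, _fmt(g.essential), _fmt(g.disease),
                _fmt(g.pfam_domain_count), _fmt(g.age_rank),
            ]) + "\n")

    with open(paths["go"], "w", encoding="utf-8") as fh:
        fh.write("\t".join(GO_COLUMNS) + "\n")
        for gid in gene_ids:
            g = dataset.genes[gid]
            for domain, terms in (("BP", g.go_bp), ("MF", g.go_mf), ("CC", g.go_cc)):
                for term in sorted(terms):
                    fh.write(f"{gid}\t{domain}\t{term}\n")

    with open(paths["pairs"], "w", encoding="utf-8") as fh:
        fh.write("\t".join(PAIR_COLUMNS) + "\n")
        for p in sorted(dataset.pairs, key=lambda p: (p.gene_a, p.gene_b, p.origin or "")):
            fh.write("\t".join([
                p.gene_a, p.gene_b, _fmt(p.origin), _fmt(p.dn), _fmt(p.ds),
                _fmt(p.identity_pct),
            ]) + "\n")

    with open(paths["expression"], "w", encoding="utf-8") as fh:
        fh.write("\t".join(["gene_id", *dataset.tissue_names]) + "\n")
        for gid in gene_ids:
            expr = dataset.genes[gid].expression
            if expr is not None:
                fh.write("\t".join([gid, *(repr(float(v)) for v in expr)]) + "\n")

    with open(paths["orthologs"], "w", encoding="utf-8") as fh:
        fh.write("\t".join(ORTHOLOG_COLUMNS) + "\n")
        for r in sorted(dataset.ortholog_rates, key=lambda r: (r.gene_id, r.outgroup)):
            fh.write(f"{r.gene_id}\t{r.outgroup}\t{_fmt(r.dn)}\t{_fmt(r.ds)}\n")

    return paths


def load_dataset_dir(directory: str | Path) -> Dataset:
    """Load a dataset written by :func:`write_dataset` from one directory."""
    d = Path(directory)
    expr = d / "expression.tsv"
    orth = d / "orthologs.tsv"
    return load_dataset(
        d / "genes.tsv", d / "pairs.tsv", d / "go.tsv",
        expr if expr.exists() else None,
        orth if orth.exists() else None,
    )


def write_report(report, out_dir: str | Path) -> list[Path]:
    """Write every table of an :class:`~dupfates.pipeline.AnalysisReport` as TSV.

    Produces one file per non-empty table plus ``summary.json``; re-running on
    the same report yields byte-identical files. Returns the file manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []

    def _write_table(name: str, df: pd.DataFrame | None) -> None:
        if df is None or df.empty:
            return
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
        manifest.append(path)

    _write_table("binned_comparison", report.binned)
    _write_table("rate_comparison", report.rates)
    _write_table("multifunctionality", report.multifunctionality)
    _write_table("proportion_tests", report.proportions)
    _write_table("exclusions", report.exclusions)
    for name, table in sorted(report.variants.items()):
        _write_table(f"variant_{name}", table)

    summary = {
        "tables": sorted(p.name for p in manifest),
        "skipped": report.skipped,
        "provenance": report.provenance,
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n",
                            encoding="utf-8")
    manifest.append(summary_path)
    return manifest
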