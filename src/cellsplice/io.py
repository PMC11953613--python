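"""Readers and writers for every table the pipeline touches.

All formats are plain TSV.  The PSI table follows an inclusion-table
dialect: identity columns ``GENE  EVENT  COORD  TYPE`` and then, per
sample, a value column ``<sample_id>`` (PSI with two decimals, or NA)
paired with a quality column ``<sample_id>.Q`` holding
``TIER@inc,exc,balance_p`` — the coverage tier, the summed inclusion and
exclusion junction reads, and the intron-retention balance p-value (NA
for non-IR events).  Genomic coordinates are ``chrom:start-end``,
1-based with inclusive ends.  Missing values are written ``NA``
everywhere; a missing PSI is distinct from PSI 0.
"""
from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import (
    IMPACT_CLASSES,
    TIERS,
    GeneSet,
    PsiMatrix,
    SampleInfo,
    SpliceEvent,
    validate_samples,
)

log = logging.getLogger("cellsplice")

NA = "NA"


# ---------------------------------------------------------------- samples

def read_sample_sheet(path: str | Path) -> list[SampleInfo]:
    """Sample sheet TSV with columns sample_id, cell_type, organ, replicate."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "cell_type", "organ", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path} lacks columns {missing}")
    samples = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            samples.append(SampleInfo(
                sample_id=row.sample_id, cell_type=row.cell_type,
                organ=row.organ, replicate=int(row.replicate),
            ))
        except ValueError as exc:
            raise ValueError(f"sample sheet row {i}: {exc}") from exc
    return validate_samples(samples)


def write_sample_sheet(samples: Sequence[SampleInfo], path: str | Path) -> None:
    pd.DataFrame(
        [(s.sample_id, s.cell_type, s.organ, s.replicate) for s in samples],
        columns=["sample_id", "cell_type", "organ", "replicate"],
    ).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- events

def read_events_table(path: str | Path) -> list[SpliceEvent]:
    """Event definitions: event_id, gene_id, event_type, coord, n_variants."""
    df = pd.read_csv(path, sep="\t", dtype={"event_id": str, "gene_id": str})
    return [
        SpliceEvent(event_id=r.event_id, gene_id=r.gene_id, event_type=r.event_type,
                    coord=r.coord, n_variants=int(r.n_variants))
        for r in df.itertuples(index=False)
    ]


def write_events_table(events: Sequence[SpliceEvent], path: str | Path) -> None:
    pd.DataFrame(
        [(e.event_id, e.gene_id, e.event_type, e.coord, e.n_variants) for e in events],
        columns=["event_id", "gene_id", "event_type", "coord", "n_variants"],
    ).to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------- junctions

def read_junction_counts(path: str | Path) -> pd.DataFrame:
    """Long-format junction counts: event_id, sample_id, junction_role, reads."""
    df = pd.read_csv(path, sep="\t",
                     dtype={"event_id": str, "sample_id": str, "junction_role": str})
    required = {"event_id", "sample_id", "junction_role", "reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"junction table {path} lacks columns {sorted(missing)}")
    df["reads"] = df["reads"].astype(int)
    return df


def write_junction_counts(junctions: pd.DataFrame, path: str | Path) -> None:
    junctions.to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------- PSI table

def _format_quality(tier: str, inc: float, exc: float, balance_p: float) -> str:
    inc_s = str(int(inc)) if float(inc) == int(inc) else f"{inc:g}"
    exc_s = str(int(exc)) if float(exc) == int(exc) else f"{exc:g}"
    bal_s = NA if (balance_p is None or math.isnan(balance_p)) else f"{balance_p:.6g}"
    return f"{tier}@{inc_s},{exc_s},{bal_s}"


def _parse_quality(q: str, where: str) -> tuple[str, float, float, float]:
    try:
        tier, _, rest = q.partition("@")
        inc_s, exc_s, bal_s = rest.split(",")
    except ValueError as exc:
        raise ValueError(f"malformed quality string {q!r} at {where}") from exc
    if tier not in TIERS:
        raise ValueError(f"unknown coverage tier {tier!r} at {where}")
    bal = math.nan if bal_s == NA else float(bal_s)
    return tier, float(inc_s), float(exc_s), bal


def write_psi_table(psi: PsiMatrix, path: str | Path) -> None:
    """Write the PSI inclusion table (dialect in the module docstring)."""
    cols: dict[str, list] = {
        "GENE": list(psi.events["gene_id"]),
        "EVENT": list(psi.events.index),
        "COORD": list(psi.events["coord"]),
        "TYPE": list(psi.events["event_type"]),
    }
    for sid in psi.sample_ids:
        values, quals = [], []
        for eid in psi.event_ids:
            v = psi.psi.at[eid, sid]
            values.append(NA if pd.isna(v) else f"{v:.2f}")
            quals.append(_format_quality(
                psi.tier.at[eid, sid], psi.inc.at[eid, sid],
                psi.exc.at[eid, sid], psi.balance_p.at[eid, sid]))
        cols[sid] = values
        cols[f"{sid}.Q"] = quals
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_psi_table(path: str | Path) -> tuple[list[SpliceEvent], PsiMatrix]:
    """Read a PSI inclusion table back into events and a PsiMatrix."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    fixed = ["GENE", "EVENT", "COORD", "TYPE"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise ValueError(f"PSI table {path} lacks identity columns {missing}")
    sample_ids = [c for c in df.columns if c not in fixed and not c.endswith(".Q")]
    for sid in sample_ids:
        if f"{sid}.Q" not in df.columns:
            raise ValueError(f"PSI table {path}: sample {sid!r} lacks its paired quality column")

    event_ids = list(df["EVENT"])
    if len(set(event_ids)) != len(event_ids):
        raise ValueError(f"PSI table {path}: duplicate event ids")

    # ALTA/ALTD variant counts are not recoverable from the focal-variant
    # table; n_variants defaults to 2 on read-back.
    events = [
        SpliceEvent(event_id=r.EVENT, gene_id=r.GENE, event_type=r.TYPE, coord=r.COORD)
        for r in df.itertuples(index=False)
    ]

    shape = (len(event_ids), len(sample_ids))
    psi = np.full(shape, np.nan)
    tier = np.full(shape, "N", dtype=object)
    bal = np.full(shape, np.nan)
    inc = np.zeros(shape)
    exc = np.zeros(shape)
    for j, sid in enumerate(sample_ids):
        for i, (v, q) in enumerate(zip(df[sid], df[f"{sid}.Q"])):
            where = f"{path}:{event_ids[i]}/{sid}"
            tier[i, j], inc[i, j], exc[i, j], bal[i, j] = _parse_quality(q, where)
            if v != NA:
                value = float(v)
                if not 0.0 <= value <= 100.0:
                    raise ValueError(f"PSI {value} outside [0, 100] at {where}")
                psi[i, j] = value

    events_df = pd.DataFrame(
        {"gene_id": df["GENE"].to_numpy(), "event_type": df["TYPE"].to_numpy(),
         "coord": df["COORD"].to_numpy(), "n_variants": 2},
        index=pd.Index(event_ids, name="event_id"),
    )
    mk = lambda arr: pd.DataFrame(arr, index=events_df.index, columns=sample_ids)
    return events, PsiMatrix(events_df, mk(psi), mk(tier), mk(bal), mk(inc), mk(exc))


# ----------------------------------------------------------- count matrix

def read_count_matrix(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Count matrix: gene_id, mappable_positions, then one column per sample.

    Returns (raw counts gene x sample, mappable positions per gene).
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "mappable_positions"):
        if col not in df.columns:
            raise ValueError(f"count matrix {path} lacks column {col!r}")
    df = df.set_index("gene_id")
    mappable = df.pop("mappable_positions").astype(int)
    return df.astype(int), mappable


def write_count_matrix(raw: pd.DataFrame, mappable: pd.Series, path: str | Path) -> None:
    out = raw.copy()
    out.insert(0, "mappable_positions", mappable.reindex(raw.index).astype(int))
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_matrix(df: pd.DataFrame, path: str | Path, index_name: str = "gene_id",
                 float_format: str = "%.6g") -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", na_rep=NA, float_format=float_format)


# ------------------------------------------------------------- gene lists

def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """One gene identifier per line; '#' lines are comments."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line.split("\t")[0])
    if not genes:
        log.warning("gene list %s is empty", path)
    return GeneSet.from_iterable(name or Path(path).stem, genes)


def write_gene_list(gene_set: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(gene_set.members):
            fh.write(f"{g}\n")


def read_term_sets(path: str | Path) -> dict[str, GeneSet]:
    """Two-column TSV (term, gene) -> {term: GeneSet}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["term", "gene"]:
        raise ValueError(f"term table {path} must have columns term, gene")
    out = {}
    for term, grp in df.groupby("term", sort=True):
        out[term] = GeneSet.from_iterable(term, grp["gene"])
    return out


def write_term_sets(terms: Mapping[str, GeneSet], path: str | Path) -> None:
    rows = [(t, g) for t in sorted(terms) for g in sorted(terms[t].members)]
    pd.DataFrame(rows, columns=["term", "gene"]).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------- impact table

def read_impact_table(path: str | Path) -> dict[str, str]:
    """event_id -> predicted impact class."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("event_id", "impact"):
        if col not in df.columns:
            raise ValueError(f"impact table {path} lacks column {col!r}")
    bad = set(df["impact"]) - set(IMPACT_CLASSES)
    if bad:
        raise ValueError(f"impact table {path}: unknown impact classes {sorted(bad)}")
    if df["event_id"].duplicated().any():
        raise ValueError(f"impact table {path}: duplicate event ids")
    return dict(zip(df["event_id"], df["impact"]))


def write_impact_table(impact: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(sorted(impact.items()), columns=["event_id", "impact"]).to_csv(
        path, sep="\t", index=False)


# ------------------------------------------------------------ call tables

def write_dse_calls(calls, path: str | Path) -> None:
    rows = [{
        "event_id": c.event_id, "cell_type": c.cell_type, "organ": c.organ,
        "dpsi_global": round(c.dpsi_global, 4), "dpsi_min": round(c.dpsi_min, 4),
        "psi_range": round(c.psi_range, 4), "direction": c.direction,
        **{f"pass_{k}": v for k, v in sorted(c.criteria_passed.items())},
    } for c in calls]
    cols = ["event_id", "cell_type", "organ", "dpsi_global", "dpsi_min",
            "psi_range", "direction"]
    extra = sorted({k for r in rows for k in r} - set(cols))
    pd.DataFrame(rows, columns=cols + extra).to_csv(path, sep="\t", index=False)


def write_deg_calls(calls, path: str | Path) -> None:
    rows = [{
        "gene_id": c.gene_id, "cell_type": c.cell_type, "organ": c.organ,
        "log2_fc_global": round(c.log2_fc_global, 4), "direction": c.direction,
        "median_target": round(c.median_target, 4),
        "global_median_others": round(c.global_median_others, 4),
    } for c in calls]
    pd.DataFrame(rows, columns=["gene_id", "cell_type", "organ", "log2_fc_global",
                                "direction", "median_target", "global_median_others"]
                 ).to_csv(path, sep="\t", index=False)


def write_enrichment_results(results, path: str | Path) -> None:
    rows = [{
        "term": r.term, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
        "ease_p": f"{r.ease_p:.6g}", "fisher_p": f"{r.fisher_p:.6g}",
        "fold_enrichment": f"{r.fold_enrichment:.6g}", "ease_p_bh": f"{r.ease_p_bh:.6g}",
    } for r in results]
    pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "ease_p", "fisher_p",
                                "fold_enrichment", "ease_p_bh"]).to_csv(
        path, sep="\t", index=False)
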