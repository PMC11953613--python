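"""Descriptive layers over the call sets: event-class proportions,
gene-set subsetting (e.g. the immunity list), predicted protein impact,
and the joint expression-vs-splicing table."""
from __future__ import annotations

import logging
import math
from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .models import (
    EVENT_TYPES,
    DegCall,
    GeneSet,
    SampleInfo,
    SpecificCall,
    SpecificityThresholds,
    SpliceEvent,
)
from .specificity import _by_organ, _cell_groups, fold_change

log = logging.getLogger("cellsplice")


def event_type_proportions(calls: Sequence[SpecificCall],
                           events: Sequence[SpliceEvent]) -> dict:
    """Counts and fractions of IR / EX / ALTA / ALTD among the called
    events, overall and per call direction.  Fractions sum to 1 per
    stratum; an empty stratum is flagged and reports all-zero fractions."""
    type_of = {e.event_id: e.event_type for e in events}

    def stratum(sub: Sequence[SpecificCall]) -> dict:
        counts = Counter(type_of[c.event_id] for c in sub)
        total = sum(counts.values())
        return {
            "counts": {t: counts.get(t, 0) for t in EVENT_TYPES},
            "fractions": {t: (counts.get(t, 0) / total if total else 0.0)
                          for t in EVENT_TYPES},
            "total": total,
            "empty": total == 0,
        }

    return {
        "overall": stratum(calls),
        "up": stratum([c for c in calls if c.direction == "up"]),
        "down": stratum([c for c in calls if c.direction == "down"]),
    }


def subset_by_gene_set(calls: Sequence, gene_set: GeneSet,
                       events: Sequence[SpliceEvent] | None = None) -> list:
    """Calls whose gene belongs to ``gene_set``; order and fields kept.

    Splicing calls carry event ids, so ``events`` must supply the
    event-to-gene map for them; expression calls carry the gene directly.
    """
    gene_of = {e.event_id: e.gene_id for e in events} if events is not None else {}

    def gene(call) -> str:
        if hasattr(call, "gene_id"):
            return call.gene_id
        if not gene_of:
            raise ValueError("events are required to map splicing calls to genes")
        return gene_of[call.event_id]

    return [c for c in calls if gene(c) in gene_set]


def classify_impact(calls: Sequence[SpecificCall],
                    impact: Mapping[str, str]) -> dict:
    """Predicted protein impact of the called events.

    Fractions are over annotated calls (impact != unknown); the
    ORF-disruption class is additionally split by call direction.
    Events absent from the annotation map to unknown.
    """
    labels = [impact.get(c.event_id, "unknown") for c in calls]
    counts = Counter(labels)
    annotated = [(lab, c) for lab, c in zip(labels, calls) if lab != "unknown"]
    n_annot = len(annotated)
    fractions = {lab: (counts[lab] / n_annot if n_annot else 0.0)
                 for lab in counts if lab != "unknown"}
    orf = [c for lab, c in annotated if lab == "ORF_disruption"]
    orf_up = sum(1 for c in orf if c.direction == "up")
    return {
        "counts": dict(counts),
        "n_annotated": n_annot,
        "fractions": fractions,
        "orf_disruption_up": orf_up,
        "orf_disruption_down": len(orf) - orf_up,
        "no_annotated_calls": n_annot == 0,
    }


def _quadrant(dpsi: float, lfc: float, dpsi_thr: float, lfc_thr: float) -> str:
    if math.isnan(lfc):
        return "fc_missing"
    spliced = "up-spliced" if dpsi > 0 else "down-spliced"
    if abs(lfc) <= lfc_thr:
        return f"{spliced} / expression-unchanged"
    expressed = "up-expressed" if lfc > 0 else "down-expressed"
    return f"{spliced} / {expressed}"


def expression_splicing_table(dse_calls: Sequence[SpecificCall],
                              expr: ExpressionMatrix,
                              samples: Sequence[SampleInfo],
                              events: Sequence[SpliceEvent],
                              thresholds: SpecificityThresholds | None = None,
                              dpsi_threshold: float = 25.0,
                              lfc_threshold: float = 2.0) -> pd.DataFrame:
    """Join each splicing call with its gene's expression log2 fold
    change (target cell-type median vs pooled median of all other
    same-organ samples, pseudocounted) in the same cell type, and label
    the quadrant against the |dPSI| and |log2 FC| thresholds."""
    th = thresholds or SpecificityThresholds()
    gene_of = {e.event_id: e.gene_id for e in events}
    by_organ = _by_organ(list(samples))
    rows = []
    for c in dse_calls:
        gene = gene_of[c.event_id]
        groups = _cell_groups(by_organ[c.organ])
        if gene in expr.crpkm.index and c.cell_type in groups:
            target_ids = groups[c.cell_type]
            other_ids = [sid for ct, sids in groups.items()
                         if ct != c.cell_type for sid in sids]
            mt = float(expr.crpkm.loc[gene, target_ids].median())
            mg = float(expr.crpkm.loc[gene, other_ids].median())
            lfc = float(np.log2(fold_change(mt, mg, th.pseudocount)))
        else:
            lfc = math.nan
            log.warning("gene %r absent from expression matrix; FC missing for %s",
                        gene, c.event_id)
        rows.append({
            "event_id": c.event_id,
            "gene_id": gene,
            "cell_type": c.cell_type,
            "organ": c.organ,
            "dpsi": c.dpsi_global,
            "log2_fc": lfc,
            "quadrant": _quadrant(c.dpsi_global, lfc, dpsi_threshold, lfc_threshold),
        })
    return pd.DataFrame(rows, columns=["event_id", "gene_id", "cell_type", "organ",
                                       "dpsi", "log2_fc", "quadrant"])
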