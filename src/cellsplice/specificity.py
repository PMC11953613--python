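"""Cell-type-specific callers for splicing (DSE) and expression (DEG).

Root and aerial cell types are analyzed separately.  A splicing event is
cell-type-specific in a target cell type when, over covered replicate
values only,

1. |global dPSI| exceeds ``global_dpsi``, where global dPSI is the
   target's mean PSI minus the mean over all other same-organ samples
   pooled;
2. |minimum dPSI| exceeds ``min_dpsi``, where minimum dPSI is the
   smallest-magnitude per-cell-type mean difference against any other
   covered cell type;
3. the PSI range — the spread between the largest and smallest
   per-cell-type maximum replicate PSI — is at least ``min_psi_range``.

Eligibility gates: the target (and each compared cell type for rule 2)
needs at least ``min_replicates`` covered values, and the organ needs at
least ``min_cell_types`` such cell types.

A gene is cell-type-specific in expression when its median cRPKM reaches
``deg_min_median_crpkm`` in some cell type and the target's median shows
a fold change of at least ``deg_fc_each`` against every other cell-type
median, at least ``deg_fc_global`` against the pooled median of all
other samples, and an absolute cRPKM difference of at least
``deg_abs_diff`` against every other cell-type median.
"""
from __future__ import annotations

import logging
import math
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .models import (
    DegCall,
    PsiMatrix,
    SampleInfo,
    SpecificCall,
    SpecificityThresholds,
    SpliceEvent,
)

log = logging.getLogger("cellsplice")


def _by_organ(samples: Sequence[SampleInfo]) -> dict[str, list[SampleInfo]]:
    out: dict[str, list[SampleInfo]] = {}
    for s in samples:
        out.setdefault(s.organ, []).append(s)
    return out


def _cell_groups(samples: Sequence[SampleInfo]) -> dict[str, list[str]]:
    """cell_type -> ordered sample_ids (deterministic: sheet order)."""
    out: dict[str, list[str]] = {}
    for s in samples:
        out.setdefault(s.cell_type, []).append(s.sample_id)
    return out


def _covered_values(row: pd.Series, mask: pd.Series, sample_ids: Sequence[str]) -> np.ndarray:
    ids = [s for s in sample_ids if s in row.index and bool(mask.get(s, False))]
    return row[ids].to_numpy(dtype=float)


def dpsi_global(row: pd.Series, mask: pd.Series, samples: Sequence[SampleInfo],
                target: str, min_replicates: int = 2) -> float:
    """Target cell-type mean PSI minus the pooled mean of all other
    same-organ covered samples; NaN when the target lacks coverage."""
    groups = _cell_groups(samples)
    tgt = _covered_values(row, mask, groups.get(target, []))
    others = [sid for ct, sids in groups.items() if ct != target for sid in sids]
    oth = _covered_values(row, mask, others)
    if len(tgt) < min_replicates or len(oth) == 0:
        return math.nan
    return float(tgt.mean() - oth.mean())


def dpsi_min(row: pd.Series, mask: pd.Series, samples: Sequence[SampleInfo],
             target: str, min_replicates: int = 2) -> float:
    """Smallest-magnitude per-cell-type mean PSI difference between the
    target and any other covered same-organ cell type (sign preserved)."""
    groups = _cell_groups(samples)
    tgt = _covered_values(row, mask, groups.get(target, []))
    if len(tgt) < min_replicates:
        return math.nan
    diffs = []
    for ct in groups:
        if ct == target:
            continue
        vals = _covered_values(row, mask, groups[ct])
        if len(vals) >= min_replicates:
            diffs.append(float(tgt.mean() - vals.mean()))
    if not diffs:
        return math.nan
    return min(diffs, key=lambda d: (abs(d), d))


def psi_range(row: pd.Series, mask: pd.Series, samples: Sequence[SampleInfo]) -> float:
    """Spread of per-cell-type maximum replicate PSI across the organ:
    (largest cell-type maximum) - (smallest cell-type maximum)."""
    groups = _cell_groups(samples)
    maxima = []
    for sids in groups.values():
        vals = _covered_values(row, mask, sids)
        if len(vals) >= 1:
            maxima.append(float(vals.max()))
    if len(maxima) < 2:
        return math.nan
    return max(maxima) - min(maxima)


def _exceeds(value: float, threshold: float, strict: bool) -> bool:
    return value > threshold if strict else value >= threshold


def call_dse(psi: PsiMatrix, samples: Sequence[SampleInfo],
             thresholds: SpecificityThresholds | None = None,
             min_tier: str = "LOW") -> list[SpecificCall]:
    """Emit one cell-type-specific splicing call per (event, cell type)
    satisfying all three dPSI criteria; each organ independently.

    ``psi`` should already have passed the coverage/balance filter;
    "covered" here means non-missing with tier >= ``min_tier``.
    """
    th = thresholds or SpecificityThresholds()
    mask_all = psi.covered(min_tier)
    event_ids = np.array(psi.event_ids)
    calls: list[SpecificCall] = []
    for organ, organ_samples in _by_organ(list(samples)).items():
        groups = _cell_groups(organ_samples)
        cts = list(groups)
        sids = [s for ct in cts for s in groups[ct] if s in psi.psi.columns]
        vals = psi.psi[sids].to_numpy(dtype=float)            # E x S
        cov = mask_all[sids].to_numpy(dtype=bool)
        vals0 = np.where(cov, vals, 0.0)
        col_of = {s: j for j, s in enumerate(sids)}

        # per-cell-type covered counts, sums and maxima (E x C)
        ct_cols = [[col_of[s] for s in groups[ct] if s in col_of] for ct in cts]
        cnt = np.stack([cov[:, c].sum(axis=1) for c in ct_cols], axis=1)
        ssum = np.stack([vals0[:, c].sum(axis=1) for c in ct_cols], axis=1)
        neg = np.where(cov, vals, -np.inf)
        cmax = np.stack([neg[:, c].max(axis=1) if c else
                         np.full(len(vals), -np.inf) for c in ct_cols], axis=1)

        with np.errstate(invalid="ignore", divide="ignore"):
            ct_mean = np.where(cnt >= th.min_replicates, ssum / np.maximum(cnt, 1), np.nan)
        eligible = cnt >= th.min_replicates
        event_ok = eligible.sum(axis=1) >= th.min_cell_types

        # PSI range across cell types with any covered value
        any_cov = cnt >= 1
        hi = np.where(any_cov, cmax, -np.inf).max(axis=1)
        lo = np.where(any_cov, cmax, np.inf).min(axis=1)
        rng_val = np.where(any_cov.sum(axis=1) >= 2, hi - lo, np.nan)

        tot_cnt = cov.sum(axis=1)
        tot_sum = vals0.sum(axis=1)

        for c, target in enumerate(cts):
            oth_cnt = tot_cnt - cnt[:, c]
            tgt_mean = ssum[:, c] / np.maximum(cnt[:, c], 1)
            oth_mean = (tot_sum - ssum[:, c]) / np.maximum(oth_cnt, 1)
            g = np.where(eligible[:, c] & (oth_cnt > 0), tgt_mean - oth_mean, np.nan)

            others = [j for j in range(len(cts)) if j != c]
            diffs = ct_mean[:, c][:, None] - ct_mean[:, others]
            absd = np.where(np.isnan(diffs), np.inf, np.abs(diffs))
            min_abs = absd.min(axis=1) if others else np.full(len(vals), np.inf)
            # smallest magnitude; ties resolved toward the smaller value
            with np.errstate(invalid="ignore"):
                m_candidates = np.where(absd == min_abs[:, None], diffs, np.inf)
            m = (np.where(np.isfinite(min_abs),
                          m_candidates.min(axis=1, initial=np.inf), np.nan)
                 if others else np.full(len(vals), np.nan))
            m = np.where(np.isfinite(m), m, np.nan)

            ok = (
                event_ok & eligible[:, c]
                & ~np.isnan(g) & ~np.isnan(m) & ~np.isnan(rng_val)
                & _exceeds(np.abs(g), th.global_dpsi, th.strict_dpsi)
                & _exceeds(np.abs(m), th.min_dpsi, th.strict_dpsi)
                & (rng_val >= th.min_psi_range)
            )
            if th.require_sign_coherence:
                ok &= ((g > 0) == (m > 0)) | (m == 0)
            for i in np.flatnonzero(ok):
                passed = {"global_dpsi": True, "min_dpsi": True, "psi_range": True}
                if th.require_sign_coherence:
                    passed["sign_coherence"] = True
                calls.append(SpecificCall(
                    event_id=str(event_ids[i]), cell_type=target, organ=organ,
                    dpsi_global=float(g[i]), dpsi_min=float(m[i]),
                    psi_range=float(rng_val[i]),
                    direction="up" if g[i] > 0 else "down",
                    criteria_passed=passed,
                ))
    # deterministic order: event, then organ/cell type as listed
    order = {str(e): i for i, e in enumerate(event_ids)}
    calls.sort(key=lambda cl: (order[cl.event_id], cl.organ, cl.cell_type))
    return calls


def fold_change(a: float, b: float, pseudocount: float = 0.01) -> float:
    """Pseudocounted ratio (a + pc) / (b + pc)."""
    if a < 0 or b < 0:
        raise ValueError("expression values must be >= 0")
    return (a + pseudocount) / (b + pseudocount)


def call_deg(expr: ExpressionMatrix, samples: Sequence[SampleInfo],
             thresholds: SpecificityThresholds | None = None) -> list[DegCall]:
    """Emit one cell-type-specific expression call per (gene, cell type)
    satisfying all four cRPKM rules; each organ independently."""
    th = thresholds or SpecificityThresholds()
    calls: list[DegCall] = []
    for organ, organ_samples in _by_organ(list(samples)).items():
        groups = _cell_groups(organ_samples)
        if len(groups) < 2:
            log.warning("organ %r has fewer than two cell types; no expression calls", organ)
            continue
        present = [ct for ct, sids in groups.items()
                   if all(s in expr.crpkm.columns for s in sids)]
        medians = pd.DataFrame(
            {ct: expr.crpkm[groups[ct]].median(axis=1) for ct in present}
        )
        for gene in expr.gene_ids:
            med = medians.loc[gene]
            if med.max() < th.deg_min_median_crpkm:
                continue
            for target in present:
                mt = float(med[target])
                other_cts = [ct for ct in present if ct != target]
                ok = True
                for ct in other_cts:
                    mo = float(med[ct])
                    fc = fold_change(mt, mo, th.pseudocount)
                    if not (fc >= th.deg_fc_each or fc <= 1.0 / th.deg_fc_each):
                        ok = False
                        break
                    if abs(mt - mo) < th.deg_abs_diff:
                        ok = False
                        break
                if not ok:
                    continue
                other_ids = [sid for ct in other_cts for sid in groups[ct]]
                mg = float(expr.crpkm.loc[gene, other_ids].median())
                fcg = fold_change(mt, mg, th.pseudocount)
                if not (fcg >= th.deg_fc_global or fcg <= 1.0 / th.deg_fc_global):
                    continue
                calls.append(DegCall(
                    gene_id=gene, cell_type=target, organ=organ,
                    log2_fc_global=float(np.log2(fcg)),
                    direction="up" if mt > mg else "down",
                    median_target=mt, global_median_others=mg,
                ))
    return calls


def upset_counts(membership: Mapping[str, Iterable[str]]) -> dict[tuple[str, ...], int]:
    """Exclusive intersection counts: item -> groups it belongs to,
    returned as {sorted group tuple: number of items with exactly that
    membership pattern}."""
    counter: Counter[tuple[str, ...]] = Counter()
    for groups in membership.values():
        counter[tuple(sorted(set(groups)))] += 1
    return dict(counter)


def overlap_summary(deg: Sequence[DegCall], dse: Sequence[SpecificCall],
                    events: Sequence[SpliceEvent]) -> dict:
    """Gene-level overlap between expression and splicing specificity.

    A DSG is a gene owning at least one called splicing event.  Returns
    the DEG/DSG set sizes, their intersection, and exclusive upset
    intersection patterns of cell-type membership for genes (DEG, DSG)
    and events (DSE).
    """
    gene_of = {e.event_id: e.gene_id for e in events}
    deg_genes = {c.gene_id for c in deg}
    dsg_genes = {gene_of[c.event_id] for c in dse}

    deg_membership: dict[str, set[str]] = {}
    for c in deg:
        deg_membership.setdefault(c.gene_id, set()).add(c.cell_type)
    dsg_membership: dict[str, set[str]] = {}
    dse_membership: dict[str, set[str]] = {}
    for c in dse:
        dsg_membership.setdefault(gene_of[c.event_id], set()).add(c.cell_type)
        dse_membership.setdefault(c.event_id, set()).add(c.cell_type)

    return {
        "n_deg_genes": len(deg_genes),
        "n_dsg_genes": len(dsg_genes),
        "n_overlap_genes": len(deg_genes & dsg_genes),
        "n_dse_events": len({c.event_id for c in dse}),
        "deg_upset": upset_counts(deg_membership),
        "dsg_upset": upset_counts(dsg_membership),
        "dse_upset": upset_counts(dse_membership),
    }
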