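"""PSI quantification from junction read counts.

PSI (percent spliced-in) is estimated per event per sample from reads
mapping to the event's splice junctions:

- exon skipping (EX): inclusion evidence I = (C1A + AC2) / 2, the mean
  of the two inclusion junctions; PSI = 100 * I / (I + C1C2);
- intron retention (IR): retention evidence R = (EI + IE) / 2, the mean
  of the two exon-intron junctions; PSI = 100 * R / (R + EE);
- alternative acceptor/donor (ALTA/ALTD): PSI of the focal variant is
  its read share, 100 * r_focal / sum(r).

A zero denominator yields a missing value, never 0: absence of evidence
is not evidence of exclusion.  Each (event, sample) cell also receives a
coverage tier (a step function of the informative read total) and, for
IR, an exact two-sided binomial test that reads are balanced between the
upstream and downstream exon-intron junctions; imbalanced retention
signals are typically alignment artifacts and are filtered out.
"""
from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    TIERS,
    TIER_RANK,
    BalanceResult,
    PsiMatrix,
    SpliceEvent,
)

#: Default coverage-tier cutoffs on the (floored) informative read total:
#: N below 10, then VLOW, LOW, OK, SOK.
DEFAULT_TIER_CUTOFFS: tuple[int, ...] = (10, 15, 20, 100)

#: Default significance level for the IR read-balance test.
DEFAULT_BALANCE_ALPHA = 0.05


def _check_nonneg(*vals: float) -> None:
    for v in vals:
        if v < 0:
            raise ValueError(f"junction read counts must be non-negative, got {v}")


def compute_psi_ex(c1a: int, ac2: int, c1c2: int) -> float:
    """PSI of an exon-skipping event; NaN when no informative reads."""
    _check_nonneg(c1a, ac2, c1c2)
    inclusion = (c1a + ac2) / 2.0
    denom = inclusion + c1c2
    if denom == 0:
        return math.nan
    return 100.0 * inclusion / denom


def compute_psi_ir(ei: int, ie: int, ee: int) -> float:
    """PSI of an intron-retention event; NaN when no informative reads."""
    _check_nonneg(ei, ie, ee)
    retention = (ei + ie) / 2.0
    denom = retention + ee
    if denom == 0:
        return math.nan
    return 100.0 * retention / denom


def compute_psi_alt(variant_counts: Mapping[str, int], focal: str) -> float:
    """PSI (read share) of the focal variant of an ALTA/ALTD event."""
    if focal not in variant_counts:
        raise ValueError(f"focal variant {focal!r} not among {sorted(variant_counts)}")
    _check_nonneg(*variant_counts.values())
    total = sum(variant_counts.values())
    if total == 0:
        return math.nan
    return 100.0 * variant_counts[focal] / total


def coverage_tier(total_reads: int, tier_cutoffs: Sequence[int] = DEFAULT_TIER_CUTOFFS) -> str:
    """Coverage tier for an informative read total (boundaries inclusive)."""
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    cutoffs = list(tier_cutoffs)
    if len(cutoffs) != len(TIERS) - 1 or any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("tier_cutoffs must be strictly increasing with one cutoff per tier above N")
    tier = TIERS[0]
    for cutoff, name in zip(cutoffs, TIERS[1:]):
        if total_reads >= cutoff:
            tier = name
    return tier


def ir_balance_test(n_upstream: int, n_downstream: int,
                    alpha: float = DEFAULT_BALANCE_ALPHA) -> BalanceResult:
    """Exact two-sided binomial test of read balance at a retained intron.

    Tests n_upstream successes in n_upstream + n_downstream trials at
    success probability 0.5.  With no reads at either junction there is
    no evidence of a genuine junction: p is NaN and the test fails.
    """
    _check_nonneg(n_upstream, n_downstream)
    n = n_upstream + n_downstream
    if n == 0:
        return BalanceResult(math.nan, 0, 0, False)
    p = stats.binomtest(n_upstream, n, 0.5).pvalue
    return BalanceResult(p, n_upstream, n_downstream, p >= alpha)


def balance_p_twosided(n_upstream: np.ndarray, n_downstream: np.ndarray) -> np.ndarray:
    """Vectorized exact two-sided binomial balance p-value at p = 0.5.

    By the symmetry of Binomial(n, 0.5), the two-sided p-value equals
    min(1, 2 * P(X <= min(k, n - k))); agrees with ``ir_balance_test``
    (checked in the test suite).  Returns NaN where n = 0.
    """
    k = np.minimum(n_upstream, n_downstream)
    n = n_upstream + n_downstream
    with np.errstate(invalid="ignore"):
        p = np.minimum(1.0, 2.0 * stats.binom.cdf(k, np.maximum(n, 1), 0.5))
    return np.where(n > 0, p, np.nan)


def _tier_vec(total: np.ndarray, tier_cutoffs: Sequence[int]) -> np.ndarray:
    cutoffs = list(tier_cutoffs)
    out = np.full(total.shape, TIERS[0], dtype=object)
    for cutoff, name in zip(cutoffs, TIERS[1:]):
        out[total >= cutoff] = name
    return out


def quantify(junctions: pd.DataFrame, events: Sequence[SpliceEvent],
             sample_ids: Sequence[str] | None = None,
             tier_cutoffs: Sequence[int] = DEFAULT_TIER_CUTOFFS,
             balance_alpha: float = DEFAULT_BALANCE_ALPHA) -> PsiMatrix:
    """Build a PsiMatrix from long-format junction counts.

    ``junctions`` has columns event_id, sample_id, junction_role, reads.
    Every row must reference a declared event with a role legal for the
    event's type.  (event, sample) pairs with no junction rows, or no
    informative reads, are missing with tier N.  PSI is stored at
    two-decimal precision and balance p-values at six significant
    digits, matching the on-disk table dialect so that written tables
    round-trip exactly.
    """
    by_id = {e.event_id: e for e in events}
    if len(by_id) != len(events):
        raise ValueError("event_id values must be unique")
    required = {"event_id", "sample_id", "junction_role", "reads"}
    missing_cols = required - set(junctions.columns)
    if missing_cols:
        raise ValueError(f"junction table lacks columns {sorted(missing_cols)}")

    legal = {eid: ev.legal_roles() for eid, ev in by_id.items()}
    jid = junctions["event_id"].to_numpy()
    jrole = junctions["junction_role"].to_numpy()
    jreads = junctions["reads"].to_numpy()
    ok = np.fromiter((r in legal.get(e, frozenset()) for e, r in zip(jid, jrole)),
                     dtype=bool, count=len(jid))
    if not ok.all():
        i = int(np.flatnonzero(~ok)[0])
        if jid[i] not in by_id:
            raise ValueError(f"junction row {i}: unknown event {jid[i]!r}")
        ev = by_id[jid[i]]
        raise ValueError(
            f"junction row {i}: role {jrole[i]!r} is illegal for "
            f"{ev.event_type} event {ev.event_id!r}"
        )
    jr = np.asarray(jreads, dtype=float)
    if jr.size and ((jr < 0).any() or (jr != np.floor(jr)).any()):
        bad = int(np.flatnonzero((jr < 0) | (jr != np.floor(jr)))[0])
        raise ValueError(f"junction row {bad}: reads must be a non-negative integer")

    if sample_ids is None:
        sample_ids = sorted(junctions["sample_id"].unique())
    sample_ids = list(sample_ids)
    event_ids = [e.event_id for e in events]
    e_pos = {e: i for i, e in enumerate(event_ids)}
    s_pos = {s: j for j, s in enumerate(sample_ids)}
    shape = (len(event_ids), len(sample_ids))

    unknown = set(junctions["sample_id"].unique()) - set(sample_ids)
    if unknown:
        raise ValueError(f"junction table references undeclared samples {sorted(unknown)}")

    # sum reads per (event, sample, role) and scatter into per-role matrices
    agg = junctions.groupby(["event_id", "sample_id", "junction_role"], sort=False)[
        "reads"].sum().reset_index()
    ei_idx = agg["event_id"].map(e_pos).to_numpy()
    sj_idx = agg["sample_id"].map(s_pos).to_numpy()
    role_mats: dict[str, np.ndarray] = {}
    for role in agg["junction_role"].unique():
        m = np.zeros(shape)
        sel = (agg["junction_role"] == role).to_numpy()
        m[ei_idx[sel], sj_idx[sel]] = agg.loc[sel, "reads"].to_numpy()
        role_mats[role] = m
    present = np.zeros(shape, dtype=bool)
    present[ei_idx, sj_idx] = True

    def role(name: str) -> np.ndarray:
        return role_mats.get(name, np.zeros(shape))

    etype = np.array([e.event_type for e in events])
    is_ex, is_ir = etype == "EX", etype == "IR"
    is_alt = ~(is_ex | is_ir)

    inc_tot = np.zeros(shape)
    exc_tot = np.zeros(shape)
    inc_tot[is_ex] = (role("C1A") + role("AC2"))[is_ex]
    exc_tot[is_ex] = role("C1C2")[is_ex]
    inc_tot[is_ir] = (role("EI") + role("IE"))[is_ir]
    exc_tot[is_ir] = role("EE")[is_ir]
    v_roles = sorted((r for r in role_mats if r.startswith("V")), key=lambda r: int(r[1:]))
    if v_roles:
        inc_tot[is_alt] = role("V1")[is_alt]
        exc_tot[is_alt] = sum(role(r) for r in v_roles[1:])[is_alt] if len(v_roles) > 1 else 0.0

    # inclusion evidence: mean of the two inclusion junctions for EX/IR,
    # the focal-variant reads for ALTA/ALTD
    evidence = np.where(is_alt[:, None], inc_tot, inc_tot / 2.0)
    denom = evidence + exc_tot
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(denom > 0, 100.0 * evidence / denom, np.nan)
    psi = np.where(present, psi, np.nan)
    psi = np.round(psi, 2)

    informative = np.floor(denom).astype(int)
    tier = np.where(np.isnan(psi), TIERS[0], _tier_vec(informative, tier_cutoffs))

    bal = np.full(shape, np.nan)
    ir_rows = np.flatnonzero(is_ir)
    if ir_rows.size:
        up, dn = role("EI")[ir_rows], role("IE")[ir_rows]
        p = balance_p_twosided(up, dn)
        finite = np.isfinite(p)
        p[finite] = np.array([float(f"{v:.6g}") for v in p[finite]])
        bal[ir_rows] = p

    events_df = pd.DataFrame(
        {
            "gene_id": [e.gene_id for e in events],
            "event_type": [e.event_type for e in events],
            "coord": [e.coord for e in events],
            "n_variants": [e.n_variants for e in events],
        },
        index=pd.Index(event_ids, name="event_id"),
    )
    mk = lambda arr, dtype=float: pd.DataFrame(arr, index=events_df.index, columns=sample_ids)
    return PsiMatrix(events_df, mk(psi), mk(tier), mk(bal), mk(inc_tot), mk(exc_tot))


def filter_events(psi: PsiMatrix, min_tier: str = "LOW", min_samples: int = 10,
                  require_balance: bool = True,
                  balance_alpha: float = DEFAULT_BALANCE_ALPHA) -> PsiMatrix:
    """Coverage and read-balance filter over a PsiMatrix.

    Keeps an event iff at least ``min_samples`` samples have a present
    PSI at tier >= ``min_tier``.  When ``require_balance``, IR cells
    whose balance test rejects (p < alpha) are set missing before the
    count.  Cells without any retention-junction reads make no retention
    claim (their PSI is 0 from the spliced junction alone) and are not
    masked.  The sample set is unchanged.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if min_tier not in TIER_RANK:
        raise ValueError(f"unknown tier {min_tier!r}")
    out = psi.copy()
    if require_balance:
        ir_ids = out.events.index[out.events["event_type"].eq("IR")]
        failed = out.balance_p.loc[ir_ids].lt(balance_alpha)
        out.psi.loc[ir_ids] = out.psi.loc[ir_ids].mask(failed)
    usable = out.covered(min_tier).sum(axis=1)
    keep = usable[usable >= min_samples].index
    return out.restrict(keep)
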