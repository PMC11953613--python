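"""Independent straight-line evaluators of the specificity criteria.

Deliberately naive re-implementations used only to cross-check the
package's callers: plain loops, no shared code with the package.
"""
from __future__ import annotations

import math


def oracle_call_dse(psi_rows, samples, th):
    """psi_rows: {event_id: {sample_id: value or None}};
    samples: list of (sample_id, cell_type, organ).
    Returns {(event_id, cell_type, organ): (dpsi_global, dpsi_min, psi_range, direction)}.
    """
    organs = sorted({o for _, _, o in samples})
    out = {}
    for organ in organs:
        org = [(sid, ct) for sid, ct, o in samples if o == organ]
        cts = []
        for _, ct in org:
            if ct not in cts:
                cts.append(ct)
        for eid, row in psi_rows.items():
            vals = {ct: [row[sid] for sid, c in org if c == ct and row.get(sid) is not None]
                    for ct in cts}
            eligible = [ct for ct in cts if len(vals[ct]) >= th.min_replicates]
            if len(eligible) < th.min_cell_types:
                continue
            maxima = [max(vals[ct]) for ct in cts if len(vals[ct]) >= 1]
            if len(maxima) < 2:
                continue
            prange = max(maxima) - min(maxima)
            for target in eligible:
                tvals = vals[target]
                others = [v for ct in cts if ct != target for v in vals[ct]]
                if not others:
                    continue
                g = sum(tvals) / len(tvals) - sum(others) / len(others)
                diffs = []
                for ct in cts:
                    if ct != target and len(vals[ct]) >= th.min_replicates:
                        diffs.append(sum(tvals) / len(tvals) - sum(vals[ct]) / len(vals[ct]))
                if not diffs:
                    continue
                best = None
                for d in diffs:
                    if best is None or abs(d) < abs(best) or (abs(d) == abs(best) and d < best):
                        best = d
                if th.strict_dpsi:
                    ok = abs(g) > th.global_dpsi and abs(best) > th.min_dpsi
                else:
                    ok = abs(g) >= th.global_dpsi and abs(best) >= th.min_dpsi
                ok = ok and prange >= th.min_psi_range
                if th.require_sign_coherence:
                    ok = ok and ((g > 0) == (best > 0) or best == 0)
                if ok:
                    out[(eid, target, organ)] = (g, best, prange,
                                                 "up" if g > 0 else "down")
    return out


def oracle_call_deg(crpkm_rows, samples, th):
    """crpkm_rows: {gene_id: {sample_id: value}};
    samples: list of (sample_id, cell_type, organ).
    Returns {(gene_id, cell_type, organ): direction}.
    """

    def median(xs):
        xs = sorted(xs)
        k = len(xs)
        return xs[k // 2] if k % 2 else (xs[k // 2 - 1] + xs[k // 2]) / 2.0

    organs = sorted({o for _, _, o in samples})
    out = {}
    for organ in organs:
        org = [(sid, ct) for sid, ct, o in samples if o == organ]
        cts = []
        for _, ct in org:
            if ct not in cts:
                cts.append(ct)
        if len(cts) < 2:
            continue
        for gene, row in crpkm_rows.items():
            med = {ct: median([row[sid] for sid, c in org if c == ct]) for ct in cts}
            if max(med.values()) < th.deg_min_median_crpkm:
                continue
            for target in cts:
                mt = med[target]
                ok = True
                for ct in cts:
                    if ct == target:
                        continue
                    mo = med[ct]
                    fc = (mt + th.pseudocount) / (mo + th.pseudocount)
                    if not (fc >= th.deg_fc_each or fc <= 1.0 / th.deg_fc_each):
                        ok = False
                    if abs(mt - mo) < th.deg_abs_diff:
                        ok = False
                if not ok:
                    continue
                pooled = [row[sid] for sid, ct in org if ct != target]
                mg = median(pooled)
                fcg = (mt + th.pseudocount) / (mg + th.pseudocount)
                if fcg >= th.deg_fc_global or fcg <= 1.0 / th.deg_fc_global:
                    out[(gene, target, organ)] = "up" if mt > mg else "down"
    return out


def binom_pmf(k: int, n: int, p: float) -> float:
    return math.comb(n, k) * p**k * (1 - p) ** (n - k)


def oracle_binomial_two_sided(k: int, n: int) -> float:
    """Two-sided exact binomial p at p0 = 0.5 by pmf summation over
    outcomes at most as probable as the observed one."""
    obs = binom_pmf(k, n, 0.5)
    return sum(binom_pmf(i, n, 0.5) for i in range(n + 1)
               if binom_pmf(i, n, 0.5) <= obs * (1 + 1e-12))


def hypergeom_pmf(x: int, N: int, K: int, n: int) -> float:
    if x < max(0, n + K - N) or x > min(K, n):
        return 0.0
    return math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)


def oracle_hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by direct pmf summation."""
    return sum(hypergeom_pmf(x, N, K, n) for x in range(k, min(K, n) + 1))
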