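"""Seeded synthetic datasets with planted cell-type-specific signals.

The generator emulates the study design the callers target: 11 cell
types split across two organs (7 root, 4 aerial), a few replicates each,
four splicing-event classes with intron retention dominant, and
dispersed measurements around per-event baselines.

Splicing layer.  Each event draws a baseline PSI from a J-shaped Beta
distribution concentrated at low inclusion (the typical profile of
plant intron retention) and clipped to [1, 99].  A planted event shifts
the baseline by +/- ``planted_dpsi`` in exactly one cell type.  Per
sample, the realized PSI is Beta-distributed around the cell-type truth
with intra-class correlation ``bb_dispersion`` (a = mu(1-rho)/rho,
b = (1-mu)(1-rho)/rho), and junction reads are Poisson: each inclusion
junction at rate depth * psi and the exclusion junction at rate
depth * (1 - psi), so the PSI estimator is consistent in expectation
and the two intron-retention junctions are, conditional on their sum,
an even binomial split.

Expression layer.  Each gene draws a relative abundance from a
log-normal; counts are negative-binomial around library_size *
abundance with gamma-Poisson dispersion ``nb_dispersion``; a planted
gene multiplies (or divides) its mean by ``planted_fc`` in one cell
type.  Mappable lengths are log-normal integers.

Planted splicing and expression signals are placed on disjoint genes,
assigned to cell types round-robin so every cell type receives signal.
Everything is reproducible from the seed.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .models import GeneSet, SampleInfo, SpliceEvent

log = logging.getLogger("cellsplice")

ROOT_CELL_TYPES = ("pATHB8", "pSCR", "pTMO5", "pPXY", "pCASP1", "pSMXL5", "pAPL")
AERIAL_CELL_TYPES = ("pML1", "pREV", "pUFO", "pLTP1")

#: Event-class mix with intron retention dominant, matching the
#: prevalence ranking seen in plant splicing surveys.
DEFAULT_EVENT_MIX: Mapping[str, float] = {"IR": 0.65, "ALTA": 0.17, "EX": 0.10, "ALTD": 0.08}

IMPACT_PROBS = {"ORF_disruption": 0.55, "alternative_isoform": 0.29,
                "UTR_overlap": 0.11, "unknown": 0.05}


@dataclass
class SimConfig:
    """Study-design and noise parameters of the generator."""

    n_cell_types_root: int = 7
    n_cell_types_aerial: int = 4
    replicates: int = 3
    n_events: Mapping[str, int] = field(
        default_factory=lambda: {"IR": 650, "ALTA": 170, "EX": 100, "ALTD": 80})
    frac_specific: float = 0.2
    planted_dpsi: float = 40.0
    #: Beta(a, b) shape of the baseline PSI draw (on [0, 1], scaled x100).
    baseline_beta: tuple[float, float] = (0.3, 1.2)
    #: Intra-class correlation rho of the per-sample Beta PSI draw.
    bb_dispersion: float = 0.02
    #: Expected informative junction reads per event per sample.
    depth_mean: float = 100.0
    n_genes: int = 2000
    frac_specific_genes: float = 0.1
    planted_fc: float = 8.0
    #: Gamma-Poisson dispersion: Var = mu + dispersion * mu^2.
    nb_dispersion: float = 0.1
    library_size_mean: float = 5e6
    #: log-normal parameters of per-gene relative abundance.
    abundance_log_mean: float = math.log(1e-4)
    abundance_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_specific <= 1 or not 0 <= self.frac_specific_genes <= 1:
            raise ValueError("planted fractions must lie in [0, 1]")
        if not 0 < self.planted_dpsi < 100:
            raise ValueError("planted_dpsi must lie in (0, 100)")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if not 0 <= self.bb_dispersion < 1:
            raise ValueError("bb_dispersion must lie in [0, 1)")

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class SimResult:
    """Everything one simulated study comprises."""

    config: SimConfig
    samples: list[SampleInfo]
    events: list[SpliceEvent]
    junctions: pd.DataFrame
    truth: pd.DataFrame       # feature_id, kind, cell_type, direction, effect_size
    counts: pd.DataFrame      # gene x sample raw counts
    mappable: pd.Series
    impact: dict[str, str]
    gene_sets: dict[str, GeneSet]
    term_sets: dict[str, GeneSet]
    #: per-sample true PSI per event (events x samples), for calibration checks
    true_psi: pd.DataFrame


def _cell_type_names(config: SimConfig) -> list[tuple[str, str]]:
    names: list[tuple[str, str]] = []
    for i in range(config.n_cell_types_root):
        base = ROOT_CELL_TYPES[i] if i < len(ROOT_CELL_TYPES) else f"pROOT{i + 1}"
        names.append((base, "root"))
    for i in range(config.n_cell_types_aerial):
        base = AERIAL_CELL_TYPES[i] if i < len(AERIAL_CELL_TYPES) else f"pAERIAL{i + 1}"
        names.append((base, "aerial"))
    if len(names) < 2:
        raise ValueError("need at least two cell types")
    return names


def make_samples(config: SimConfig) -> list[SampleInfo]:
    samples = []
    for ct, organ in _cell_type_names(config):
        for rep in range(1, config.replicates + 1):
            samples.append(SampleInfo(sample_id=f"{ct}_r{rep}", cell_type=ct,
                                      organ=organ, replicate=rep))
    return samples


def _beta_around(rng: np.random.Generator, mean01: np.ndarray, rho: float) -> np.ndarray:
    if rho <= 0:
        return mean01.copy()
    a = mean01 * (1 - rho) / rho
    b = (1 - mean01) * (1 - rho) / rho
    return rng.beta(a, b)


def _draw_baseline(rng: np.random.Generator, config: SimConfig) -> float:
    a, b = config.baseline_beta
    return float(np.clip(rng.beta(a, b) * 100.0, 1.0, 99.0))


def _plant_baseline(rng: np.random.Generator, config: SimConfig) -> tuple[float, str, int]:
    """(baseline, direction) with baseline redrawn until the shift fits in
    [1, 99]; returns the redraw count as third element."""
    direction = "up" if rng.random() < 0.5 else "down"
    shift = config.planted_dpsi if direction == "up" else -config.planted_dpsi
    redraws = 0
    while True:
        base = _draw_baseline(rng, config)
        if 1.0 <= base + shift <= 99.0:
            return base, direction, redraws
        redraws += 1
        if redraws > 10_000:
            raise RuntimeError("cannot place planted shift; baseline distribution too extreme")


def simulate_dataset(config: SimConfig) -> SimResult:
    """Generate one full synthetic study (see the module docstring)."""
    rng = np.random.default_rng(config.seed)
    samples = make_samples(config)
    cell_types = [ct for ct, _ in _cell_type_names(config)]
    sample_ids = [s.sample_id for s in samples]

    # ---- gene universe -------------------------------------------------
    genes = [f"AT{i + 1:07d}" for i in range(config.n_genes)]
    n_planted_genes = int(round(config.frac_specific_genes * config.n_genes))
    planted_gene_ids = genes[:n_planted_genes]  # ids are arbitrary labels
    free_genes = genes[n_planted_genes:]

    # ---- splicing events ----------------------------------------------
    events: list[SpliceEvent] = []
    idx = 0
    for etype in ("IR", "ALTA", "ALTD", "EX"):
        for _ in range(int(config.n_events.get(etype, 0))):
            start = 1000 + idx * 500
            gene = free_genes[idx % len(free_genes)] if free_genes else genes[idx % len(genes)]
            events.append(SpliceEvent(
                event_id=f"SIM{etype}{idx:05d}", gene_id=gene, event_type=etype,
                coord=f"chr{idx % 5 + 1}:{start}-{start + 299}", n_variants=2))
            idx += 1

    n_planted_events = int(round(config.frac_specific * len(events)))
    planted_order = rng.permutation(len(events))[:n_planted_events]

    truth_rows = []
    baseline = np.empty(len(events))
    planted_ct = [None] * len(events)
    planted_dir = [None] * len(events)
    total_redraws = 0
    for rank, ei in enumerate(sorted(planted_order)):
        base, direction, redraws = _plant_baseline(rng, config)
        total_redraws += redraws
        baseline[ei] = base
        planted_ct[ei] = cell_types[rank % len(cell_types)]
        planted_dir[ei] = direction
    if total_redraws:
        log.info("planted-baseline redraws: %d", total_redraws)
    for ei in range(len(events)):
        if planted_ct[ei] is None:
            baseline[ei] = _draw_baseline(rng, config)

    for ei, ev in enumerate(events):
        if planted_ct[ei] is not None:
            truth_rows.append((ev.event_id, "event", planted_ct[ei], planted_dir[ei],
                               config.planted_dpsi))

    # per-(event, cell type) true PSI
    true_ct = np.tile(baseline[:, None], (1, len(cell_types)))
    ct_pos = {ct: j for j, ct in enumerate(cell_types)}
    for ei in range(len(events)):
        if planted_ct[ei] is not None:
            shift = config.planted_dpsi if planted_dir[ei] == "up" else -config.planted_dpsi
            true_ct[ei, ct_pos[planted_ct[ei]]] = baseline[ei] + shift

    # per-(event, sample) realized PSI and junction reads; with two
    # competing outcomes per event, every event has an inclusion-side
    # rate depth*psi (per junction) and an exclusion-side rate
    # depth*(1-psi), so the three role draws vectorize across events
    etypes = np.array([e.event_type for e in events])
    eids = np.array([e.event_id for e in events])
    role1 = np.where(etypes == "EX", "C1A", np.where(etypes == "IR", "EI", "V1"))
    role2 = np.where(etypes == "EX", "AC2", np.where(etypes == "IR", "IE", ""))
    role3 = np.where(etypes == "EX", "C1C2", np.where(etypes == "IR", "EE", "V2"))
    has_role2 = role2 != ""

    true_sample = np.empty((len(events), len(sample_ids)))
    frames = []
    for j, s in enumerate(samples):
        mu = true_ct[:, ct_pos[s.cell_type]] / 100.0
        p = np.clip(_beta_around(rng, mu, config.bb_dispersion), 0.0, 1.0)
        true_sample[:, j] = 100.0 * p
        inc_rate = config.depth_mean * p
        exc_rate = config.depth_mean * (1.0 - p)
        r1 = rng.poisson(inc_rate)
        r2 = np.where(has_role2, rng.poisson(inc_rate), 0)
        r3 = rng.poisson(exc_rate)
        for role_arr, reads in ((role1, r1), (role2, r2), (role3, r3)):
            keep = (reads > 0) & (role_arr != "")
            frames.append(pd.DataFrame({
                "event_id": eids[keep], "sample_id": s.sample_id,
                "junction_role": role_arr[keep], "reads": reads[keep].astype(int)}))
    junctions = (pd.concat(frames, ignore_index=True)
                 .sort_values(["event_id", "sample_id", "junction_role"], kind="stable")
                 .reset_index(drop=True))

    # ---- gene expression -----------------------------------------------
    abundance = np.exp(rng.normal(config.abundance_log_mean, config.abundance_log_sd,
                                  config.n_genes))
    mappable = pd.Series(
        np.clip(np.exp(rng.normal(math.log(2000), 0.4, config.n_genes)), 200, None).astype(int),
        index=pd.Index(genes, name="gene_id"), name="mappable_positions")

    gene_ct = [None] * config.n_genes
    gene_dir = [None] * config.n_genes
    gpos = {g: i for i, g in enumerate(genes)}
    for rank, g in enumerate(planted_gene_ids):
        gene_ct[gpos[g]] = cell_types[rank % len(cell_types)]
        gene_dir[gpos[g]] = "up" if rng.random() < 0.5 else "down"
        truth_rows.append((g, "gene", gene_ct[gpos[g]], gene_dir[gpos[g]], config.planted_fc))

    counts = np.empty((config.n_genes, len(sample_ids)), dtype=np.int64)
    disp = config.nb_dispersion
    for j, s in enumerate(samples):
        lib = config.library_size_mean * float(rng.normal(1.0, 0.05))
        mu = abundance * lib
        fc_mask_up = np.array([ct == s.cell_type and d == "up"
                               for ct, d in zip(gene_ct, gene_dir)])
        fc_mask_dn = np.array([ct == s.cell_type and d == "down"
                               for ct, d in zip(gene_ct, gene_dir)])
        mu = mu * np.where(fc_mask_up, config.planted_fc, 1.0)
        mu = mu / np.where(fc_mask_dn, config.planted_fc, 1.0)
        if disp > 0:
            shape = 1.0 / disp
            lam = rng.gamma(shape, mu / shape)
        else:
            lam = mu
        counts[:, j] = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                             columns=sample_ids)

    # ---- annotations ---------------------------------------------------
    classes = list(IMPACT_PROBS)
    probs = np.array([IMPACT_PROBS[c] for c in classes])
    impact = {ev.event_id: classes[k]
              for ev, k in zip(events, rng.choice(len(classes), len(events), p=probs))}

    n_imm = max(1, int(round(0.15 * config.n_genes)))
    immunity = rng.choice(genes, size=n_imm, replace=False)
    gene_sets = {"immunity": GeneSet.from_iterable("immunity", immunity)}

    term_sets: dict[str, GeneSet] = {}
    n_terms, term_size = 20, max(10, config.n_genes // 40)
    for t in range(n_terms):
        members = rng.choice(genes, size=term_size, replace=False)
        term_sets[f"GO:{t + 1:07d}"] = GeneSet.from_iterable(f"GO:{t + 1:07d}", members)

    truth = pd.DataFrame(truth_rows,
                         columns=["feature_id", "kind", "cell_type", "direction",
                                  "effect_size"])
    true_psi = pd.DataFrame(true_sample,
                            index=pd.Index([e.event_id for e in events], name="event_id"),
                            columns=sample_ids)
    return SimResult(config=config, samples=samples, events=events, junctions=junctions,
                     truth=truth, counts=counts_df, mappable=mappable, impact=impact,
                     gene_sets=gene_sets, term_sets=term_sets, true_psi=true_psi)


def write_dataset(result: SimResult, outdir: str | Path) -> None:
    """Write every standard table of one simulated study to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cio.write_sample_sheet(result.samples, outdir / "samples.tsv")
    cio.write_events_table(result.events, outdir / "events.tsv")
    cio.write_junction_counts(result.junctions, outdir / "junctions.tsv")
    cio.write_count_matrix(result.counts, result.mappable, outdir / "counts.tsv")
    cio.write_impact_table(result.impact, outdir / "impact.tsv")
    for name, gs in result.gene_sets.items():
        cio.write_gene_list(gs, outdir / f"geneset_{name}.txt")
    cio.write_term_sets(result.term_sets, outdir / "terms.tsv")
    result.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def truth_recovery(calls: Sequence, truth: pd.DataFrame, kind: str = "event") -> dict:
    """Precision/recall/direction accuracy of calls against planted truth.

    A true positive requires matching feature id AND cell type; direction
    accuracy is computed over true positives.  Precision is NaN when
    there are no calls.
    """
    planted = truth[truth["kind"] == kind]
    planted_map = {(r.feature_id, r.cell_type): r.direction
                   for r in planted.itertuples(index=False)}
    call_keys = []
    for c in calls:
        fid = c.event_id if kind == "event" else c.gene_id
        call_keys.append(((fid, c.cell_type), c.direction))
    tp = [(key, d) for key, d in call_keys if key in planted_map]
    n_tp = len({key for key, _ in tp})
    precision = n_tp / len(call_keys) if call_keys else math.nan
    recall = n_tp / len(planted_map) if planted_map else math.nan
    dir_ok = sum(1 for key, d in tp if planted_map[key] == d)
    return {
        "n_calls": len(call_keys),
        "n_planted": len(planted_map),
        "true_positives": n_tp,
        "precision": precision,
        "recall": recall,
        "direction_accuracy": dir_ok / len(tp) if tp else math.nan,
    }
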