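"""Core domain types shared across the pipeline.

The pipeline quantifies alternative splicing as percent-spliced-in (PSI)
per event per sample, annotates every value with a read-coverage tier and
(for intron retention) a junction read-balance p-value, and calls
cell-type-specific splicing and expression differences per organ.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

# Alternative-splicing event classes: intron retention, exon skipping,
# alternative acceptor and alternative donor sites.
EVENT_TYPES = ("IR", "EX", "ALTA", "ALTD")

# Read-coverage tiers, ordered from no coverage to strong coverage.
TIERS = ("N", "VLOW", "LOW", "OK", "SOK")
TIER_RANK = {t: i for i, t in enumerate(TIERS)}

ORGANS = ("root", "aerial")

# Junction roles legal per event type.  EX: the two inclusion junctions
# (upstream exon to alternative exon, alternative exon to downstream exon)
# and the skipping junction.  IR: the two exon-intron junctions and the
# spliced exon-exon junction.  ALTA/ALTD: one junction per competing
# variant, V1 being the focal variant whose PSI is reported.
EX_ROLES = ("C1A", "AC2", "C1C2")
IR_ROLES = ("EI", "IE", "EE")

IMPACT_CLASSES = ("ORF_disruption", "alternative_isoform", "UTR_overlap", "unknown")


def _parse_coord(coord: str) -> tuple[str, int, int]:
    chrom, _, span = coord.partition(":")
    lo, _, hi = span.partition("-")
    return chrom, int(lo), int(hi)


@dataclass(frozen=True)
class SpliceEvent:
    """One alternative-splicing event: identity, owning gene and class.

    ``coord`` is ``chrom:start-end`` with 1-based inclusive ends.
    ``n_variants`` is the number of competing splice outcomes (2 for
    IR/EX, >=2 for ALTA/ALTD).
    """

    event_id: str
    gene_id: str
    event_type: str
    coord: str
    n_variants: int = 2

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r} for {self.event_id}")
        if self.n_variants < 2:
            raise ValueError(f"{self.event_id}: n_variants must be >= 2")
        _, lo, hi = _parse_coord(self.coord)
        if lo > hi:
            raise ValueError(f"{self.event_id}: coord start {lo} > end {hi}")

    def legal_roles(self) -> frozenset[str]:
        if self.event_type == "EX":
            return frozenset(EX_ROLES)
        if self.event_type == "IR":
            return frozenset(IR_ROLES)
        return frozenset(f"V{i + 1}" for i in range(self.n_variants))


@dataclass(frozen=True)
class SampleInfo:
    """One sequenced sample: a replicate of one cell type in one organ."""

    sample_id: str
    cell_type: str
    organ: str
    replicate: int

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise ValueError(
                f"sample {self.sample_id!r}: organ must be one of {ORGANS}, got {self.organ!r}"
            )
        if self.replicate < 1:
            raise ValueError(f"sample {self.sample_id!r}: replicate must be >= 1")


def validate_samples(samples: Iterable[SampleInfo]) -> list[SampleInfo]:
    """Check cross-sample invariants: unique ids, unique (cell type,
    replicate) pairs, and a single organ per cell type."""
    samples = list(samples)
    seen_ids: set[str] = set()
    seen_pairs: set[tuple[str, int]] = set()
    organ_of: dict[str, str] = {}
    for s in samples:
        if s.sample_id in seen_ids:
            raise ValueError(f"duplicate sample_id {s.sample_id!r}")
        seen_ids.add(s.sample_id)
        pair = (s.cell_type, s.replicate)
        if pair in seen_pairs:
            raise ValueError(f"duplicate (cell_type, replicate) {pair!r}")
        seen_pairs.add(pair)
        if organ_of.setdefault(s.cell_type, s.organ) != s.organ:
            raise ValueError(f"cell type {s.cell_type!r} maps to more than one organ")
    return samples


@dataclass
class SpecificityThresholds:
    """Rule thresholds for the cell-type-specific callers.

    Splicing: a call needs |global dPSI| > ``global_dpsi`` (target cell
    type vs all other same-organ samples pooled), |minimum dPSI| >
    ``min_dpsi`` (vs every other covered cell type), and a PSI range >=
    ``min_psi_range`` across cell-type maxima.  Expression: median cRPKM
    >= ``deg_min_median_crpkm`` in some cell type, fold change >=
    ``deg_fc_each`` vs each other cell-type median, >= ``deg_fc_global``
    vs the pooled median of all other samples, and an absolute cRPKM
    difference >= ``deg_abs_diff`` vs every other cell-type median.
    """

    global_dpsi: float = 25.0
    min_dpsi: float = 15.0
    min_psi_range: float = 2.0
    min_replicates: int = 2
    min_cell_types: int = 4
    deg_min_median_crpkm: float = 5.0
    deg_fc_each: float = 2.0
    deg_fc_global: float = 5.0
    deg_abs_diff: float = 2.0
    pseudocount: float = 0.01
    # Strict '>' for the two dPSI magnitude rules ('>=' when False).
    strict_dpsi: bool = True
    # Require sign(dpsi_global) == sign(dpsi_min) when True.
    require_sign_coherence: bool = False

    def __post_init__(self) -> None:
        positives = (
            self.global_dpsi, self.min_dpsi, self.min_psi_range,
            self.min_replicates, self.min_cell_types,
            self.deg_min_median_crpkm, self.deg_fc_each,
            self.deg_fc_global, self.deg_abs_diff,
        )
        if any(v <= 0 for v in positives):
            raise ValueError("all specificity thresholds must be strictly positive")
        if self.min_dpsi > self.global_dpsi:
            raise ValueError("min_dpsi must not exceed global_dpsi")

    def replace(self, **kw) -> "SpecificityThresholds":
        return replace(self, **kw)


@dataclass(frozen=True)
class SpecificCall:
    """One cell-type-specific splicing call (a DSE) with its criterion values."""

    event_id: str
    cell_type: str
    organ: str
    dpsi_global: float
    dpsi_min: float
    psi_range: float
    direction: str  # "up" | "down", sign of dpsi_global
    criteria_passed: Mapping[str, bool] = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class DegCall:
    """One cell-type-specific expression call (a DEG) with its criterion values."""

    gene_id: str
    cell_type: str
    organ: str
    log2_fc_global: float
    direction: str  # "up" | "down", sign of the global comparison
    median_target: float
    global_median_others: float


@dataclass(frozen=True)
class BalanceResult:
    """Exact binomial read-balance test at one retained intron.

    ``passed`` means the upstream/downstream exon-intron junction reads
    are consistent with an even split, i.e. p_value >= alpha.
    """

    p_value: float  # NaN when there is no read evidence at all
    n_upstream: int
    n_downstream: int
    passed: bool


@dataclass(frozen=True)
class GeneSet:
    """A named, duplicate-free set of gene identifiers."""

    name: str
    members: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str]) -> "GeneSet":
        return cls(name=name, members=frozenset(genes))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation of one term in a gene list vs a background.

    k: list genes in the term; K: background genes in the term; n: list
    size; N: background size.  ``ease_p`` is the conservative variant of
    the one-tailed hypergeometric ``fisher_p`` computed after removing
    one gene from the observed overlap; ease_p >= fisher_p always.
    """

    term: str
    k: int
    K: int
    n: int
    N: int
    ease_p: float
    fisher_p: float
    fold_enrichment: float
    ease_p_bh: float = float("nan")


class PsiMatrix:
    """Event x sample PSI values with coverage and balance annotations.

    All five panels are pandas DataFrames indexed by event_id with one
    column per sample_id, kept in lock-step:

    - ``psi``: percent in [0, 100], NaN where missing;
    - ``tier``: coverage tier string (N < VLOW < LOW < OK < SOK);
    - ``balance_p``: IR read-balance p-value (NaN for non-IR events and
      for IR cells without junction evidence);
    - ``inc`` / ``exc``: summed inclusion / exclusion junction reads.

    ``events`` is a DataFrame indexed by event_id with columns gene_id,
    event_type, coord, n_variants.
    """

    def __init__(self, events: pd.DataFrame, psi: pd.DataFrame, tier: pd.DataFrame,
                 balance_p: pd.DataFrame, inc: pd.DataFrame, exc: pd.DataFrame) -> None:
        idx, cols = psi.index, psi.columns
        for name, df in (("tier", tier), ("balance_p", balance_p), ("inc", inc), ("exc", exc)):
            if not (df.index.equals(idx) and df.columns.equals(cols)):
                raise ValueError(f"panel {name!r} is not aligned with psi")
        if not events.index.equals(idx):
            raise ValueError("events index does not match psi index")
        bad = psi.to_numpy(dtype=float)
        bad = bad[np.isfinite(bad)]
        if bad.size and (bad.min() < 0 or bad.max() > 100):
            raise ValueError("PSI values must lie in [0, 100]")
        self.events = events
        self.psi = psi
        self.tier = tier
        self.balance_p = balance_p
        self.inc = inc
        self.exc = exc

    @property
    def sample_ids(self) -> list[str]:
        return list(self.psi.columns)

    @property
    def event_ids(self) -> list[str]:
        return list(self.psi.index)

    def tier_rank(self) -> pd.DataFrame:
        return self.tier.apply(lambda col: col.map(TIER_RANK))

    def covered(self, min_tier: str = "LOW") -> pd.DataFrame:
        """Boolean mask: PSI present and coverage tier >= min_tier."""
        return self.psi.notna() & (self.tier_rank() >= TIER_RANK[min_tier])

    def restrict(self, event_ids: Iterable[str]) -> "PsiMatrix":
        ids = [e for e in self.event_ids if e in set(event_ids)]
        return PsiMatrix(
            self.events.loc[ids], self.psi.loc[ids], self.tier.loc[ids],
            self.balance_p.loc[ids], self.inc.loc[ids], self.exc.loc[ids],
        )

    def copy(self) -> "PsiMatrix":
        return PsiMatrix(self.events.copy(), self.psi.copy(), self.tier.copy(),
                         self.balance_p.copy(), self.inc.copy(), self.exc.copy())

    def equals(self, other: "PsiMatrix") -> bool:
        def _num_eq(a: pd.DataFrame, b: pd.DataFrame) -> bool:
            if not (a.index.equals(b.index) and a.columns.equals(b.columns)):
                return False
            x, y = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
            return bool(np.all((x == y) | (np.isnan(x) & np.isnan(y))))

        return (
            self.events.equals(other.events)
            and _num_eq(self.psi, other.psi)
            and self.tier.equals(other.tier)
            and _num_eq(self.balance_p, other.balance_p)
            and _num_eq(self.inc, other.inc)
            and _num_eq(self.exc, other.exc)
        )
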