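from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cellsplice import ExpressionMatrix, PsiMatrix, SampleInfo, quantify
from cellsplice.simulate import SimConfig, simulate_dataset


def make_psi_matrix(values: pd.DataFrame, event_types: dict[str, str] | None = None,
                    tier: str = "OK") -> PsiMatrix:
    """Wrap a plain event x sample PSI DataFrame into a PsiMatrix with
    every present value covered at the given tier."""
    event_types = event_types or {}
    events = pd.DataFrame(
        {
            "gene_id": [f"G{e}" for e in values.index],
            "event_type": [event_types.get(e, "EX") for e in values.index],
            "coord": [f"chr1:{100 + i}-{200 + i}" for i in range(len(values))],
            "n_variants": 2,
        },
        index=pd.Index(values.index, name="event_id"),
    )
    tier_df = values.where(values.isna(), other=tier).fillna("N")
    nan = values * np.nan
    zero = values.fillna(0.0) * 0.0
    return PsiMatrix(events, values.astype(float), tier_df.astype(object), nan, zero, zero)


def make_samples(cell_types: dict[str, int], organ: str = "root",
                 prefix: str = "") -> list[SampleInfo]:
    """cell_types: {cell_type: n_replicates} -> sample list with ids
    '<ct>_r<k>'."""
    out = []
    for ct, reps in cell_types.items():
        for r in range(1, reps + 1):
            out.append(SampleInfo(sample_id=f"{prefix}{ct}_r{r}", cell_type=ct,
                                  organ=organ, replicate=r))
    return out


@pytest.fixture(scope="session")
def recovery_sim():
    """Default recovery-study simulation: one organ, 4 cell types x 3
    replicates, 1000 events (200 planted at dPSI 40), 2000 genes (200
    planted at 8-fold)."""
    cfg = SimConfig(n_cell_types_root=4, n_cell_types_aerial=0, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def recovery_psi(recovery_sim):
    return quantify(recovery_sim.junctions, recovery_sim.events,
                    sample_ids=[s.sample_id for s in recovery_sim.samples])


@pytest.fixture(scope="session")
def recovery_expr(recovery_sim):
    return ExpressionMatrix.from_raw(recovery_sim.counts, recovery_sim.mappable)
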