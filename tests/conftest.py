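"""Shared fixtures: tiny hand-built panels and session-scoped simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from seedgwas import genio, simdata
from seedgwas.panel import GenotypePanel


def make_panel(
    columns: list[list[float]],
    positions: list[int] | None = None,
    chrom: str = "Chr01",
    line_prefix: str = "L",
) -> GenotypePanel:
    """Panel from explicit dosage columns (one list per marker)."""
    dosage = np.array(columns, dtype=float).T
    n_lines, m = dosage.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    markers = pd.DataFrame(
        {
            "id": [f"{chrom}:{p}" for p in positions],
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "T",
            "major": "A",
            "minor": "T",
        }
    )
    return GenotypePanel(
        line_ids=[f"{line_prefix}{i + 1:03d}" for i in range(n_lines)],
        markers=markers,
        dosage=dosage,
    )


@pytest.fixture(scope="session")
def small_sim() -> simdata.GenotypeSim:
    """80-line, 400-marker structured panel reused by read-only tests."""
    cfg = simdata.SimConfig(
        n_lines=80,
        n_subpops=2,
        fst=0.2,
        chrom_lengths=(2_000_000, 2_000_000),
        n_snps=400,
        ld_persist=0.9,
        missing_rate=0.05,
        het_rate=0.02,
        seed=11,
    )
    return simdata.simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def big_unlinked_sim() -> simdata.GenotypeSim:
    """500-line panel with ld_persist=0 (independent markers), no call noise."""
    cfg = simdata.SimConfig(
        n_lines=500,
        n_subpops=2,
        fst=0.1,
        chrom_lengths=(6_000_000,),
        n_snps=1200,
        ld_persist=0.0,
        missing_rate=0.0,
        het_rate=0.0,
        seed=17,
    )
    return simdata.simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def small_filtered(small_sim):
    return genio.filter_markers(small_sim.panel)
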