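"""Effective number of independent tests via windowed LD pruning.

Linked markers make a plain Bonferroni correction over-conservative, so the
genome-wide level is set to alpha divided by the number of markers surviving
PLINK-style indep-pairwise pruning (physical window, r^2 ceiling, step in
kept SNPs). Removal prefers the lower-MAF member of an over-correlated pair;
ties break toward the later position, pinned here for determinism.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._util import UserInputError, logger, round_half_up
from .panel import GenotypePanel

__all__ = [
    "MultiplicityResult",
    "dosage_r2",
    "pairwise_r2",
    "prune_indep_pairwise",
    "adjusted_threshold",
]


@dataclasses.dataclass
class MultiplicityResult:
    """Effective-test count and the resulting family-wise threshold."""

    m_total: int
    m_eff: int
    alpha: float
    threshold: float
    eff_fraction_pct: float  # m_eff/m_total as a percent, one decimal

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def pairwise_r2(D: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns, pairwise-complete.

    Pairs where either column has zero variance over the joint non-missing
    lines are undefined and reported as 0 (logged).
    """
    D = np.asarray(D, dtype=float)
    M = (~np.isnan(D)).astype(float)
    X = np.nan_to_num(D)
    n = M.T @ M
    Sx = X.T @ M
    Sxx = (X * X).T @ M
    Sxy = X.T @ X
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * Sxy - Sx * Sx.T
        varx = n * Sxx - Sx**2
        denom = varx * varx.T
        r2 = np.where(denom > 0, cov**2 / denom, np.nan)
    undef = ~np.isfinite(r2)
    if undef.any():
        logger.debug("pairwise_r2: %d undefined pairs treated as 0", int(undef.sum()))
    r2 = np.where(undef, 0.0, np.clip(r2, 0.0, 1.0))
    return r2


def dosage_r2(panel: GenotypePanel, i: int, j: int) -> float:
    """r^2 between two markers over pairwise-complete lines."""
    D = panel.dosage[:, [i, j]]
    ok = ~np.isnan(D).any(axis=1)
    if ok.sum() < 2:
        logger.info("dosage_r2: <2 complete lines for (%d, %d); returning 0", i, j)
        return 0.0
    x, y = D[ok, 0], D[ok, 1]
    if x.std() == 0 or y.std() == 0:
        logger.info("dosage_r2: zero variance at (%d, %d); returning 0", i, j)
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _maf(panel: GenotypePanel) -> np.ndarray:
    p = panel.minor_freq()
    return np.minimum(p, 1.0 - p)


def prune_indep_pairwise(
    panel: GenotypePanel,
    window_kb: float = 100.0,
    step_snps: int = 10,
    r2_max: float = 0.8,
) -> np.ndarray:
    """Deterministic windowed LD pruning; returns kept marker indices.

    Per chromosome: take the sliding physical window of ``window_kb`` kbp
    anchored at the current kept marker; while any kept pair inside exceeds
    ``r2_max`` (strictly), remove the lower-MAF member of the currently
    most-correlated pair (MAF tie -> later position); then advance the anchor
    by ``step_snps`` kept markers.
    """
    kept = np.ones(panel.n_markers, dtype=bool)
    maf = _maf(panel)
    pos = panel.markers["pos"].to_numpy()
    window_bp = window_kb * 1000.0
    for chrom, sub in panel.markers.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        anchor = 0
        while True:
            kept_idx = idx[kept[idx]]
            if anchor >= len(kept_idx):
                break
            w0 = kept_idx[anchor]
            in_win = kept_idx[
                (pos[kept_idx] >= pos[w0]) & (pos[kept_idx] <= pos[w0] + window_bp)
            ]
            _prune_window(panel, in_win, kept, maf, pos, r2_max)
            anchor += step_snps
    return np.flatnonzero(kept)


def _prune_window(panel, win, kept, maf, pos, r2_max):
    """Greedy removal inside one window until no kept pair exceeds r2_max."""
    active = [int(i) for i in win if kept[i]]
    if len(active) < 2:
        return
    r2 = pairwise_r2(panel.dosage[:, active])
    alive = np.ones(len(active), dtype=bool)
    while True:
        best = (-1.0, None)
        for a in range(len(active)):
            if not alive[a]:
                continue
            for b in range(a + 1, len(active)):
                if not alive[b]:
                    continue
                if r2[a, b] > r2_max and r2[a, b] > best[0]:
                    best = (r2[a, b], (a, b))
        if best[1] is None:
            break
        a, b = best[1]
        ia, ib = active[a], active[b]
        if maf[ia] < maf[ib]:
            drop = a
        elif maf[ib] < maf[ia]:
            drop = b
        else:  # MAF tie: drop the later position
            drop = a if pos[ia] > pos[ib] else b
        alive[drop] = False
        kept[active[drop]] = False


def adjusted_threshold(
    alpha: float, m_eff: int, m_total: int | None = None
) -> MultiplicityResult:
    """Family-wise significance threshold alpha / m_eff."""
    if m_eff < 1:
        raise UserInputError("m_eff must be >= 1")
    m_total = m_total if m_total is not None else m_eff
    if not (1 <= m_eff <= m_total):
        raise UserInputError("need 1 <= m_eff <= m_total")
    return MultiplicityResult(
        m_total=int(m_total),
        m_eff=int(m_eff),
        alpha=float(alpha),
        threshold=alpha / m_eff,
        eff_fraction_pct=round_half_up(100.0 * m_eff / m_total, 1),
    )
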