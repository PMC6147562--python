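"""Core genotype containers shared by the simulator and the analysis stages.

The panel stores dosages as copies of the MINOR allele (0, 1, 2, or NaN for a
missing call) in a dense float matrix of lines x markers. Minor/major
assignment is part of the container contract: downstream association results
report the effect of the major allele by negating the minor-allele
coefficient, so the assignment must be explicit and reproducible.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import UserInputError, logger

#: required columns of the marker table, one row per marker (genome order)
MARKER_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "major", "minor"]


@dataclasses.dataclass
class GenotypePanel:
    """Lines x biallelic markers with minor-allele dosages.

    Attributes
    ----------
    line_ids:
        Ordered line labels (length n_lines).
    markers:
        DataFrame with columns :data:`MARKER_COLUMNS`; positions are 1-based
        bp, strictly increasing within each chromosome.
    dosage:
        float array (n_lines, n_markers) with values in {0, 1, 2, NaN};
        counts copies of the minor allele.
    """

    line_ids: list[str]
    markers: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = list(self.line_ids)
        self.markers = self.markers.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.line_ids), len(self.markers)):
            raise UserInputError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.markers)} markers"
            )
        missing_cols = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing_cols:
            raise UserInputError(f"marker table lacks columns {missing_cols}")
        finite = self.dosage[~np.isnan(self.dosage)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise UserInputError("dosages must be 0, 1, 2 or missing (NaN)")
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise UserInputError(f"positions not strictly increasing on {chrom}")

    # ------------------------------------------------------------------ views
    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_index(self, marker_id: str) -> int:
        idx = self.markers.index[self.markers["id"] == marker_id]
        if len(idx) == 0:
            raise UserInputError(f"marker {marker_id!r} not in panel")
        return int(idx[0])

    def minor_freq(self) -> np.ndarray:
        """Frequency of the minor allele per marker over non-missing calls.

        Markers with all calls missing get frequency 0 (monomorphic flag is
        handled by :func:`seedgwas.genio.marker_stats`).
        """
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosage, axis=0) / 2.0
        return np.where(np.isnan(p), 0.0, p)

    # ------------------------------------------------------------- subsetting
    def take_markers(self, index: Iterable[int] | np.ndarray) -> "GenotypePanel":
        index = np.asarray(list(index), dtype=int)
        return GenotypePanel(
            line_ids=self.line_ids,
            markers=self.markers.iloc[index],
            dosage=self.dosage[:, index],
        )

    def take_lines(self, line_ids: Sequence[str]) -> "GenotypePanel":
        pos = {l: i for i, l in enumerate(self.line_ids)}
        missing = [l for l in line_ids if l not in pos]
        if missing:
            raise UserInputError(f"lines not in panel: {missing[:5]}")
        idx = [pos[l] for l in line_ids]
        return GenotypePanel(
            line_ids=list(line_ids), markers=self.markers, dosage=self.dosage[idx, :]
        )

    # -------------------------------------------------------------- encodings
    def alt_dosage(self) -> np.ndarray:
        """Dosage re-expressed as copies of the ALT allele (for VCF export)."""
        flip = (self.markers["minor"] != self.markers["alt"]).to_numpy()
        out = self.dosage.copy()
        out[:, flip] = 2.0 - out[:, flip]
        return out


def assign_minor_major(
    line_ids: Sequence[str], markers: pd.DataFrame, alt_dosage: np.ndarray
) -> GenotypePanel:
    """Build a panel from ALT-allele dosages, assigning minor/major alleles.

    The minor allele is the one with non-missing frequency <= 0.5; exact ties
    keep ALT as the minor allele so the assignment is deterministic.
    """
    alt_dosage = np.asarray(alt_dosage, dtype=float)
    with np.errstate(invalid="ignore"):
        p_alt = np.nanmean(alt_dosage, axis=0) / 2.0
    p_alt = np.where(np.isnan(p_alt), 0.0, p_alt)
    minor_is_alt = p_alt <= 0.5
    dosage = alt_dosage.copy()
    dosage[:, ~minor_is_alt] = 2.0 - dosage[:, ~minor_is_alt]
    markers = markers.copy().reset_index(drop=True)
    markers["minor"] = np.where(minor_is_alt, markers["alt"], markers["ref"])
    markers["major"] = np.where(minor_is_alt, markers["ref"], markers["alt"])
    n_flip = int((~minor_is_alt).sum())
    if n_flip:
        logger.debug("minor/major assignment flipped %d markers to REF-minor", n_flip)
    return GenotypePanel(line_ids=list(line_ids), markers=markers, dosage=dosage)


@dataclasses.dataclass
class KinshipMatrix:
    """Symmetric line x line identity-by-state proportions (diagonal = 1)."""

    line_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise UserInputError("kinship shape does not match line count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise UserInputError("kinship matrix is not symmetric")
        if np.nanmin(self.values) < -1e-12 or np.nanmax(self.values) > 1 + 1e-12:
            raise UserInputError("IBS kinship values must lie in [0, 1]")

    def subset(self, line_ids: Sequence[str]) -> "KinshipMatrix":
        pos = {l: i for i, l in enumerate(self.line_ids)}
        idx = np.array([pos[l] for l in line_ids])
        return KinshipMatrix(list(line_ids), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.line_ids)


@dataclasses.dataclass
class StructureModel:
    """Per-line principal-component scores used as structure covariates (Q)."""

    line_ids: list[str]
    scores: np.ndarray          # n_lines x n_components
    eigenvalues: np.ndarray     # n_components
    variance_fractions: np.ndarray  # n_components, of total genotypic variance

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.variance_fractions = np.asarray(self.variance_fractions, dtype=float)
        if np.any(np.diff(self.variance_fractions) > 1e-12):
            raise UserInputError("variance fractions must be non-increasing")
        if self.variance_fractions.sum() > 1 + 1e-8:
            raise UserInputError("variance fractions must sum to <= 1")

    def covariates(self, line_ids: Sequence[str], n_components: int) -> np.ndarray:
        pos = {l: i for i, l in enumerate(self.line_ids)}
        idx = np.array([pos[l] for l in line_ids])
        k = min(n_components, self.scores.shape[1])
        return self.scores[np.ix_(idx, np.arange(k))]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i+1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.line_ids, columns=cols)
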