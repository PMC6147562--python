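"""Genotype I/O, marker filtering, IBS kinship and structure PCA.

Implements the genotype side of the association pipeline: reading biallelic
SNPs from VCF (optionally converting residual heterozygous calls to missing,
as is standard for inbred panels), removing markers with >= 30% missing calls
or <= 5% minor allele frequency, and computing the two covariance structures
the mixed model needs — an identity-by-state kinship matrix (k) and
principal-component structure covariates (Q).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from ._util import UserInputError, logger
from .panel import GenotypePanel, KinshipMatrix, StructureModel, assign_minor_major

__all__ = [
    "read_vcf",
    "write_vcf",
    "marker_stats",
    "filter_markers",
    "ibs_kinship",
    "structure_pca",
]

_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def read_vcf(path: str | Path, het_to_missing: bool = True) -> GenotypePanel:
    """Read biallelic SNP records from a VCF into a :class:`GenotypePanel`.

    Heterozygous calls become missing when ``het_to_missing`` is set (the
    convention for panels of inbred lines, where residual hets are treated as
    call noise). Multi-allelic and non-SNP records are skipped with a logged
    count; minor/major alleles are assigned from the observed frequencies.
    """
    path = Path(path)
    if not path.exists():
        raise UserInputError(f"VCF not found: {path}")
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise UserInputError(f"malformed VCF {path}: {exc}") from exc
    line_ids = list(vcf.samples)
    rows = []
    cols = []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped += 1
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=missing
        g = rec.gt_types.astype(float)
        g[g == 3] = np.nan
        if het_to_missing:
            g[g == 1] = np.nan
        cols.append(g)
        rows.append(
            {
                "id": rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}",
                "chrom": rec.CHROM,
                "pos": int(rec.POS),
                "ref": rec.REF,
                "alt": rec.ALT[0],
            }
        )
    if skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP records", skipped)
    if not rows:
        raise UserInputError(f"no usable biallelic SNP records in {path}")
    markers = pd.DataFrame(rows)
    alt_dosage = np.column_stack(cols)
    panel = assign_minor_major(line_ids, markers, alt_dosage)
    panel.n_skipped_records = skipped  # type: ignore[attr-defined]
    return panel


def write_vcf(panel: GenotypePanel, path: str | Path, force: bool = False) -> Path:
    """Write the panel back to a minimal VCF 4.2 (GT field only)."""
    path = Path(path)
    if path.exists() and not force:
        raise UserInputError(f"refusing to overwrite {path} (use force=True)")
    alt = panel.alt_dosage()
    chrom_lens = panel.markers.groupby("chrom", sort=False)["pos"].max()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=seedgwas\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, ln in chrom_lens.items():
            fh.write(f"##contig=<ID={chrom},length={int(ln) + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.line_ids)
            + "\n"
        )
        for j, m in panel.markers.iterrows():
            calls = [
                "./." if np.isnan(d) else _GT_STRINGS[d] for d in alt[:, j]
            ]
            fh.write(
                f"{m['chrom']}\t{m['pos']}\t{m['id']}\t{m['ref']}\t{m['alt']}\t"
                ".\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )
    return path


def marker_stats(panel: GenotypePanel) -> pd.DataFrame:
    """Per-marker missing fraction, MAF and monomorphic flag.

    MAF is computed over non-missing calls only; a marker with every call
    missing gets maf 0 and the monomorphic flag.
    """
    if panel.n_markers == 0:
        raise UserInputError("empty panel")
    miss = np.isnan(panel.dosage)
    missing_fraction = miss.mean(axis=0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(panel.dosage, axis=0) / 2.0
    p = np.where(np.isnan(p), 0.0, p)
    maf = np.minimum(p, 1.0 - p)
    maf = np.where(missing_fraction >= 1.0, 0.0, maf)
    return pd.DataFrame(
        {
            "id": panel.markers["id"].to_numpy(),
            "missing_fraction": missing_fraction,
            "maf": maf,
            "monomorphic": maf == 0.0,
        }
    )


def filter_markers(
    panel: GenotypePanel, max_missing: float = 0.30, min_maf: float = 0.05
) -> GenotypePanel:
    """Drop markers with missing fraction >= ``max_missing`` or MAF <= ``min_maf``.

    Both boundaries are removed (a marker at exactly 30% missing or exactly
    5% MAF is dropped); order is preserved and minor/major alleles are
    re-assigned on the surviving panel.
    """
    stats = marker_stats(panel)
    keep = (stats["missing_fraction"].to_numpy() < max_missing) & (
        stats["maf"].to_numpy() > min_maf
    )
    n_drop = int((~keep).sum())
    if keep.sum() == 0:
        raise UserInputError(
            "no markers survive filtering; relax max_missing/min_maf thresholds"
        )
    logger.info(
        "filter_markers: kept %d of %d markers (dropped %d)",
        int(keep.sum()),
        panel.n_markers,
        n_drop,
    )
    sub = panel.take_markers(np.flatnonzero(keep))
    # re-assign on the filtered panel so minor really is minor post-filter
    return assign_minor_major(sub.line_ids, sub.markers, sub.alt_dosage())


def ibs_kinship(panel: GenotypePanel) -> KinshipMatrix:
    """Identity-by-state kinship: mean allele sharing over pairwise-complete markers.

    K[i, j] = mean over markers non-missing in both lines of 1 - |g_i - g_j| / 2.
    The diagonal is forced to 1. A line pair with zero overlapping markers is a
    hard error (kinship undefined for that pair).
    """
    D = panel.dosage
    M = (~np.isnan(D)).astype(float)
    overlap = M @ M.T
    if np.any(overlap == 0):
        i, j = np.argwhere(overlap == 0)[0]
        raise UserInputError(
            f"lines {panel.line_ids[i]!r} and {panel.line_ids[j]!r} share no "
            "non-missing markers; IBS kinship undefined"
        )
    # |g_i - g_j| decomposed over dosage-level indicators: sum_{k,l} |k-l| A_k A_l'
    A = [((D == k) & ~np.isnan(D)).astype(float) for k in (0.0, 1.0, 2.0)]
    absdiff = np.zeros_like(overlap)
    for k in range(3):
        for l in range(3):
            if k != l:
                absdiff += abs(k - l) * (A[k] @ A[l].T)
    K = 1.0 - absdiff / (2.0 * overlap)
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    return KinshipMatrix(list(panel.line_ids), K)


def check_psd(K: KinshipMatrix, tol: float = 1e-8) -> np.ndarray:
    """Validate positive semi-definiteness; clip tiny negative eigenvalues.

    Eigenvalues below ``-tol`` are a hard error (a genuinely indefinite
    kinship means corrupted input); negatives within tolerance are clipped to
    zero with a log entry. Returns the repaired matrix.
    """
    w, U = np.linalg.eigh(K.values)
    if w.min() < -tol:
        raise UserInputError(f"kinship has eigenvalue {w.min():.3g} < -{tol:g}")
    if w.min() < 0:
        logger.info("check_psd: clipped %d tiny negative eigenvalues", int((w < 0).sum()))
        w = np.clip(w, 0.0, None)
        return (U * w) @ U.T
    return K.values


def structure_pca(panel: GenotypePanel, n_components: int) -> StructureModel:
    """Principal components of the standardized genotype matrix (Q covariates).

    Missing calls are mean-imputed per marker, columns centered and scaled by
    sqrt(2 p (1 - p)) with p the minor-allele frequency, and the line x line
    covariance eigendecomposed. Zero-variance markers after imputation are
    dropped with a log entry. Sign convention: the largest-magnitude score of
    each component is positive.
    """
    if n_components >= panel.n_lines:
        raise UserInputError("n_components must be < number of lines")
    D = panel.dosage.copy()
    col_mean = np.nanmean(D, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(D))
    D[nan_r, nan_c] = col_mean[nan_c]
    p = panel.minor_freq()
    scale = np.sqrt(2.0 * p * (1.0 - p))
    keep = (scale > 0) & (D.std(axis=0) > 0)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("structure_pca: dropped %d zero-variance markers", n_drop)
    Z = (D[:, keep] - D[:, keep].mean(axis=0)) / scale[keep]
    m = Z.shape[1]
    if m == 0:
        raise UserInputError("no variable markers available for PCA")
    G = (Z @ Z.T) / m  # per-marker-normalized so duplicated markers change nothing
    w, U = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    U = U[:, order]
    total = w.sum()
    k = n_components
    scores = U[:, :k] * np.sqrt(w[:k])
    # deterministic sign: largest-|score| entry of each component positive
    for j in range(k):
        i = int(np.argmax(np.abs(scores[:, j])))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return StructureModel(
        line_ids=list(panel.line_ids),
        scores=scores,
        eigenvalues=w[:k],
        variance_fractions=w[:k] / total if total > 0 else np.zeros(k),
    )
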