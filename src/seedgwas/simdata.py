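"""Synthetic structured inbred panels and two-treatment phenotypes.

The generator emulates the statistical structure the association pipeline
assumes: a homozygous inbred diversity panel with subpopulation structure
(Balding–Nichols allele-frequency divergence), islands of elevated LD (a
first-order copying chain along each chromosome), a bounded minor-allele
frequency spectrum, residual heterozygous calls and missing data, plus a
randomized two-treatment tray/replicate phenotyping design with planted QTLs.

Ground truth (true kinship, subpopulation labels, per-QTL effects and true
relative effect sizes) is a first-class output so recovery tests never have
to reverse-engineer the simulator.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import UserInputError, logger, substream
from .genio import ibs_kinship, write_vcf
from .panel import GenotypePanel, KinshipMatrix, assign_minor_major

__all__ = [
    "SimConfig",
    "QTLSpec",
    "DesignSpec",
    "GenotypeSim",
    "simulate_genotypes",
    "simulate_phenotypes",
    "random_genes",
    "write_fixture",
]

TREATMENTS = ("well-watered", "water-limited")
_BASES = np.array(["A", "C", "G", "T"])


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Genotype-simulation parameters.

    Defaults emulate a diversity panel of a couple hundred inbred lines with
    moderate subpopulation structure and LD blocks of roughly ten markers
    (``ld_persist`` = 0.9 gives geometric block lengths with mean 10). The
    default chromosome lengths keep marker spacing near 10 kbp — the density
    of a large shotgun SNP set — so physical LD-pruning windows see whole
    blocks; chromosome count and length are scaled down from a real genome.
    """

    n_lines: int = 200
    n_subpops: int = 3
    fst: float = 0.15
    chrom_lengths: tuple[int, ...] = (10_000_000, 10_000_000, 10_000_000)
    n_snps: int = 3000
    ld_persist: float = 0.9
    maf_floor: float = 0.05
    missing_rate: float = 0.05
    het_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise UserInputError("n_lines must be >= 2")
        if not (0 <= self.fst < 1):
            raise UserInputError("fst must lie in [0, 1)")
        if self.n_subpops > self.n_lines:
            raise UserInputError("n_subpops must not exceed n_lines")
        if not (0 <= self.ld_persist < 1):
            raise UserInputError("ld_persist must lie in [0, 1)")
        if not (0 < self.maf_floor < 0.5):
            raise UserInputError("maf_floor must lie in (0, 0.5)")
        if not (0 <= self.missing_rate + self.het_rate < 1):
            raise UserInputError("missing_rate + het_rate must lie in [0, 1)")
        if self.n_snps < len(self.chrom_lengths):
            raise UserInputError("need at least one SNP per chromosome")

    def snps_per_chrom(self) -> list[int]:
        """Largest-remainder allocation of n_snps proportional to length."""
        lengths = np.asarray(self.chrom_lengths, dtype=float)
        quota = self.n_snps * lengths / lengths.sum()
        counts = np.floor(quota).astype(int)
        rem = self.n_snps - counts.sum()
        order = np.argsort(-(quota - counts))
        counts[order[:rem]] += 1
        return counts.tolist()


@dataclasses.dataclass(frozen=True)
class QTLSpec:
    """A planted causal marker: per-treatment effect per MINOR-allele copy."""

    marker: int
    beta: dict[str, float]  # treatment -> effect (trait units per allele copy)
    trait: str

    def __post_init__(self) -> None:
        for t, b in self.beta.items():
            if not np.isfinite(b):
                raise UserInputError(f"QTL effect for {t!r} must be finite")


@dataclasses.dataclass(frozen=True)
class DesignSpec:
    """Two-treatment replicated tray design and variance components.

    Defaults mirror a growth-room layout of three sequential replicates with
    four trays per treatment per replicate; every line appears exactly once
    per replicate x treatment, randomly assigned to a tray.
    """

    n_replicates: int = 3
    n_trays_per_treatment: int = 4
    treatments: tuple[str, str] = TREATMENTS
    var_line: float = 1.0
    var_line_treatment: float = 0.2
    var_tray: float = 0.1
    var_resid: float = 1.0
    treatment_means: dict[str, dict[str, float]] = dataclasses.field(
        default_factory=lambda: {"trait1": {TREATMENTS[0]: 0.0, TREATMENTS[1]: 0.0}}
    )

    def __post_init__(self) -> None:
        if len(self.treatments) != 2:
            raise UserInputError("exactly two treatments required")
        for v in (self.var_line, self.var_line_treatment, self.var_tray, self.var_resid):
            if v < 0:
                raise UserInputError("variance components must be >= 0")
        for trait, mus in self.treatment_means.items():
            if set(mus) != set(self.treatments):
                raise UserInputError(f"trait {trait!r} needs a mean per treatment")

    @property
    def traits(self) -> list[str]:
        return list(self.treatment_means)


@dataclasses.dataclass
class GenotypeSim:
    """Simulated panel plus ground truth."""

    panel: GenotypePanel
    clean_panel: GenotypePanel  # noise-free (no hets, no missing)
    k_true: KinshipMatrix       # IBS kinship of the noise-free panel
    subpop: np.ndarray          # per-line subpopulation index
    config: SimConfig


def simulate_genotypes(cfg: SimConfig) -> GenotypeSim:
    """Simulate a structured homozygous panel with LD, hets and missingness.

    Balding–Nichols model: ancestral frequency p ~ U(maf_floor, 1-maf_floor)
    per marker; subpopulation frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F) for
    F > 0 (equal to p when F = 0). Each line carries one latent haplotype per
    chromosome built by a copying chain: the state at a marker is copied from
    the previous marker with probability ``ld_persist``, otherwise redrawn
    Bernoulli(subpop frequency). Dosage is twice the haplotype state (fully
    homozygous); heterozygous calls and missing calls are injected afterwards
    as mutually exclusive noise. Deterministic given the seed.
    """
    rng = substream(cfg.seed, "genotypes")
    n, m = cfg.n_lines, cfg.n_snps
    counts = cfg.snps_per_chrom()

    p_anc = rng.uniform(cfg.maf_floor, 1.0 - cfg.maf_floor, size=m)
    if cfg.fst > 0:
        F = cfg.fst
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        p_sub = rng.beta(a, b, size=(cfg.n_subpops, m))
    else:
        p_sub = np.tile(p_anc, (cfg.n_subpops, 1))

    # contiguous, near-balanced subpopulation blocks
    subpop = (np.arange(n) * cfg.n_subpops) // n
    p_line = p_sub[subpop, :]  # n x m alt-allele frequency per line

    hap = np.empty((n, m), dtype=np.int8)
    j0 = 0
    positions: list[np.ndarray] = []
    chrom_labels: list[str] = []
    for c, (L, k) in enumerate(zip(cfg.chrom_lengths, counts)):
        pos = _sample_positions(rng, L, k)
        positions.append(pos)
        chrom_labels.extend([f"Chr{c + 1:02d}"] * k)
        for j in range(j0, j0 + k):
            fresh = rng.random(n) < p_line[:, j]
            if j == j0:
                hap[:, j] = fresh
            else:
                copy = rng.random(n) < cfg.ld_persist
                hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
        j0 += k

    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    pos_all = np.concatenate(positions)
    markers = pd.DataFrame(
        {
            "id": [f"{c}:{p}" for c, p in zip(chrom_labels, pos_all)],
            "chrom": chrom_labels,
            "pos": pos_all,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
        }
    )

    clean_alt = 2.0 * hap.astype(float)
    line_ids = [f"L{i + 1:04d}" for i in range(n)]
    clean_panel = assign_minor_major(line_ids, markers, clean_alt)
    k_true = ibs_kinship(clean_panel)

    noisy = clean_alt.copy()
    u = rng.random((n, m))
    noisy[u < cfg.het_rate] = 1.0
    noisy[(u >= cfg.het_rate) & (u < cfg.het_rate + cfg.missing_rate)] = np.nan
    panel = assign_minor_major(line_ids, markers, noisy)
    logger.info(
        "simulate_genotypes: %d lines x %d markers, %d subpops, Fst=%.2f",
        n, m, cfg.n_subpops, cfg.fst,
    )
    return GenotypeSim(panel=panel, clean_panel=clean_panel, k_true=k_true,
                       subpop=subpop, config=cfg)


def _sample_positions(rng: np.random.Generator, length: int, k: int) -> np.ndarray:
    """k distinct sorted 1-based positions on a chromosome of given bp length."""
    if k > length:
        raise UserInputError("more SNPs than base pairs on a chromosome")
    pos: set[int] = set()
    while len(pos) < k:
        need = k - len(pos)
        pos.update(rng.integers(1, length + 1, size=max(need * 2, 16)).tolist())
    arr = np.array(sorted(pos), dtype=np.int64)
    if len(arr) > k:
        arr = np.sort(rng.choice(arr, size=k, replace=False))
    return arr


def simulate_phenotypes(
    sim: GenotypeSim | GenotypePanel,
    qtls: Sequence[QTLSpec],
    design: DesignSpec,
    seed: int,
    k_true: KinshipMatrix | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the replicated two-treatment phenotype table plus truth table.

    The observation model is
    ``y = mu_t + sum_q beta_qt x_q + u_i + gamma_it + tray(rep, trt) + eps``
    with line effects u ~ N(0, var_line * K_true) drawn against the true
    (noise-free) kinship, independent line-by-treatment, tray and residual
    normal effects, and QTL dosages taken from the panel (minor-allele
    copies; missing dosages mean-imputed and flagged in the truth table).

    Returns (raw phenotype table, truth table). The truth table records, per
    QTL x treatment, the planted minor- and major-allele effects and the true
    relative effect size against the realized range of true line means.
    """
    if isinstance(sim, GenotypeSim):
        panel = sim.panel
        k_true = k_true or sim.k_true
    else:
        panel = sim
        if k_true is None:
            k_true = ibs_kinship(panel)
    for q in qtls:
        if not (0 <= q.marker < panel.n_markers):
            raise UserInputError(f"QTL marker index {q.marker} out of range")
        if q.trait not in design.traits:
            raise UserInputError(f"QTL trait {q.trait!r} has no treatment means")

    n = panel.n_lines
    traits = design.traits
    rng = substream(seed, "phenotypes")

    # genetic line effects against the true kinship (shared across reps/trays)
    w, U = np.linalg.eigh(k_true.values)
    L = U * np.sqrt(np.clip(w, 0.0, None))
    u_line = {
        tr: np.sqrt(design.var_line) * (L @ rng.standard_normal(n)) for tr in traits
    }
    gamma = {
        (tr, t): np.sqrt(design.var_line_treatment) * rng.standard_normal(n)
        for tr in traits
        for t in design.treatments
    }

    # QTL genetic values per trait x treatment (mean-imputed dosages)
    x_cols = {}
    n_imputed = {}
    for q in qtls:
        x = panel.dosage[:, q.marker].copy()
        nmiss = int(np.isnan(x).sum())
        if nmiss:
            x[np.isnan(x)] = np.nanmean(x)
        x_cols[q.marker] = x
        n_imputed[q.marker] = nmiss
    g_val = {
        (tr, t): np.zeros(n) for tr in traits for t in design.treatments
    }
    for q in qtls:
        for t, b in q.beta.items():
            g_val[(q.trait, t)] += b * x_cols[q.marker]

    # tray assignment: per replicate x treatment, random near-even partition
    rows = []
    tray_labels = [f"T{k + 1}" for k in range(design.n_trays_per_treatment)]
    for rep in range(1, design.n_replicates + 1):
        for t in design.treatments:
            perm = rng.permutation(n)
            tray_of = np.empty(n, dtype=int)
            for k, chunk in enumerate(np.array_split(perm, design.n_trays_per_treatment)):
                tray_of[chunk] = k
            tray_eff = np.sqrt(design.var_tray) * rng.standard_normal(
                design.n_trays_per_treatment
            )
            eps = {
                tr: np.sqrt(design.var_resid) * rng.standard_normal(n) for tr in traits
            }
            for i, line in enumerate(panel.line_ids):
                rec = {
                    "line": line,
                    "treatment": t,
                    "replicate": rep,
                    "tray": tray_labels[tray_of[i]],
                }
                for tr in traits:
                    rec[tr] = (
                        design.treatment_means[tr][t]
                        + g_val[(tr, t)][i]
                        + u_line[tr][i]
                        + gamma[(tr, t)][i]
                        + tray_eff[tray_of[i]]
                        + eps[tr][i]
                    )
                rows.append(rec)
    raw = pd.DataFrame(rows)

    truth_rows = []
    for q in qtls:
        for t in design.treatments:
            true_means = (
                design.treatment_means[q.trait][t]
                + g_val[(q.trait, t)]
                + u_line[q.trait]
                + gamma[(q.trait, t)]
            )
            rng_range = float(true_means.max() - true_means.min())
            beta_minor = q.beta.get(t, 0.0)
            truth_rows.append(
                {
                    "trait": q.trait,
                    "treatment": t,
                    "marker": panel.markers["id"].iloc[q.marker],
                    "marker_index": q.marker,
                    "chrom": panel.markers["chrom"].iloc[q.marker],
                    "pos": panel.markers["pos"].iloc[q.marker],
                    "beta_minor": beta_minor,
                    "beta_major": -beta_minor,
                    "true_range": rng_range,
                    "true_effect_size_pct": abs(2.0 * beta_minor / rng_range) * 100.0
                    if rng_range > 0
                    else np.nan,
                    "n_dosages_imputed": n_imputed[q.marker],
                }
            )
    truth = pd.DataFrame(truth_rows)
    return raw, truth


def random_genes(
    cfg: SimConfig,
    genes_per_chrom: int,
    seed: int,
    mean_length: int = 3000,
) -> pd.DataFrame:
    """Non-overlapping gene models tiling each simulated chromosome."""
    rng = substream(seed, "genes")
    rows = []
    gid = 0
    for c, L in enumerate(cfg.chrom_lengths):
        chrom = f"Chr{c + 1:02d}"
        starts = np.sort(rng.choice(L - mean_length * 2, size=genes_per_chrom, replace=False)) + 1
        prev_end = 0
        for s in starts:
            start = max(int(s), prev_end + 1)
            end = start + int(rng.integers(mean_length // 2, mean_length * 2))
            end = min(end, L)
            if end <= start:
                continue
            gid += 1
            rows.append(
                {
                    "gene_id": f"gene{gid:05d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": "+" if rng.random() < 0.5 else "-",
                }
            )
            prev_end = end
    return pd.DataFrame(rows)


def write_gff3(genes: pd.DataFrame, path: str | Path, force: bool = False) -> Path:
    """Write a minimal GFF3 of gene features (1-based inclusive coordinates)."""
    path = Path(path)
    if path.exists() and not force:
        raise UserInputError(f"refusing to overwrite {path} (use force=True)")
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(
                f"{g['chrom']}\tseedgwas\tgene\t{int(g['start'])}\t{int(g['end'])}\t."
                f"\t{g['strand']}\t.\tID={g['gene_id']};Name={g['gene_id']}\n"
            )
    return path


def write_fixture(
    outdir: str | Path,
    panel: GenotypePanel,
    phenotypes: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    truth: pd.DataFrame | None = None,
    force: bool = False,
) -> dict[str, Path]:
    """Write VCF + phenotype TSV (+ optional GFF3 and truth TSV) to a directory.

    Round-trip contract: reading the VCF back with het_to_missing=False
    reproduces the dosage matrix exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"vcf": outdir / "genotypes.vcf", "phenotypes": outdir / "phenotypes.tsv"}
    if genes is not None:
        paths["gff3"] = outdir / "genes.gff3"
    if truth is not None:
        paths["truth"] = outdir / "truth.tsv"
    for p in paths.values():
        if p.exists() and not force:
            raise UserInputError(f"refusing to overwrite {p} (use force=True)")
    write_vcf(panel, paths["vcf"], force=True)
    phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    if genes is not None:
        write_gff3(genes, paths["gff3"], force=True)
    if truth is not None:
        truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
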