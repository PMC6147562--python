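"""End-to-end orchestration: genio -> phenostats -> mma -> multiplicity -> regions -> downstream.

Each stage writes plot-ready TSV outputs into the run directory and the run
manifest (JSON) records versions, configuration, seed and the headline
counts: markers before/after filtering, effective test number, significance
threshold and region counts. Stages are pure functions of their inputs, so a
rerun of the same configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from ._util import PipelineError, UserInputError, logger
from . import genio, mma, multiplicity, phenostats, simdata
from . import downstream as ds
from . import regions as rg
from .panel import GenotypePanel
from .regions import AssociatedRegion, RegionConfig

__all__ = ["RunConfig", "run_pipeline", "make_demo"]


@dataclasses.dataclass
class RunConfig:
    """Single structured configuration for a full pipeline run."""

    vcf: str
    phenotypes: str
    outdir: str
    gff3: str | None = None
    het_to_missing: bool = True
    max_missing: float = 0.30
    min_maf: float = 0.05
    n_structure_components: int = 4
    ls_engine: str = "reml"
    prune_window_kb: float = 100.0
    prune_step_snps: int = 10
    prune_r2_max: float = 0.8
    alpha: float = 0.05
    r2_bin: float = 0.80
    suggestive_top_frac: float = 0.05
    gene_buffer: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.max_missing <= 1) or not (0 <= self.min_maf < 0.5):
            raise UserInputError("filter thresholds out of range")
        if not (0 < self.alpha < 1):
            raise UserInputError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except UserInputError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        wrapper.__name__ = fn.__name__
        return wrapper

    return deco


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Run every stage in order and return the manifest dict."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "seedgwas",
        "version": __version__,
        "python": platform.python_version(),
        "versions": _lib_versions(),
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "stages": [],
    }
    if cfg.gff3 is not None and not Path(cfg.gff3).exists():
        raise UserInputError(f"stage 'downstream' needs GFF3 but {cfg.gff3} is missing")

    panel, stats = _stage_genio(cfg, out, manifest)
    K, Q = _stage_covariance(cfg, panel, out, manifest)
    tm = _stage_phenostats(cfg, out, manifest)
    scans = _stage_mma(cfg, tm, panel, K, Q, out, manifest)
    mres = _stage_multiplicity(cfg, panel, out, manifest)
    all_regions = _stage_regions(cfg, scans, panel, mres.threshold, out, manifest)
    _stage_downstream(cfg, all_regions, scans, tm, out, manifest)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    logger.info("pipeline complete: %s", out / "manifest.json")
    return manifest


def _lib_versions() -> dict[str, str]:
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


@_stage("genio")
def _stage_genio(cfg: RunConfig, out: Path, manifest: dict):
    panel = genio.read_vcf(cfg.vcf, het_to_missing=cfg.het_to_missing)
    n_before = panel.n_markers
    stats = genio.marker_stats(panel)
    stats.to_csv(out / "marker_stats.tsv", sep="\t", index=False)
    panel = genio.filter_markers(panel, cfg.max_missing, cfg.min_maf)
    genio.write_vcf(panel, out / "filtered.vcf", force=True)
    manifest["markers_before_filter"] = n_before
    manifest["markers_after_filter"] = panel.n_markers
    manifest["n_lines"] = panel.n_lines
    manifest["stages"].append("genio")
    return panel, stats


@_stage("genio")
def _stage_covariance(cfg: RunConfig, panel: GenotypePanel, out: Path, manifest: dict):
    K = genio.ibs_kinship(panel)
    genio.check_psd(K)
    K.to_frame().to_csv(out / "kinship.tsv", sep="\t")
    Q = genio.structure_pca(
        panel, n_components=min(cfg.n_structure_components, panel.n_lines - 1)
    )
    Q.to_frame().to_csv(out / "structure.tsv", sep="\t")
    manifest["stages"].append("covariance")
    return K, Q


@_stage("phenostats")
def _stage_phenostats(cfg: RunConfig, out: Path, manifest: dict):
    raw = pd.read_csv(cfg.phenotypes, sep="\t")
    tm = phenostats.trait_matrix(raw, engine=cfg.ls_engine)
    tm.wide().to_csv(out / "ls_means.tsv", sep="\t")
    phenostats.trait_correlations(tm).to_csv(
        out / "trait_correlations.tsv", sep="\t", index=False
    )
    pca = phenostats.trait_pca(tm)
    pca.scores.to_csv(out / "trait_pca_scores.tsv", sep="\t")
    manifest["traits"] = tm.traits
    manifest["trait_transforms"] = tm.transforms
    manifest["trait_pca_variance_fractions"] = pca.variance_fractions[:4].tolist()
    manifest["stages"].append("phenostats")
    return tm

@_stage("mma")
def _stage_mma(cfg: RunConfig, tm, panel, K, Q, out: Path, manifest: dict):
    scans = mma.gwa_scan_all(tm, panel, K, Q, n_components=cfg.n_structure_components)
    for (trait, treatment), tab in scans.items():
        tab.to_csv(out / f"assoc_{_slug(trait)}_{_slug(treatment)}.tsv", sep="\t", index=False)
    manifest["n_scans"] = len(scans)
    manifest["stages"].append("mma")
    return scans


@_stage("multiplicity")
def _stage_multiplicity(cfg: RunConfig, panel: GenotypePanel, out: Path, manifest: dict):
    kept = multiplicity.prune_indep_pairwise(
        panel, cfg.prune_window_kb, cfg.prune_step_snps, cfg.prune_r2_max
    )
    mres = multiplicity.adjusted_threshold(cfg.alpha, len(kept), panel.n_markers)
    panel.markers.iloc[kept][["id", "chrom", "pos"]].to_csv(
        out / "pruned_markers.tsv", sep="\t", index=False
    )
    manifest["multiplicity"] = mres.to_dict()
    manifest["stages"].append("multiplicity")
    return mres


@_stage("regions")
def _stage_regions(cfg, scans, panel, threshold, out: Path, manifest: dict):
    rcfg = RegionConfig(r2_bin=cfg.r2_bin, suggestive_top_frac=cfg.suggestive_top_frac)
    all_regions: list[AssociatedRegion] = []
    for tab in scans.values():
        all_regions.extend(rg.delineate_regions(tab, panel, threshold, rcfg))
    pd.DataFrame([r.to_dict() for r in all_regions]).to_csv(
        out / "regions.tsv", sep="\t", index=False
    )
    unique = rg.deduplicate_regions(all_regions)
    unique.to_csv(out / "unique_regions.tsv", sep="\t", index=False)
    ld_dir = out / "region_ld"
    ld_dir.mkdir(exist_ok=True)
    for r in all_regions:
        heat = rg.ld_heatmap_data(r, panel)
        if not heat.empty:
            heat.to_csv(ld_dir / f"{_slug(r.region_id)}.tsv", sep="\t")
    manifest["n_regions"] = len(all_regions)
    manifest["n_unique_regions"] = int(len(unique))
    manifest["stages"].append("regions")
    return all_regions


@_stage("downstream")
def _stage_downstream(cfg, all_regions, scans, tm, out: Path, manifest: dict):
    ds.effect_sizes(all_regions, tm).to_csv(out / "effect_sizes.tsv", sep="\t", index=False)
    pleio = [ds.pleiotropy_scan(r, scans) for r in all_regions]
    pleio_df = (
        pd.concat(pleio, ignore_index=True) if pleio else pd.DataFrame()
    )
    pleio_df.to_csv(out / "pleiotropy.tsv", sep="\t", index=False)
    if cfg.gff3 is not None:
        ann = ds.read_gff3(cfg.gff3)
        genes = [ds.candidate_genes(r, ann, b=cfg.gene_buffer) for r in all_regions]
        genes_df = pd.concat(genes, ignore_index=True) if genes else pd.DataFrame()
        genes_df.to_csv(out / "candidate_genes.tsv", sep="\t", index=False)
        manifest["n_candidate_genes"] = (
            int(genes_df["gene_id"].nunique()) if len(genes_df) else 0
        )
    manifest["stages"].append("downstream")


def _slug(s: str) -> str:
    return "".join(c if c.isalnum() or c in "-._" else "-" for c in s)


# --------------------------------------------------------------------- demo
DEMO_TRAITS = {
    "stem_diameter": {"well-watered": 2.41, "water-limited": 2.26},
    "root_biomass": {"well-watered": 8.2, "water-limited": 7.9},
    "taproot_length": {"well-watered": 102.6, "water-limited": 113.9},
}


def make_demo(
    seed: int,
    outdir: str | Path,
    n_lines: int = 150,
    n_snps: int = 2000,
    ls_engine: str = "reml",
) -> dict[str, Any]:
    """Generate a documented small fixture with planted QTLs and run the pipeline.

    Two QTLs are planted: one on root biomass with equal effects in both
    treatments, one on taproot length acting only under water limitation.
    Returns the run manifest; the fixture (VCF, phenotype TSV, GFF3, truth
    TSV) lands in ``outdir/fixture`` and outputs in ``outdir/run``.
    """
    outdir = Path(outdir)
    cfg = simdata.SimConfig(
        n_lines=n_lines,
        n_subpops=3,
        fst=0.15,
        chrom_lengths=(10_000_000, 10_000_000, 10_000_000),
        n_snps=n_snps,
        ld_persist=0.9,
        maf_floor=0.1,
        missing_rate=0.03,
        het_rate=0.01,
        seed=seed,
    )
    sim = simdata.simulate_genotypes(cfg)
    design = simdata.DesignSpec(treatment_means=DEMO_TRAITS)
    qtls = [
        simdata.QTLSpec(
            marker=n_snps // 4,
            beta={"well-watered": 0.9, "water-limited": 0.9},
            trait="root_biomass",
        ),
        simdata.QTLSpec(
            marker=(2 * n_snps) // 3,
            beta={"well-watered": 0.0, "water-limited": 1.0},
            trait="taproot_length",
        ),
    ]
    raw, truth = simdata.simulate_phenotypes(sim, qtls, design, seed=seed)
    genes = simdata.random_genes(cfg, genes_per_chrom=60, seed=seed)
    fixture = simdata.write_fixture(
        outdir / "fixture", sim.panel, raw, genes=genes, truth=truth, force=True
    )
    run_cfg = RunConfig(
        vcf=str(fixture["vcf"]),
        phenotypes=str(fixture["phenotypes"]),
        gff3=str(fixture["gff3"]),
        outdir=str(outdir / "run"),
        ls_engine=ls_engine,
        seed=seed,
    )
    manifest = run_pipeline(run_cfg)
    manifest["fixture"] = {k: str(v) for k, v in fixture.items()}
    with open(outdir / "run" / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    return manifest
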