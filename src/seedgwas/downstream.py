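"""Post-association summaries: relative effect sizes, pleiotropy, candidate genes.

The relative effect size of a focal marker is |2 beta / trait range| x 100 —
the percent of the observed LS-mean range covered by the contrast between
the two homozygotes. The pleiotropy screen converts the focal marker's
P-value in every alternate context (other traits in the same treatment, and
the same trait in the other treatment) into a percentile rank, with
direction-of-effect agreement from the sign of the major-allele effect.
Candidate genes are every annotated gene intersecting the region interval
plus a buffer of b flanking genes on each side.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

from ._util import UserInputError, logger, round_half_up
from .phenostats import TraitMatrix
from .regions import AssociatedRegion

__all__ = [
    "GeneAnnotation",
    "read_gff3",
    "relative_effect_size",
    "effect_sizes",
    "pleiotropy_scan",
    "candidate_genes",
]

#: percentile tier cutoffs (percentile rank -> label)
TIERS = ((99.0, "top1"), (95.0, "top5"), (90.0, "top10"))


@dataclasses.dataclass
class GeneAnnotation:
    """Position-sorted gene models (1-based inclusive coordinates)."""

    genes: pd.DataFrame  # gene_id, chrom, start, end, strand

    def __post_init__(self) -> None:
        need = {"gene_id", "chrom", "start", "end", "strand"}
        if not need.issubset(self.genes.columns):
            raise UserInputError(f"gene table needs columns {sorted(need)}")
        if (self.genes["start"] > self.genes["end"]).any():
            raise UserInputError("gene start must be <= end")
        self.genes = self.genes.sort_values(["chrom", "start", "end"]).reset_index(drop=True)

    def on(self, chrom: str) -> pd.DataFrame:
        sub = self.genes[self.genes["chrom"] == chrom]
        if sub.empty:
            raise UserInputError(f"chromosome {chrom!r} absent from annotation")
        return sub


def read_gff3(path: str | Path) -> GeneAnnotation:
    """Load gene features from a GFF3 file."""
    path = Path(path)
    if not path.exists():
        raise UserInputError(f"GFF3 not found: {path}")
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = [
        {
            "gene_id": g.id,
            "chrom": g.seqid,
            "start": int(g.start),
            "end": int(g.end),
            "strand": g.strand,
        }
        for g in db.features_of_type("gene")
    ]
    if not rows:
        raise UserInputError(f"no gene features in {path}")
    return GeneAnnotation(pd.DataFrame(rows))


def relative_effect_size(beta: float, trait_range: float) -> float:
    """|2 beta / trait_range| x 100, reported to one decimal (half-up).

    ``trait_range`` is the max - min of the LS means of the trait in the
    focal treatment; a non-positive range leaves the effect size undefined.
    """
    if not np.isfinite(trait_range) or trait_range <= 0:
        logger.warning("relative_effect_size: non-positive trait range; undefined")
        return np.nan
    return round_half_up(abs(2.0 * beta / trait_range) * 100.0, 1)


def effect_sizes(regions: list[AssociatedRegion], tm: TraitMatrix) -> pd.DataFrame:
    """Relative effect size of each region's focal marker."""
    rows = []
    for r in regions:
        rng = tm.range(r.trait, r.treatment)
        rows.append(
            {
                "region_id": r.region_id,
                "trait": r.trait,
                "treatment": r.treatment,
                "focal_marker": r.focal_marker,
                "beta_major": r.focal_beta_major,
                "trait_range": rng,
                "effect_size_pct": relative_effect_size(r.focal_beta_major, rng),
            }
        )
    return pd.DataFrame(rows)


def _tier(percentile: float) -> str:
    for cut, label in TIERS:
        if percentile >= cut:
            return label
    return "none"


def pleiotropy_scan(
    region: AssociatedRegion,
    assoc_tables: dict[tuple[str, str], pd.DataFrame],
) -> pd.DataFrame:
    """Percentile rank of the focal marker in every alternate context.

    Contexts are the other traits within the focal treatment plus the same
    trait in the alternate treatment (self-comparisons excluded). The
    percentile counts markers with strictly greater P, so the best of M
    markers ranks 100 (M - 1) / M, never 100. Direction agreement compares
    the sign of the major-allele effect between contexts.
    """
    focal_key = (region.trait, region.treatment)
    if focal_key not in assoc_tables:
        raise UserInputError(f"focal scan {focal_key} missing from assoc tables")
    focal_tab = assoc_tables[focal_key].set_index("marker")
    if region.focal_marker not in focal_tab.index:
        raise UserInputError(f"focal marker {region.focal_marker} missing from focal scan")
    focal_beta = float(focal_tab.loc[region.focal_marker, "beta_major"])

    contexts = []
    for (trait, treatment) in assoc_tables:
        if (trait, treatment) == focal_key:
            continue
        if treatment == region.treatment or trait == region.trait:
            contexts.append((trait, treatment))

    rows = []
    for trait, treatment in contexts:
        tab = assoc_tables[(trait, treatment)]
        sub = tab.set_index("marker")
        kind = "same_treatment" if treatment == region.treatment else "alternate_treatment"
        if region.focal_marker not in sub.index or not np.isfinite(
            sub.loc[region.focal_marker, "p_value"]
        ):
            logger.warning(
                "pleiotropy_scan: focal marker %s absent from %s/%s scan",
                region.focal_marker, trait, treatment,
            )
            rows.append(
                {
                    "region_id": region.region_id,
                    "focal_marker": region.focal_marker,
                    "alt_trait": trait,
                    "alt_treatment": treatment,
                    "context": kind,
                    "percentile": np.nan,
                    "tier": "missing",
                    "direction_match": "missing",
                }
            )
            continue
        p_all = sub["p_value"].dropna()
        focal_p = float(sub.loc[region.focal_marker, "p_value"])
        percentile = 100.0 * float((p_all > focal_p).sum()) / len(p_all)
        alt_beta = float(sub.loc[region.focal_marker, "beta_major"])
        rows.append(
            {
                "region_id": region.region_id,
                "focal_marker": region.focal_marker,
                "alt_trait": trait,
                "alt_treatment": treatment,
                "context": kind,
                "percentile": percentile,
                "tier": _tier(percentile),
                "direction_match": "same"
                if np.sign(alt_beta) == np.sign(focal_beta)
                else "opposite",
            }
        )
    return pd.DataFrame(rows)


def candidate_genes(
    region: AssociatedRegion, ann: GeneAnnotation, b: int = 1
) -> pd.DataFrame:
    """Genes intersecting the region plus b flanking genes on each side.

    A gene is "in" the region when its [start, end] intersects
    [region.start, region.stop] (1-based inclusive). The buffer adds the b
    nearest genes lying strictly before the region start and the b nearest
    strictly after the stop; a single-position marker therefore yields
    2b genes when it falls between genes and 1 + 2b when inside a gene
    (flanks permitting — a chromosome edge yields fewer, logged).
    """
    if b < 0:
        raise UserInputError("buffer b must be >= 0")
    genes = ann.on(region.chrom)
    overlap = genes[(genes["start"] <= region.stop) & (genes["end"] >= region.start)]
    before = genes[genes["end"] < region.start].nlargest(b, "end") if b else genes.iloc[0:0]
    after = genes[genes["start"] > region.stop].nsmallest(b, "start") if b else genes.iloc[0:0]
    if b and (len(before) < b or len(after) < b):
        logger.info(
            "candidate_genes(%s): only %d upstream / %d downstream flanking genes",
            region.region_id, len(before), len(after),
        )
    out = (
        pd.concat([before, overlap, after])
        .drop_duplicates(subset="gene_id")
        .sort_values(["start", "end"])
        .reset_index(drop=True)
    )
    out.insert(0, "region_id", region.region_id)
    out["in_region"] = (out["start"] <= region.stop) & (out["end"] >= region.start)
    return out
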