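"""LD-delimited associated regions from per-trait/treatment scans.

Significant markers (P at or below the genome-wide threshold) are collapsed
together with suggestive markers (best 5% of the scan's P-values) into LD
bins at r^2 >= 0.80 by the greedy tag-SNP (LDSelect-style) set cover; bins
holding at least one significant marker become associated regions whose
boundaries are the outermost member positions. Regions from different
traits/treatments whose intervals overlap on a chromosome merge into unique
regions.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from ._util import UserInputError, logger, round_half_up
from .multiplicity import pairwise_r2
from .panel import GenotypePanel

__all__ = [
    "RegionConfig",
    "AssociatedRegion",
    "significant_set",
    "suggestive_set",
    "ld_bins",
    "delineate_regions",
    "deduplicate_regions",
    "ld_heatmap_data",
]


@dataclasses.dataclass(frozen=True)
class RegionConfig:
    r2_bin: float = 0.80
    suggestive_top_frac: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.suggestive_top_frac < 1):
            raise UserInputError("suggestive_top_frac must lie in (0, 1)")
        if not (0 < self.r2_bin <= 1):
            raise UserInputError("r2_bin must lie in (0, 1]")


@dataclasses.dataclass
class AssociatedRegion:
    """A trait/treatment-specific LD-delimited genomic interval."""

    region_id: str
    trait: str
    treatment: str
    chrom: str
    start: int
    stop: int
    start_marker: str
    stop_marker: str
    members: list[str]
    significant: list[str]
    focal_marker: str
    focal_p: float
    focal_beta_major: float
    length_mbp: float
    single_marker: bool

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise UserInputError("region start must be <= stop")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["members"] = ",".join(self.members)
        d["significant"] = ",".join(self.significant)
        d["n_members"] = len(self.members)
        d["n_significant"] = len(self.significant)
        return d


def significant_set(assoc: pd.DataFrame, threshold: float) -> list[str]:
    """Markers with P at or below the genome-wide threshold (boundary included)."""
    ok = assoc["p_value"].notna() & (assoc["p_value"] <= threshold)
    return assoc.loc[ok, "marker"].tolist()


def suggestive_set(assoc: pd.DataFrame, top_frac: float = 0.05) -> list[str]:
    """Markers whose P ranks within the smallest ceil(top_frac * M) values.

    Ties at the cutoff P are all included, so the set can exceed the nominal
    count. Computed genome-wide per trait/treatment scan.
    """
    p = assoc["p_value"].dropna()
    if p.empty:
        return []
    k = math.ceil(top_frac * len(p))
    cutoff = p.nsmallest(k).max()
    ok = assoc["p_value"].notna() & (assoc["p_value"] <= cutoff)
    return assoc.loc[ok, "marker"].tolist()


def ld_bins(
    marker_ids: list[str], panel: GenotypePanel, r2_bin: float = 0.80
) -> list[list[str]]:
    """Greedy tag-SNP set cover of markers on one chromosome.

    Repeatedly pick the marker with the most unbinned companions at
    r^2 >= r2_bin (ties -> leftmost position), bin it with those companions,
    and remove them; singleton bins are allowed. Bins partition the input.
    """
    if not marker_ids:
        return []
    idx = [panel.marker_index(m) for m in marker_ids]
    chroms = set(panel.markers["chrom"].iloc[idx])
    if len(chroms) > 1:
        raise UserInputError(f"ld_bins expects one chromosome, got {sorted(chroms)}")
    order = np.argsort(panel.markers["pos"].iloc[idx].to_numpy(), kind="stable")
    ids = [marker_ids[i] for i in order]
    idx = [idx[i] for i in order]
    r2 = pairwise_r2(panel.dosage[:, idx])
    remaining = list(range(len(ids)))
    bins: list[list[str]] = []
    while remaining:
        # companion counts among remaining markers (position order = tie-break)
        best_i, best_count = None, -1
        for i in remaining:
            count = sum(1 for j in remaining if j != i and r2[i, j] >= r2_bin)
            if count > best_count:
                best_i, best_count = i, count
        group = [best_i] + [
            j for j in remaining if j != best_i and r2[best_i, j] >= r2_bin
        ]
        group_sorted = sorted(group)
        bins.append([ids[j] for j in group_sorted])
        remaining = [j for j in remaining if j not in set(group)]
    return bins


def delineate_regions(
    assoc: pd.DataFrame,
    panel: GenotypePanel,
    threshold: float,
    cfg: RegionConfig = RegionConfig(),
) -> list[AssociatedRegion]:
    """Associated regions for one trait/treatment scan.

    LD bins are built over the union of significant and suggestive markers
    per chromosome; bins holding at least one significant marker become
    regions spanning min..max member positions, with the lowest-P member as
    the focal marker. Region ids follow trait.chrom.counter with counters in
    start-position order.
    """
    trait = assoc["trait"].iloc[0]
    treatment = assoc["treatment"].iloc[0]
    sig = set(significant_set(assoc, threshold))
    if not sig:
        return []
    sugg = set(suggestive_set(assoc, cfg.suggestive_top_frac))
    members_all = sig | sugg
    info = assoc.set_index("marker")
    regions: list[AssociatedRegion] = []
    for chrom, sub in assoc[assoc["marker"].isin(members_all)].groupby("chrom", sort=False):
        chrom_sig = sig & set(sub["marker"])
        if not chrom_sig:
            continue
        bins = ld_bins(sub["marker"].tolist(), panel, cfg.r2_bin)
        chrom_regions = []
        for members in bins:
            bin_sig = sorted(chrom_sig & set(members), key=lambda m: info.loc[m, "pos"])
            if not bin_sig:
                continue
            pos = info.loc[members, "pos"]
            p = info.loc[members, "p_value"]
            focal = p.idxmin()
            start_m = pos.idxmin()
            stop_m = pos.idxmax()
            start, stop = int(pos.min()), int(pos.max())
            chrom_regions.append(
                AssociatedRegion(
                    region_id="",
                    trait=trait,
                    treatment=treatment,
                    chrom=chrom,
                    start=start,
                    stop=stop,
                    start_marker=start_m,
                    stop_marker=stop_m,
                    members=sorted(members, key=lambda m: info.loc[m, "pos"]),
                    significant=bin_sig,
                    focal_marker=focal,
                    focal_p=float(p.min()),
                    focal_beta_major=float(info.loc[focal, "beta_major"]),
                    length_mbp=round_half_up((stop - start) / 1e6, 2),
                    single_marker=start == stop,
                )
            )
        chrom_regions.sort(key=lambda r: r.start)
        for k, r in enumerate(chrom_regions, start=1):
            r.region_id = f"{trait}.{chrom}.{k}"
        regions.extend(chrom_regions)
    logger.info(
        "delineate_regions(%s/%s): %d significant markers -> %d regions",
        trait, treatment, len(sig), len(regions),
    )
    return regions


def deduplicate_regions(regions: list[AssociatedRegion]) -> pd.DataFrame:
    """Merge overlapping intervals across traits/treatments into unique regions.

    Regions on the same chromosome whose [start, stop] intervals overlap
    (inclusively) collapse into one unique region carrying every contributing
    trait/treatment label.
    """
    rows = []
    by_chrom: dict[str, list[AssociatedRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    uid = 0
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.stop))
        cluster: list[AssociatedRegion] = []
        hi = None
        for r in rs + [None]:
            if r is not None and (hi is None or r.start <= hi):
                cluster.append(r)
                hi = r.stop if hi is None else max(hi, r.stop)
                continue
            if cluster:
                uid += 1
                start = min(c.start for c in cluster)
                stop = max(c.stop for c in cluster)
                rows.append(
                    {
                        "unique_region_id": f"UR{uid:03d}",
                        "chrom": chrom,
                        "start": start,
                        "stop": stop,
                        "length_mbp": round_half_up((stop - start) / 1e6, 2),
                        "n_source_regions": len(cluster),
                        "traits": ";".join(sorted({c.trait for c in cluster})),
                        "treatments": ";".join(sorted({c.treatment for c in cluster})),
                        "source_regions": ";".join(c.region_id for c in cluster),
                    }
                )
            if r is not None:
                cluster = [r]
                hi = r.stop
    return pd.DataFrame(rows)


def ld_heatmap_data(region: AssociatedRegion, panel: GenotypePanel) -> pd.DataFrame:
    """Pairwise r^2 among region members, in position order, for plotting."""
    if len(region.members) < 2:
        logger.info("ld_heatmap_data: singleton region %s", region.region_id)
        return pd.DataFrame()
    idx = [panel.marker_index(m) for m in region.members]
    r2 = pairwise_r2(panel.dosage[:, idx])
    df = pd.DataFrame(r2, index=region.members, columns=region.members)
    df.attrs["significant"] = list(region.significant)
    return df
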