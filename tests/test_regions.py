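"""Region delineation: significant/suggestive sets, LD bins, merging, lengths."""

import numpy as np
import pandas as pd
import pytest

from seedgwas import multiplicity
from seedgwas.regions import (
    RegionConfig,
    deduplicate_regions,
    delineate_regions,
    ld_bins,
    ld_heatmap_data,
    significant_set,
    suggestive_set,
)
from tests.conftest import make_panel


def assoc_table(markers, p_values, panel, trait="t", treatment="ww", betas=None):
    info = panel.markers.set_index("id")
    betas = betas if betas is not None else np.ones(len(markers))
    return pd.DataFrame(
        {
            "marker": markers,
            "chrom": [info.loc[m, "chrom"] for m in markers],
            "pos": [info.loc[m, "pos"] for m in markers],
            "trait": trait,
            "treatment": treatment,
            "beta_major": betas,
            "p_value": p_values,
        }
    )


class TestSignificantAndSuggestive:
    def test_boundary_p_included(self):
        panel = make_panel([[0, 2, 0, 2], [0, 2, 2, 0]])
        tab = assoc_table(panel.markers["id"].tolist(), [5.6e-7, 2.10e-9], panel)
        got = significant_set(tab, 5.6e-7)
        assert set(got) == set(panel.markers["id"])

    def test_top_fraction_count_and_ties(self):
        panel = make_panel([list(np.random.default_rng(0).choice([0.0, 2.0], 10))] * 100,
                           positions=list(range(1000, 101000, 1000)))
        ps = np.linspace(1e-6, 1.0, 100)
        tab = assoc_table(panel.markers["id"].tolist(), ps, panel)
        assert len(suggestive_set(tab, 0.05)) == 5
        # 3-way tie straddling the cutoff rank pulls all ties in
        ps_tied = ps.copy()
        ps_tied[4] = ps_tied[5] = ps_tied[6] = ps_tied[4]
        tab2 = assoc_table(panel.markers["id"].tolist(), ps_tied, panel)
        assert len(suggestive_set(tab2, 0.05)) == 7

    def test_significant_subset_of_suggestive(self):
        rng = np.random.default_rng(1)
        panel = make_panel([[0, 2, 0, 2]] * 50, positions=list(range(1000, 51000, 1000)))
        ps = rng.uniform(size=50)
        tab = assoc_table(panel.markers["id"].tolist(), ps, panel)
        thr = np.quantile(ps, 0.02)
        assert set(significant_set(tab, thr)) <= set(suggestive_set(tab, 0.05))


class TestLdBins:
    def test_single_marker_singleton_bin(self):
        panel = make_panel([[0, 0, 2, 2]])
        assert ld_bins(panel.markers["id"].tolist(), panel) == [
            [panel.markers["id"][0]]
        ]

    def test_block_plus_isolate(self):
        rng = np.random.default_rng(2)
        a = rng.choice([0.0, 2.0], size=40)
        d = rng.choice([0.0, 2.0], size=40)
        panel = make_panel([a, a, a, d], positions=[100, 200, 300, 400])
        ids = panel.markers["id"].tolist()
        bins = ld_bins(ids, panel)
        assert sorted(map(len, bins)) == [1, 3]
        assert set(bins[0]) == set(ids[:3])
        assert bins[1] == [ids[3]]

    def test_bins_partition_input(self, small_filtered):
        chrom = small_filtered.markers["chrom"].iloc[0]
        sub = small_filtered.markers[small_filtered.markers["chrom"] == chrom]
        ids = sub["id"].tolist()[:60]
        bins = ld_bins(ids, small_filtered)
        flat = [m for b in bins for m in b]
        assert sorted(flat) == sorted(ids)
        assert len(flat) == len(set(flat))


class TestDelineate:
    def _two_marker_region(self, chrom, pos_a, pos_b):
        rng = np.random.default_rng(3)
        col = rng.choice([0.0, 2.0], size=40)
        panel = make_panel([col, col.copy()], positions=[pos_a, pos_b], chrom=chrom)
        tab = assoc_table(panel.markers["id"].tolist(), [1e-9, 1e-8], panel)
        regs = delineate_regions(tab, panel, threshold=1e-6)
        assert len(regs) == 1
        return regs[0]

    def test_region_length_rounding_10_25(self):
        r = self._two_marker_region("Chr08", 80858728, 91104021)
        assert r.length_mbp == 10.25

    def test_region_length_rounding_186_22(self):
        r = self._two_marker_region("Chr10", 23215730, 209437850)
        assert r.length_mbp == 186.22
        from seedgwas._util import round_half_up

        assert round_half_up((r.stop - r.start) / 1e6, 1) == 186.2

    def test_single_marker_region_zero_length(self):
        rng = np.random.default_rng(4)
        iso = rng.choice([0.0, 2.0], size=60)
        other = rng.choice([0.0, 2.0], size=60)
        panel = make_panel([iso, other], positions=[190678838, 195000000], chrom="Chr13")
        ids = panel.markers["id"].tolist()
        tab = assoc_table(ids, [4.76e-7, 0.9], panel)
        regs = delineate_regions(tab, panel, threshold=5.6e-7)
        assert len(regs) == 1
        assert regs[0].single_marker and regs[0].length_mbp == 0.00
        assert regs[0].focal_marker == ids[0]

    def test_suggestive_members_extend_boundaries(self):
        rng = np.random.default_rng(5)
        col = rng.choice([0.0, 2.0], size=80)
        noisy = col.copy()
        flip = rng.random(80) < 0.02
        noisy[flip] = 2.0 - noisy[flip]
        far = rng.choice([0.0, 2.0], size=80)
        panel = make_panel([col, noisy, far], positions=[1000, 50000, 90000])
        ids = panel.markers["id"].tolist()
        # marker 2 significant, marker 1 merely suggestive, marker 3 unrelated
        tab = assoc_table(ids, [1e-9, 5e-4, 0.5], panel)
        regs = delineate_regions(tab, panel, threshold=1e-6,
                                 cfg=RegionConfig(suggestive_top_frac=0.67))
        assert len(regs) == 1
        assert regs[0].start == 1000 and regs[0].stop == 50000
        assert set(regs[0].significant) == {ids[0]}

    def test_every_significant_marker_in_exactly_one_region(self, small_filtered):
        rng = np.random.default_rng(6)
        ids = small_filtered.markers["id"].tolist()
        ps = rng.uniform(size=len(ids))
        ps[rng.choice(len(ids), 12, replace=False)] = rng.uniform(1e-10, 1e-8, 12)
        tab = assoc_table(ids, ps, small_filtered)
        regs = delineate_regions(tab, small_filtered, threshold=1e-7)
        sig = set(significant_set(tab, 1e-7))
        seen: list[str] = []
        for r in regs:
            seen.extend(set(r.significant))
        assert sorted(seen) == sorted(sig)

    def test_no_significant_markers_no_regions(self, small_filtered):
        ids = small_filtered.markers["id"].tolist()
        tab = assoc_table(ids, np.linspace(0.1, 1.0, len(ids)), small_filtered)
        assert delineate_regions(tab, small_filtered, threshold=1e-6) == []


class TestDeduplicate:
    def _region(self, trait, treatment, chrom, start, stop, rid="r"):
        from seedgwas.regions import AssociatedRegion

        return AssociatedRegion(
            region_id=rid, trait=trait, treatment=treatment, chrom=chrom,
            start=start, stop=stop, start_marker="a", stop_marker="b",
            members=["a", "b"], significant=["a"], focal_marker="a",
            focal_p=1e-8, focal_beta_major=0.1,
            length_mbp=round((stop - start) / 1e6, 2), single_marker=start == stop,
        )

    def test_shared_boundaries_merge_with_both_labels(self):
        a = self._region("root_biomass", "wl", "Chr08", 80858728, 91104021, "A")
        b = self._region("trl", "wl", "Chr08", 80858728, 91104021, "B")
        out = deduplicate_regions([a, b])
        assert len(out) == 1
        assert set(out.loc[0, "traits"].split(";")) == {"root_biomass", "trl"}

    def test_disjoint_intervals_not_merged(self):
        a = self._region("x", "ww", "Chr01", 100, 200, "A")
        b = self._region("y", "ww", "Chr01", 300, 400, "B")
        assert len(deduplicate_regions([a, b])) == 2

    def test_unique_count_never_exceeds_input(self):
        rng = np.random.default_rng(7)
        regs = []
        for i in range(20):
            s = int(rng.integers(0, 1_000_000))
            regs.append(self._region("x", "ww", f"Chr{rng.integers(1, 4)}",
                                     s, s + int(rng.integers(0, 200_000)), str(i)))
        assert len(deduplicate_regions(regs)) <= 20


class TestHeatmap:
    def test_symmetric_unit_diagonal_consistent(self, small_filtered):
        ids = small_filtered.markers["id"].tolist()[:5]
        from seedgwas.regions import AssociatedRegion

        pos = small_filtered.markers["pos"].tolist()[:5]
        r = AssociatedRegion(
            region_id="r", trait="t", treatment="ww",
            chrom=small_filtered.markers["chrom"].iloc[0],
            start=pos[0], stop=pos[4], start_marker=ids[0], stop_marker=ids[4],
            members=ids, significant=ids[:1], focal_marker=ids[0], focal_p=1e-8,
            focal_beta_major=0.2, length_mbp=0.0, single_marker=False,
        )
        heat = ld_heatmap_data(r, small_filtered)
        np.testing.assert_allclose(np.diag(heat.to_numpy()), 1.0)
        np.testing.assert_allclose(heat.to_numpy(), heat.to_numpy().T)
        got = heat.iloc[0, 3]
        want = multiplicity.dosage_r2(
            small_filtered,
            small_filtered.marker_index(ids[0]),
            small_filtered.marker_index(ids[3]),
        )
        assert got == pytest.approx(want, abs=1e-12)

    def test_singleton_region_empty_table(self, small_filtered):
        from seedgwas.regions import AssociatedRegion

        ids = small_filtered.markers["id"].tolist()[:1]
        pos = small_filtered.markers["pos"].iloc[0]
        r = AssociatedRegion(
            region_id="r", trait="t", treatment="ww",
            chrom=small_filtered.markers["chrom"].iloc[0],
            start=pos, stop=pos, start_marker=ids[0], stop_marker=ids[0],
            members=ids, significant=ids, focal_marker=ids[0], focal_p=1e-8,
            focal_beta_major=0.2, length_mbp=0.0, single_marker=True,
        )
        assert ld_heatmap_data(r, small_filtered).empty
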