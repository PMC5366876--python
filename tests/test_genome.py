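"""Chromatin model construction and break-induction rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from iontrack.genome import (
    DamageParams,
    build_nucleus_model,
    convert_sb_to_dsb,
    deposits_to_direct_breaks,
    direct_sb_probability,
    dna_mass_per_slab,
    indirect_breaks,
    read_breaks,
    write_breaks,
)
from iontrack.geometry import sphere_slab_volume
from iontrack.pipeline import uniform_deposit_set
from iontrack.transport import Deposits


class TestModelConstruction:
    def test_full_genome_occupancy_fraction(self, full_model):
        # 6.4 Gbp / 5500 bp per 50-nm voxel inside a 10-um sphere:
        # about 28% of the lattice cells are chromatin
        r = full_model.nucleus_radius
        centers = (np.arange(full_model.grid.shape[0]) + 0.5) * 0.05 - 5.0
        ii, jj, kk = np.meshgrid(centers, centers, centers, indexing="ij")
        inside = (ii**2 + jj**2 + kk**2) <= r**2
        frac = full_model.n_voxels / inside.sum()
        assert frac == pytest.approx(0.28, abs=0.02)

    def test_every_bp_maps_to_exactly_one_voxel(self, small_model):
        m = small_model
        # per chromosome, bp_start increments by bp_per_voxel: the voxel
        # intervals partition [1, chrom_length]
        for c in range(m.n_chromosomes):
            bp = m.bp_start[m.chrom_id == c]
            assert bp[0] == 1
            assert np.all(np.diff(bp) == m.bp_per_voxel)
            assert bp[-1] + m.bp_per_voxel - 1 == m.chrom_lengths_bp[c]
        assert m.chrom_lengths_bp.sum() == m.genome_length

    def test_grid_and_walk_agree(self, small_model):
        m = small_model
        w = m.grid[m.voxel_ijk[:, 0], m.voxel_ijk[:, 1], m.voxel_ijk[:, 2]]
        np.testing.assert_array_equal(w, np.arange(m.n_voxels))
        assert (m.grid >= 0).sum() == m.n_voxels

    def test_chromosome_territories_essentially_connected(self, small_model):
        # every voxel after a chromosome's first is lattice-adjacent to
        # some earlier voxel of the same chromosome, up to a handful of
        # fresh-component starts when a territory gets enclosed
        m = small_model
        for c in range(m.n_chromosomes):
            vox = {tuple(v) for v in m.voxel_ijk[m.chrom_id == c]}
            sel = m.voxel_ijk[m.chrom_id == c]
            detached = 0
            for v in sel[1:]:
                nbrs = [(v[0] + d[0], v[1] + d[1], v[2] + d[2])
                        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                  (0, -1, 0), (0, 0, 1), (0, 0, -1))]
                if not any(nb in vox for nb in nbrs):
                    detached += 1
            assert detached == 0  # isolated single voxels never occur
        # and the number of walk-order discontinuities stays tiny
        jumps = 0
        for c in range(m.n_chromosomes):
            sel = m.voxel_ijk[m.chrom_id == c]
            step = np.abs(np.diff(sel.astype(int), axis=0)).sum(axis=1)
            jumps += int(np.count_nonzero(step != 1))
        assert jumps < 0.05 * m.n_voxels

    def test_different_seeds_different_walks_same_coverage(self, geometry):
        a = build_nucleus_model(geometry, 2e7, seed=1)
        b = build_nucleus_model(geometry, 2e7, seed=2)
        assert a.n_voxels == b.n_voxels
        assert not np.array_equal(a.voxel_ijk, b.voxel_ijk)

    def test_oversized_genome_rejected(self, geometry):
        with pytest.raises(ValueError, match="fit|dense|cells"):
            build_nucleus_model(geometry, 5e10, seed=0)


class TestDnaMassPerSlab:
    def test_closure_and_central_dominance(self, small_model, geometry, rng):
        mass = dna_mass_per_slab(small_model, geometry, 25, rng)
        assert mass.sum() == pytest.approx(small_model.genome_length,
                                           rel=0.005)
        assert mass[20:30].mean() > mass[:5].mean()
        assert mass[20:30].mean() > mass[-5:].mean()

    def test_matches_analytic_chord_profile(self, full_model, geometry):
        # DNA is uniform over the sphere at large scale, so the slab
        # profile follows the sphere's slab-volume profile
        rng = np.random.default_rng(99)
        mass = dna_mass_per_slab(full_model, geometry, 300, rng)
        vols = np.array([sphere_slab_volume(5.0, -5 + 0.2 * i,
                                            -5 + 0.2 * (i + 1))
                         for i in range(50)])
        expected = vols / vols.sum() * full_model.genome_length
        err = np.abs(mass - expected) / expected.max()
        assert err.max() < 0.03


class TestDirectBreaks:
    def test_ramp_endpoints_and_midpoint(self):
        assert direct_sb_probability(5.0) == 0.0
        assert direct_sb_probability(37.5) == 1.0
        assert direct_sb_probability(21.25) == pytest.approx(0.5)
        assert direct_sb_probability(0.0) == 0.0
        assert direct_sb_probability(100.0) == 1.0

    def test_no_deposits_in_chromatin_no_breaks(self, small_model, rng):
        # deposits placed outside the nucleus cannot break anything
        dep = Deposits([[0, 0, 30.0]], [100.0], [0], [0])
        out = deposits_to_direct_breaks(dep, small_model,
                                        DamageParams(f_dna=1.0), rng)
        assert len(out) == 0

    def test_single_saturating_deposit_breaks_exactly_once(self, small_model,
                                                           rng):
        center = small_model.voxel_centers()[123]
        dep = Deposits([center], [40.0], [0], [7])
        out = deposits_to_direct_breaks(dep, small_model,
                                        DamageParams(f_dna=1.0), rng)
        assert len(out) == 1
        assert out.iloc[0]["origin"] == "direct"
        assert out.iloc[0]["track_id"] == 7

    def test_accumulation_matches_closed_form(self, small_model):
        # two 15 eV deposits at one point: with probability 1/2 they hit
        # the same strand (break prob ramp(30)), else two independent
        # ramp(15) chances; overall expectation 0.5*0.7692 + 0.6154/2... =
        # computed below from the ramp directly
        p30 = direct_sb_probability(30.0)
        p15 = direct_sb_probability(15.0)
        expected = 0.5 * p30 + 0.5 * 2 * p15
        vox = small_model.voxel_centers()
        n_v = min(20_000, len(vox))
        pts = np.repeat(vox[:n_v], 2, axis=0)
        dep = Deposits(pts, np.full(2 * n_v, 15.0),
                       np.zeros(2 * n_v, dtype=np.int8),
                       np.zeros(2 * n_v, dtype=np.int64))
        out = deposits_to_direct_breaks(dep, small_model,
                                        DamageParams(f_dna=1.0),
                                        np.random.default_rng(6))
        # per voxel the two deposits may land in different groups (the
        # longitudinal projection maps both to the same bp, strands are
        # coin flips): mean breaks per voxel follows the closed form
        rate = len(out) / n_v
        sem = np.sqrt(expected / n_v) * 3
        assert rate == pytest.approx(expected, abs=3 * sem)

    def test_break_positions_uniform_over_genome(self, small_model):
        # uniform deposits -> break genomic positions uniform (chi^2)
        dep = uniform_deposit_set(2e6, 5.0, seed=8)
        out = deposits_to_direct_breaks(dep, small_model,
                                        DamageParams(f_dna=1.0),
                                        np.random.default_rng(9))
        m = small_model
        # global genomic coordinate
        offs = np.concatenate([[0], np.cumsum(m.chrom_lengths_bp)[:-1]])
        g = out["pos"].to_numpy() + offs[out["chromosome"].to_numpy()]
        counts, _ = np.histogram(g, bins=20, range=(1, m.genome_length))
        exp = len(g) / 20
        chi2 = ((counts - exp) ** 2 / exp).sum()
        assert stats.chi2.sf(chi2, df=19) > 1e-3


class TestIndirectBreaks:
    def test_deoxyribose_break_fraction_is_65_percent(self, small_model):
        # radicals spawned right inside chromatin voxels so that many
        # deoxyribose encounters accumulate
        n = 40_000
        vox = small_model.voxel_centers()
        pts = vox[np.arange(n) % len(vox)]
        pts = pts + np.random.default_rng(1).uniform(-0.02, 0.02, (n, 3))
        dep = Deposits(pts, np.full(n, 50.0), np.zeros(n, dtype=np.int8),
                       np.arange(n, dtype=np.int64))
        stats_d = {}
        params = DamageParams(f_dna=0.0, p_oh=1.0, p_deoxy=0.5)
        indirect_breaks(dep, small_model, params,
                        np.random.default_rng(11), stats=stats_d)
        n_enc = stats_d["deoxyribose_encounters"]
        assert n_enc > 5000
        frac = stats_d["breaks"] / n_enc
        assert frac == pytest.approx(0.65, abs=4 * np.sqrt(0.2275 / n_enc))

    def test_no_radicals_no_breaks(self, small_model, rng):
        dep = uniform_deposit_set(1e5, 5.0, seed=12)
        out = indirect_breaks(dep, small_model, DamageParams(p_oh=0.0), rng)
        assert len(out) == 0

    def test_concentrated_deposits_less_efficient_than_dispersed(
            self, small_model):
        # same total energy: all deposits inside one voxel (track core
        # surrogate) vs spread over the nucleus; the per-voxel radical
        # cap suppresses the concentrated configuration
        params = DamageParams(f_dna=0.0, p_oh=1.0, p_deoxy=0.3,
                              k_max_radicals_per_voxel=12)
        n = 4000
        center = small_model.voxel_centers()[200]
        conc = Deposits(np.repeat([center], n, axis=0)
                        + np.random.default_rng(1).uniform(-0.02, 0.02, (n, 3)),
                        np.full(n, 50.0), np.zeros(n, dtype=np.int8),
                        np.zeros(n, dtype=np.int64))
        disp = uniform_deposit_set(n * 50.0, 5.0, seed=2)
        out_c = indirect_breaks(conc, small_model, params,
                                np.random.default_rng(3))
        out_d = indirect_breaks(disp, small_model, params,
                                np.random.default_rng(4))
        assert len(out_c) < 0.5 * len(out_d)


class TestConversion:
    def test_binomial_rate(self, rng):
        n = 100_000
        breaks = pd.DataFrame({
            "chromosome": np.zeros(n, dtype=np.int64),
            "pos": np.arange(1, n + 1) * 100,
            "strand": np.zeros(n, dtype=np.int8),
            "origin": "direct",
            "track_id": np.zeros(n, dtype=np.int64),
        })
        out = convert_sb_to_dsb(breaks, rng, prob=0.01)
        n_conv = len(out) - n
        assert n_conv == pytest.approx(1000, abs=4 * np.sqrt(1000))

    def test_zero_probability_is_identity(self, rng):
        breaks = pd.DataFrame({
            "chromosome": [0], "pos": [10], "strand": [0],
            "origin": ["direct"], "track_id": [0]})
        out = convert_sb_to_dsb(breaks, rng, prob=0.0)
        pd.testing.assert_frame_equal(out, breaks)

    def test_partner_on_opposite_strand_same_position(self):
        breaks = pd.DataFrame({
            "chromosome": [0], "pos": [10], "strand": [0],
            "origin": ["direct"], "track_id": [3]})
        out = convert_sb_to_dsb(breaks, np.random.default_rng(0), prob=1.0)
        assert len(out) == 2
        partner = out.iloc[1]
        assert partner["strand"] == 1
        assert partner["pos"] == 10
        assert partner["origin"] == "converted"
        assert partner["track_id"] == 3


class TestBreakListIO:
    def test_round_trip(self, tmp_path, rng):
        from iontrack.pipeline import random_breaks

        df = random_breaks(50, 1_000_000, seed=3)
        p = tmp_path / "breaks.tsv"
        write_breaks(df, p)
        back = read_breaks(p)
        pd.testing.assert_frame_equal(back, df)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chromosome\tpos\n1\t2\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_breaks(p)
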