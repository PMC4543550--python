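"""Fate rules, Notch contacts, gradients, samplers, division and lifecycle."""

import numpy as np
import pytest
from scipy import stats as sps

import cryptsim as cs
from cryptsim.lineage import (CellCollection, GradientSpec, contact_neighbors,
                              notch_activity, compute_notch, exogenous_signal,
                              total_wnt, fate_table, update_fate, update_fates,
                              draw_cycle_length, draw_paneth_lifetime,
                              divide_cell, lifecycle_update,
                              STEM, PANETH, ENTEROCYTE, GOBLET)

CFG = cs.load_config()
SURF = cs.CryptSurface(30.0, 160.0)


def _pair(rng, types, d=6.0, n=10):
    coll = CellCollection()
    for k, t in enumerate(types):
        coll.add_cell(rng.normal(0, 1.2, (n, 3)) + [k * d, 0, 50.0], t, 24.0)
    return coll


class TestNotch:
    def test_two_paneth_contacts_sum(self):
        rng = np.random.default_rng(0)
        coll = _pair(rng, [STEM, PANETH, PANETH], d=5.0)
        # middle the target? use cell 0 with both paneth nearby
        coll.pos[10:20] -= [0.0, 0, 0]   # cells at x=0,5,10
        nb = contact_neighbors(coll, 0, CFG.contact_distance)
        act = notch_activity(coll, nb, CFG)
        assert act == pytest.approx(0.35 * len(nb))

    def test_goblet_contact_weight(self):
        rng = np.random.default_rng(1)
        coll = _pair(rng, [STEM, GOBLET], d=5.0)
        nb = contact_neighbors(coll, 0, CFG.contact_distance)
        assert len(nb) == 1
        assert notch_activity(coll, nb, CFG) == pytest.approx(1.0)

    def test_stem_and_enterocyte_contacts_contribute_zero(self):
        rng = np.random.default_rng(2)
        coll = _pair(rng, [STEM, STEM, ENTEROCYTE], d=5.0)
        nb = contact_neighbors(coll, 0, CFG.contact_distance)
        assert len(nb) >= 1
        assert notch_activity(coll, nb, CFG) == 0.0

    def test_distant_cells_not_in_contact(self):
        rng = np.random.default_rng(3)
        coll = _pair(rng, [STEM, PANETH], d=25.0)
        assert len(contact_neighbors(coll, 0, CFG.contact_distance)) == 0

    def test_vectorised_matches_per_cell(self):
        rng = np.random.default_rng(4)
        coll = _pair(rng, [STEM, PANETH, GOBLET, ENTEROCYTE, PANETH], d=6.0)
        allv = compute_notch(coll, CFG)
        for i in range(coll.n_cells):
            nb = contact_neighbors(coll, i, CFG.contact_distance)
            assert allv[i] == pytest.approx(notch_activity(coll, nb, CFG))


class TestGradients:
    def test_profile_endpoints(self):
        wnt = GradientSpec("WNT", 160.0, 0.0)
        bmp = GradientSpec("BMP", 160.0, 0.0)
        rng = np.random.default_rng(0)
        assert exogenous_signal(0.0, wnt, rng) == 1.0
        assert exogenous_signal(160.0, wnt, rng) == 0.0
        assert exogenous_signal(0.0, bmp, rng) == 0.0
        assert exogenous_signal(160.0, bmp, rng) == 1.0

    def test_wnt_threshold_height(self):
        # 1 - z/H = 0.85 at z = 24 μm: the stem-zone boundary
        wnt = GradientSpec("WNT", 160.0, 0.0)
        rng = np.random.default_rng(0)
        assert exogenous_signal(24.0, wnt, rng) == pytest.approx(0.85)

    def test_noise_reproducible_and_floored(self):
        spec = GradientSpec("WNT", 160.0, 0.4)
        a = [exogenous_signal(80.0, spec, np.random.default_rng(9))
             for _ in range(3)]
        assert a[0] == a[1] == a[2]
        vals = exogenous_signal(np.full(2000, 158.0),
                                GradientSpec("WNT", 160.0, 5.0),
                                np.random.default_rng(1))
        assert np.all(vals >= 0.0)

    def test_global_gradient_stem_zone_is_exactly_low_crypt(self):
        """With the gradient alone, I_wnt >= 0.85 iff z <= 24 μm."""
        spec = GradientSpec("WNT", 160.0, 0.0)
        z = np.linspace(0, 160, 1601)
        vals = spec.profile(z)
        assert np.array_equal(vals >= 0.85, z <= 24.0 + 1e-9)


class TestTotalWnt:
    def test_gradient_only_at_base(self):
        rng = np.random.default_rng(0)
        coll = CellCollection()
        coll.add_cell(rng.normal(0, 1.0, (10, 3)) * [1, 1, 0], STEM, 24.0)
        spec = GradientSpec("WNT", 160.0, 0.0)
        v = total_wnt(coll, 0, None, spec, rng, global_on=True)
        assert v == pytest.approx(1.0, abs=0.02)

    def test_local_only_and_additivity(self):
        rng = np.random.default_rng(1)
        coll = CellCollection()
        coll.add_cell(rng.normal(0, 1.0, (10, 3)) + [5, 5, 5], STEM, 24.0)
        g = cs.ChemicalGrid((0, 0, 0), 1.0, (12, 12, 12))
        g.mask[:] = True
        g.c[:] = 0.9
        spec = GradientSpec("WNT", 160.0, 0.0)
        local = total_wnt(coll, 0, g, spec, rng, global_on=False)
        assert local == pytest.approx(0.9)
        both = total_wnt(coll, 0, g, spec, rng, global_on=True)
        grad_only = total_wnt(coll, 0, None, spec, rng, global_on=True)
        assert both == pytest.approx(local + grad_only)


class TestFateRules:
    @pytest.mark.parametrize("iw,inotch,start,expect", [
        (0.9, 0.7, STEM, STEM),
        (0.9, 0.0, STEM, PANETH),
        (0.5, 1.0, GOBLET, ENTEROCYTE),
        (0.5, 0.1, ENTEROCYTE, GOBLET),
        (0.9, 0.7, PANETH, PANETH),   # absorbing
        (0.2, 0.0, PANETH, PANETH),
    ])
    def test_fate_examples(self, iw, inotch, start, expect):
        assert update_fate(start, iw, inotch, CFG) == expect

    def test_fate_table_exhaustive_against_reimplementation(self):
        """The vectorised fate map equals a literal if/else enumeration."""
        grid = np.linspace(0, 1.5, 31)
        for iw in grid:
            for inot in grid:
                got = int(fate_table(iw, inot, CFG))
                if iw >= 0.85:
                    want = STEM if inot >= 0.3 else PANETH
                else:
                    want = ENTEROCYTE if inot >= 0.3 else GOBLET
                assert got == want

    def test_differentiated_cells_never_reenter_stem_by_default(self):
        types = np.array([ENTEROCYTE, GOBLET], dtype=np.int8)
        new = update_fates(types, np.array([1.0, 1.0]), np.array([1.0, 0.0]),
                           CFG)
        assert new[0] == ENTEROCYTE and new[1] == GOBLET
        cfg2 = CFG.replace(allow_stem_reentry=True)
        new2 = update_fates(types, np.array([1.0, 1.0]), np.array([1.0, 0.0]),
                            cfg2)
        assert new2[0] == STEM and new2[1] == PANETH


class TestSamplers:
    def test_cycle_lengths_bounded_and_centred(self):
        rng = np.random.default_rng(11)
        x = draw_cycle_length(rng, CFG, size=100_000)
        assert np.all((x >= 20.0) & (x <= 28.0))
        assert x.mean() == pytest.approx(24.0, abs=0.05)

    def test_paneth_lifetimes_bounded_and_centred(self):
        rng = np.random.default_rng(12)
        x = draw_paneth_lifetime(rng, CFG, size=100_000)
        assert np.all((x >= 6.0) & (x <= 10.0))
        assert x.mean() == pytest.approx(8.0, abs=0.05)

    def test_distribution_matches_truncated_normal(self):
        rng = np.random.default_rng(13)
        x = draw_cycle_length(rng, CFG, size=100_000)
        a, b = (20 - 24) / 4, (28 - 24) / 4
        _, p = sps.kstest(x, sps.truncnorm(a, b, loc=24, scale=4).cdf)
        assert p > 0.01

    def test_same_seed_same_sequence(self):
        a = draw_cycle_length(np.random.default_rng(5), CFG, size=100)
        b = draw_cycle_length(np.random.default_rng(5), CFG, size=100)
        assert np.array_equal(a, b)

    def test_cycle_shift_subtracts(self):
        cfg = CFG.replace(cycle_shift_h=3.0)
        a = draw_cycle_length(np.random.default_rng(6), CFG, size=1000)
        b = draw_cycle_length(np.random.default_rng(6), cfg, size=1000)
        assert np.allclose(a - 3.0, b)


class TestDivision:
    def _wall_cell(self, rng, n):
        # a blob hugging the cylinder wall at z=100
        els = np.array([28.0, 0, 100.0]) + rng.normal(0, 1.6, (n, 3))
        coll = CellCollection()
        coll.add_cell(els, STEM, 24.0)
        coll.timer_h[0] = 25.0
        return coll

    def test_even_split(self):
        rng = np.random.default_rng(0)
        coll = self._wall_cell(rng, 20)
        j = divide_cell(coll, 0, SURF, rng, CFG)
        assert sorted([coll.counts[0], coll.counts[j]]) == [10, 10]

    def test_odd_split_differs_by_one(self):
        rng = np.random.default_rng(1)
        coll = self._wall_cell(rng, 21)
        j = divide_cell(coll, 0, SURF, rng, CFG)
        assert sorted([coll.counts[0], coll.counts[j]]) == [10, 11]

    def test_timers_reset_and_cycles_redrawn(self):
        rng = np.random.default_rng(2)
        coll = self._wall_cell(rng, 20)
        j = divide_cell(coll, 0, SURF, rng, CFG)
        assert coll.timer_h[0] == 0.0 and coll.timer_h[j] == 0.0
        assert 20.0 <= coll.cycle_length_h[j] <= 28.0

    def test_daughters_keep_wall_contact(self):
        """Division plane contains the wall normal, so both daughters keep
        at least one element within the adhesion range."""
        from cryptsim.lineage import wall_distances
        for seed in range(5):
            rng = np.random.default_rng(seed)
            coll = self._wall_cell(rng, 20)
            j = divide_cell(coll, 0, SURF, rng, CFG)
            for i in (0, j):
                d = wall_distances(coll.elements_of(i), SURF)
                assert d.min() <= CFG.wall_cutoff

    def test_nonstem_division_rejected(self):
        rng = np.random.default_rng(3)
        coll = self._wall_cell(rng, 20)
        coll.type[0] = GOBLET
        with pytest.raises(ValueError):
            divide_cell(coll, 0, SURF, rng, CFG)


class TestLifecycle:
    def _niche_cell(self, rng, z, cell_type=STEM, n=20):
        coll = CellCollection()
        # place on the wall at the requested height
        if z < 30:
            phi = np.arccos(1 - z / 30.0)
            c = np.array([30 * np.sin(phi) - 3.0, 0.0, z])
        else:
            c = np.array([27.0, 0.0, z])
        coll.add_cell(c + rng.normal(0, 1.5, (n, 3)), cell_type, 24.0)
        return coll

    def test_low_bmp_stem_divides(self):
        rng = np.random.default_rng(0)
        coll = self._niche_cell(rng, 8.0)          # BMP ~ 0.05 < 0.15
        coll.timer_h[0] = 30.0
        stats = lifecycle_update(coll, None, SURF, CFG, rng, dt_h=0.1)
        assert stats["births"] == 1 and coll.n_cells == 2

    def test_high_bmp_blocks_division(self):
        rng = np.random.default_rng(1)
        coll = self._niche_cell(rng, 80.0)         # BMP = 0.5 >= 0.15
        coll.timer_h[0] = 30.0
        # keep the cell stem for the check: give it a Paneth neighbour
        coll.add_cell(coll.pos[:20] + [0, 6.0, 0], PANETH, 24.0)
        coll.paneth_life_wk[1] = 8.0
        stats = lifecycle_update(coll, None, SURF, CFG, rng, dt_h=0.1)
        assert stats["births"] == 0

    def test_bmp_off_allows_division_up_high(self):
        rng = np.random.default_rng(2)
        cfg = CFG.replace(bmp_on=False, global_wnt_on=False)
        coll = self._niche_cell(rng, 80.0)
        coll.timer_h[0] = 30.0
        stats = lifecycle_update(coll, None, SURF, cfg, rng, dt_h=0.1)
        assert stats["births"] == 1

    def test_paneth_outliving_lifetime_removed(self):
        rng = np.random.default_rng(3)
        coll = self._niche_cell(rng, 8.0, cell_type=PANETH)
        coll.paneth_life_wk[0] = 8.0
        coll.age_paneth_wk[0] = 10.1
        stats = lifecycle_update(coll, None, SURF, CFG, rng, dt_h=0.1)
        assert stats["removed_apoptosis"] == 1 and coll.n_cells == 0

    def test_cell_over_rim_removed(self):
        rng = np.random.default_rng(4)
        coll = self._niche_cell(rng, 80.0, cell_type=ENTEROCYTE)
        coll.pos[:, 2] += 85.0                      # centroid beyond H=160
        stats = lifecycle_update(coll, None, SURF, CFG, rng, dt_h=0.1)
        assert stats["removed_rim"] == 1 and coll.n_cells == 0

    def test_detached_cell_removed_after_grace(self):
        rng = np.random.default_rng(5)
        coll = CellCollection()
        coll.add_cell(rng.normal(0, 1.0, (20, 3)) + [0, 0, 80.0],
                      ENTEROCYTE, 24.0)             # mid-lumen, 27 μm off wall
        s1 = lifecycle_update(coll, None, SURF, CFG, rng, dt_h=0.1)
        assert coll.n_cells == 1                    # one update of grace
        s2 = lifecycle_update(coll, None, SURF, CFG, rng, dt_h=0.1)
        assert s2["removed_detached"] == 1 and coll.n_cells == 0

    def test_bookkeeping_identity(self):
        """cells(t+dt) = cells(t) + births - removals, exactly."""
        rng = np.random.default_rng(6)
        coll = CellCollection()
        for k in range(6):
            z = 5.0 + 6.0 * k
            phi = np.arccos(max(-1.0, 1 - z / 30.0)) if z < 30 else None
            c = (np.array([30 * np.sin(phi) - 3, 0, z]) if phi is not None
                 else np.array([27.0, 0, z]))
            coll.add_cell(c + rng.normal(0, 1.5, (20, 3)),
                          [STEM, PANETH][k % 2], 24.0)
        coll.timer_h[:] = 23.9
        for _ in range(40):
            before = coll.n_cells
            stats = lifecycle_update(coll, None, SURF, CFG, rng, dt_h=0.5)
            removed = (stats["removed_rim"] + stats["removed_detached"]
                       + stats["removed_apoptosis"])
            assert coll.n_cells == before + stats["births"] - removed

    def test_paneth_fate_is_absorbing_over_time(self):
        rng = np.random.default_rng(7)
        coll = self._niche_cell(rng, 8.0, cell_type=PANETH)
        coll.paneth_life_wk[0] = 8.0
        ids = coll.cell_id.copy()
        for _ in range(30):
            lifecycle_update(coll, None, SURF, CFG, rng, dt_h=0.2)
            for cid in coll.cell_id:
                if cid in ids:
                    assert coll.type[np.nonzero(coll.cell_id == cid)[0][0]] \
                        == PANETH
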