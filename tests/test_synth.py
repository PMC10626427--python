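"""Synthetic scenes, vote tables and morphology sets against ground truth."""

import numpy as np
import pytest
from scipy.ndimage import maximum_filter

from mtlumen import (
    COFILACTIN,
    F_ACTIN,
    LuminalFilamentSpec,
    MicrotubuleSpec,
    SceneSpec,
    VoteSimSpec,
    apply_missing_wedge,
    fractions_over_pf,
    render_scene,
    simulate_morphology_set,
    simulate_vote_table,
)
from mtlumen.synth import (
    POLARITY_WEIGHT,
    SIGMA_ACTIN,
    DensityVolume,
    render_helical_filament,
)


def straight_mt(box=96, apix=11.81, n_pf=13, polarity="plus"):
    ext = box * apix / 10.0
    tr = np.array([[ext / 2, ext / 2, 10.0], [ext / 2, ext / 2, ext - 10.0]])
    return MicrotubuleSpec(tr, n_pf, polarity)


class TestDensityVolume:
    def test_cubic_enforced(self):
        with pytest.raises(ValueError, match="cubic"):
            DensityVolume(np.zeros((16, 16, 8), dtype=np.float32), 11.81)
        with pytest.raises(ValueError, match="16"):
            DensityVolume(np.zeros((8, 8, 8), dtype=np.float32), 11.81)


class TestRenderScene:
    def test_empty_scene_is_zero(self):
        vol, truth = render_scene(SceneSpec(), box=32, apix=11.81)
        assert np.all(vol.grid == 0)
        assert len(truth["microtubules"]) == 0

    @pytest.mark.parametrize("n_pf", [12, 13, 14, 15])
    def test_protofilament_ring_peak_count(self, n_pf):
        spec = SceneSpec(microtubules=[straight_mt(n_pf=n_pf)], noise_sigma=0.0)
        vol, _ = render_scene(spec, box=96, apix=11.81)
        sl = vol.grid[48]
        peaks = (sl == maximum_filter(sl, size=5)) & (sl > 0.5 * sl.max())
        ys, xs = np.nonzero(peaks)
        r = np.hypot(ys - 48.0, xs - 48.0)
        ring = (r > 4) & (r < 14)
        assert ring.sum() == n_pf

    def test_luminal_filament_mass_matches_gaussian_integral(self):
        # a bare f-actin filament away from any microtubule wall: total mass
        # equals n_subunits * (actin blob + polarity marker) analytically
        box, apix = 64, 5.9
        ext = box * apix / 10.0
        mt = MicrotubuleSpec(
            np.array([[ext / 2, ext / 2, 3.0], [ext / 2, ext / 2, ext - 3.0]]),
            13,
            "plus",
        )
        spec = SceneSpec(
            microtubules=[mt],
            luminal_filaments=[
                LuminalFilamentSpec(0, 0.0, ext - 6.0, F_ACTIN, "plus", cofilin=False)
            ],
            noise_sigma=0.0,
        )
        # render only the luminal part by subtracting the microtubule-only scene
        vol_all, truth = render_scene(spec, box, apix)
        vol_mt, _ = render_scene(
            SceneSpec(microtubules=[mt], noise_sigma=0.0), box, apix
        )
        lum_mass = float(vol_all.grid.sum() - vol_mt.grid.sum())
        n_sub = len(
            np.arange(0.0, ext - 6.0 + 1e-9, F_ACTIN.rise_ang / 10.0)
        )
        blob = (2 * np.pi) ** 1.5 * (
            SIGMA_ACTIN**3 + POLARITY_WEIGHT * (0.6 * SIGMA_ACTIN) ** 3
        ) / apix**3
        assert lum_mass == pytest.approx(n_sub * blob, rel=0.01)

    def test_polar_lattice_differs_from_mirror(self):
        plus, _ = render_scene(
            SceneSpec(microtubules=[straight_mt(polarity="plus")], noise_sigma=0.0),
            96,
            11.81,
        )
        minus, _ = render_scene(
            SceneSpec(microtubules=[straight_mt(polarity="minus")], noise_sigma=0.0),
            96,
            11.81,
        )
        mirrored = plus.grid[::-1]
        assert np.abs(minus.grid - mirrored).max() > 1e-3 * plus.grid.max()

    def test_out_of_box_filament_rejected(self):
        bad = MicrotubuleSpec(
            np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]]), 13, "plus"
        )
        with pytest.raises(ValueError, match="fit"):
            render_scene(SceneSpec(microtubules=[bad]), 32, 11.81)

    def test_luminal_extent_must_lie_inside_host(self):
        mt = straight_mt()
        with pytest.raises(ValueError, match="extent"):
            SceneSpec(
                microtubules=[mt],
                luminal_filaments=[
                    LuminalFilamentSpec(0, 0.0, 1e4, COFILACTIN, "plus")
                ],
            )


class TestMissingWedge:
    def test_output_real_and_hermitian_mask(self):
        rng = np.random.default_rng(3)
        g = rng.normal(size=(32, 32, 32)).astype(np.float32)
        w = apply_missing_wedge(g, 60.0)
        assert w.dtype == np.float32
        # re-derive with complex arithmetic: imaginary residue must vanish
        ft = np.fft.fftn(g.astype(np.float64))
        kz = np.fft.fftfreq(32)[:, None, None]
        kx = np.fft.fftfreq(32)[None, None, :]
        angle = np.degrees(np.arctan2(np.abs(kz), np.abs(kx)))
        mask = (angle <= 60.0) | ((kz == 0) & (kx == 0))
        back = np.fft.ifftn(ft * mask)
        assert np.abs(back.imag).max() < 1e-9 * np.abs(back.real).max()
        np.testing.assert_allclose(w, back.real, atol=1e-5)

    def test_wedge_removes_power(self):
        rng = np.random.default_rng(4)
        g = rng.normal(size=(32, 32, 32)).astype(np.float32)
        w = apply_missing_wedge(g, 60.0)
        assert np.sum(w**2) < np.sum(g**2)

    def test_invalid_halfangle(self):
        with pytest.raises(ValueError):
            apply_missing_wedge(np.zeros((16, 16, 16), dtype=np.float32), 0.0)
        with pytest.raises(ValueError):
            apply_missing_wedge(np.zeros((16, 16, 16), dtype=np.float32), 95.0)


class TestVoteTable:
    def test_perfect_votes_single_class(self):
        spec = VoteSimSpec(
            class_fractions={(13, "plus"): 1.0},
            n_filaments=10,
            particles_per_filament=5,
            p_correct=1.0,
            seed=0,
        )
        table, truth = simulate_vote_table(spec)
        assert (table["class_n"] == 13).all()
        assert (table["class_polarity"] == "plus").all()

    def test_expected_correct_fraction(self):
        spec = VoteSimSpec(
            class_fractions=fractions_over_pf({13: 0.5, 12: 0.5}),
            n_filaments=400,
            particles_per_filament=40,
            p_correct=0.85,
            seed=5,
        )
        table, truth = simulate_vote_table(spec)
        merged = table.merge(truth, on="filament_id")
        correct = (
            (merged["class_n"] == merged["true_n"])
            & (merged["class_polarity"] == merged["true_polarity"])
        ).mean()
        assert correct == pytest.approx(0.85, abs=0.01)

    def test_deterministic_under_seed(self):
        spec = VoteSimSpec(
            class_fractions=fractions_over_pf({13: 1.0}),
            n_filaments=20,
            particles_per_filament=8,
            seed=11,
        )
        t1, _ = simulate_vote_table(spec)
        t2, _ = simulate_vote_table(spec)
        assert t1.equals(t2)

    def test_marginal_class_frequencies_converge(self):
        fr = fractions_over_pf({12: 0.1, 13: 0.6, 14: 0.2, 15: 0.1})
        spec = VoteSimSpec(
            class_fractions=fr, n_filaments=10_000, particles_per_filament=1,
            p_correct=1.0, seed=2,
        )
        _, truth = simulate_vote_table(spec)
        for n, expected in [(12, 0.1), (13, 0.6), (14, 0.2), (15, 0.1)]:
            got = (truth["true_n"] == n).mean()
            se = np.sqrt(expected * (1 - expected) / 10_000)
            assert abs(got - expected) <= 3 * se

    def test_zero_particles_rejected(self):
        with pytest.raises(ValueError):
            VoteSimSpec(
                class_fractions={(13, "plus"): 1.0}, particles_per_filament=0
            )

    def test_cc_nonnegative(self):
        spec = VoteSimSpec(
            class_fractions=fractions_over_pf({13: 1.0}),
            n_filaments=100,
            particles_per_filament=10,
            cc_wrong=(0.01, 0.05),
            seed=1,
        )
        table, _ = simulate_vote_table(spec)
        assert (table["cc"] >= 0).all()


class TestMorphologySet:
    def test_pure_composition_labels(self):
        _, meta = simulate_morphology_set((1.0, 0.0, 0.0), n=20, seed=0)
        assert (meta["morphology"] == "cofilactin").all()

    def test_empty_set(self):
        imgs, meta = simulate_morphology_set((1.0, 0.0, 0.0), n=0, seed=0)
        assert imgs.shape[0] == 0 and len(meta) == 0

    def test_composition_recovered_at_scale(self):
        _, meta = simulate_morphology_set((0.5, 0.5, 0.0), n=10_000, seed=3, snr=np.inf)
        frac = (meta["morphology"] == "cofilactin").mean()
        assert abs(frac - 0.5) <= 0.02  # ~4 binomial s.e.

    def test_bad_composition(self):
        with pytest.raises(ValueError):
            simulate_morphology_set((0.5, 0.2, 0.1), n=10, seed=0)


class TestRenderHelicalFilament:
    def test_axial_periodicity_at_rise(self):
        vol = render_helical_filament(COFILACTIN, box=64, apix=5.9, decorated=True)
        prof = vol.grid.sum(axis=(1, 2))
        ft = np.abs(np.fft.rfft(prof - prof.mean()))
        k = np.argmax(ft[1:]) + 1
        period_ang = 64 * 5.9 / k
        assert period_ang == pytest.approx(COFILACTIN.rise_ang, rel=0.1)
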