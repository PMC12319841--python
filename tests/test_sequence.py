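"""Timeline builders and the Monte Carlo simulation loop."""

import numpy as np
import pytest

from boldwalk import (
    SubstrateSet,
    build_bssfp,
    build_grase,
    build_gre,
    build_se,
    build_ste,
    run_simulation,
    save_result,
)

DEG = np.pi / 180.0


class TestBuilders:
    def test_gre_echo_step(self):
        tl = build_gre(20.0, 0.05)
        assert tl.echo_steps == [400]
        assert tl.rf_events == [(0, pytest.approx(np.pi / 2), 0.0)]

    def test_gre_minimal(self):
        assert build_gre(0.05, 0.05).echo_steps == [1]

    def test_off_grid_te_rejected(self):
        with pytest.raises(ValueError, match="multiple of dt"):
            build_gre(20.003, 0.05)

    def test_se_refocus_and_echo_steps(self):
        tl = build_se(30.0, 0.05)
        assert [s for s, *_ in tl.rf_events] == [0, 300]
        assert tl.echo_steps == [600]

    def test_bssfp_pulse_train(self):
        tl = build_bssfp(5.0, 10.0, 20 * DEG, np.pi, n_prep=1100, dt=0.05)
        assert len(tl.rf_events) == 1101
        assert tl.echo_steps == [1100 * 200 + 100]
        phases = [p for *_, p in tl.rf_events[:4]]
        np.testing.assert_allclose(phases, [0, np.pi, 0, np.pi])

    def test_bssfp_requires_te_half_tr(self):
        with pytest.raises(ValueError, match="TE = TR/2"):
            build_bssfp(4.0, 10.0, 20 * DEG)

    def test_grase_echo_count(self):
        tl = build_grase(9, 40.0, 0.05)
        assert len(tl.echo_steps) == 19
        # refocusing pulses at odd multiples of half the echo spacing
        steps = [s for s, f, _ in tl.rf_events if f == pytest.approx(np.pi)]
        assert steps == [(2 * k + 1) * 400 for k in range(9)]

    def test_grase_degenerate_single_se(self):
        tl = build_grase(1, 4.0, 0.05)
        assert len(tl.echo_steps) == 3

    def test_ste_echo_times(self):
        tl = build_ste(20.0, 40.0, 0.05)
        assert tl.echo_times[0] == pytest.approx(40.0)  # primary SE at 2*tau
        assert tl.echo_times[-1] == pytest.approx(80.0)  # STE at 2*tau + Tm

    def test_ste_zero_mixing_collapses(self):
        tl = build_ste(20.0, 0.0, 0.05)
        assert len(tl.rf_events) == 3
        assert tl.echo_times[-1] == pytest.approx(40.0)


class TestRunSimulation:
    def test_single_static_spin_gre_decay(self, uniform_phantom):
        ss = SubstrateSet([2000.0], [41.0], [0.0])
        res = run_simulation(uniform_phantom, ss, build_gre(20.0, 0.05), n_spins=1, seed=0)
        assert abs(res.signal[-1]) == pytest.approx(np.exp(-20 / 41), rel=1e-12)

    def test_se_refocuses_static_spins_in_random_field(self, random_field_phantom):
        """90-180 spin echo fully recovers Ns*exp(-TE/T2) for D = 0."""
        ns, t2 = 400, 41.0
        ss = SubstrateSet([2000.0], [t2], [0.0])
        res = run_simulation(
            random_field_phantom, ss, build_se(30.0, 0.05), n_spins=ns, b0=9.4, seed=1
        )
        assert abs(res.signal[-1]) == pytest.approx(ns * np.exp(-30 / t2), rel=1e-10)

    def test_gre_dephases_but_se_recovers(self, random_field_phantom):
        ns = 400
        ss = SubstrateSet([2000.0], [41.0], [0.0])
        gre = run_simulation(
            random_field_phantom, ss, build_gre(30.0, 0.05), n_spins=ns, b0=9.4, seed=1
        )
        se = run_simulation(
            random_field_phantom, ss, build_se(30.0, 0.05), n_spins=ns, b0=9.4, seed=1
        )
        assert abs(gre.signal[-1]) < 0.95 * abs(se.signal[-1])

    def test_diffusion_in_field_is_irreversible(self, random_field_phantom):
        """With D > 0 in an inhomogeneous field the SE no longer refocuses."""
        ns, t2 = 2000, 41.0
        ss = SubstrateSet([2000.0], [t2], [1.0])
        res = run_simulation(
            random_field_phantom, ss, build_se(30.0, 0.05), n_spins=ns, b0=9.4, seed=2
        )
        assert abs(res.signal[-1]) < ns * np.exp(-30 / t2)

    def test_zero_field_diffusion_invisible(self, uniform_phantom):
        """No field gradients: diffusion leaves GRE/SE at the closed form."""
        ns, t2 = 300, 41.0
        ss = SubstrateSet([2000.0], [t2], [1.0])
        for tl in (build_gre(20.0, 0.05), build_se(20.0, 0.05)):
            res = run_simulation(uniform_phantom, ss, tl, n_spins=ns, seed=3)
            assert abs(res.signal[-1]) == pytest.approx(ns * np.exp(-20 / t2), rel=1e-10)

    def test_bssfp_first_echo_equals_gre(self, random_field_phantom):
        """n_prep = 0 with a 90 degree pulse reduces to a GRE at TE."""
        ss = SubstrateSet([2000.0], [41.0], [1.0])
        a = run_simulation(
            random_field_phantom, ss, build_bssfp(5.0, 10.0, np.pi / 2, n_prep=0, dt=0.05),
            n_spins=200, b0=9.4, seed=4,
        )
        b = run_simulation(
            random_field_phantom, ss, build_gre(5.0, 0.05), n_spins=200, b0=9.4, seed=4
        )
        assert a.signal[-1] == b.signal[-1]

    def test_grase_even_echoes_refocus_static_spins(self, random_field_phantom):
        """Even echoes are pure spin echoes; odd echoes carry GRE weighting."""
        ns, t2 = 300, 60.0
        ss = SubstrateSet([2000.0], [t2], [0.0])
        res = run_simulation(
            random_field_phantom, ss, build_grase(4, 8.0, 0.05), n_spins=ns, b0=9.4, seed=5
        )
        for k, echo in enumerate(res.echoes, start=1):
            expected = ns * np.exp(-echo.time / t2)
            if k % 2 == 0:
                assert abs(echo.total) == pytest.approx(expected, rel=1e-10)
            else:
                assert abs(echo.total) < expected

    def test_ste_closed_form(self, uniform_phantom):
        """STE amplitude follows Ns/2 * exp(-2tau/T2) * exp(-Tm/T1)."""
        ns, t1, t2, tau = 400, 2200.0, 41.0, 20.0
        ss = SubstrateSet([t1], [t2], [0.0])
        for tm in (40.0, 200.0, 1000.0):
            res = run_simulation(
                uniform_phantom, ss, build_ste(tau, tm, 0.05), n_spins=ns, seed=6
            )
            se_exp = 0.5 * ns * np.exp(-2 * tau / t2)
            ste_exp = se_exp * np.exp(-tm / t1)
            assert abs(res.signal[0]) == pytest.approx(se_exp, rel=1e-9)
            assert abs(res.signal[-1]) == pytest.approx(ste_exp, rel=1e-9)

    def test_compartment_sums_add_to_total(self, halfspace_phantom):
        ss = SubstrateSet([2000.0] * 2, [40.0, 20.0], [1.0, 0.5], perm=[[1, 0.4], [0.9, 1]])
        res = run_simulation(
            halfspace_phantom, ss, build_gre(5.0, 0.05), n_spins=2000, b0=9.4, seed=7
        )
        for echo in res.echoes:
            assert echo.by_current.sum() == pytest.approx(echo.total, rel=1e-9)
            assert echo.by_initial.sum() == pytest.approx(echo.total, rel=1e-9)
            assert echo.n_current.sum() == 2000

    def test_seed_reproducibility_bitwise(self, halfspace_phantom):
        ss = SubstrateSet([2000.0] * 2, [40.0, 20.0], [1.0, 0.5])
        kw = dict(n_spins=500, b0=9.4, seed=8)
        a = run_simulation(halfspace_phantom, ss, build_se(10.0, 0.05), **kw)
        b = run_simulation(halfspace_phantom, ss, build_se(10.0, 0.05), **kw)
        assert a.signal[-1] == b.signal[-1]
        np.testing.assert_array_equal(a.echoes[-1].by_current, b.echoes[-1].by_current)

    def test_substrate_count_mismatch_rejected(self, halfspace_phantom):
        ss = SubstrateSet([2000.0], [40.0], [1.0])
        with pytest.raises(ValueError, match="substrate"):
            run_simulation(halfspace_phantom, ss, build_gre(5.0, 0.05), n_spins=10)

    def test_trajectory_recording_shapes(self, halfspace_phantom):
        ss = SubstrateSet([2000.0] * 2, [40.0] * 2, [1.0] * 2)
        res = run_simulation(
            halfspace_phantom, ss, build_gre(1.0, 0.05), n_spins=50, seed=9,
            record_trajectory=True, record_every=5,
        )
        assert res.trajectory.shape == (5, 50, 3)
        assert res.substrate_track.shape == (5, 50)

    def test_save_result_layout(self, tmp_path, uniform_phantom):
        import h5py

        ss = SubstrateSet([2000.0], [41.0], [0.0])
        res = run_simulation(uniform_phantom, ss, build_gre(1.0, 0.05), n_spins=20, seed=1)
        p = tmp_path / "out.h5"
        save_result({"rest/scale_000": res}, p, extra_attrs={"config": "x"})
        with h5py.File(p, "r") as f:
            g = f["rest/scale_000"]
            assert g["echoes/signal_real"].shape == (1, 3)  # total + 1 + 1 compartments
            assert g.attrs["seed"] == 1
            assert "version" in f.attrs
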