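import numpy as np
import pytest

from abzinc.itc import (
    PUBLISHED_PARAMS,
    BindingModel,
    BindingSiteParams,
    ItcError,
    TitrationCurve,
    ZincTitrationModel,
    default_protocol,
    fit_binding_model,
    read_curve_table,
    select_n_sites,
    simulate_titration,
    subtract_blank,
    write_curve_table,
)
from abzinc.synthetic import synth_itc
from .conftest import oracle_titration_heats


def one_site(n=1.0, ka=1e5, dh=-10.0):
    return BindingModel((BindingSiteParams(n, ka, dh),))


class TestSimulate:
    def test_zero_enthalpy_gives_zero_heat(self, protocol):
        model = BindingModel(
            (BindingSiteParams(1.0, 1e5, 0.0), BindingSiteParams(0.4, 1e4, 0.0))
        )
        curve = simulate_titration(model, protocol)
        assert np.allclose(curve.heats, 0.0)

    def test_stoichiometric_limit_saturation_and_inflection(self, protocol):
        # with effectively infinite affinity the titration is stoichiometric:
        # cumulative heat saturates at V0*M*N*dH and the drop sits at ratio ~ N
        n_true = 0.8
        model = one_site(n=n_true, ka=1e12, dh=-10.0)
        det = simulate_titration(model, protocol, return_details=True)
        v0_L = protocol.cell_volume_uL * 1e-6
        q_sat = v0_L * det["m_total_M"].iloc[-1] * n_true * -10.0
        assert det["q_cumulative_kcal"].iloc[-1] == pytest.approx(q_sat, rel=1e-6)
        drops = np.diff(det["heat_kcal_per_mol"])
        ratio_at_drop = det["molar_ratio"].iloc[int(np.argmax(drops)) + 1]
        spacing = float(np.diff(det["molar_ratio"]).max())
        assert abs(ratio_at_drop - n_true) < 1.5 * spacing

    def test_matches_brute_force_oracle_on_random_draws(self, protocol):
        rng = np.random.default_rng(7)
        for _ in range(100):
            sites = []
            for _k in range(rng.integers(1, 3)):
                sites.append(
                    BindingSiteParams(
                        n=float(rng.uniform(0.2, 1.5)),
                        ka=float(10 ** rng.uniform(3, 6)),
                        dh=float(rng.uniform(-15, -2)),
                    )
                )
            model = BindingModel(tuple(sites))
            got = np.asarray(simulate_titration(model, protocol).heats)
            want = oracle_titration_heats(model, protocol)
            assert np.allclose(got, want, rtol=1e-8, atol=1e-12)

    def test_heat_conservation_with_displacement_terms(self, protocol):
        det = simulate_titration(PUBLISHED_PARAMS["D7H-AB16"], protocol, return_details=True)
        dv = np.asarray(protocol.injection_volumes_uL) / protocol.cell_volume_uL
        q = det["q_cumulative_kcal"].to_numpy()
        q_prev = np.concatenate(([0.0], q[:-1]))
        displacement = dv * (q + q_prev) / 2
        total = np.sum(det["dq_kcal"].to_numpy() - displacement)
        assert total == pytest.approx(q[-1], rel=1e-9)

    def test_single_site_heats_decay_after_equivalence(self, protocol):
        curve = simulate_titration(one_site(n=1.0, ka=1e5, dh=-10.0), protocol)
        mags = np.abs(curve.heats)
        after = mags[np.asarray(curve.molar_ratios) > 1.0]
        assert np.all(np.diff(after) <= 1e-12)


class TestBlank:
    def test_blank_equal_to_curve_zeroes_heats(self, protocol):
        c = simulate_titration(PUBLISHED_PARAMS["D7H-AB16"], protocol)
        out = subtract_blank(c, c)
        assert np.allclose(out.heats, 0.0)

    def test_zero_blank_is_identity_and_offset_removed(self, protocol):
        c = simulate_titration(PUBLISHED_PARAMS["D7H-AB16"], protocol)
        zero = TitrationCurve(c.molar_ratios, (0.0,) * len(c), protocol=protocol)
        assert subtract_blank(c, zero).heats == c.heats
        offset = TitrationCurve(c.molar_ratios, (0.25,) * len(c), protocol=protocol)
        got = subtract_blank(c, offset).heats
        assert np.allclose(np.asarray(c.heats) - 0.25, got)

    def test_schedule_mismatch_rejected(self, protocol):
        c = simulate_titration(PUBLISHED_PARAMS["D7H-AB16"], protocol)
        short = TitrationCurve(c.molar_ratios[:-1], c.heats[:-1], protocol=protocol)
        with pytest.raises(ItcError):
            subtract_blank(c, short)


class TestFit:
    def test_noise_free_two_site_recovery(self, protocol):
        true = PUBLISHED_PARAMS["D7H-AB16"]
        curve = simulate_titration(true, protocol)
        res = ZincTitrationModel(curve, 2).fit(n_bootstrap=0)
        for got, want in zip(
            res.model.sorted_by_affinity().sites, true.sorted_by_affinity().sites
        ):
            assert got.n == pytest.approx(want.n, rel=1e-3)
            assert got.ka == pytest.approx(want.ka, rel=1e-3)
            assert got.dh == pytest.approx(want.dh, rel=1e-3)

    def test_noise_free_one_site_recovery(self, protocol):
        true = PUBLISHED_PARAMS["E11A-D7H-AB16"]
        curve = simulate_titration(true, protocol)
        res = ZincTitrationModel(curve, 1).fit(n_bootstrap=0)
        got = res.model.sites[0]
        want = true.sites[0]
        assert got.n == pytest.approx(want.n, rel=1e-3)
        assert got.ka == pytest.approx(want.ka, rel=1e-3)
        assert got.dh == pytest.approx(want.dh, rel=1e-3)

    def test_two_site_fit_of_one_site_data_collapses_a_site(self, protocol):
        curve, _ = synth_itc(PUBLISHED_PARAMS["E11A-D7H-AB16"], protocol, 0.02, seed=11)
        res2 = fit_binding_model(curve, 2, {"n_bootstrap": 0})
        res1 = fit_binding_model(curve, 1, {"n_bootstrap": 0})
        sites = res2.model.sorted_by_affinity().sites
        collapsed = min(s.n for s in sites) < 0.05 or (
            max(s.ka for s in sites) / min(s.ka for s in sites) < 3
        )
        assert collapsed
        # parsimony: the information criterion prefers the one-site model
        assert res1.aicc - res2.aicc <= 2.0

    def test_bootstrap_uncertainties_are_finite_and_nonnegative(self, protocol):
        curve, _ = synth_itc(PUBLISHED_PARAMS["E11A-D7H-AB16"], protocol, 0.02, seed=3)
        res = fit_binding_model(curve, 1, {"n_bootstrap": 25, "seed": 5})
        unc = res.parameter_uncertainties
        assert set(unc) == {"site0_N", "site0_Ka", "site0_dH"}
        assert all(np.isfinite(v) and v >= 0 for v in unc.values())
        assert "RMSE" in res.summary() or "rmse" in res.summary().lower()

    def test_flat_curve_rejected(self, protocol):
        ratios = tuple(np.linspace(0.1, 3.0, 20))
        flat = TitrationCurve(ratios, (0.0,) * 20, protocol=protocol)
        with pytest.raises(ItcError):
            ZincTitrationModel(flat, 1)

    def test_too_few_points_rejected(self, protocol):
        c = simulate_titration(PUBLISHED_PARAMS["D7H-AB16"], protocol)
        short = TitrationCurve(c.molar_ratios[:6], c.heats[:6], protocol=protocol)
        with pytest.raises(ItcError):
            ZincTitrationModel(short, 1)


class TestModelSelection:
    def test_single_site_curve_selects_one(self, protocol):
        curve, _ = synth_itc(PUBLISHED_PARAMS["E11A-D7H-AB16"], protocol, 0.02, seed=21)
        assert select_n_sites(curve) == 1

    def test_noise_free_two_site_curve_selects_two(self, protocol):
        curve = simulate_titration(PUBLISHED_PARAMS["D7H-AB16"], protocol)
        assert select_n_sites(curve) == 2


def test_curve_table_round_trip(tmp_path, protocol):
    curve = simulate_titration(PUBLISHED_PARAMS["D7H-AB16"], protocol)
    path = tmp_path / "titration.tsv"
    write_curve_table(curve, path)
    back = read_curve_table(path, protocol)
    assert np.allclose(back.heats, curve.heats)
    assert np.allclose(back.molar_ratios, curve.molar_ratios)


def test_fit_plot_renders(tmp_path, protocol):
    import matplotlib

    matplotlib.use("Agg")
    curve = simulate_titration(PUBLISHED_PARAMS["E11A-D7H-AB16"], protocol)
    res = ZincTitrationModel(curve, 1).fit(n_bootstrap=0)
    ax = res.plot()
    assert len(ax.lines) == 2
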