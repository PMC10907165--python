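import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dboxkit.binding import (
    AnisotropyModel,
    BindingTruth,
    DegenerateDataError,
    ItcModel,
    ItcProtocol,
    TitrationSeries,
    anisotropy_model,
    bound_complex,
    equilibrium_heats_oracle,
    fit_anisotropy,
    fit_itc,
    itc_injection_heats,
)
from dboxkit.binding.io import (
    DialectError,
    read_anisotropy_csv,
    read_itc_csv,
    write_anisotropy_csv,
    write_fit_report,
    write_itc_csv,
)
from dboxkit.synthetic import gen_anisotropy_series, gen_itc_series

conc = st.floats(min_value=0.0, max_value=1e4, allow_nan=False)
kd = st.floats(min_value=1e-3, max_value=1e4, allow_nan=False)


class TestBoundComplex:
    def test_zero_protein_gives_zero(self):
        assert bound_complex(0.0, 2.0, 19.0) == 0.0

    def test_tight_binding_limit_is_min_of_totals(self):
        assert bound_complex(10.0, 2.0, 1e-9) == pytest.approx(2.0, rel=1e-6)

    def test_weak_depletion_half_saturation(self):
        # Pt = Kd >> Lt: half of the labelled species is bound
        assert bound_complex(45.0, 0.1, 45.0) == pytest.approx(0.04997, abs=1e-5)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            bound_complex(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            bound_complex(1.0, 1.0, 0.0)

    @given(conc, conc, kd)
    @settings(max_examples=300, deadline=None)
    def test_bounds_property(self, Pt, Lt, Kd):
        c = bound_complex(Pt, Lt, Kd)
        assert 0.0 <= c <= min(Pt, Lt) + 1e-9

    def test_vectorized_matches_scalar(self):
        Pt = np.array([0.0, 1.0, 50.0, 500.0])
        vec = bound_complex(Pt, 0.1, 45.0)
        assert vec == pytest.approx([bound_complex(p, 0.1, 45.0) for p in Pt])


class TestAnisotropyModel:
    def test_endpoints(self, fa_truth):
        t = fa_truth
        assert anisotropy_model(0.0, 0.1, t.A0, t.Amax, t.Kd) == t.A0
        assert anisotropy_model(1e7, 0.1, t.A0, t.Amax, t.Kd) == pytest.approx(
            t.Amax, rel=1e-4
        )

    def test_half_saturation_weak_depletion(self, fa_truth):
        t = fa_truth
        mid = anisotropy_model(t.Kd, 1e-4, t.A0, t.Amax, t.Kd)
        assert mid == pytest.approx(t.A0 + 0.5 * (t.Amax - t.A0), rel=1e-3)

    def test_corrected_mode_is_monotone_and_bounded(self, fa_truth):
        t = fa_truth
        Pt = np.linspace(0.0, 1000.0, 200)
        A = anisotropy_model(Pt, 0.1, t.A0, t.Amax, t.Kd)
        assert np.all(np.diff(A) >= -1e-12)
        assert np.all((A >= t.A0 - 1e-12) & (A <= t.Amax + 1e-12))

    def test_as_printed_mode_at_zero_protein(self, fa_truth):
        t = fa_truth
        a = anisotropy_model(0.0, 0.1, t.A0, t.Amax, t.Kd, mode="as_printed")
        assert a == t.A0

    def test_as_printed_differs_from_corrected(self, fa_truth):
        # dividing by 2*Pt instead of 2*Lt does not saturate at Amax
        t = fa_truth
        a = anisotropy_model(500.0, 0.1, t.A0, t.Amax, t.Kd, mode="as_printed")
        c = anisotropy_model(500.0, 0.1, t.A0, t.Amax, t.Kd, mode="corrected")
        assert a < c


class TestItcHeats:
    def test_zero_enthalpy_gives_zero_heats(self, itc_protocol):
        truth = BindingTruth(Kd=19.0, n=0.5, dH=0.0)
        assert np.allclose(itc_injection_heats(truth, itc_protocol), 0.0)

    def test_saturating_titration_heats_decay(self, itc_truth):
        proto = ItcProtocol(injection_volumes=(2.0,) * 60)
        q = itc_injection_heats(itc_truth, proto)
        assert abs(q[-1]) < 0.01 * abs(q[0])

    def test_matches_mass_balance_oracle(self, itc_truth, itc_protocol):
        q = itc_injection_heats(itc_truth, itc_protocol)
        oracle = equilibrium_heats_oracle(itc_truth, itc_protocol)
        assert q == pytest.approx(oracle, abs=1e-9)

    def test_total_heat_matches_final_bound_amount(self, itc_truth, itc_protocol):
        # displaced-volume bookkeeping: summed heats == V0*dH*C_final plus
        # the heat carried out of the cell by displaced complex
        q = itc_injection_heats(itc_truth, itc_protocol)
        V0 = itc_protocol.cell_volume
        from dboxkit.binding import itc_concentrations

        Ms, Xs = itc_concentrations(itc_protocol)
        C = bound_complex(itc_truth.n * Ms, Xs, itc_truth.Kd)
        displaced = sum(
            C_prev * dV / V0
            for C_prev, dV in zip([0.0, *C[:-1]], itc_protocol.injection_volumes)
        )
        expected = V0 * itc_truth.dH * (C[-1] + displaced) * 1e-3
        assert q.sum() == pytest.approx(expected, rel=1e-9)


class TestItcFit:
    def test_noiseless_recovery(self, itc_truth, itc_protocol):
        series, _ = gen_itc_series(itc_truth, itc_protocol, noise_sd=0.0)
        res = fit_itc(series)
        assert res.converged
        assert res.params["Kd"] == pytest.approx(19.0, rel=1e-3)
        assert res.params["n"] == pytest.approx(0.5, rel=1e-3)
        assert res.params["dH"] == pytest.approx(-8.0, rel=1e-3)

    def test_skip_first_default_excludes_first_injection(self, itc_truth, itc_protocol):
        series, _ = gen_itc_series(itc_truth, itc_protocol, noise_sd=0.0)
        # corrupt the first injection; default fit must be unaffected
        heats = (999.0,) + series.heats[1:]
        bad = TitrationSeries("ITC", heats=heats, protocol=itc_protocol)
        res = fit_itc(bad)
        assert res.params["Kd"] == pytest.approx(19.0, rel=1e-3)

    def test_fix_n(self, itc_truth, itc_protocol):
        series, _ = gen_itc_series(itc_truth, itc_protocol, noise_sd=0.0)
        res = fit_itc(series, fix_n=0.5)
        assert res.params["n"] == 0.5
        assert res.params["Kd"] == pytest.approx(19.0, rel=1e-3)

    def test_all_zero_heats_flagged(self, itc_protocol):
        series = TitrationSeries(
            "ITC", heats=(0.0,) * 20, protocol=itc_protocol
        )
        with pytest.raises(DegenerateDataError, match="no detectable binding"):
            fit_itc(series)

    def test_too_few_injections_rejected(self, itc_truth):
        proto = ItcProtocol(injection_volumes=(2.0,) * 5)
        series, _ = gen_itc_series(itc_truth, proto, noise_sd=0.0)
        with pytest.raises(DegenerateDataError, match="usable injections"):
            fit_itc(series)

    def test_summary_mentions_parameters(self, itc_truth, itc_protocol):
        series, _ = gen_itc_series(itc_truth, itc_protocol, noise_sd=0.0)
        text = fit_itc(series).summary()
        for name in ("Kd", "n", "dH", "converged"):
            assert name in text


class TestAnisotropyFit:
    def test_noiseless_recovery(self, fa_truth):
        series, _ = gen_anisotropy_series(fa_truth, noise_sd=0.0)
        res = fit_anisotropy(series)
        assert res.converged
        assert res.params["Kd"] == pytest.approx(45.0, rel=1e-4)
        assert res.params["A0"] == pytest.approx(0.05, abs=1e-6)
        assert res.params["Amax"] == pytest.approx(0.20, abs=1e-4)

    def test_flat_data_unidentifiable(self):
        series = TitrationSeries(
            "ANISOTROPY", Pt=tuple(float(x) for x in range(1, 9)),
            Lt=0.1, A=(0.1,) * 8,
        )
        with pytest.raises(DegenerateDataError, match="flat"):
            fit_anisotropy(series)

    def test_too_few_points_rejected(self):
        series = TitrationSeries(
            "ANISOTROPY", Pt=(1.0, 2.0, 4.0), Lt=0.1, A=(0.1, 0.12, 0.15)
        )
        with pytest.raises(DegenerateDataError, match=">= 6"):
            fit_anisotropy(series)


class TestBootstrap:
    def test_deterministic_under_seed(self, fa_truth):
        series, _ = gen_anisotropy_series(fa_truth, seed=4)
        res = fit_anisotropy(series)
        ci1 = res.bootstrap_ci(n_boot=50, seed=11)
        ci2 = fit_anisotropy(series).bootstrap_ci(n_boot=50, seed=11)
        assert ci1 == ci2

    def test_intervals_contain_estimate(self, itc_truth, itc_protocol):
        series, _ = gen_itc_series(itc_truth, itc_protocol, seed=3)
        res = fit_itc(series)
        for k, (lo, hi) in res.bootstrap_ci(n_boot=40, seed=1).items():
            assert lo <= res.params[k] <= hi

    def test_small_n_boot_rejected(self, fa_truth):
        series, _ = gen_anisotropy_series(fa_truth, seed=4)
        with pytest.raises(ValueError, match="at least 20"):
            fit_anisotropy(series).bootstrap_ci(n_boot=5)


class TestCsvIo:
    def test_itc_round_trip(self, tmp_path, itc_truth, itc_protocol):
        series, _ = gen_itc_series(itc_truth, itc_protocol, seed=0)
        path = tmp_path / "itc.csv"
        write_itc_csv(series, path)
        back = read_itc_csv(
            path, cell_volume=200.0, cell_concentration=100.0,
            syringe_concentration=1000.0,
        )
        assert back.heats == pytest.approx(series.heats)
        assert back.protocol.injection_volumes == itc_protocol.injection_volumes

    def test_anisotropy_round_trip(self, tmp_path, fa_truth):
        series, _ = gen_anisotropy_series(fa_truth, seed=0)
        path = tmp_path / "fa.csv"
        write_anisotropy_csv(series, path)
        back = read_anisotropy_csv(path, Lt=0.1)
        assert back.A == pytest.approx(series.A)

    def test_wrong_dialect_reported(self, tmp_path):
        path = tmp_path / "fa.csv"
        path.write_text("Pt_uM,anisotropy\n1.0,0.1\n")
        with pytest.raises(DialectError, match="missing column"):
            read_itc_csv(path)

    def test_fit_report_is_json(self, tmp_path, fa_truth):
        series, _ = gen_anisotropy_series(fa_truth, seed=0)
        res = fit_anisotropy(series)
        out = tmp_path / "report.json"
        write_fit_report(res, out, mode="fa")
        payload = json.loads(out.read_text())
        assert payload["converged"] is True
        assert payload["params"]["Kd"] == pytest.approx(res.params["Kd"])
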