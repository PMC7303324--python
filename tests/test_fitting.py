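"""BLOQ filtering, log-scale compartmental fitting, secondary parameters."""

import numpy as np
import pytest

from renalcocktail.design import PlasmaProfile, TrueParameterSet
from renalcocktail.errors import EmptyProfileError
from renalcocktail.fitting import (
    derive_secondary,
    exclude_bloq,
    fit_profile,
)
from renalcocktail.models import (
    OneCompartmentParams,
    TwoCompartmentParams,
    predict,
)
from renalcocktail.pipeline import fit_all
from renalcocktail.simulate import generate_cohort, simulate_study
from renalcocktail.units import ml_min_kg_to_l_h_kg


def make_profile(params, dose, times, lloq=1e-9, analyte="x", noise=None):
    times = np.asarray(times, dtype=float)
    concs = np.asarray(predict(params, dose, times), dtype=float)
    if noise is not None:
        concs = concs * (1.0 + noise)
    censored = concs < lloq
    return PlasmaProfile(animal_id="a1", analyte=analyte, times=times,
                         concs=concs, lloq=lloq, censored=censored,
                         dose_per_kg=dose)


TIMES = np.array([5 / 60, 15 / 60, 30 / 60, 45 / 60, 1, 2, 4, 6, 8, 12, 24, 36, 48.0])


class TestExcludeBloq:
    def test_below_lloq_record_removed(self):
        prof = PlasmaProfile("a1", "fluconazole", np.array([1.0, 2.0]),
                             np.array([0.5, 0.05]), lloq=0.1,
                             censored=np.array([False, True]), dose_per_kg=0.5)
        filtered, n = exclude_bloq(prof)
        assert n == 1
        np.testing.assert_array_equal(filtered.times, [1.0])
        # original untouched
        assert prof.times.size == 2

    def test_noop_when_nothing_censored(self):
        p = OneCompartmentParams(V=1.0, CL=0.5)
        prof = make_profile(p, 1.0, TIMES[:10])  # all points above LLOQ
        filtered, n = exclude_bloq(prof)
        assert n == 0
        np.testing.assert_array_equal(filtered.concs, prof.concs)

    def test_censored_tail_count(self):
        times = np.arange(1.0, 16.0)
        concs = 10.0 * np.exp(-0.5 * times)
        lloq = concs[10]  # censors the 4 points after index 10
        censored = concs < lloq
        prof = PlasmaProfile("a1", "x", times, concs, lloq, censored, 1.0)
        filtered, n = exclude_bloq(prof)
        assert n == 4 and filtered.times.size == 11

    def test_fully_censored_profile_raises(self):
        prof = PlasmaProfile("a1", "x", np.array([1.0]), np.array([0.01]),
                             lloq=1.0, censored=np.array([True]), dose_per_kg=1.0)
        with pytest.raises(EmptyProfileError):
            exclude_bloq(prof)


class TestFitProfile:
    def test_noise_free_1cpt_recovery(self):
        p = OneCompartmentParams(V=2.0, CL=3.0)  # ke = 1.5 /h
        prof = make_profile(p, 1.0, TIMES[TIMES < 8])
        fit = fit_profile(prof, "1cpt")
        assert fit.params.V == pytest.approx(2.0, rel=1e-6)
        assert fit.params.ke == pytest.approx(1.5, rel=1e-6)
        assert fit.sigma == pytest.approx(0.0, abs=1e-7)

    @pytest.mark.parametrize("params", [
        TwoCompartmentParams(V1=0.11, CL=0.2472, Q=0.15, V2=0.16),
        TwoCompartmentParams(V1=0.70, CL=0.027, Q=0.1, V2=0.28),
        TwoCompartmentParams(V1=1.5, CL=0.8, Q=0.4, V2=3.0),
    ], ids=["iohexol-like", "fluconazole-like", "generic"])
    def test_noise_free_2cpt_recovery(self, params):
        prof = make_profile(params, 10.0, TIMES)
        fit = fit_profile(prof, "2cpt")
        for name in ("V1", "CL", "Q", "V2"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(params, name), rel=1e-4), name

    def test_scale_equivariance(self):
        """Scaling concentrations by c scales V by 1/c, leaves ke invariant."""
        p = OneCompartmentParams(V=1.3, CL=0.9)
        prof = make_profile(p, 1.0, TIMES[:8])
        scaled = PlasmaProfile("a1", "x", prof.times, prof.concs * 10.0,
                               prof.lloq, prof.censored, prof.dose_per_kg)
        f1 = fit_profile(prof, "1cpt")
        f2 = fit_profile(scaled, "1cpt")
        assert f2.params.V == pytest.approx(f1.params.V / 10.0, rel=1e-6)
        assert f2.params.ke == pytest.approx(f1.params.ke, rel=1e-6)

    def test_deterministic(self):
        p = TwoCompartmentParams(V1=0.5, CL=0.3, Q=0.2, V2=0.4)
        rng = np.random.default_rng(5)
        prof = make_profile(p, 1.0, TIMES, noise=rng.normal(0, 0.1, TIMES.size))
        f1 = fit_profile(prof, "2cpt")
        f2 = fit_profile(prof, "2cpt")
        assert f1.params == f2.params

    def test_too_few_points_rejected(self):
        p = TwoCompartmentParams(V1=0.5, CL=0.3, Q=0.2, V2=0.4)
        prof = make_profile(p, 1.0, TIMES[:4])
        with pytest.raises(EmptyProfileError):
            fit_profile(prof, "2cpt")

    def test_predose_sample_rejected(self):
        prof = PlasmaProfile("a1", "x", np.array([0.0, 1.0, 2.0]),
                             np.array([1.0, 0.5, 0.25]), 1e-9,
                             np.zeros(3, bool), 1.0)
        with pytest.raises(ValueError, match="pre-dose"):
            fit_profile(prof, "1cpt")

    def test_monte_carlo_recovery_iohexol(self, design, truth):
        """200 virtual pigs at 10% proportional noise: mean CL bias < 2%,
        mean V bias < 5%."""
        ioh = TrueParameterSet(analytes={"iohexol": truth.analytes["iohexol"]},
                               urine_flow=truth.urine_flow)
        cohort = generate_cohort(200, seed=11)
        ds = simulate_study(cohort, design=design, truth=ioh, noise_cv=0.10,
                            between_animal_cv=0.0, leakage_prob=0.0, seed=12)
        fits = fit_all(ds)
        assert fits["converged"].all()
        true_cl = 4.12
        assert abs(fits["cl_tot"].mean() - true_cl) / true_cl < 0.02
        true_vss = 0.11 + 0.16
        assert abs(fits["Vss"].mean() - true_vss) / true_vss < 0.05


class TestDeriveSecondary:
    def test_one_compartment_r_pindolol_values(self):
        """V 2.12 L/kg with CL 54.20 ml/min/kg gives ke 1.534/h, T1/2 0.45 h."""
        p = OneCompartmentParams(V=2.12, CL=ml_min_kg_to_l_h_kg(54.20))
        prof = make_profile(p, 0.0255, TIMES[:6])
        sec = derive_secondary(fit_profile(prof, "1cpt"), 0.0255)
        assert sec.Ke == pytest.approx(1.534, abs=0.001)
        assert sec.T_half_el == pytest.approx(np.log(2) / sec.Ke, rel=1e-12)
        assert sec.Vss == pytest.approx(2.12, rel=1e-5)

    def test_half_life_from_ke(self):
        p = OneCompartmentParams(V=1.0, CL=1.54)
        prof = make_profile(p, 1.0, TIMES[:6])
        sec = derive_secondary(fit_profile(prof, "1cpt"), 1.0)
        assert sec.T_half_el == pytest.approx(0.450, abs=0.001)

    def test_auc_is_dose_over_cl(self):
        # fluconazole-like: 0.5 mg/kg at 0.45 ml/min/kg -> 18.5 mg*h/L
        p = TwoCompartmentParams(V1=0.70, CL=ml_min_kg_to_l_h_kg(0.45),
                                 Q=0.1, V2=0.28)
        prof = make_profile(p, 0.5, TIMES)
        sec = derive_secondary(fit_profile(prof, "2cpt"), 0.5)
        assert sec.AUC_0_inf == pytest.approx(0.5 / ml_min_kg_to_l_h_kg(0.45),
                                              rel=1e-6)
        assert sec.AUC_0_inf == pytest.approx(18.5, abs=0.02)

    def test_two_compartment_ke_is_terminal_beta(self):
        p = TwoCompartmentParams(V1=0.70, CL=0.027, Q=0.1, V2=0.28)
        prof = make_profile(p, 0.5, TIMES)
        sec = derive_secondary(fit_profile(prof, "2cpt"), 0.5)
        assert sec.Ke == pytest.approx(0.0269, abs=0.0002)  # beta, T1/2 ~ 25.7 h
        assert sec.Vss == pytest.approx(0.98, rel=1e-4)
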