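"""Mixed-effects estimation: likelihood oracles, invariances, recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from ldlresponse.datagen import Arm, TrialDesign, generate_trial
from ldlresponse.estimate import FitSpec, FitResult, fit_monotherapy, negloglik, profile_gamma
from ldlresponse.params import PopulationParams, bempedoic_model, cv_to_sigma, population_params

TRUE = {
    "baseline": 147.1,
    "emax": 0.34,
    "ed50": 43.96,
    "hill": 1.0,
    "omega_baseline": 0.230,
    "omega_emax": 0.362,
    "prop": 0.084,
    "add": 11.4,
}


def mono_dataset(n_per_arm, seed, doses=(0, 20, 60, 120, 180, 240), **kwargs):
    design = TrialDesign(
        name="sim", arms=tuple(Arm(None, 0.0, float(d), n_per_arm) for d in doses)
    )
    return generate_trial(design, seed=seed, **kwargs)


#: degenerate population: typical values only, no inter-individual spread
NO_IIV_POP = PopulationParams(147.1, 0.0, 0.0, 0.084, 11.4)


def full_spec(free=(), seed=0, **fixed_overrides):
    fixed = {k: v for k, v in TRUE.items() if k not in free}
    fixed.update(fixed_overrides)
    return FitSpec(free=tuple(free), fixed=fixed, seed=seed)


class TestNegloglik:
    def test_single_observation_matches_hand_computed_density(self):
        """With variability off, the objective is the combined
        proportional+additive normal density, computed by hand."""
        ds = pd.DataFrame(
            {
                "subject_id": [1],
                "statin": pd.array([None], dtype="string"),
                "statin_dose_mg": [0.0],
                "ba_dose_mg": [180.0],
                "week": [12],
                "ldl_mgdl": [110.0],
            }
        )
        spec = full_spec(omega_baseline=0.0, omega_emax=0.0)
        f = 147.1 * (1 - 0.34 * 180 / (43.96 + 180) * (1 - math.exp(-0.01 * 2016)))
        v = (0.084 * f) ** 2 + 11.4**2
        expected = 0.5 * (math.log(2 * math.pi * v) + (110.0 - f) ** 2 / v)
        assert negloglik(ds, spec, {}) == pytest.approx(expected, rel=1e-10)

    def test_quadrature_matches_direct_integration(self):
        """Gauss-Hermite marginal equals brute-force 2-D integration of the
        random-effect density on a small dataset."""
        ds = mono_dataset(2, seed=21, doses=(0, 180))
        spec = FitSpec(free=(), fixed=dict(TRUE), gh_nodes=41)
        nll = negloglik(ds, spec, {})

        sb = cv_to_sigma(TRUE["omega_baseline"])
        se = cv_to_sigma(TRUE["omega_emax"])
        total = 0.0
        for sid, grp in ds.groupby("subject_id"):
            y = grp["ldl_mgdl"].to_numpy()
            dose = grp["ba_dose_mg"].to_numpy()
            week = grp["week"].to_numpy()

            def lik(e2, e1):
                b = TRUE["baseline"] * np.exp(e1)
                em = TRUE["emax"] * np.exp(e2)  # unclamped, as in the model density
                e = em * dose / (TRUE["ed50"] + dose)
                expr = 1 - np.exp(-0.01 * week * 168.0)
                f = b * (1 - e * expr)
                v = (TRUE["prop"] * f) ** 2 + TRUE["add"] ** 2
                dens = np.prod(np.exp(-((y - f) ** 2) / (2 * v)) / np.sqrt(2 * np.pi * v))
                return dens * stats.norm.pdf(e1, 0, sb) * stats.norm.pdf(e2, 0, se)

            val, _ = integrate.dblquad(lik, -5 * sb, 5 * sb, -5 * se, 5 * se)
            total += math.log(val)
        assert nll == pytest.approx(-total, rel=1e-4)

    def test_laplace_agrees_with_quadrature(self):
        """The two marginalization routes agree on a realistic dataset."""
        ds = mono_dataset(15, seed=31)
        spec = full_spec()
        gh = negloglik(ds, spec, {})
        la = negloglik(ds, spec, {}, method="laplace")
        assert la == pytest.approx(gh, rel=2e-3)

    def test_record_order_invariance(self):
        ds = mono_dataset(10, seed=41)
        spec = full_spec()
        shuffled = ds.sample(frac=1.0, random_state=7).reset_index(drop=True)
        relabeled = ds.copy()
        relabeled["subject_id"] = relabeled["subject_id"].map(
            {s: 10_000 - s for s in ds["subject_id"].unique()}
        )
        ref = negloglik(ds, spec, {})
        assert negloglik(shuffled, spec, {}) == pytest.approx(ref, rel=1e-12)
        assert negloglik(relabeled, spec, {}) == pytest.approx(ref, rel=1e-12)

    def test_invalid_parameters_penalized_not_raised(self):
        ds = mono_dataset(3, seed=1)
        spec = full_spec(free=("emax", "ed50"))
        assert negloglik(ds, spec, {"emax": 0.3, "ed50": -1.0}) == 1e12
        assert negloglik(ds, spec, {"emax": float("nan"), "ed50": 44.0}) == 1e12

    def test_noiseless_limit_minimized_at_truth(self):
        """Data generated exactly on the model surface: the objective at the
        generating parameters beats nearby perturbations."""
        ds = mono_dataset(5, seed=2, residual=False, emax_iiv=False, pop=NO_IIV_POP)
        spec = full_spec(
            free=("emax", "ed50"), omega_baseline=0.0, omega_emax=0.0,
            prop=0.001, add=0.1,
        )
        at_truth = negloglik(ds, spec, {"emax": 0.34, "ed50": 43.96})
        for de, dd in [(0.02, 0), (-0.02, 0), (0, 4.0), (0, -4.0), (0.01, 2.0)]:
            perturbed = negloglik(ds, spec, {"emax": 0.34 + de, "ed50": 43.96 + dd})
            assert at_truth < perturbed

    def test_zero_variability_data_fit_is_exact(self):
        """Generator/estimator self-consistency in the degenerate limit:
        with no noise the fitted fixed effects land on the truth."""
        ds = mono_dataset(30, seed=3, residual=False, emax_iiv=False, pop=NO_IIV_POP)
        # tiny nominal residual keeps the density proper
        spec = FitSpec(
            free=("baseline", "emax", "ed50"),
            fixed={
                "hill": 1.0, "omega_baseline": 0.0, "omega_emax": 0.0,
                "prop": 0.01, "add": 0.5,
            },
        )
        res = fit_monotherapy(ds, spec)
        assert res.estimates["baseline"] == pytest.approx(147.1, rel=1e-3)
        assert res.estimates["emax"] == pytest.approx(0.34, rel=1e-2)
        assert res.estimates["ed50"] == pytest.approx(43.96, rel=2e-2)


class TestFitMonotherapy:
    def test_single_dose_level_unidentifiable(self):
        ds = mono_dataset(5, seed=4, doses=(180,))
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_monotherapy(ds, full_spec(free=("emax", "ed50")))

    def test_moderate_n_recovery_and_cis(self):
        """A single fit on a rich design recovers the generating values and
        its intervals behave (bracket estimates, hill CI covers 1)."""
        ds = mono_dataset(120, seed=5)
        spec = FitSpec(
            free=("baseline", "emax", "ed50", "hill", "omega_baseline",
                  "omega_emax", "prop", "add"),
            fixed={},
            seed=0,
        )
        res = fit_monotherapy(ds, spec)
        assert res.converged
        assert res.estimates["emax"] == pytest.approx(0.34, rel=0.25)
        # hill and ED50 are strongly correlated at this n: ask the interval,
        # not the point, to cover the generating ED50
        lo, hi = res.ci95["ed50"]
        assert lo < 43.96 < hi
        lo, hi = res.ci95["hill"]
        assert lo < 1.0 < hi  # sigmoid variant: data generated with hill = 1
        for name, est in res.estimates.items():
            clo, chi = res.ci95[name]
            assert clo <= est <= chi

    def test_result_round_trip(self):
        res = FitResult(
            estimates={"emax": 0.34}, se={"emax": 0.01},
            ci95={"emax": (0.32, 0.36)}, objective=10.0, converged=True,
        )
        assert FitResult.from_dict(res.to_dict()) == res
        spec = full_spec(free=("emax",))
        assert FitSpec.from_dict(spec.to_dict()) == spec


class TestProfileGamma:
    def _combo_dataset(self, n_per_arm, seed, gamma=-1.35):
        design = TrialDesign(
            name="combo",
            arms=(
                Arm("atorvastatin", 20.0, 180.0, n_per_arm),
                Arm("atorvastatin", 40.0, 180.0, n_per_arm),
                Arm("simvastatin", 20.0, 180.0, n_per_arm),
                Arm("pravastatin", 40.0, 180.0, n_per_arm),
            ),
            population="atorvastatin",
        )
        return generate_trial(design, seed=seed, gamma=gamma)

    def _spec(self):
        pop = population_params("atorvastatin")
        ba = bempedoic_model("combination")
        return FitSpec(
            free=(),
            fixed={
                "baseline": pop.baseline_typical, "emax": ba.emax,
                "ed50": ba.ed50, "hill": ba.hill,
                "omega_baseline": pop.omega_baseline,
                "omega_emax": pop.omega_emax,
                "prop": pop.residual_proportional,
                "add": pop.residual_additive,
            },
        )

    def test_null_interaction_recovered(self):
        ds = self._combo_dataset(100, seed=6, gamma=0.0)
        prof = profile_gamma(ds, self._spec(), np.arange(-1.0, 1.01, 0.1))
        assert abs(prof.gamma_hat) <= 0.2

    def test_single_point_grid(self):
        ds = self._combo_dataset(10, seed=7)
        prof = profile_gamma(ds, self._spec(), [-1.0])
        assert prof.gamma_hat == -1.0
        assert len(prof.objective) == 1

    def test_requires_combination_records(self):
        ds = mono_dataset(5, seed=8)
        with pytest.raises(ValueError, match="combination"):
            profile_gamma(ds, self._spec(), [-1.0, 0.0])

    def test_empty_grid_rejected(self):
        ds = self._combo_dataset(5, seed=9)
        with pytest.raises(ValueError):
            profile_gamma(ds, self._spec(), [])
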