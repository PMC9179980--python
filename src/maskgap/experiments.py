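"""Replicated simulation experiments: parameter recovery and model selection.

These drive the validation studies for the whole pipeline: data are drawn
from the BYM count model at known parameter values on fresh synthetic
regions, all four models are refitted, and recovery (credible-interval
coverage, bias), model-selection direction (DIC/WAIC ordering) and
predictive error ratios are recorded.

Problem sizes default to ~1000-village regions with 20 replicates and
2-chain samplers — large enough for the asymptotics that make recovery
meaningful, small enough to run on a single CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bhm, synthgen

#: overall service rate (customers per adult per day) used to form the
#: expected-count offset in simulation studies, metropolitan-study scale
SERVICE_RATE = 0.033

MODELS = ("poisson", "negbin", "poisson_spatial", "negbin_spatial")


def _model_spec(name: str, seed: int, iterations: int, burnin: int) -> bhm.ModelSpec:
    return bhm.ModelSpec(
        family="negbin" if name.startswith("negbin") else "poisson",
        spatial=name.endswith("_spatial"),
        chains=2,
        iterations=iterations,
        burnin=burnin,
        thin=2,
        seed=seed,
    )


def make_simulated_region(
    cfg: synthgen.SyntheticConfig,
) -> tuple[pd.DataFrame, synthgen.SyntheticTruth, bhm.Adjacency]:
    """One synthetic region with offsets, BYM-simulated counts and adjacency."""
    vil = synthgen.generate_villages(cfg)
    vil["E"] = SERVICE_RATE * vil["pop"].to_numpy()
    adj = bhm.build_adjacency(vil)
    Y, truth = synthgen.simulate_counts(vil, cfg, adjacency=adj.a)
    vil["Y"] = Y
    vil["rho_raw"] = Y / vil["E"].to_numpy()
    return vil, truth, adj


@dataclass
class RecoveryResult:
    """Outcome of a replicated recovery / model-selection experiment."""

    coef_names: list
    truth: np.ndarray  # (7,)
    covered: np.ndarray  # (reps, 7) bool, 95% CI covers truth
    errors: np.ndarray  # (reps, 7) posterior mean - truth
    dic: pd.DataFrame  # (reps, models)
    waic: pd.DataFrame
    mape: pd.DataFrame
    mse: pd.DataFrame

    @property
    def coverage(self) -> np.ndarray:
        return self.covered.mean(axis=0)

    @property
    def mean_bias(self) -> np.ndarray:
        return self.errors.mean(axis=0)

    def selection_wins(self, criterion: str = "dic") -> int:
        """Replicates in which the Poisson spatial model scores lowest."""
        tab = getattr(self, criterion)
        return int((tab.idxmin(axis=1) == "poisson_spatial").sum())


def recovery_experiment(
    n_reps: int = 20,
    n_villages: int = 1000,
    seed: int = 0,
    iterations: int = 3000,
    burnin: int = 1500,
    models: tuple = MODELS,
    fit_model_scores: bool = True,
) -> RecoveryResult:
    """Repeatedly simulate from the Poisson spatial model and refit.

    Fixed-effect truth is the study-scale coefficient vector
    (synthgen.DEFAULT_COEFFICIENTS); each replicate gets a fresh region,
    fresh random effects and fresh counts.
    """
    from . import evaluation

    names = list(bhm.DESIGN_NAMES)
    truth_b = np.asarray(synthgen.DEFAULT_COEFFICIENTS)
    covered = np.zeros((n_reps, 7), dtype=bool)
    errors = np.zeros((n_reps, 7))
    rows_dic, rows_waic, rows_mape, rows_mse = [], [], [], []
    base = int(seed) % 2**31

    for rep in range(n_reps):
        cfg = synthgen.SyntheticConfig(
            n_villages=n_villages,
            n_stores=max(n_villages // 2, 2),
            region_size=40.0 * n_villages,
            seed=base + 1000 + rep,
        )
        vil, truth, adj = make_simulated_region(cfg)
        rho_raw = vil["rho_raw"].to_numpy()

        fit_models = models if fit_model_scores else ("poisson_spatial",)
        dics, waics, mapes, mses = {}, {}, {}, {}
        for name in fit_models:
            model_off = MODELS.index(name) if name in MODELS else 0
            spec = _model_spec(name, base + 17 * rep + model_off, iterations, burnin)
            fit = bhm.fit(spec, vil, adj)
            if name == "poisson_spatial":
                s = fit.summary.set_index("parameter")
                lo = s.loc[names, "q025"].to_numpy()
                hi = s.loc[names, "q975"].to_numpy()
                mn = s.loc[names, "mean"].to_numpy()
                covered[rep] = (lo <= truth_b) & (truth_b <= hi)
                errors[rep] = mn - truth_b
            if fit_model_scores:
                sc = evaluation.score(fit, rho_raw)
                dics[name] = sc.dic
                waics[name] = sc.waic
                mapes[name] = sc.mape
                mses[name] = sc.mse
        rows_dic.append(dics)
        rows_waic.append(waics)
        rows_mape.append(mapes)
        rows_mse.append(mses)

    return RecoveryResult(
        coef_names=names,
        truth=truth_b,
        covered=covered,
        errors=errors,
        dic=pd.DataFrame(rows_dic),
        waic=pd.DataFrame(rows_waic),
        mape=pd.DataFrame(rows_mape),
        mse=pd.DataFrame(rows_mse),
    )


def overdispersion_experiment(
    seed: int = 0,
    n_villages: int = 1488,
    size_parameter: float = 1.6,
    iterations: int = 4000,
    burnin: int = 2000,
) -> dict:
    """NB-spatial fit on NB-generated data: does the size parameter recover?"""
    cfg = synthgen.SyntheticConfig(
        n_villages=n_villages,
        n_stores=max(n_villages // 2, 2),
        region_size=40.0 * n_villages,
        seed=int(seed) % 2**31 + 5,
        family="negbin",
        size_parameter=size_parameter,
    )
    vil, truth, adj = make_simulated_region(cfg)
    spec = _model_spec("negbin_spatial", int(seed) % 2**31 + 6, iterations, burnin)
    fit = bhm.fit(spec, vil, adj)
    s = fit.summary.set_index("parameter")
    return {
        "theta_truth": size_parameter,
        "theta_posterior_mean": float(s.loc["size_theta", "mean"]),
        "theta_posterior_sd": float(s.loc["size_theta", "sd"]),
        "fit": fit,
    }


def negbin_poisson_agreement(
    seed: int = 0,
    n_villages: int = 800,
    iterations: int = 3000,
    burnin: int = 1500,
) -> dict:
    """On near-Poisson data (NB truth with enormous size), the NB and Poisson
    spatial fits should give the same fixed-effect summaries."""
    cfg = synthgen.SyntheticConfig(
        n_villages=n_villages,
        n_stores=max(n_villages // 2, 2),
        region_size=40.0 * n_villages,
        seed=int(seed) % 2**31 + 9,
        family="negbin",
        size_parameter=1e6,
    )
    vil, _, adj = make_simulated_region(cfg)
    fits = {}
    for name in ("poisson_spatial", "negbin_spatial"):
        spec = _model_spec(name, int(seed) % 2**31 + 10, iterations, burnin)
        fits[name] = bhm.fit(spec, vil, adj).summary.set_index("parameter")
    names = list(bhm.DESIGN_NAMES)
    p = fits["poisson_spatial"].loc[names]
    nb = fits["negbin_spatial"].loc[names]
    gap_sd = np.abs(p["mean"] - nb["mean"]) / np.maximum(p["sd"], nb["sd"])
    return {
        "poisson": p,
        "negbin": nb,
        "max_gap_in_sd": float(gap_sd.max()),
    }
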