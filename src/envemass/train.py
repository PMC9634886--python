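"""Refitting the linear models and evaluating the pipeline at desk scale.

Mirrors the train-then-predict workflow: fit the initial linear estimate on
a synthetic proteome (with k-fold cross-validation of the off-by-one-free
fraction), fit the universal grid-step law against per-protein optimal
steps, calibrate the recentering term lambda, and score the end-to-end
predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import kendalltau, pearsonr, spearmanr

from .config import PredictorCoefficients, RunConfig
from .grid import GridModel, estimate_delta, optimal_zeta, round_to_grid, universal_zeta
from .model import initial_estimate, predict_theoretical
from .simulate import SyntheticProtein

#: Absolute error below which a prediction counts as off-by-one free.
OFF_BY_ONE_THRESHOLD = 0.5


@dataclass(frozen=True)
class Eq1Fit:
    beta0: float
    beta_avg: float
    beta_var: float
    cv_fraction: float
    residual_sd: float
    n: int


@dataclass(frozen=True)
class Eq2Fit:
    gamma0: float
    gamma_avg: float
    pearson: float
    kendall: float
    spearman: float
    n: int


@dataclass(frozen=True)
class EvalReport:
    n: int
    mae_da: float
    mae_ppm: float
    off_by_one_free_fraction: float
    conditional_mae_da: float
    conditional_mae_ppm: float
    bands: pd.DataFrame
    errors: np.ndarray


def _design(proteins: Sequence[SyntheticProtein]):
    x = np.array([[p.m_avg, p.m_var] for p in proteins])
    y = np.array([p.m_mono for p in proteins])
    return sm.add_constant(x), y


def refit_eq1(
    proteins: Sequence[SyntheticProtein],
    n_folds: int = 10,
    seed: int = 0,
    threshold: float = OFF_BY_ONE_THRESHOLD,
) -> Eq1Fit:
    """OLS of the true monoisotopic mass on (M_avg, M_var), with k-fold CV.

    The cross-validated statistic is the out-of-fold fraction of proteins
    whose absolute prediction error stays below ``threshold``.
    """
    if len(proteins) < 100:
        raise ValueError("refit needs at least 100 proteins")
    X, y = _design(proteins)
    fit = sm.OLS(y, X).fit()
    beta0, beta_avg, beta_var = fit.params
    rng = np.random.default_rng(seed)
    fold = rng.permuted(np.arange(len(y)) % n_folds)
    hits = 0
    for f in range(n_folds):
        test = fold == f
        cv_fit = sm.OLS(y[~test], X[~test]).fit()
        err = y[test] - X[test] @ cv_fit.params
        hits += int(np.sum(np.abs(err) < threshold))
    return Eq1Fit(
        beta0=float(beta0),
        beta_avg=float(beta_avg),
        beta_var=float(beta_var),
        cv_fraction=hits / len(y),
        residual_sd=float(np.std(y - fit.fittedvalues)),
        n=len(y),
    )


def compute_zeta_stars(
    proteins: Sequence[SyntheticProtein],
    config: RunConfig = RunConfig(),
) -> List[float]:
    """Per-protein variance-minimizing grid steps (the slow validation route)."""
    return [
        optimal_zeta(
            p.spectrum(config.boundary),
            search=(config.zeta_search_lo, config.zeta_search_hi),
        )
        for p in proteins
    ]


def refit_eq2(
    proteins: Sequence[SyntheticProtein],
    zeta_stars: Sequence[float],
) -> Eq2Fit:
    """OLS of the optimal grid step on the average mass, with correlations."""
    if len(proteins) != len(zeta_stars):
        raise ValueError("proteins and zeta_stars must pair up")
    if len(proteins) < 50:
        raise ValueError("eq2 refit needs at least 50 proteins")
    m_avg = np.array([p.m_avg for p in proteins])
    z = np.asarray(zeta_stars, dtype=float)
    X = sm.add_constant(m_avg)
    fit = sm.OLS(z, X).fit()
    return Eq2Fit(
        gamma0=float(fit.params[0]),
        gamma_avg=float(fit.params[1]),
        pearson=float(pearsonr(m_avg, z)[0]),
        kendall=float(kendalltau(m_avg, z)[0]),
        spearman=float(spearmanr(m_avg, z)[0]),
        n=len(z),
    )


def _grid_nodes(
    proteins: Sequence[SyntheticProtein],
    coef: PredictorCoefficients,
    config: RunConfig,
) -> np.ndarray:
    """Uncorrected nearest-node predictions for a batch of proteins."""
    nodes = np.empty(len(proteins))
    for i, p in enumerate(proteins):
        spectrum = p.spectrum(config.boundary)
        zeta = universal_zeta(p.m_avg, coef.gamma0, coef.gamma_avg)
        delta = estimate_delta(spectrum, zeta)
        grid = GridModel(zeta, delta, 0.0, config.lambda_mode)
        nodes[i] = round_to_grid(
            initial_estimate(p.m_avg, p.m_var, coef), grid
        )
    return nodes


def calibrate_lambda(
    proteins: Sequence[SyntheticProtein],
    coef: PredictorCoefficients,
    config: RunConfig = RunConfig(),
) -> float:
    """Relative correction that centers the rounded-prediction errors.

    Restricted to off-by-one-free cases (a wrong cluster would swamp the
    ppb-scale recentering); returns lambda with final = node * (1 + lambda).
    """
    if len(proteins) < 500:
        raise ValueError("lambda calibration needs at least 500 proteins")
    nodes = _grid_nodes(proteins, coef, config)
    truth = np.array([p.m_mono for p in proteins])
    ok = np.abs(nodes - truth) < OFF_BY_ONE_THRESHOLD
    if not np.any(ok):
        raise RuntimeError("no off-by-one-free cases to calibrate on")
    return float(-np.mean((nodes[ok] - truth[ok]) / nodes[ok]))


_BAND_EDGES = [8_000, 20_000, 40_000, 60_000, 400_000]
_BAND_LABELS = ["8-20 kDa", "20-40 kDa", "40-60 kDa", "60-400 kDa"]


def evaluate(
    proteins: Sequence[SyntheticProtein],
    coef: Optional[PredictorCoefficients] = None,
    config: RunConfig = RunConfig(),
) -> EvalReport:
    """Run the full theoretical-spectrum predictor and score it.

    Reports the mean absolute error in Da and ppm (relative to the true
    monoisotopic mass), the off-by-one-free fraction (absolute error below
    0.5 Da), the conditional MAE on that subset, and a per-band breakdown.
    """
    if len(proteins) < 100:
        raise ValueError("evaluation needs at least 100 proteins")
    coef = coef or config.coefficients
    run = replace(config, coefficients=coef)
    truth = np.array([p.m_mono for p in proteins])
    pred = np.array(
        [predict_theoretical(p.spectrum(run.boundary), run).m_mono for p in proteins]
    )
    err = pred - truth
    abs_err = np.abs(err)
    ppm = 1e6 * abs_err / truth
    ok = abs_err < OFF_BY_ONE_THRESHOLD
    m_avg = np.array([p.m_avg for p in proteins])
    band = pd.cut(m_avg, _BAND_EDGES, labels=_BAND_LABELS)
    frame = pd.DataFrame(
        {"band": band, "abs_err_da": abs_err, "ppm": ppm, "ok": ok}
    )
    bands = (
        frame.groupby("band", observed=False)
        .agg(
            n=("ok", "size"),
            off_by_one_free=("ok", "mean"),
            mae_da=("abs_err_da", "mean"),
            mae_ppm=("ppm", "mean"),
        )
        .reset_index()
    )
    return EvalReport(
        n=len(proteins),
        mae_da=float(abs_err.mean()),
        mae_ppm=float(ppm.mean()),
        off_by_one_free_fraction=float(ok.mean()),
        conditional_mae_da=float(abs_err[ok].mean()) if ok.any() else float("nan"),
        conditional_mae_ppm=float(ppm[ok].mean()) if ok.any() else float("nan"),
        bands=bands,
        errors=err,
    )


def train_profile(
    proteins: Sequence[SyntheticProtein],
    n_eq2: int = 300,
    n_lambda: int = 5_000,
    seed: int = 0,
    config: RunConfig = RunConfig(),
) -> Tuple[PredictorCoefficients, Eq1Fit, Eq2Fit]:
    """Full coefficient training pass on a synthetic proteome.

    Fits the initial linear model on all proteins, the universal grid-step
    law on the first ``n_eq2`` (per-protein step optimization is the
    expensive part), then calibrates lambda on the first ``n_lambda``.
    """
    eq1 = refit_eq1(proteins, seed=seed)
    eq2_proteins = proteins[: min(n_eq2, len(proteins))]
    eq2 = refit_eq2(eq2_proteins, compute_zeta_stars(eq2_proteins, config))
    partial = PredictorCoefficients(
        beta0=eq1.beta0,
        beta_avg=eq1.beta_avg,
        beta_var=eq1.beta_var,
        gamma0=eq2.gamma0,
        gamma_avg=eq2.gamma_avg,
        lambda_corr=0.0,
    )
    lam = calibrate_lambda(proteins[: min(n_lambda, len(proteins))], partial, config)
    coef = replace(partial, lambda_corr=lam)
    return coef, eq1, eq2
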