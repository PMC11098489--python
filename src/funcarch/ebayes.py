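"""Exponential-prior empirical-Bayes shrinkage of heritability estimates.

Across a collection of phenotypes, the per-class heritability estimates from
stratified LD-score regression are noisy and sometimes negative, while the
true per-class contributions are nonnegative and, empirically, roughly
exponentially distributed across phenotypes.  This module therefore models,
class by class,

    h ~ Exponential(λ_C),        est_i | h ~ Normal(h, se_i²),

estimates λ_C by maximizing the marginal likelihood of the observed
estimates (their standard errors taken into account), and replaces each
estimate by its posterior expectation.  The posterior of h given (est, se)
is a Normal(est − λ·se², se²) truncated to (0, ∞), so the posterior mean
has the closed form

    E[h | est, se] = μ′ + se·φ(μ′/se)/Φ(μ′/se),     μ′ = est − λ·se²,

and the per-observation marginal likelihood is

    λ · exp(λ²se²/2 − λ·est) · Φ((est − λ·se²)/se).

Both are evaluated in log space with the Mills-ratio asymptotics scipy's
``norm.logcdf`` provides, so deeply negative estimates remain stable.
Shrinkage is deliberately biased toward the cross-phenotype mean; negative
input estimates are retained in the likelihood and mapped to small positive
posteriors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "EbayesInput",
    "EbayesResult",
    "marginal_loglik",
    "fit_exponential_prior",
    "posterior_mean",
    "shrink_matrix",
    "load_phenotype_results",
]

LAMBDA_BOUNDS = (1e-3, 1e4)


@dataclass
class EbayesInput:
    """Phenotype × class estimate and standard-error matrices."""

    estimates: pd.DataFrame
    ses: pd.DataFrame

    def __post_init__(self) -> None:
        if self.estimates.shape != self.ses.shape:
            raise ValueError("estimate and SE matrices must have equal shape")
        if not (self.estimates.index.equals(self.ses.index)
                and self.estimates.columns.equals(self.ses.columns)):
            raise ValueError("estimate and SE matrices must share labels")
        se = self.ses.to_numpy(dtype=float)
        if not np.isfinite(se).all() or (se <= 0).any():
            raise ValueError("standard errors must be finite and > 0")
        if not np.isfinite(self.estimates.to_numpy(dtype=float)).all():
            raise ValueError("estimates must be finite")


@dataclass
class EbayesResult:
    lambda_: pd.Series  # per-class exponential rate
    posterior_mean: pd.DataFrame
    log_marginal: pd.Series  # maximized log marginal likelihood per class
    at_bound: pd.Series  # True where the ML fit hit a λ bound


def marginal_loglik(lambda_: float, estimates, ses) -> float:
    """Log marginal likelihood of estimates under the Exp(λ) prior.

    Σ_i log ∫₀^∞ λ e^{−λh} · N(est_i; h, se_i²) dh, via the closed form.
    """
    if lambda_ <= 0:
        raise ValueError("lambda must be positive")
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    terms = (
        np.log(lambda_)
        + 0.5 * lambda_**2 * se**2
        - lambda_ * est
        + sps.norm.logcdf((est - lambda_ * se**2) / se)
    )
    return float(terms.sum())


def fit_exponential_prior(
    estimates, ses, bounds: tuple[float, float] = LAMBDA_BOUNDS
) -> tuple[float, float, bool]:
    """Maximum-likelihood λ for one class across phenotypes.

    Bounded scalar search on log λ (deterministic); returns
    ``(lambda_hat, log_marginal, at_bound)``.  In the noise-free limit this
    reduces to the textbook exponential MLE 1/mean.
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.size < 2:
        raise ValueError("need at least 2 phenotypes to fit the prior")
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    res = optimize.minimize_scalar(
        lambda t: -marginal_loglik(np.exp(t), est, se),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.exp(res.x))
    at_bound = res.x - lo < 1e-6 or hi - res.x < 1e-6
    if at_bound:
        warnings.warn(
            f"exponential-prior ML fit hit bound (lambda={lam:.3g}); "
            "estimates may be too noisy to pin down the prior"
        )
    return lam, float(-res.fun), at_bound


def posterior_mean(est, se, lambda_: float):
    """Posterior expectation of h under the Exp(λ) prior and Normal noise.

    Always strictly positive; decreasing in λ, increasing in est.
    """
    if lambda_ <= 0:
        raise ValueError("lambda must be positive")
    est = np.asarray(est, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ValueError("se must be positive")
    mu = est - lambda_ * se**2
    a = mu / se
    # φ(a)/Φ(a) via logs: stable for a far into the left tail
    mills = np.exp(sps.norm.logpdf(a) - sps.norm.logcdf(a))
    out = mu + se * mills
    return float(out) if out.ndim == 0 else out


def shrink_matrix(input_: EbayesInput) -> EbayesResult:
    """Fit λ per class (column) and shrink every cell to its posterior mean.

    Shrinkage pulls each phenotype's estimate toward the cross-phenotype
    prior mean 1/λ_C, with weight governed by the estimate's SE: precise
    estimates barely move, noisy ones move most.
    """
    est = input_.estimates
    ses = input_.ses
    lam = {}
    logm = {}
    bound = {}
    post = pd.DataFrame(index=est.index, columns=est.columns, dtype=float)
    for col in est.columns:
        l, ll, ab = fit_exponential_prior(est[col].to_numpy(), ses[col].to_numpy())
        lam[col], logm[col], bound[col] = l, ll, ab
        post[col] = posterior_mean(est[col].to_numpy(), ses[col].to_numpy(), l)
    return EbayesResult(
        lambda_=pd.Series(lam),
        posterior_mean=post,
        log_marginal=pd.Series(logm),
        at_bound=pd.Series(bound),
    )


def load_phenotype_results(
    manifest: str | Path,
    quantity: str = "prop_h2",
    drop_base: bool = True,
    drop_undefined: bool = True,
) -> EbayesInput:
    """Assemble the phenotype × class matrices from per-phenotype result CSVs.

    ``manifest`` is a TSV with columns ``phenotype`` and ``path`` pointing
    at per-phenotype stratified-regression results.  ``quantity`` selects
    which estimate to shrink: per-class proportions of h² (``prop_h2``,
    default) or absolute h² (``h2``).  A phenotype whose total h² estimate
    was non-positive has undefined proportions; with ``drop_undefined``
    such phenotypes are dropped from the fit (with a warning) rather than
    poisoning it.
    """
    from .sldsr import read_results

    if quantity not in {"prop_h2", "h2"}:
        raise ValueError("quantity must be 'prop_h2' or 'h2'")
    se_col = {"prop_h2": "se_prop", "h2": "se_h2"}[quantity]
    man = pd.read_csv(manifest, sep="\t")
    est_rows, se_rows = {}, {}
    base = Path(manifest).parent
    for _, row in man.iterrows():
        path = Path(row["path"])
        if not path.is_absolute():
            path = base / path
        df = read_results(path).set_index("class")
        if drop_base:
            df = df.drop(index="base", errors="ignore")
        est_rows[row["phenotype"]] = df[quantity]
        se_rows[row["phenotype"]] = df[se_col]
    est = pd.DataFrame(est_rows).T
    ses = pd.DataFrame(se_rows).T
    undefined = est.isna().any(axis=1) | ses.isna().any(axis=1)
    if undefined.any():
        if not drop_undefined:
            raise ValueError(
                f"undefined estimates for {list(est.index[undefined])}"
            )
        warnings.warn(
            "dropping phenotypes with undefined estimates "
            f"(non-positive total h²): {list(est.index[undefined])}"
        )
        est, ses = est[~undefined], ses[~undefined]
    return EbayesInput(estimates=est, ses=ses)
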