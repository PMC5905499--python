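"""Two-component Poisson mixture over per-scaffold read depths.

In a diploid assembly that retains unmerged haplotypes, per-scaffold mean read
depth is bimodal: scaffolds representing a single haplotype of a divergent
region attract half the reads (the haploid peak, lambda_hap), while scaffolds
where both haplotypes collapsed attract them all (the diploid peak,
lambda_dip).  An unconstrained two-component Poisson mixture is fitted by EM
and scaffolds are classified as haploid- or diploid-depth either by posterior
probability or by a central probability interval of the haploid component.

Scaffold mean depths are continuous, so the Poisson log-pmf is evaluated
continuously via the gamma function (x log lam - lam - lgamma(x + 1)) rather
than after rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import poisson

__all__ = [
    "DepthMixtureModel",
    "fit_poisson_mixture",
    "classify_scaffold",
    "scaffold_depths",
]


@dataclass
class DepthMixtureModel:
    """Fitted two-component Poisson mixture; components ordered lambda_hap < lambda_dip."""

    lambda_hap: float
    lambda_dip: float
    weight_hap: float
    loglik: float
    n_iter: int
    converged: bool

    @property
    def weight_dip(self) -> float:
        return 1.0 - self.weight_hap


def _log_pmf(x: np.ndarray, lam: float) -> np.ndarray:
    # continuous extension of the Poisson log-pmf
    return x * np.log(lam) - lam - gammaln(x + 1.0)


def fit_poisson_mixture(
    depths,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> DepthMixtureModel:
    """Fit an unconstrained two-component Poisson mixture by EM.

    Components are initialized at the 25th and 75th percentiles of the data
    and ordered afterwards so lambda_hap < lambda_dip.  The fit is
    deterministic given the data (the seed parameter is accepted for interface
    uniformity; percentile initialization involves no randomness).  The
    log-likelihood is asserted non-decreasing across iterations.
    """
    x = np.asarray(depths, dtype=float)
    if x.size < 50:
        raise ValueError("need at least 50 depth observations")
    if np.any(x < 0):
        raise ValueError("depths must be nonnegative")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate input: all depths identical")
    x = np.maximum(x, 1e-9)  # zero depths break x*log(lam) gradient bookkeeping

    lam = np.array([np.percentile(x, 25), np.percentile(x, 75)])
    if lam[0] == lam[1]:
        lam[1] = lam[0] * 1.5 + 1.0
    w = np.array([0.5, 0.5])

    prev_ll = -np.inf
    ll = prev_ll
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E step
        log_resp = np.log(w)[:, None] + np.vstack([_log_pmf(x, l) for l in lam])
        norm = logsumexp(log_resp, axis=0)
        ll = float(norm.sum())
        assert ll >= prev_ll - 1e-8, "EM log-likelihood decreased"
        resp = np.exp(log_resp - norm)
        # M step
        nk = resp.sum(axis=1)
        w = nk / x.size
        lam = resp @ x / nk
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll

    order = np.argsort(lam)
    lam, w = lam[order], w[order]
    return DepthMixtureModel(
        lambda_hap=float(lam[0]),
        lambda_dip=float(lam[1]),
        weight_hap=float(w[0]),
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
    )


def classify_scaffold(
    mean_depth: float,
    model: DepthMixtureModel,
    rule: str = "posterior",
    posterior_band: float = 0.05,
    interval_mass: float = 0.99,
) -> str:
    """Classify a scaffold depth as 'haploid', 'diploid', or 'ambiguous'.

    rule='posterior' (default): the component with posterior probability > 0.5
    wins; within ``posterior_band`` of 0.5 the call is 'ambiguous' to avoid
    knife-edge purging.  rule='central_interval': 'haploid' iff the depth falls
    in the central ``interval_mass`` probability interval of
    Poisson(lambda_hap) — the literal "fell in a Poisson distribution" reading.
    """
    if mean_depth < 0:
        raise ValueError("depth must be nonnegative")
    if rule == "posterior":
        x = np.array([max(mean_depth, 1e-9)])
        log_h = np.log(model.weight_hap) + _log_pmf(x, model.lambda_hap)[0]
        log_d = np.log(model.weight_dip) + _log_pmf(x, model.lambda_dip)[0]
        post_h = float(np.exp(log_h - logsumexp([log_h, log_d])))
        if abs(post_h - 0.5) < posterior_band:
            return "ambiguous"
        return "haploid" if post_h > 0.5 else "diploid"
    if rule == "central_interval":
        alpha = (1.0 - interval_mass) / 2.0
        lo = poisson.ppf(alpha, model.lambda_hap)
        hi = poisson.ppf(1.0 - alpha, model.lambda_hap)
        return "haploid" if lo <= mean_depth <= hi else "diploid"
    raise ValueError(f"unknown rule {rule!r}")


def scaffold_depths(table: pd.DataFrame) -> pd.Series:
    """Per-scaffold arithmetic mean depth from a long-format depth table.

    The table's first column is the scaffold id; the depth is taken from a
    column named 'depth' (or 'mean_depth'), ignoring any other columns such as
    mapping quality.  A scaffold with zero rows is simply absent from the
    result (missing, not zero).
    """
    id_col = table.columns[0]
    for depth_col in ("depth", "mean_depth"):
        if depth_col in table.columns:
            break
    else:
        depth_col = table.columns[1]
    means = table.groupby(id_col, sort=False)[depth_col].mean()
    means.name = "mean_depth"
    return means
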