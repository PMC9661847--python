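"""Dirichlet multinomial mixture (DMM) community typing.

Samples are count vectors; each mixture component is a Dirichlet-multinomial
with its own concentration vector ``alpha_k``.  Fitting is by EM on the
posterior: the E-step computes component responsibilities from the DM
marginal likelihood, the M-step re-estimates mixture weights and updates
each ``alpha_k`` by a damped fixed-point iteration that includes a weakly
informative ``Gamma(0.1, 0.1)`` prior on every concentration.  The prior is
parameterised in log-concentration space (``lambda = log alpha``), where its
mode is well defined; the same space hosts the Laplace approximation used
for model selection.

The number of components is chosen by minimising the Laplace-approximated
negative log model evidence.  Per component the Hessian of the penalised
negative log-likelihood with respect to the concentrations has the closed
form ``diag(d) + c * 1 1'`` with

    d_t = sum_i w_i [psi'(a_t) - psi'(x_it + a_t)]
    c   = sum_i w_i [psi'(n_i + a_0) - psi'(a_0)]

whose determinant is ``prod(d_t) * (1 + c * sum(1/d_t))``; transforming to
lambda space adds ``nu * a_t`` prior curvature to the diagonal.  BIC is
available as a configurable alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, polygamma, psi

from .config import derive_rng
from .containers import CountTable

log = logging.getLogger("pneumotyper")

_ALPHA_FLOOR = 1e-8
# Gamma(shape ETA, rate NU) prior on each concentration parameter
ETA = 0.1
NU = 0.1


@dataclass
class DMMFit:
    k: int
    weights: np.ndarray
    alphas: np.ndarray  # (k, n_taxa)
    responsibilities: pd.DataFrame  # samples x components
    log_likelihood: float
    scores: dict[int, float]  # candidate k -> selection score (lower better)
    converged: bool
    taxon_ids: list[str]

    def assignments(self) -> pd.Series:
        """Hard component assignment per sample."""
        return self.responsibilities.idxmax(axis=1)


def _dm_loglik_rows(x: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """log DM(x_i | alpha) for every row of x (constant multinomial
    coefficient omitted — it cancels in responsibilities and model
    comparison alike)."""
    a0 = alpha.sum()
    n = x.sum(axis=1)
    return (
        gammaln(a0)
        - gammaln(n + a0)
        + (gammaln(x + alpha) - gammaln(alpha)).sum(axis=1)
    )


def _log_prior(alphas: np.ndarray) -> float:
    """Gamma(ETA, NU) prior ordinate in log-concentration space."""
    return float(
        (ETA * np.log(NU) - gammaln(ETA) + ETA * np.log(alphas) - NU * alphas).sum()
    )


def _update_alpha(
    x: np.ndarray,
    resp_k: np.ndarray,
    alpha: np.ndarray,
    n_inner: int = 25,
) -> np.ndarray:
    """Fixed-point MAP update of one component's concentration vector.

    Stationarity of the penalised objective in lambda space gives
    ``alpha <- (alpha * num + ETA) / (den + NU)`` with the usual Minka
    numerator/denominator of the weighted DM likelihood.
    """
    n = x.sum(axis=1)
    w = resp_k
    if w.sum() <= 0:
        return alpha
    for _ in range(n_inner):
        a0 = alpha.sum()
        num = (w[:, None] * (psi(x + alpha) - psi(alpha))).sum(axis=0)
        den = (w * (psi(n + a0) - psi(a0))).sum()
        if den + NU <= 0:
            break
        new = np.maximum((alpha * num + ETA) / (den + NU), _ALPHA_FLOOR)
        if np.max(np.abs(new - alpha) / (alpha + 1e-12)) < 1e-7:
            alpha = new
            break
        alpha = new
    return alpha


def _em_once(
    x: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    ll_trace: list | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool]:
    """One EM run.  ``ll_trace`` records the penalised objective
    (data log-likelihood + log prior), the quantity MAP-EM ascends."""
    n_samples, n_taxa = x.shape
    rel = x / x.sum(axis=1, keepdims=True)
    # seed each component at a random sample's composition, mildly concentrated
    picks = rng.choice(n_samples, size=k, replace=False)
    alphas = np.maximum(rel[picks] * 50.0, _ALPHA_FLOOR)
    weights = np.full(k, 1.0 / k)

    prev_obj = -np.inf
    converged = False
    for _ in range(max_iter):
        log_p = np.stack([_dm_loglik_rows(x, alphas[j]) for j in range(k)], axis=1)
        log_p = log_p + np.log(weights)[None, :]
        ll = float(logsumexp(log_p, axis=1).sum())
        obj = ll + _log_prior(alphas)
        if ll_trace is not None:
            ll_trace.append(obj)
        resp = np.exp(log_p - logsumexp(log_p, axis=1, keepdims=True))

        weights = np.maximum(resp.mean(axis=0), 1e-12)
        weights /= weights.sum()
        for j in range(k):
            alphas[j] = _update_alpha(x, resp[:, j], alphas[j])

        if abs(obj - prev_obj) < tol * max(1.0, abs(obj)):
            converged = True
            break
        prev_obj = obj
    log_p = np.stack([_dm_loglik_rows(x, alphas[j]) for j in range(k)], axis=1)
    log_p = log_p + np.log(weights)[None, :]
    ll = float(logsumexp(log_p, axis=1).sum())
    resp = np.exp(log_p - logsumexp(log_p, axis=1, keepdims=True))
    return weights, alphas, resp, ll, converged


def _laplace_score(
    x: np.ndarray, weights: np.ndarray, alphas: np.ndarray, resp: np.ndarray, ll: float
) -> float:
    """Laplace-approximated negative log evidence at the MAP (lower better)."""
    k, n_taxa = alphas.shape
    n_samples = x.shape[0]
    n = x.sum(axis=1)
    half_log_det = 0.0
    for j in range(k):
        a = alphas[j]
        a0 = a.sum()
        w = resp[:, j]
        d = (w[:, None] * (polygamma(1, a)[None, :] - polygamma(1, x + a))).sum(axis=0)
        c = float((w * (polygamma(1, n + a0) - polygamma(1, a0))).sum())
        diag_l = np.maximum(a * a * d + NU * a, 1e-10)
        rank_one = 1.0 + c * float((a * a / diag_l).sum())
        half_log_det += 0.5 * (
            float(np.log(diag_l).sum()) + np.log(max(rank_one, 1e-10))
        )
    n_params = k * n_taxa + (k - 1)
    return (
        -ll
        - _log_prior(alphas)
        - 0.5 * n_params * np.log(2 * np.pi)
        + half_log_det
        + 0.5 * max(k - 1, 0) * np.log(n_samples)
    )


def _bic_score(x, weights, alphas, resp, ll) -> float:
    k, n_taxa = alphas.shape
    n_params = k * n_taxa + (k - 1)
    return -ll + 0.5 * n_params * np.log(x.shape[0])


def fit_dmm(
    table: CountTable,
    k_range=(1, 2, 3),
    seed: int = 0,
    *,
    restarts: int = 3,
    max_iter: int = 200,
    tol: float = 1e-7,
    selection: str = "laplace",
) -> DMMFit:
    """Fit DMMs over ``k_range`` and keep the k with the best score.

    Each k gets ``restarts`` random initialisations; the best-likelihood run
    is scored.  Components that capture fewer than one sample's worth of
    responsibility are pruned with a warning before scoring.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if min(k_range) < 1 or max(k_range) > 6:
        raise ValueError("k_range must lie within [1, 6]")
    x = table.counts.to_numpy(dtype=float)
    if x.shape[0] < 2 * max(k_range):
        raise ValueError("need at least 2 samples per candidate component")
    score_fn = {"laplace": _laplace_score, "bic": _bic_score}[selection]
    rng = derive_rng(seed, "fit_dmm")

    scores: dict[int, float] = {}
    best_by_k: dict[int, tuple] = {}
    for k in k_range:
        best = None
        for _ in range(restarts):
            weights, alphas, resp, ll, conv = _em_once(x, k, rng, max_iter, tol)
            if best is None or ll > best[3]:
                best = (weights, alphas, resp, ll, conv)
        weights, alphas, resp, ll, conv = best
        occupied = resp.sum(axis=0) >= 1.0
        if not occupied.all():
            log.warning("pruning %d empty DMM component(s) at k=%d", (~occupied).sum(), k)
            weights, alphas, resp = weights[occupied], alphas[occupied], resp[:, occupied]
            weights /= weights.sum()
            resp = resp / resp.sum(axis=1, keepdims=True)
        if not conv:
            log.warning("DMM EM did not converge at k=%d; keeping best-so-far", k)
        scores[k] = float(score_fn(x, weights, alphas, resp, ll))
        best_by_k[k] = (weights, alphas, resp, ll, conv)

    k_best = min(scores, key=scores.get)
    weights, alphas, resp, ll, conv = best_by_k[k_best]
    resp_df = pd.DataFrame(
        resp, index=table.sample_ids, columns=[f"C{j+1}" for j in range(resp.shape[1])]
    )
    return DMMFit(
        k=int(resp.shape[1]),
        weights=weights,
        alphas=alphas,
        responsibilities=resp_df,
        log_likelihood=ll,
        scores=scores,
        converged=conv,
        taxon_ids=table.taxon_ids,
    )
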