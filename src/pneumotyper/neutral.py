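"""Sloan neutral community model: single- and multiple-source fits.

The model predicts the occurrence frequency of a taxon across local (sink)
communities from its mean relative abundance ``p`` in a source pool, a
migration (diffusion) coefficient ``m`` and the community size ``N_T``::

    F_hat(p) = 1 - BetaCDF(d; N_T*m*p, N_T*m*(1-p)),   d = 1/N_T

``N_T`` is taken as the mean sink read depth and ``d`` is the corresponding
detection limit.  ``m`` is fitted by bounded nonlinear least squares on the
observed occurrence frequencies, with a 95% Wilson score band around the
fitted curve used to partition taxa into neutrally distributed, above- and
below-prediction sets.

The multiple-source variant pools several source sites into one species
pool, refits, attributes each taxon to the site where it is most abundant,
and cross-tabulates attributed sites against lung occurrence-frequency
quartile groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import CountTable

M_BOUNDS = (1e-6, 10.0)
N_STARTS = 5


def predict_occurrence(p, m: float, n_t: float, d: float):
    """Predicted occurrence frequency; vectorised over source abundance p.

    Monotone increasing in p, and in m for p > d.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("source abundances must lie strictly in (0, 1)")
    if m <= 0 or n_t <= 0:
        raise ValueError("m and N_T must be positive")
    if not 0 < d < 1:
        raise ValueError("detection limit d must lie in (0, 1)")
    return stats.beta.sf(d, n_t * m * p, n_t * m * (1.0 - p))


def wilson_interval(phat: float, n: int, z: float = 1.959963984540054):
    """95% Wilson score interval for a proportion, clamped to [0, 1]."""
    phat = np.asarray(phat, dtype=float)
    if n < 1:
        raise ValueError("n must be at least 1")
    if np.any((phat < 0) | (phat > 1)):
        raise ValueError("phat must lie in [0, 1]")
    z2 = z * z
    denom = 1.0 + z2 / n
    centre = (phat + z2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(phat * (1 - phat) / n + z2 / (4 * n * n))
    lo = np.clip(centre - half, 0.0, 1.0)
    hi = np.clip(centre + half, 0.0, 1.0)
    return lo, hi


@dataclass
class NeutralFit:
    """Fitted migration rate, fit quality, and the per-taxon frequency table.

    ``taxa`` columns: p (source abundance), F (observed sink occurrence),
    Fhat (prediction), ci_lo/ci_hi (Wilson band around Fhat), partition
    (above / neutral / below).
    """

    m: float
    r2: float
    n_t: float
    d: float
    n_sinks: int
    taxa: pd.DataFrame

    def partition_counts(self) -> dict[str, int]:
        return self.taxa["partition"].value_counts().to_dict()

    def summary(self) -> dict:
        return {
            "m": self.m,
            "r2": self.r2,
            "n_t": self.n_t,
            "d": self.d,
            "n_sinks": self.n_sinks,
            "n_taxa": int(len(self.taxa)),
            "partition": self.partition_counts(),
        }


@dataclass
class MultiSourceAttribution:
    """Per-taxon source attribution and frequency-quartile contribution table.

    ``contribution`` rows are source sites (plus possibly ``unattributed``),
    columns the lung-frequency groups; cells count attributed taxa.
    """

    attribution: pd.Series
    freq_group: pd.Series
    contribution: pd.DataFrame


def source_profile(source: CountTable) -> pd.Series:
    """Mean of per-sample relative abundances (robust to depth imbalance)."""
    return source.relative_abundance().mean(axis=0)


def occurrence_frequencies(sinks: CountTable) -> pd.Series:
    """Fraction of sink samples in which each taxon is detected (count > 0)."""
    return (sinks.counts > 0).mean(axis=0)


def _fit_m(p: np.ndarray, f_obs: np.ndarray, n_t: float, d: float) -> float:
    """Bounded least squares on m with log-spaced multistarts."""

    def sse(log_m: np.ndarray) -> float:
        resid = f_obs - predict_occurrence(p, float(np.exp(log_m[0])), n_t, d)
        return float(resid @ resid)

    lo, hi = np.log(M_BOUNDS[0]), np.log(M_BOUNDS[1])
    starts = np.linspace(np.log(1e-4), np.log(1.0), N_STARTS)
    best, best_val = None, np.inf
    for s in starts:
        res = optimize.minimize(
            sse, x0=[s], method="L-BFGS-B", bounds=[(lo, hi)]
        )
        if res.fun < best_val:
            best, best_val = res, res.fun
    if best is None or not np.isfinite(best_val):
        raise RuntimeError("neutral-model optimiser failed at every start")
    return float(np.exp(best.x[0]))


def fit_neutral_profile(
    profile: pd.Series, sinks: CountTable, *, min_taxa: int = 20, min_sinks: int = 10
) -> NeutralFit:
    """Fit the neutral model of a source profile against sink samples.

    Taxa with source abundance outside (0, 1) are excluded; the remainder
    must number at least ``min_taxa``.
    """
    if sinks.n_samples < min_sinks:
        raise ValueError(f"need at least {min_sinks} sink samples, got {sinks.n_samples}")
    shared = [t for t in sinks.taxon_ids if 0.0 < profile.get(t, 0.0) < 1.0]
    if len(shared) < min_taxa:
        raise ValueError(
            f"only {len(shared)} taxa with source abundance in (0,1); need {min_taxa}"
        )
    p = profile[shared].to_numpy(dtype=float)
    f_obs = occurrence_frequencies(sinks)[shared].to_numpy(dtype=float)
    n_t = float(sinks.depths().mean())
    d = 1.0 / n_t

    m_hat = _fit_m(p, f_obs, n_t, d)
    f_hat = predict_occurrence(p, m_hat, n_t, d)
    sse = float(np.sum((f_obs - f_hat) ** 2))
    sst = float(np.sum((f_obs - f_obs.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf)

    ci_lo, ci_hi = wilson_interval(f_hat, sinks.n_samples)
    partition = np.where(
        f_obs > ci_hi, "above", np.where(f_obs < ci_lo, "below", "neutral")
    )
    taxa = pd.DataFrame(
        {
            "p": p,
            "F": f_obs,
            "Fhat": f_hat,
            "ci_lo": ci_lo,
            "ci_hi": ci_hi,
            "partition": partition,
        },
        index=pd.Index(shared, name="taxon"),
    )
    return NeutralFit(m=m_hat, r2=r2, n_t=n_t, d=d, n_sinks=sinks.n_samples, taxa=taxa)


def fit_neutral(source: CountTable, sinks: CountTable, **kwargs) -> NeutralFit:
    """Fit against the mean relative-abundance profile of a source table."""
    return fit_neutral_profile(source_profile(source), sinks, **kwargs)


def _frequency_groups(f_obs: pd.Series) -> pd.Series:
    """Inclusive quartile grouping; boundary taxa go to the extreme group."""
    q1, q3 = np.quantile(f_obs.to_numpy(), [0.25, 0.75])
    groups = pd.Series("interquartile", index=f_obs.index)
    groups[f_obs >= q3] = "upper-quartile"
    groups[f_obs <= q1] = "lower-quartile"
    return groups


def fit_multi_source(
    sources: Mapping[str, CountTable], sinks: CountTable, **kwargs
) -> tuple[NeutralFit, MultiSourceAttribution]:
    """Pooled multi-source neutral fit plus per-taxon site attribution.

    The pooled species pool is the mean relative abundance over the
    concatenated source samples (sites implicitly weighted by sample count).
    Each fitted taxon is attributed to the site where its mean relative
    abundance is maximal; ties break by higher prevalence within the site,
    then lexicographic site name.  Taxa absent from every source are
    ``unattributed``.
    """
    if not sources:
        raise ValueError("at least one source site is required")
    site_names = sorted(sources)
    universe = sinks.taxon_ids
    site_means = {}
    site_prev = {}
    frames = []
    for site in site_names:
        tab = sources[site]
        rel = tab.relative_abundance().reindex(columns=universe, fill_value=0.0)
        site_means[site] = rel.mean(axis=0)
        site_prev[site] = (
            (tab.counts > 0).reindex(columns=universe, fill_value=False).mean(axis=0)
        )
        frames.append(rel)
    pooled = pd.concat(frames, axis=0).mean(axis=0)

    fit = fit_neutral_profile(pooled, sinks, **kwargs)
    fitted_taxa = list(fit.taxa.index)

    mean_mat = pd.DataFrame({s: site_means[s] for s in site_names}).loc[fitted_taxa]
    prev_mat = pd.DataFrame({s: site_prev[s] for s in site_names}).loc[fitted_taxa]
    attribution = []
    for taxon in fitted_taxa:
        row = mean_mat.loc[taxon]
        if row.max() <= 0:
            attribution.append("unattributed")
            continue
        best = row[np.isclose(row, row.max())].index.tolist()
        if len(best) > 1:
            prow = prev_mat.loc[taxon, best]
            best = prow[np.isclose(prow, prow.max())].index.tolist()
        attribution.append(sorted(best)[0])
    attribution = pd.Series(attribution, index=fitted_taxa, name="site")

    groups = _frequency_groups(fit.taxa["F"])
    order = ["lower-quartile", "interquartile", "upper-quartile"]
    contribution = (
        pd.crosstab(attribution, groups)
        .reindex(columns=order, fill_value=0)
        .reindex(index=sorted(attribution.unique()), fill_value=0)
    )
    return fit, MultiSourceAttribution(
        attribution=attribution, freq_group=groups, contribution=contribution
    )
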