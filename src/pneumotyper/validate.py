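"""Self-validation experiments: recovery of known ground truth.

Each function sets up a generative scenario with known parameters, runs the
corresponding pipeline stage, and returns the measured quantities alongside
the truth.  The test suite asserts tolerances on these results and the
acceptance script reports them; keeping the experiments here guarantees the
two always run identical conditions.

Problem sizes are desk-scale: 200 sinks x 300 taxa for migration-rate
recovery, 60-subject cohorts for pneumo-typing, 50 taxa x 500 samples for
correlation recovery.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.metrics import adjusted_rand_score

from . import ecology, networks, neutral, pneumotype, simulate, sourcetracker
from .config import derive_rng
from .containers import CountTable
from .dmm import fit_dmm


# ------------------------------------------------------------- neutral model

def neutral_recovery(m_true: float, seed: int) -> dict:
    """Fit m on a cohort generated with known m (matched N_T = depth = 1000).

    200 sink subjects, 300 taxa; the fit uses the cohort-mean mixed source
    pool, as the real analysis pools sources across subjects.
    """
    _, truth = simulate.simulate_sources(
        n_taxa=300, n_subjects=200, overlap=0.6, seed=seed
    )
    truth.n_t = 1000
    truth.depth = 1000
    truth = simulate.assign_groups_and_weights(
        truth, seed=seed, hi_fraction=1.0, m_hi=m_true, m_lo=m_true
    )
    truth.n_t = 1000
    truth.depth = 1000
    lungs = simulate.simulate_lung_cohort(truth, seed=seed)
    pool = np.mean([truth.mixed_pool(s) for s in truth.subjects], axis=0)
    fit = neutral.fit_neutral_profile(pd.Series(pool, index=truth.taxon_ids), lungs)
    return {
        "m_true": m_true,
        "m_hat": fit.m,
        "relative_error": (fit.m - m_true) / m_true,
        "r2": fit.r2,
        "n_sinks": fit.n_sinks,
    }


# ------------------------------------------------- source apportionment

def apportionment_recovery(seed: int, *, depth: int = 2000, restarts: int = 10) -> dict:
    """Recover a known (0.6, 0.3, 0.0, 0.1) mixture over 3 sources + unknown.

    The 0.1 slice comes from taxa absent from every named source, so it must
    be absorbed by the unknown component.
    """
    rng = derive_rng(seed, "apportionment_recovery")
    n_taxa = 120
    taxa = [f"t{i}" for i in range(n_taxa)]
    profiles = [rng.dirichlet(np.full(n_taxa, 0.3)) for _ in range(3)]
    novel = np.zeros(n_taxa)
    picked = rng.choice(n_taxa, 15, replace=False)
    novel[picked] = rng.dirichlet(np.ones(15))
    for prof in profiles:
        prof[picked] = 0.0
        prof /= prof.sum()
    truth = {"A": 0.6, "B": 0.3, "C": 0.0, "unknown": 0.1}
    mix = 0.6 * profiles[0] + 0.3 * profiles[1] + 0.0 * profiles[2] + 0.1 * novel
    sources = {
        name: pd.Series(rng.multinomial(20_000, prof), index=taxa)
        for name, prof in zip(("A", "B", "C"), profiles)
    }
    sink = pd.Series(rng.multinomial(depth, mix), index=taxa)
    est = sourcetracker.apportion(
        sink, sources, seed=seed, restarts=restarts, rarefaction_depth=0
    )
    errors = {k: abs(float(est.proportions[k]) - v) for k, v in truth.items()}
    return {
        "truth": truth,
        "estimate": est.proportions.to_dict(),
        "mean_absolute_error": float(np.mean(list(errors.values()))),
        "max_absolute_error": float(max(errors.values())),
    }


def enumerate_posterior(
    sink_taxa: np.ndarray,
    source_counts: np.ndarray,
    alpha1: float,
    alpha2: float,
    beta: float,
) -> np.ndarray:
    """Exact posterior mean source proportions by exhaustive enumeration.

    Sums the collapsed-model joint weight over every assignment vector of
    the sink reads to (named sources + unknown); tractable for a handful of
    reads.  Independent of the Gibbs sampler: no sampling is involved.
    """
    n_known, n_taxa = source_counts.shape
    n_src = n_known + 1
    n_reads = sink_taxa.size
    theta = (source_counts + alpha1) / (
        source_counts.sum(axis=1, keepdims=True) + alpha1 * n_taxa
    )
    total_w = 0.0
    mean = np.zeros(n_src)
    for z in itertools.product(range(n_src), repeat=n_reads):
        z = np.asarray(z)
        logw = 0.0
        n_s = np.bincount(z, minlength=n_src)
        for r in range(n_reads):
            if z[r] < n_known:
                logw += math.log(theta[z[r], sink_taxa[r]])
        c_unk = np.bincount(sink_taxa[z == n_known], minlength=n_taxa)
        logw += float((gammaln(alpha2 + c_unk) - gammaln(alpha2)).sum())
        logw += gammaln(alpha2 * n_taxa) - gammaln(alpha2 * n_taxa + n_s[n_known])
        logw += float((gammaln(beta + n_s) - gammaln(beta)).sum())
        w = math.exp(logw)
        total_w += w
        mean += w * n_s / n_reads
    return mean / total_w


def gibbs_vs_enumeration(seed: int) -> dict:
    """Compare Gibbs posterior means with exhaustive enumeration on a toy.

    2 taxa, 2 named sources, 6 sink reads.  The Monte-Carlo standard error
    is estimated from the spread of independent restart means.
    """
    alpha1, alpha2, beta = 0.01, 0.1, 1.0
    source_counts = np.array([[8, 2], [2, 8]], dtype=float)
    sink_taxa = np.array([0, 0, 0, 1, 1, 0], dtype=np.int64)
    exact = enumerate_posterior(sink_taxa, source_counts, alpha1, alpha2, beta)

    taxa = ["tA", "tB"]
    sink = pd.Series(np.bincount(sink_taxa, minlength=2), index=taxa)
    sources = {
        "A": pd.Series(source_counts[0], index=taxa),
        "B": pd.Series(source_counts[1], index=taxa),
    }
    n_restarts = 40
    est = sourcetracker.apportion(
        sink,
        sources,
        seed=seed,
        alpha1=alpha1,
        alpha2=alpha2,
        beta=beta,
        burnin=200,
        restarts=n_restarts,
        draws_per_restart=100,
        draw_gap=2,
        rarefaction_depth=0,
    )
    draws = est.draws  # (restarts * draws_per_restart, 3)
    restart_means = draws.reshape(n_restarts, -1, draws.shape[1]).mean(axis=1)
    mc_sigma = restart_means.std(axis=0, ddof=1) / np.sqrt(n_restarts)
    gibbs_mean = draws.mean(axis=0)
    diff = np.abs(gibbs_mean - exact)
    return {
        "exact": exact.tolist(),
        "gibbs": gibbs_mean.tolist(),
        "mc_sigma": mc_sigma.tolist(),
        "max_sigma_units": float(np.max(diff / np.maximum(mc_sigma, 1e-12))),
    }


# ----------------------------------------------------------- pneumo-typing

def pneumotype_recovery(seed: int) -> dict:
    """End-to-end typing of the default synthetic cohort.

    Returns the KDE cutoff and modes, agreement of trough labels with the
    latent groups, DMM selected k, ARI against the latent groups, and the
    Fisher p of KDE/DMM concordance.
    """
    sources, lungs, meta, truth = simulate.simulate_cohort(seed=seed)
    st = sourcetracker.cohort_st(lungs, sources, meta, seed=seed)
    cutoff, modes, _, _ = pneumotype.density_trough(st["ST"])
    labels = pneumotype.assign_pneumotypes(st["ST"], cutoff)
    latent = pd.Series(truth.group).map({"HI": "HOIT", "LO": "LOIT"})
    agreement = float((labels == latent[labels.index]).mean())

    # community typing runs on the core taxa, as in network construction
    fit = fit_dmm(networks.core_taxa_filter(lungs), k_range=(1, 2, 3), seed=seed)
    assign = fit.assignments()
    assign.index = [s.rsplit("_", 1)[0] for s in assign.index]
    ari = adjusted_rand_score(
        latent[assign.index].to_numpy(), pd.factorize(assign)[0]
    )
    # concordance needs binary typings: when the DMM keeps more than two
    # components, collapse each onto whether its mean ST sits above the cutoff
    binary = assign
    if assign.nunique() > 2:
        comp_mean_st = st["ST"].groupby(assign[st.index]).mean()
        binary = assign.map(lambda c: "high" if comp_mean_st[c] >= cutoff else "low")
    _, fisher_p = pneumotype.concordance(labels, binary[labels.index])
    group_means = st["ST"].groupby(pd.Series(truth.group)).mean()
    return {
        "cutoff": float(cutoff),
        "modes": modes.tolist(),
        "label_agreement": agreement,
        "dmm_k": fit.k,
        "dmm_ari": float(ari),
        "fisher_p": float(fisher_p),
        "mean_st_hi": float(group_means["HI"]),
        "mean_st_lo": float(group_means["LO"]),
    }


# ------------------------------------------------------------------- sparcc

def _lognormal_counts(
    rng: np.random.Generator, n_samples: int, n_taxa: int, planted_rho: float | None
) -> CountTable:
    mu = rng.normal(0, 1, n_taxa)
    sig = rng.uniform(0.3, 1.0, n_taxa)
    z = rng.normal(size=(n_samples, n_taxa))
    if planted_rho is not None:
        z[:, 1] = planted_rho * z[:, 0] + np.sqrt(1 - planted_rho**2) * z[:, 1]
    basis = np.exp(mu + sig * z)
    frac = basis / basis.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(5000, f) for f in frac])
    return CountTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"t{j}" for j in range(n_taxa)],
        )
    )


def sparcc_recovery(seed: int) -> dict:
    """Recover a planted basis correlation of 0.8 (50 taxa, 500 samples)."""
    rng = derive_rng(seed, "sparcc_recovery")
    table = _lognormal_counts(rng, 500, 50, planted_rho=0.8)
    rho = networks.sparcc(table)
    p = networks.edge_significance(table, rho, n_iter=1000, seed=seed)
    return {
        "rho_true": 0.8,
        "rho_hat": float(rho.iloc[0, 1]),
        "p_planted": float(p.iloc[0, 1]),
        "p_min_attainable": 1.0 / 1001.0,
    }


def sparcc_calibration(seed: int) -> dict:
    """Null false-positive rate at alpha=0.05 on independent taxa."""
    rng = derive_rng(seed, "sparcc_calibration")
    table = _lognormal_counts(rng, 200, 30, planted_rho=None)
    rho = networks.sparcc(table)
    p = networks.edge_significance(table, rho, n_iter=1000, seed=seed)
    iu = np.triu_indices(table.n_taxa, 1)
    return {
        "false_positive_rate": float((p.to_numpy()[iu] < 0.05).mean()),
        "n_pairs": int(len(iu[0])),
    }


# ---------------------------------------------------------------------- NST

def nst_direction(seed: int) -> dict:
    """NST of a purely neutral group, a selection-dominated group, and the
    two cohort groups (higher-m HI vs lower-m LO)."""
    # neutral: one group, shared pool, moderate migration
    _, truth = simulate.simulate_sources(n_taxa=300, n_subjects=40, overlap=0.6, seed=seed)
    truth.n_t = 1000
    truth.depth = 1000
    truth = simulate.assign_groups_and_weights(
        truth, seed=seed, hi_fraction=1.0, m_hi=0.05, m_lo=0.05
    )
    truth.n_t = 1000
    truth.depth = 1000
    neutral_lungs = simulate.simulate_lung_cohort(truth, seed=seed)
    g_neutral = pd.Series("neutral", index=neutral_lungs.sample_ids)
    nst_neutral = ecology.nst(neutral_lungs, g_neutral, seed=seed)["neutral"].nst

    # selection-dominated: two disjoint heavy-tailed templates, 1% noise
    rng = derive_rng(seed, "nst_templates")
    n_taxa = 100
    tmpl_a = np.zeros(n_taxa)
    tmpl_b = np.zeros(n_taxa)
    tmpl_a[:50] = rng.lognormal(0, 1.5, 50)
    tmpl_b[50:] = rng.lognormal(0, 1.5, 50)
    tmpl_a /= tmpl_a.sum()
    tmpl_b /= tmpl_b.sum()
    rows = []
    for i in range(20):
        base = tmpl_a if i % 2 == 0 else tmpl_b
        comp = 0.99 * base + 0.01 * rng.dirichlet(np.ones(n_taxa))
        rows.append(rng.multinomial(2000, comp / comp.sum()))
    det = CountTable(
        pd.DataFrame(
            rows, index=[f"d{i}" for i in range(20)], columns=[f"t{j}" for j in range(n_taxa)]
        )
    )
    g_det = pd.Series("templates", index=det.sample_ids)
    nst_det = ecology.nst(det, g_det, seed=seed)["templates"].nst

    # cohort groups: HI (m=0.04) vs LO (m=0.012)
    _, lungs, _, cohort_truth = simulate.simulate_cohort(seed=seed)
    groups = pd.Series({f"{s}_BAL": cohort_truth.group[s] for s in cohort_truth.subjects})
    res = ecology.nst(lungs, groups, seed=seed)
    return {
        "nst_neutral": float(nst_neutral),
        "nst_selection": float(nst_det),
        "nst_hi": float(res["HI"].nst),
        "nst_lo": float(res["LO"].nst),
    }
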