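"""Community ecology statistics used to characterise pneumo-types.

Shannon alpha diversity, Bray-Curtis dissimilarity, classical PCoA,
PERMANOVA with free permutation of sample labels, Levins' niche breadth,
and a normalised stochasticity ratio (NST) built on a
richness-preserving occupancy/abundance null model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .config import derive_rng
from .containers import CountTable

log = logging.getLogger("pneumotyper")


@dataclass
class DistanceMatrix:
    """Symmetric Bray-Curtis dissimilarities in [0, 1] with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValueError("Bray-Curtis distances must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def shannon(table: CountTable) -> pd.Series:
    """Shannon index H = -sum p ln p (natural log) per sample."""
    rel = table.relative_abundance().to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(rel > 0, rel * np.log(rel), 0.0)
    return pd.Series(-terms.sum(axis=1), index=table.sample_ids, name="shannon")


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """BC(a, b) = 1 - 2 sum_t min(a_t, b_t) / sum_t (a_t + b_t) on proportions."""
    if table.n_samples < 2:
        raise ValueError("Bray-Curtis needs at least 2 samples")
    rel = table.relative_abundance().to_numpy()
    d = squareform(pdist(rel, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, d)


def pcoa(dm: DistanceMatrix, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling of a distance matrix.

    Eigendecomposition of the double-centred squared distances; coordinates
    use the positive eigenvalues only, and the mass carried by negative
    eigenvalues is logged.  Returns (coordinates, positive eigenvalues).
    """
    d = dm.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    neg_mass = float(np.abs(evals[evals < 0]).sum())
    total_mass = float(np.abs(evals).sum())
    if neg_mass > 0 and total_mass > 0:
        log.info("PCoA: negative eigenvalue mass fraction %.3g", neg_mass / total_mass)
    n_pos = int(pos.sum())
    if k > n_pos:
        log.warning("PCoA: only %d positive axes available (requested %d)", n_pos, k)
        k = n_pos
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    frame = pd.DataFrame(
        coords, index=dm.sample_ids, columns=[f"PC{i+1}" for i in range(k)]
    )
    return frame, evals[pos]


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Anderson's pseudo-F from squared distances and integer group codes."""
    n = d2.shape[0]
    sst = d2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ssa = sst - ssw
    return (ssa / (n_groups - 1)) / (ssw / (n - n_groups))


def permanova(
    dm: DistanceMatrix, groups: pd.Series, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """PERMANOVA: pseudo-F and permutation p with free label shuffling.

    p = (1 + #{F_perm >= F_obs}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    groups = groups.reindex(dm.sample_ids)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    codes, uniques = pd.factorize(groups)
    if len(uniques) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if pd.Series(codes).value_counts().min() < 2:
        raise ValueError("every group needs at least 2 members")
    d2 = dm.values**2
    f_obs = _pseudo_f(d2, codes, len(uniques))
    rng = derive_rng(seed, "permanova")
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, len(uniques)) >= f_obs:
            hits += 1
    return f_obs, (1 + hits) / (n_perm + 1)


def pairwise_permanova(
    dm: DistanceMatrix, groups: pd.Series, n_perm: int = 999, seed: int = 0
) -> pd.DataFrame:
    """All group pairs with Bonferroni-corrected p values."""
    groups = groups.reindex(dm.sample_ids)
    uniques = sorted(groups.dropna().unique())
    pairs = [(a, b) for i, a in enumerate(uniques) for b in uniques[i + 1 :]]
    rows = []
    frame = dm.to_frame()
    for a, b in pairs:
        keep = groups[(groups == a) | (groups == b)].index
        sub = DistanceMatrix(list(keep), frame.loc[keep, keep].to_numpy())
        f, p = permanova(sub, groups[keep], n_perm=n_perm, seed=seed)
        rows.append({"group_a": a, "group_b": b, "pseudo_F": f, "p": p})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(out["p"] * len(pairs), 1.0)
    return out


def niche_breadth(table: CountTable) -> pd.Series:
    """Levins' B_j = 1 / sum_i P_ij^2 with P_ij the share of taxon j's
    cohort-wide relative abundance found in sample i; range [1, n_samples].

    Taxa absent from every sample are excluded.
    """
    rel = table.relative_abundance()
    totals = rel.sum(axis=0)
    present = totals > 0
    if not present.all():
        log.info("niche_breadth: excluding %d absent taxa", int((~present).sum()))
    p = rel.loc[:, present] / totals[present]
    return pd.Series(1.0 / (p**2).sum(axis=0), name="levins_B")


@dataclass
class NSTResult:
    """Group-level normalised stochasticity ratio and its ingredients."""

    group: str
    nst: float
    observed: np.ndarray  # condensed observed dissimilarities
    null_expectation: np.ndarray  # condensed mean null dissimilarities
    per_pair: np.ndarray  # condensed per-pair stochasticity values
    n_randomizations: int


def _null_communities(
    rel: np.ndarray, richness: np.ndarray, occupancy: np.ndarray,
    mean_abund: np.ndarray, rng: np.random.Generator,
) -> np.ndarray:
    """One null cohort: per-sample richness preserved; taxa drawn with
    probability proportional to occupancy; abundances proportional to the
    cohort mean relative abundance of the drawn taxa."""
    n_samples, n_taxa = rel.shape
    null = np.zeros_like(rel)
    p_draw = occupancy / occupancy.sum()
    for i in range(n_samples):
        k = int(richness[i])
        chosen = rng.choice(n_taxa, size=k, replace=False, p=p_draw)
        weights = mean_abund[chosen]
        null[i, chosen] = weights / weights.sum()
    return null


def nst(
    table: CountTable,
    groups: pd.Series,
    n_randomizations: int = 100,
    seed: int = 0,
) -> dict[str, NSTResult]:
    """Normalised stochasticity ratio per group.

    For each within-group sample pair, the observed Bray-Curtis similarity
    ``C = 1 - D`` is compared with its mean ``E`` over null cohorts that
    preserve per-sample richness and draw taxa by cohort occupancy with
    cohort-mean abundances.  The per-pair value ``1 - |C - E| / max(E, 1-E)``
    is 1 when observed turnover matches the null (pure stochasticity) and 0
    at maximal deviation; NST is the group mean, clamped to [0, 1].
    """
    if n_randomizations < 30:
        raise ValueError("need at least 30 randomizations")
    groups = groups.reindex(table.sample_ids)
    results: dict[str, NSTResult] = {}
    for g in sorted(groups.dropna().unique()):
        ids = list(groups[groups == g].index)
        if len(ids) < 4:
            log.warning("NST: group %s has < 4 samples; skipped", g)
            continue
        sub = table.select_samples(ids)
        rel = sub.relative_abundance().to_numpy()
        present = rel > 0
        richness = present.sum(axis=1)
        occupancy = present.mean(axis=0)
        mean_abund = rel.mean(axis=0)
        obs = pdist(rel, metric="braycurtis")

        rng = derive_rng(seed, f"nst:{g}")
        null_sum = np.zeros_like(obs)
        for _ in range(n_randomizations):
            null = _null_communities(rel, richness, occupancy, mean_abund, rng)
            null_sum += pdist(null, metric="braycurtis")
        null_mean = null_sum / n_randomizations

        c_obs = 1.0 - obs
        c_null = 1.0 - null_mean
        per_pair = 1.0 - np.abs(c_obs - c_null) / np.maximum(c_null, 1.0 - c_null)
        value = float(np.clip(per_pair.mean(), 0.0, 1.0))
        results[g] = NSTResult(
            group=g,
            nst=value,
            observed=obs,
            null_expectation=null_mean,
            per_pair=per_pair,
            n_randomizations=n_randomizations,
        )
    return results
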