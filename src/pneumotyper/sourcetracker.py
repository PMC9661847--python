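"""Gibbs-sampling microbial source tracking.

Each sink (BAL) community is modelled as a mixture of named source
communities plus an ``unknown`` source.  Reads are assigned to sources by a
collapsed Gibbs sampler: the conditional probability that read ``r`` of
taxon ``t`` came from source ``s`` is

    P(z_r = s) ∝ (m_st + a1) / (m_s + a1*T) * (n_s^{-r} + b) / (n - 1 + b*S)

where ``m_st`` are the source's training counts (for the unknown source, the
sink reads currently assigned to it, smoothed by ``a2`` instead of ``a1``),
``n_s`` the number of sink reads currently assigned to ``s``, ``T`` the taxon
universe size and ``S`` the number of sources.  Posterior mixing proportions
are the fraction of sink reads per source, averaged over retained draws
across independent restarts.

The saliva proportion of a BAL sink is the ST value whose cohort
distribution defines the pneumo-types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from numba import njit

from .config import derive_rng
from .containers import CountTable, SampleMetadata

log = logging.getLogger("pneumotyper")

# Reference defaults of the Gibbs source-tracking method.
DEFAULT_PARAMS = dict(
    alpha1=0.001,
    alpha2=0.1,
    beta=10.0,
    burnin=100,
    restarts=10,
    draws_per_restart=1,
    draw_gap=1,
    rarefaction_depth=1000,
)


@dataclass
class MixtureEstimate:
    """Posterior mixing proportions of one sink over sources + unknown."""

    sink_id: str
    proportions: pd.Series
    draws: np.ndarray  # (total retained draws, n_sources+1), rows sum to 1
    st: float  # proportion of the designated oral source (saliva)

    def __post_init__(self) -> None:
        total = float(self.proportions.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, not 1")


@njit(cache=False)
def _gibbs_chain(
    read_taxa,
    theta,
    n_taxa,
    alpha2,
    beta,
    burnin,
    n_draws,
    draw_gap,
    seed,
):  # pragma: no cover - exercised via apportion()
    np.random.seed(seed)
    n_known = theta.shape[0]
    n_src = n_known + 1
    n_reads = read_taxa.shape[0]

    z = np.empty(n_reads, dtype=np.int64)
    n_s = np.zeros(n_src, dtype=np.int64)
    c_unk = np.zeros(n_taxa, dtype=np.int64)
    for r in range(n_reads):
        s = np.random.randint(0, n_src)
        z[r] = s
        n_s[s] += 1
        if s == n_known:
            c_unk[read_taxa[r]] += 1

    draws = np.zeros((n_draws, n_src))
    probs = np.empty(n_src)
    sweeps = burnin + n_draws * draw_gap
    taken = 0
    for sweep in range(sweeps):
        for r in range(n_reads):
            t = read_taxa[r]
            old = z[r]
            n_s[old] -= 1
            if old == n_known:
                c_unk[t] -= 1
            total = 0.0
            for s in range(n_known):
                probs[s] = theta[s, t] * (n_s[s] + beta)
                total += probs[s]
            n_unk = n_s[n_known]
            probs[n_known] = (
                (c_unk[t] + alpha2) / (n_unk + alpha2 * n_taxa) * (n_unk + beta)
            )
            total += probs[n_known]
            u = np.random.random() * total
            acc = 0.0
            new = n_src - 1
            for s in range(n_src):
                acc += probs[s]
                if u <= acc:
                    new = s
                    break
            z[r] = new
            n_s[new] += 1
            if new == n_known:
                c_unk[t] += 1
        if sweep >= burnin and (sweep - burnin + 1) % draw_gap == 0 and taken < n_draws:
            for s in range(n_src):
                draws[taken, s] = n_s[s] / n_reads
            taken += 1
    return draws


def rarefy(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement."""
    total = int(counts.sum())
    if total <= depth:
        return counts.copy()
    reads = np.repeat(np.arange(counts.size), counts)
    picked = rng.choice(reads, size=depth, replace=False)
    return np.bincount(picked, minlength=counts.size)


def apportion(
    sink: pd.Series,
    sources: Mapping[str, pd.Series],
    seed: int = 0,
    *,
    sink_id: str = "sink",
    include_unknown: bool = True,
    **params,
) -> MixtureEstimate:
    """Estimate the mixing proportions of one sink over the named sources.

    ``sink`` and each source are count vectors over a shared taxon universe
    (aligned by index).  Parameters default to :data:`DEFAULT_PARAMS`.
    """
    p = {**DEFAULT_PARAMS, **params}
    source_names = sorted(sources)
    if not source_names:
        raise ValueError("at least one source is required")
    universe = list(sink.index)
    n_taxa = len(universe)
    sink_counts = sink.to_numpy(dtype=np.int64)
    if sink_counts.sum() == 0:
        raise ValueError(f"sink {sink_id} has no reads")

    if len(source_names) == 1 and not include_unknown:
        prop = pd.Series([1.0], index=source_names)
        return MixtureEstimate(sink_id, prop, np.ones((1, 1)), float(prop.get("saliva", 0.0)))

    rng = derive_rng(seed, f"apportion:{sink_id}")
    depth = int(p["rarefaction_depth"])
    if depth > 0:
        if sink_counts.sum() < depth:
            log.warning(
                "sink %s has %d < %d reads; using as-is", sink_id, sink_counts.sum(), depth
            )
        sink_counts = rarefy(sink_counts, depth, rng)

    m = np.stack(
        [sources[s].reindex(universe).fillna(0.0).to_numpy(dtype=float) for s in source_names]
    )
    a1 = float(p["alpha1"])
    theta = (m + a1) / (m.sum(axis=1, keepdims=True) + a1 * n_taxa)

    read_taxa = np.repeat(np.arange(n_taxa), sink_counts).astype(np.int64)
    all_draws = []
    for _ in range(int(p["restarts"])):
        chain_seed = int(rng.integers(0, 2**31 - 1))
        draws = _gibbs_chain(
            read_taxa,
            theta,
            n_taxa,
            float(p["alpha2"]),
            float(p["beta"]),
            int(p["burnin"]),
            int(p["draws_per_restart"]),
            int(p["draw_gap"]),
            chain_seed,
        )
        all_draws.append(draws)
    draws = np.vstack(all_draws)
    mean = draws.mean(axis=0)
    labels = source_names + ["unknown"]
    if not include_unknown:
        # fold the (never-sampled) unknown column away for the degenerate case
        mean = mean[:-1] / mean[:-1].sum()
        labels = source_names
    proportions = pd.Series(mean, index=labels)
    proportions /= proportions.sum()
    st = float(proportions.get("saliva", 0.0))
    return MixtureEstimate(sink_id, proportions, draws, st)


def cohort_st(
    sinks: CountTable,
    sources: CountTable,
    meta: SampleMetadata,
    seed: int = 0,
    *,
    designated_source: str = "saliva",
    mode: str = "auto",
    **params,
) -> pd.DataFrame:
    """Per-subject source proportions and ST values for a cohort of sinks.

    ``mode='paired'`` uses each subject's own source samples, ``'pooled'``
    sums source samples per site across the cohort, and ``'auto'`` picks
    paired when every sink subject has a full set of source samples.
    Subjects with incomplete pairs are skipped with a warning in paired
    mode.  Returns a DataFrame indexed by subject with one column per source
    site, ``unknown`` and ``ST``.
    """
    subject_of = meta.subject_of()
    site_names = sorted(set(sources.site_of.values()))
    if designated_source not in site_names:
        raise ValueError(f"designated source {designated_source!r} not among {site_names}")
    sinks_aligned, sources_aligned = sinks.merge_taxa(sources)
    universe = sinks_aligned.taxon_ids

    by_site: dict[str, dict[str, pd.Series]] = {s: {} for s in site_names}
    for sample in sources_aligned.sample_ids:
        site = sources_aligned.site_of[sample]
        subj = subject_of.get(sample, sample)
        by_site[site][subj] = sources_aligned.counts.loc[sample]

    sink_subjects = [subject_of.get(s, s) for s in sinks_aligned.sample_ids]
    complete = all(
        all(subj in by_site[site] for site in site_names) for subj in sink_subjects
    )
    if mode == "auto":
        mode = "paired" if complete else "pooled"
    log.info("cohort_st running in %s mode over sites %s", mode, site_names)

    pooled = {
        site: pd.Series(
            np.sum([v.to_numpy() for v in by_site[site].values()], axis=0), index=universe
        )
        for site in site_names
    }

    rows = {}
    for sample, subj in zip(sinks_aligned.sample_ids, sink_subjects):
        if mode == "paired":
            if not all(subj in by_site[site] for site in site_names):
                log.warning("subject %s lacks paired source samples; skipped", subj)
                continue
            source_vecs = {site: by_site[site][subj] for site in site_names}
        else:
            source_vecs = pooled
        est = apportion(
            sinks_aligned.counts.loc[sample],
            source_vecs,
            seed=seed,
            sink_id=sample,
            **params,
        )
        row = est.proportions.to_dict()
        row["ST"] = float(est.proportions.get(designated_source, 0.0))
        rows[subj] = row
    if not rows:
        raise ValueError("no sink subject had a complete set of source samples")
    return pd.DataFrame.from_dict(rows, orient="index")
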