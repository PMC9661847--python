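"""Synthetic multi-site cohort generator with known ground truth.

The generator emulates the structure of an oral/upper-airway/lung cohort:

* three source body sites — two correlated oral-type profiles (saliva,
  oropharynx) drawn from a shared log-normal abundance spectrum, and one
  nasal profile dominated by a disjoint taxon block;
* per-subject lung (BAL) communities assembled neutrally: the subject's
  regional species pool is a weighted mixture of the source profiles, and
  the local community is a Dirichlet draw whose concentration is the product
  of community size ``N_T`` and the subject's group migration rate ``m``;
* two latent subject groups, HI and LO, that differ in how much saliva feeds
  the lung pool (bimodal Beta-distributed saliva weights) and in migration
  rate, so downstream pneumo-typing is a true inverse problem.

Because the lung marginal of ``Dirichlet(N_T * m * q)`` is
``Beta(N_T*m*q_i, N_T*m*(1-q_i))``, the occurrence frequencies of generated
cohorts follow exactly the beta-CDF prediction the neutral-model fitter uses,
making parameter recovery well-posed by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .config import derive_rng
from .containers import CountTable, SampleMetadata

SOURCE_SITES = ("saliva", "oropharynx", "nasal")

# Cohort-level defaults: 60 subjects at 10,000 reads/sample; community size
# N_T equals the read depth so the detection limit the downstream fitter
# assumes (1/mean depth) is the generative one.  HI group saliva weight ~
# Beta(8,2) with m=0.04, LO ~ Beta(2,8) with m=0.012 (migration magnitudes
# echo fitted values reported for real high/low-oral-input lung cohorts);
# ~70% of subjects are HI.
DEFAULTS = dict(
    n_taxa=300,
    n_subjects=60,
    overlap=0.6,
    nasal_fraction=1 / 3,
    depth=10_000,
    source_depth=10_000,
    n_t=10_000,
    m_hi=0.04,
    m_lo=0.012,
    hi_fraction=0.7,
    beta_hi=(8.0, 2.0),
    beta_lo=(2.0, 8.0),
    oroph_share_of_rest=0.3,
    unknown_weight=0.0,
    n_unknown_taxa=30,
    lognormal_sigma=1.5,
)


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort.

    ``profiles`` maps each source site (plus optionally ``unknown``) to its
    relative-abundance vector over ``taxon_ids``; ``weights`` holds one
    mixing-weight row per subject (columns: sites + ``unknown``); ``group``
    maps subject to latent label; ``m_group`` holds per-group migration
    rates; ``n_t`` is the community size whose product with ``m`` sets the
    Dirichlet concentration; ``depth`` is reads per lung sample.
    """

    taxon_ids: list[str]
    profiles: dict[str, np.ndarray]
    subjects: list[str] = field(default_factory=list)
    group: dict[str, str] = field(default_factory=dict)
    weights: pd.DataFrame | None = None
    m_group: dict[str, float] = field(default_factory=dict)
    n_t: int = 1000
    depth: int = 10_000

    def __post_init__(self) -> None:
        for site, prof in self.profiles.items():
            if prof.min() < 0 or not np.isclose(prof.sum(), 1.0):
                raise ValueError(f"profile for {site} is not a probability vector")
        for g, m in self.m_group.items():
            if m <= 0:
                raise ValueError(f"migration rate for group {g} must be > 0")
        if self.n_t < 100:
            raise ValueError("community size N_T must be at least 100")

    def mixed_pool(self, subject: str) -> np.ndarray:
        """Regional source pool q = sum_s w_s p^(s) for one subject."""
        if self.weights is None:
            raise ValueError("truth has no mixing weights yet")
        w = self.weights.loc[subject]
        q = np.zeros(len(self.taxon_ids))
        for site, prof in self.profiles.items():
            q += float(w.get(site, 0.0)) * prof
        if np.isnan(q).any():
            raise ValueError(f"mixed pool for {subject} contains NaN (taxa mismatch)")
        return q

    def to_dict(self) -> dict:
        return {
            "taxon_ids": self.taxon_ids,
            "profiles": {k: v.tolist() for k, v in self.profiles.items()},
            "subjects": self.subjects,
            "group": self.group,
            "weights": None if self.weights is None else self.weights.to_dict(),
            "m_group": self.m_group,
            "n_t": self.n_t,
            "depth": self.depth,
        }


def _lognormal_profile(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    x = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    return x / x.sum()


def simulate_sources(
    n_taxa: int = DEFAULTS["n_taxa"],
    n_subjects: int = DEFAULTS["n_subjects"],
    overlap: float = DEFAULTS["overlap"],
    seed: int = 0,
    *,
    nasal_fraction: float = DEFAULTS["nasal_fraction"],
    source_depth: int = DEFAULTS["source_depth"],
    lognormal_sigma: float = DEFAULTS["lognormal_sigma"],
    nasal_leak: float = 0.05,
) -> tuple[CountTable, CohortTruth]:
    """Draw the three source-site profiles and per-subject source samples.

    ``overlap`` is the fraction of each oral-type site's taxa shared with the
    other oral site; shared taxa carry identical base abundances, so
    ``overlap=1`` makes saliva and oropharynx profiles identical.  The nasal
    profile puts ``1 - nasal_leak`` of its mass on a taxon block the oral
    sites never use.
    """
    if n_taxa < 50:
        raise ValueError("n_taxa must be at least 50 to honour the site blocks")
    if not 0 <= overlap <= 1:
        raise ValueError("overlap must lie in [0, 1]")
    rng = derive_rng(seed, "simulate_sources")

    n_nasal = int(round(n_taxa * nasal_fraction))
    n_oral = n_taxa - n_nasal
    if n_nasal < 10 or n_oral < 20:
        raise ValueError("n_taxa too small to honour disjoint site blocks")

    # carve the oral block into shared / saliva-only / oropharynx-only
    n_site = int(round(n_oral / (2.0 - overlap)))
    n_shared = int(round(overlap * n_site))
    n_unique = n_site - n_shared
    used = n_shared + 2 * n_unique
    taxa = np.arange(n_taxa)
    shared = taxa[:n_shared]
    sal_only = taxa[n_shared : n_shared + n_unique]
    oro_only = taxa[n_shared + n_unique : used]
    nasal_block = taxa[n_oral:]

    base = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=n_taxa)

    saliva = np.zeros(n_taxa)
    saliva[shared] = base[shared]
    saliva[sal_only] = base[sal_only]
    saliva /= saliva.sum()

    oroph = np.zeros(n_taxa)
    oroph[shared] = base[shared]
    oroph[oro_only] = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=len(oro_only))
    oroph /= oroph.sum()

    nasal = np.zeros(n_taxa)
    nasal[nasal_block] = _lognormal_profile(rng, n_nasal, lognormal_sigma) * (1 - nasal_leak)
    if nasal_leak > 0:
        leak = np.zeros(n_taxa)
        leak[:used] = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=used)
        nasal += nasal_leak * leak / leak.sum()
    nasal /= nasal.sum()

    taxon_ids = [f"t{i:04d}" for i in range(n_taxa)]
    profiles = {"saliva": saliva, "oropharynx": oroph, "nasal": nasal}

    subjects = [f"subj{i:03d}" for i in range(n_subjects)]
    rows, ids, site_of = [], [], {}
    for subj in subjects:
        for site in SOURCE_SITES:
            reads = rng.multinomial(source_depth, profiles[site])
            sample = f"{subj}_{site}"
            rows.append(reads)
            ids.append(sample)
            site_of[sample] = site
    counts = pd.DataFrame(np.array(rows), index=ids, columns=taxon_ids)
    table = CountTable(counts, site_of=site_of)
    truth = CohortTruth(taxon_ids=taxon_ids, profiles=profiles, subjects=subjects)
    return table, truth


def assign_groups_and_weights(
    truth: CohortTruth,
    seed: int = 0,
    *,
    hi_fraction: float = DEFAULTS["hi_fraction"],
    beta_hi: tuple[float, float] = DEFAULTS["beta_hi"],
    beta_lo: tuple[float, float] = DEFAULTS["beta_lo"],
    m_hi: float = DEFAULTS["m_hi"],
    m_lo: float = DEFAULTS["m_lo"],
    oroph_share_of_rest: float = DEFAULTS["oroph_share_of_rest"],
    unknown_weight: float = DEFAULTS["unknown_weight"],
    n_unknown_taxa: int = DEFAULTS["n_unknown_taxa"],
    lognormal_sigma: float = DEFAULTS["lognormal_sigma"],
) -> CohortTruth:
    """Attach latent groups, mixing weights and migration rates to a truth.

    Saliva weight is Beta-distributed per group (bimodal across the cohort);
    the remaining mass is split between oropharynx and nasal at a fixed ratio
    (nasal-heavy, so LO lungs receive mostly nasal input).  An optional
    ``unknown`` environmental source with its own profile takes a fixed
    weight slice when enabled.
    """
    rng = derive_rng(seed, "assign_groups_and_weights")
    subjects = truth.subjects
    n_hi = int(round(hi_fraction * len(subjects)))
    groups = ["HI"] * n_hi + ["LO"] * (len(subjects) - n_hi)

    profiles = dict(truth.profiles)
    taxon_ids = list(truth.taxon_ids)
    if unknown_weight > 0:
        extra_ids = [f"unk{i:03d}" for i in range(n_unknown_taxa)]
        unk = _lognormal_profile(rng, n_unknown_taxa, lognormal_sigma)
        for site in profiles:
            profiles[site] = np.concatenate([profiles[site], np.zeros(n_unknown_taxa)])
        profiles["unknown"] = np.concatenate([np.zeros(len(taxon_ids)), unk])
        taxon_ids = taxon_ids + extra_ids

    rows = []
    for subj, g in zip(subjects, groups):
        a, b = beta_hi if g == "HI" else beta_lo
        w_sal = rng.beta(a, b) * (1 - unknown_weight)
        rest = (1 - unknown_weight) - w_sal
        row = {
            "saliva": w_sal,
            "oropharynx": rest * oroph_share_of_rest,
            "nasal": rest * (1 - oroph_share_of_rest),
            "unknown": unknown_weight,
        }
        rows.append(row)
    weights = pd.DataFrame(rows, index=subjects)

    return CohortTruth(
        taxon_ids=taxon_ids,
        profiles=profiles,
        subjects=subjects,
        group=dict(zip(subjects, groups)),
        weights=weights,
        m_group={"HI": m_hi, "LO": m_lo},
        n_t=truth.n_t,
        depth=truth.depth,
    )


def simulate_lung_cohort(truth: CohortTruth, seed: int = 0) -> CountTable:
    """Draw one neutral BAL community per subject from the completed truth.

    Per subject: pool ``q`` is the weighted source mixture; composition is
    ``Dirichlet(N_T * m_g * q)`` restricted to the support of ``q``; reads
    are a multinomial draw of ``truth.depth`` from that composition.
    """
    if truth.weights is None or not truth.m_group:
        raise ValueError("truth is incomplete: run assign_groups_and_weights first")
    rng = derive_rng(seed, "simulate_lung_cohort")
    rows, ids, site_of = [], [], {}
    for subj in truth.subjects:
        q = truth.mixed_pool(subj)
        m = truth.m_group[truth.group[subj]]
        alpha = truth.n_t * m * q
        comp = np.zeros_like(q)
        support = alpha > 0
        comp[support] = rng.dirichlet(alpha[support])
        reads = rng.multinomial(truth.depth, comp)
        sample = f"{subj}_BAL"
        rows.append(reads)
        ids.append(sample)
        site_of[sample] = "BAL"
    counts = pd.DataFrame(np.array(rows), index=ids, columns=truth.taxon_ids)
    return CountTable(counts, site_of=site_of, drop_empty=True)


def simulate_cohort(
    seed: int = 0, **overrides,
) -> tuple[CountTable, CountTable, SampleMetadata, CohortTruth]:
    """End-to-end cohort: sources, lungs, metadata, truth.

    Keyword overrides replace entries of :data:`DEFAULTS`.
    """
    p: dict = {**DEFAULTS, **overrides}
    sources, truth = simulate_sources(
        n_taxa=p["n_taxa"],
        n_subjects=p["n_subjects"],
        overlap=p["overlap"],
        seed=seed,
        nasal_fraction=p["nasal_fraction"],
        source_depth=p["source_depth"],
        lognormal_sigma=p["lognormal_sigma"],
    )
    truth.n_t = p["n_t"]
    truth.depth = p["depth"]
    truth = assign_groups_and_weights(
        truth,
        seed=seed,
        hi_fraction=p["hi_fraction"],
        beta_hi=p["beta_hi"],
        beta_lo=p["beta_lo"],
        m_hi=p["m_hi"],
        m_lo=p["m_lo"],
        oroph_share_of_rest=p["oroph_share_of_rest"],
        unknown_weight=p["unknown_weight"],
        n_unknown_taxa=p["n_unknown_taxa"],
        lognormal_sigma=p["lognormal_sigma"],
    )
    if truth.taxon_ids != list(sources.taxon_ids):
        sources = CountTable(
            sources.counts.reindex(columns=truth.taxon_ids, fill_value=0),
            sources.site_of,
        )
    lungs = simulate_lung_cohort(truth, seed=seed)

    rows = []
    for sample, site in {**sources.site_of, **lungs.site_of}.items():
        subj = sample.rsplit("_", 1)[0]
        rows.append(
            {
                "sample_id": sample,
                "subject_id": subj,
                "site": site if site != "BAL" else "BAL",
                "group": truth.group.get(subj),
            }
        )
    meta = SampleMetadata(pd.DataFrame(rows))
    return sources, lungs, meta, truth
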