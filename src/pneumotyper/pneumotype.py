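"""Pneumo-type calling from the oral-input (ST) score distribution.

Across a cohort the saliva-to-lung contribution score is bimodal: one mode of
subjects whose lungs receive heavy oral input and one with little.  The
trough of a kernel density estimate between the two modes is used as the
cutoff: subjects at or above it are HOIT (high oral input type), below it
LOIT (low oral input type).  An independent Dirichlet-multinomial-mixture
typing of the lung communities provides a cross-check, quantified by a 2x2
contingency table and Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

HOIT, LOIT = "HOIT", "LOIT"


class UnimodalError(ValueError):
    """Raised when the score distribution has fewer than two clear modes."""


@dataclass
class PneumotypeResult:
    grid: np.ndarray
    density: np.ndarray
    modes: np.ndarray
    cutoff: float
    labels: pd.Series  # subject -> HOIT/LOIT
    dmm_assignments: pd.Series | None = None
    contingency: pd.DataFrame | None = None
    fisher_p: float | None = None


def density_trough(
    st_values,
    *,
    bandwidth: str | float = "silverman",
    grid_size: int = 512,
    mode_floor: float = 0.05,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Locate the cutoff between the two highest modes of the ST density.

    Gaussian KDE (Silverman bandwidth by default) on a uniform grid over
    [0, 1]; local maxima below ``mode_floor`` of the global maximum are
    ignored as ripple.  Returns ``(cutoff, modes, grid, density)``.

    Raises :class:`UnimodalError` when fewer than two qualifying modes
    exist; the caller may then force a manual cutoff.
    """
    x = np.asarray(st_values, dtype=float)
    if x.size < 20:
        raise ValueError(f"need at least 20 values, got {x.size}")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("ST values must lie in [0, 1]")
    if np.ptp(x) == 0:
        raise UnimodalError("all values identical; no trough exists")
    grid = np.linspace(0.0, 1.0, grid_size)
    kde = stats.gaussian_kde(x, bw_method=bandwidth)
    dens = kde(grid)

    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
    idx = np.flatnonzero(interior) + 1
    # grid endpoints can also be modes
    if dens[0] > dens[1]:
        idx = np.concatenate([[0], idx])
    if dens[-1] > dens[-2]:
        idx = np.concatenate([idx, [grid_size - 1]])
    # collapse flat plateaus to one representative
    if idx.size > 1:
        keep = np.concatenate([[True], np.diff(idx) > 1])
        idx = idx[keep]
    idx = idx[dens[idx] >= mode_floor * dens.max()]
    if idx.size < 2:
        raise UnimodalError(
            f"found {idx.size} qualifying mode(s); distribution looks unimodal"
        )
    top_two = idx[np.argsort(dens[idx])[-2:]]
    lo, hi = int(top_two.min()), int(top_two.max())
    trough_rel = int(np.argmin(dens[lo + 1 : hi]))
    cutoff = float(grid[lo + 1 + trough_rel])
    modes = grid[np.sort(idx)]
    return cutoff, modes, grid, dens


def assign_pneumotypes(st_values: pd.Series, cutoff: float) -> pd.Series:
    """HOIT iff ST >= cutoff (boundary values are HOIT), else LOIT."""
    if not 0 < cutoff < 1:
        if cutoff == 0:
            return pd.Series(HOIT, index=st_values.index)
        raise ValueError("cutoff must lie in (0, 1)")
    return pd.Series(
        np.where(st_values.to_numpy(dtype=float) >= cutoff, HOIT, LOIT),
        index=st_values.index,
    )


def concordance(labels_a: pd.Series, labels_b: pd.Series) -> tuple[pd.DataFrame, float]:
    """2x2 contingency table and two-sided Fisher exact p for two typings."""
    common = labels_a.index.intersection(labels_b.index)
    if len(common) != len(labels_a) or len(common) != len(labels_b):
        raise ValueError("label series must cover the same subjects")
    a, b = labels_a[common], labels_b[common]
    if a.nunique() > 2 or b.nunique() > 2:
        raise ValueError("concordance requires binary partitions")
    table = pd.crosstab(a, b)
    # pad to 2x2 if one category is empty
    while table.shape[0] < 2:
        table.loc[f"_empty{table.shape[0]}"] = 0
    while table.shape[1] < 2:
        table[f"_empty{table.shape[1]}"] = 0
    _, p = stats.fisher_exact(table.to_numpy()[:2, :2], alternative="two-sided")
    return table, float(p)


def call_pneumotypes(
    st_values: pd.Series,
    *,
    manual_cutoff: float | None = None,
    dmm_assignments: pd.Series | None = None,
    **kde_params,
) -> PneumotypeResult:
    """Full typing: trough cutoff, labels, optional DMM concordance."""
    if manual_cutoff is None:
        cutoff, modes, grid, dens = density_trough(st_values, **kde_params)
    else:
        cutoff, modes = float(manual_cutoff), np.array([])
        grid = np.linspace(0, 1, 512)
        dens = np.full_like(grid, np.nan)
    labels = assign_pneumotypes(st_values, cutoff)
    result = PneumotypeResult(
        grid=grid, density=dens, modes=modes, cutoff=cutoff, labels=labels
    )
    if dmm_assignments is not None:
        # map the DMM component richer in HOIT subjects onto the HOIT label
        named = dmm_assignments.astype(str)
        result.dmm_assignments = named
        result.contingency, result.fisher_p = concordance(labels, named)
    return result
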