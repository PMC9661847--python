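"""Core in-memory containers shared by every analysis stage.

A cohort is exchanged as a :class:`CountTable` (samples x taxa integer read
counts) plus a :class:`SampleMetadata` table mapping samples to subjects and
body sites.  Relative abundances are always derived views, never stored, so a
table cannot be normalised twice by accident.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

KNOWN_SITES = ("saliva", "oropharynx", "nasal", "BAL")


class CountTableError(ValueError):
    """Raised when a count table violates its contract."""


class MetadataError(ValueError):
    """Raised when a sample metadata table violates its contract."""


class CountTable:
    """Samples x taxa non-negative integer read counts.

    Parameters
    ----------
    counts:
        DataFrame with sample identifiers as the index and taxon identifiers
        as columns.  Cells must be non-negative integers (integral floats are
        accepted and cast).
    site_of:
        Optional map ``sample_id -> body site``; required only by site-aware
        operations.
    drop_empty:
        If True, silently drop samples whose row total is zero instead of
        raising.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        site_of: Mapping[str, str] | None = None,
        *,
        drop_empty: bool = False,
    ) -> None:
        counts = pd.DataFrame(counts).copy()
        counts.index = counts.index.astype(str)
        counts.columns = counts.columns.astype(str)
        if counts.index.duplicated().any():
            dupes = counts.index[counts.index.duplicated()].tolist()
            raise CountTableError(f"duplicate sample identifiers: {dupes}")
        if counts.columns.duplicated().any():
            dupes = counts.columns[counts.columns.duplicated()].tolist()
            raise CountTableError(f"duplicate taxon identifiers: {dupes}")

        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = np.argwhere(~np.vectorize(np.isreal)(values))
            raise CountTableError(f"non-numeric cell at {self._coord(counts, bad)}")
        if np.isnan(values.astype(float)).any():
            bad = np.argwhere(np.isnan(values.astype(float)))
            raise CountTableError(f"missing value at {self._coord(counts, bad)}")
        if (values < 0).any():
            bad = np.argwhere(values < 0)
            raise CountTableError(f"negative count at {self._coord(counts, bad)}")
        if not np.allclose(values, np.round(values)):
            bad = np.argwhere(~np.isclose(values.astype(float), np.round(values.astype(float))))
            raise CountTableError(f"non-integer count at {self._coord(counts, bad)}")

        counts = counts.astype(np.int64)
        totals = counts.sum(axis=1)
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            if drop_empty:
                counts = counts.loc[totals > 0]
            else:
                raise CountTableError(f"samples with zero total reads: {empty}")
        self.counts = counts
        self.site_of = dict(site_of) if site_of is not None else {}

    @staticmethod
    def _coord(counts: pd.DataFrame, bad: np.ndarray) -> str:
        i, j = bad[0]
        return f"row '{counts.index[i]}', column '{counts.columns[j]}'"

    # ------------------------------------------------------------------ views
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> pd.Series:
        """Total reads per sample."""
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalised proportions; every row sums to 1."""
        totals = self.counts.sum(axis=1).to_numpy()[:, None]
        return self.counts / totals

    def sites(self) -> pd.Series:
        """Site label per sample; raises if any sample is unlabelled."""
        missing = [s for s in self.sample_ids if s not in self.site_of]
        if missing:
            raise CountTableError(f"samples without a site label: {missing[:5]}")
        return pd.Series({s: self.site_of[s] for s in self.sample_ids})

    # -------------------------------------------------------------- subsetting
    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        sub = self.counts.loc[list(sample_ids)]
        site_of = {s: self.site_of[s] for s in sample_ids if s in self.site_of}
        return CountTable(sub, site_of, drop_empty=True)

    def select_taxa(self, taxon_ids: Sequence[str]) -> "CountTable":
        sub = self.counts[list(taxon_ids)]
        return CountTable(sub, self.site_of, drop_empty=True)

    def merge_taxa(self, other: "CountTable") -> tuple["CountTable", "CountTable"]:
        """Align two tables on the union of their taxon sets (zero-filled)."""
        universe = sorted(set(self.taxon_ids) | set(other.taxon_ids))
        a = self.counts.reindex(columns=universe, fill_value=0)
        b = other.counts.reindex(columns=universe, fill_value=0)
        return (
            CountTable(a, self.site_of, drop_empty=True),
            CountTable(b, other.site_of, drop_empty=True),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.site_of == other.site_of

    def __repr__(self) -> str:
        return f"CountTable({self.n_samples} samples x {self.n_taxa} taxa)"


class SampleMetadata:
    """Sample annotations: subject, body site, optional group label."""

    REQUIRED = ("sample_id", "subject_id", "site")

    def __init__(self, table: pd.DataFrame, *, allow_replicates: bool = False) -> None:
        table = pd.DataFrame(table).copy()
        for col in self.REQUIRED:
            if col not in table.columns:
                raise MetadataError(f"metadata is missing required column '{col}'")
        if "group" not in table.columns:
            table["group"] = pd.NA
        table["sample_id"] = table["sample_id"].astype(str)
        table["subject_id"] = table["subject_id"].astype(str)
        if table["sample_id"].duplicated().any():
            raise MetadataError("duplicate sample_id in metadata")
        unknown = set(table["site"]) - set(KNOWN_SITES)
        if unknown:
            raise MetadataError(
                f"unknown body site labels {sorted(unknown)}; expected one of {KNOWN_SITES}"
            )
        if not allow_replicates:
            pairs = table[["subject_id", "site"]]
            if pairs.duplicated().any():
                dup = pairs[pairs.duplicated()].iloc[0]
                raise MetadataError(
                    f"subject '{dup.subject_id}' has more than one '{dup.site}' sample"
                )
        self.table = table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def site_of(self) -> dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table["site"]))

    def samples_at(self, site: str) -> list[str]:
        return list(self.table.loc[self.table["site"] == site, "sample_id"])

    def subject_of(self) -> dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table["subject_id"]))

    def paired_samples(self, site_a: str, site_b: str) -> list[tuple[str, str, str]]:
        """(subject, sample_at_a, sample_at_b) for subjects sampled at both sites."""
        t = self.table
        a = t[t["site"] == site_a].set_index("subject_id")["sample_id"]
        b = t[t["site"] == site_b].set_index("subject_id")["sample_id"]
        subjects = sorted(set(a.index) & set(b.index))
        return [(s, a[s], b[s]) for s in subjects]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleMetadata):
            return NotImplemented
        left = self.table.fillna("").astype(str)
        right = other.table.fillna("").astype(str)
        return left.equals(right)

    def __repr__(self) -> str:
        sites = self.table["site"].value_counts().to_dict()
        return f"SampleMetadata({len(self.table)} samples, sites={sites})"


def align_taxa(tables: Iterable[CountTable]) -> list[CountTable]:
    """Reindex several tables onto the sorted union of their taxa."""
    tables = list(tables)
    universe = sorted(set().union(*(t.taxon_ids for t in tables)))
    return [
        CountTable(t.counts.reindex(columns=universe, fill_value=0), t.site_of, drop_empty=True)
        for t in tables
    ]
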