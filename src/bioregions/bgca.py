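"""Correspondence analysis and between-group CA of class composition.

The sites × biogeographic-class count table (entry = number of species of a
class recorded at a site) is analysed by classic correspondence analysis:
SVD of the standardized Pearson residuals of the relative-frequency table,
so that total inertia equals the chi-square statistic divided by the grand
total.  The between-group variant aggregates sites into their module's
mass-weighted centroid profile (equivalently, the module-summed count table)
and runs CA on the centroids; individual sites are then projected into the
group space as supplementary rows.  Because column margins are preserved by
the aggregation, the centroid-table inertia is exactly the between-group
share of the full-table inertia.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .incidence import BIOGEOGRAPHIC_CLASSES, IncidenceMatrix, SpeciesClassTable
from .modularity import Partition

logger = logging.getLogger(__name__)

__all__ = ["CAResult", "BGCAResult", "class_counts",
           "correspondence_analysis", "between_group_ca"]


@dataclass
class CAResult:
    """Correspondence analysis decomposition of a count table."""

    eigenvalues: np.ndarray
    total_inertia: float
    row_coords: pd.DataFrame       # principal coordinates
    col_coords: pd.DataFrame       # principal coordinates
    row_contrib: pd.DataFrame      # per-axis contribution fractions
    col_contrib: pd.DataFrame
    col_standard: pd.DataFrame     # standard coordinates (for projections)
    row_masses: pd.Series
    col_masses: pd.Series

    @property
    def pct_inertia(self) -> np.ndarray:
        if self.total_inertia == 0:
            return np.zeros_like(self.eigenvalues)
        return 100.0 * self.eigenvalues / self.total_inertia


@dataclass
class BGCAResult:
    """Between-group CA: group-centroid ordination with site projections."""

    ca: CAResult
    group_scores: pd.DataFrame
    site_scores: pd.DataFrame
    class_scores: pd.DataFrame
    class_contrib: pd.DataFrame
    between_inertia: float
    total_inertia: float
    eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def between_total_ratio(self) -> float:
        if self.total_inertia == 0:
            return 0.0
        return self.between_inertia / self.total_inertia

    @property
    def pct_inertia(self) -> np.ndarray:
        return self.ca.pct_inertia


def class_counts(
    inc: IncidenceMatrix, classes: SpeciesClassTable
) -> pd.DataFrame:
    """Sites × class table counting classified species present at each site.

    Species with no class entry are excluded (count logged); sites left with
    zero classified species are dropped with a warning.
    """
    uncovered = classes.coverage_report(inc)
    if uncovered:
        logger.info("excluding %d species without class entry", len(uncovered))
    covered = [s for s in inc.species_ids if s not in set(uncovered)]
    if not covered:
        raise ValueError("no species in the incidence matrix has a class entry")
    cols = {cls: np.zeros(inc.n_sites, dtype=int) for cls in BIOGEOGRAPHIC_CLASSES}
    frame = inc.to_frame()
    for sp in covered:
        cols[classes[sp]] += frame[sp].to_numpy()
    out = pd.DataFrame(cols, index=inc.site_ids)
    empty = out.sum(axis=1) == 0
    if empty.any():
        warnings.warn(
            f"dropping site(s) with no classified species: "
            f"{out.index[empty].tolist()}", stacklevel=2,
        )
        out = out.loc[~empty]
    return out


def correspondence_analysis(table: pd.DataFrame) -> CAResult:
    """Classic CA via SVD of standardized Pearson residuals.

    Total inertia equals the Pearson chi-square statistic of the table
    divided by its grand total; a table of exactly independent counts has
    zero inertia and all-zero scores.  Zero-sum rows or columns are removed
    before decomposition.
    """
    t = table.to_numpy(dtype=float)
    if t.min() < 0:
        raise ValueError("count table must be non-negative")
    if t.sum() <= 0:
        raise ValueError("count table has zero grand total")
    keep_rows = t.sum(axis=1) > 0
    keep_cols = t.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        table = table.loc[keep_rows, keep_cols]
        t = table.to_numpy(dtype=float)
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least 2 non-empty rows and columns")

    n = t.sum()
    p = t / n
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    expected = np.outer(r, c)
    s = (p - expected) / np.sqrt(expected)
    u, sv, vt = np.linalg.svd(s, full_matrices=False)

    tol = max(t.shape) * np.finfo(float).eps * (sv[0] if sv.size else 0.0)
    n_axes = min(t.shape[0] - 1, t.shape[1] - 1)
    sv = sv[:n_axes]
    u = u[:, :n_axes]
    vt = vt[:n_axes]
    sv = np.where(sv > tol, sv, 0.0)
    eig = sv**2

    with np.errstate(divide="ignore", invalid="ignore"):
        row_std = (u / np.sqrt(r)[:, None])
        col_std = (vt.T / np.sqrt(c)[:, None])
    row_pc = row_std * sv
    col_pc = col_std * sv
    # contribution of each point to each axis's inertia
    row_ctr = np.where(eig > 0, r[:, None] * row_pc**2 / np.where(eig > 0, eig, 1), 0.0)
    col_ctr = np.where(eig > 0, c[:, None] * col_pc**2 / np.where(eig > 0, eig, 1), 0.0)

    axes = [f"CA{i + 1}" for i in range(n_axes)]
    return CAResult(
        eigenvalues=eig,
        total_inertia=float(eig.sum()),
        row_coords=pd.DataFrame(row_pc, index=table.index, columns=axes),
        col_coords=pd.DataFrame(col_pc, index=table.columns, columns=axes),
        row_contrib=pd.DataFrame(row_ctr, index=table.index, columns=axes),
        col_contrib=pd.DataFrame(col_ctr, index=table.columns, columns=axes),
        col_standard=pd.DataFrame(col_std, index=table.columns, columns=axes),
        row_masses=pd.Series(r, index=table.index, name="mass"),
        col_masses=pd.Series(c, index=table.columns, name="mass"),
    )


def between_group_ca(
    table: pd.DataFrame, groups: Partition | dict
) -> BGCAResult:
    """CA of the mass-weighted group centroids, with supplementary sites.

    ``groups`` maps every row (site) of ``table`` to a module label.  Rows
    of a group are summed — the count-table equivalent of averaging row
    profiles with row-total weights — and the summed table is analysed by
    CA.  The centroid-table inertia over the full-table inertia is the
    between-group share.  Site rows are projected into the group space via
    the column standard coordinates, so that the mass-weighted mean of a
    group's site scores equals the group's own score exactly.
    """
    mapping = groups.mapping if isinstance(groups, Partition) else dict(groups)
    missing = [s for s in table.index if s not in mapping]
    if missing:
        raise ValueError(f"group map does not cover site(s): {missing}")
    labels = pd.Series([mapping[s] for s in table.index], index=table.index)
    if labels.nunique() < 2:
        raise ValueError("between-group CA needs at least 2 groups")

    grouped = table.groupby(labels).sum()
    grouped = grouped.loc[sorted(grouped.index)]

    full_ca = correspondence_analysis(table)
    ca = correspondence_analysis(grouped)

    # supplementary projection of sites (restricted to columns kept by CA)
    cols = ca.col_standard.index
    sub = table.loc[:, cols].to_numpy(dtype=float)
    row_tot = sub.sum(axis=1)
    keep = row_tot > 0
    profiles = sub[keep] / row_tot[keep, None]
    site_scores = pd.DataFrame(
        profiles @ ca.col_standard.to_numpy(),
        index=table.index[keep],
        columns=ca.col_standard.columns,
    )
    return BGCAResult(
        ca=ca,
        group_scores=ca.row_coords,
        site_scores=site_scores,
        class_scores=ca.col_coords,
        class_contrib=ca.col_contrib,
        between_inertia=ca.total_inertia,
        total_inertia=full_ca.total_inertia,
        eigenvalues=ca.eigenvalues,
    )
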