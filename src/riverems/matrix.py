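"""Site-by-taxon matrices and site tables.

The canonical containers are plain pandas DataFrames:

* an **abundance matrix** has one row per site (index = site ids), one
  column per taxon (columns = taxon ids), and non-negative integer counts;
* an **incidence matrix** is the same shape with 0/1 entries;
* a **site table** has one row per site with at least a ``catch_size``
  column (catchment area, km²) and usually planar coordinates ``x``/``y``
  (metres), elevation, land-use percentages and chemistry summaries.

CSV conventions: comma-separated, UTF-8, header row = taxon ids, first
column = site id.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: River-section labels, in upstream-to-downstream order.
SECTION_LABELS = ("headwaters", "mid-sized", "large")


class MatrixValidationError(ValueError):
    """Raised when a community matrix violates its contract."""


def validate_abundance(m: pd.DataFrame) -> pd.DataFrame:
    """Validate an abundance matrix: unique ids, integer cells, counts >= 0.

    Returns the matrix with an integer dtype. Raises
    :class:`MatrixValidationError` naming the offending cell otherwise.
    """
    if m.index.has_duplicates:
        dupes = m.index[m.index.duplicated()].unique().tolist()
        raise MatrixValidationError(f"duplicate site ids: {dupes}")
    if m.columns.has_duplicates:
        dupes = m.columns[m.columns.duplicated()].unique().tolist()
        raise MatrixValidationError(f"duplicate taxon ids: {dupes}")
    values = m.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        bad = _first_offending_cell(m, lambda v: not np.isreal(v))
        raise MatrixValidationError(f"non-numeric count at {bad}")
    if values.size:
        frac = np.mod(values.astype(float), 1.0)
        if np.any(frac != 0):
            i, j = np.argwhere(frac != 0)[0]
            raise MatrixValidationError(
                f"non-integer count at site {m.index[i]!r}, taxon {m.columns[j]!r}"
            )
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise MatrixValidationError(
                f"negative count at site {m.index[i]!r}, taxon {m.columns[j]!r}"
            )
    return m.astype(np.int64)


def _first_offending_cell(m: pd.DataFrame, pred) -> str:
    for i, site in enumerate(m.index):
        for j, taxon in enumerate(m.columns):
            if pred(m.iat[i, j]):
                return f"site {site!r}, taxon {taxon!r}"
    return "unknown cell"


def validate_incidence(m: pd.DataFrame) -> pd.DataFrame:
    """Validate a presence/absence matrix (entries in {0, 1})."""
    m = validate_abundance(m)
    values = m.to_numpy()
    if values.size and np.any(values > 1):
        i, j = np.argwhere(values > 1)[0]
        raise MatrixValidationError(
            f"incidence entry > 1 at site {m.index[i]!r}, taxon {m.columns[j]!r}"
        )
    return m


def load_abundance(path) -> pd.DataFrame:
    """Read and validate a site-by-taxon abundance CSV.

    First column holds site ids, the header holds taxon ids.
    """
    m = pd.read_csv(path, index_col=0)
    m.index = m.index.astype(str)
    m.columns = m.columns.astype(str)
    return validate_abundance(m)


def save_abundance(m: pd.DataFrame, path) -> None:
    """Write a site-by-taxon matrix using the package CSV conventions."""
    m.to_csv(path, index_label="site_id")


def load_site_table(path, require_coords: bool = False) -> pd.DataFrame:
    """Read a site table CSV (index = site id); checks the catch_size column."""
    t = pd.read_csv(path, index_col=0)
    t.index = t.index.astype(str)
    if "catch_size" not in t.columns:
        raise MatrixValidationError("site table lacks a 'catch_size' column")
    if (t["catch_size"] <= 0).any():
        bad = t.index[t["catch_size"] <= 0].tolist()
        raise MatrixValidationError(f"non-positive catchment size for sites {bad}")
    if require_coords and not {"x", "y"} <= set(t.columns):
        raise MatrixValidationError("site table lacks 'x'/'y' coordinate columns")
    return t


def to_incidence(m: pd.DataFrame) -> pd.DataFrame:
    """Convert counts to presence/absence (1 wherever count > 0)."""
    return (validate_abundance(m) > 0).astype(np.int64)


def filter_rare_taxa(m: pd.DataFrame, min_sites: int = 2) -> pd.DataFrame:
    """Drop taxa occurring at fewer than ``min_sites`` sites.

    Taxa found at a single site carry no co-occurrence information and bias
    the coherence and boundary-clumping tests, so the default removes
    everything below two sites. The site set is left unchanged; use
    :func:`drop_empty_sites` before ordination.
    """
    inc = validate_incidence((m > 0).astype(np.int64))
    keep = inc.sum(axis=0) >= min_sites
    if not keep.any():
        raise MatrixValidationError(
            f"no taxon occurs at >= {min_sites} sites; nothing left to analyse"
        )
    dropped = inc.columns[~keep].tolist()
    if dropped:
        logger.info("filter_rare_taxa: dropped %d taxa: %s", len(dropped), dropped)
    return m.loc[:, keep.to_numpy()]


def drop_empty_sites(m: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Remove all-zero site rows (ordination is undefined for them).

    Returns ``(matrix, dropped_site_ids)``; raises if every site is empty.
    """
    row_sums = (m > 0).sum(axis=1)
    keep = row_sums > 0
    if not keep.any():
        raise MatrixValidationError("all sites are empty")
    dropped = m.index[~keep].tolist()
    if dropped:
        logger.info("drop_empty_sites: dropped %d sites: %s", len(dropped), dropped)
    return m.loc[keep.to_numpy()], dropped


def categorize_sites(
    site_table: pd.DataFrame, breaks: tuple[float, float] = (20.0, 100.0)
) -> pd.Series:
    """Assign each site to a river section from its catchment size.

    Sections partition the catchment-size axis with half-open intervals:
    headwaters ``[0, breaks[0])``, mid-sized ``[breaks[0], breaks[1])`` and
    large ``[breaks[1], inf)`` km².
    """
    sizes = site_table["catch_size"]
    if sizes.isna().any():
        bad = site_table.index[sizes.isna()].tolist()
        raise MatrixValidationError(f"missing catchment size for sites {bad}")
    lo, hi = breaks
    labels = pd.cut(
        sizes,
        bins=[-np.inf, lo, hi, np.inf],
        right=False,
        labels=SECTION_LABELS,
    )
    return pd.Series(labels.astype(str), index=site_table.index, name="section")
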