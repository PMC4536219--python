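"""Fixed-incidence proportional ("r1") null model for incidence matrices.

Each simulated matrix keeps every site's observed richness exactly (row
sums fixed) and draws that many taxa without replacement with selection
weight proportional to each taxon's observed incidence (column totals
proportional in expectation). This is the classic conservative null for
coherence/turnover/clumping testing: it scrambles co-occurrence while
respecting both how rich sites are and how widespread taxa are.

Sampling uses the exponential-race formulation of weighted sampling
without replacement: draw ``E_j ~ Exponential(w_j)`` per taxon and keep
the ``k`` smallest keys. Per-matrix RNG streams are spawned from one root
seed, so ensembles are reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class NullEnsemble:
    """A stack of r1 null matrices sharing the source matrix's dimensions."""

    matrices: np.ndarray  # (n_sim, n_sites, n_taxa) uint8
    method: str
    seed: int
    site_ids: np.ndarray | None = None
    taxon_ids: np.ndarray | None = None
    row_sums: np.ndarray = field(default=None)

    def __len__(self) -> int:
        return self.matrices.shape[0]

    def __iter__(self):
        return iter(self.matrices)


def generate_r1(m, n_sim: int = 1000, seed: int = 0) -> NullEnsemble:
    """Generate ``n_sim`` r1 null matrices for incidence matrix ``m``.

    Parameters
    ----------
    m : DataFrame or array of shape (n_sites, n_taxa)
        Binary incidence matrix; no site may be richer than the number of
        taxa with non-zero incidence.
    n_sim : int, default 1000
        Ensemble size; at least 2 (a null SD is undefined otherwise).
    seed : int
        Root seed; fully determines the ensemble.
    """
    if n_sim < 2:
        raise ValueError("n_sim must be >= 2: the null SD is undefined otherwise")
    site_ids = taxon_ids = None
    if isinstance(m, pd.DataFrame):
        site_ids = m.index.to_numpy()
        taxon_ids = m.columns.to_numpy()
        m = m.to_numpy()
    A = np.asarray(m)
    if A.size == 0 or not np.isin(A, (0, 1)).all():
        raise ValueError("input must be a non-empty binary matrix")
    n_sites, n_taxa = A.shape
    richness = A.sum(axis=1)
    weights = A.sum(axis=0).astype(float)
    if richness.max() > int((weights > 0).sum()):
        raise ValueError("a site is richer than the number of non-absent taxa")

    root = np.random.SeedSequence(seed)
    streams = root.spawn(n_sim)
    out = np.zeros((n_sim, n_sites, n_taxa), dtype=np.uint8)
    with np.errstate(divide="ignore"):
        inv_w = np.where(weights > 0, 1.0 / weights, np.inf)
    for s in range(n_sim):
        rng = np.random.default_rng(streams[s])
        keys = rng.standard_exponential((n_sites, n_taxa)) * inv_w
        ranks = np.argsort(np.argsort(keys, axis=1, kind="stable"), axis=1)
        out[s] = ranks < richness[:, None]
    return NullEnsemble(
        matrices=out,
        method="r1",
        seed=seed,
        site_ids=site_ids,
        taxon_ids=taxon_ids,
        row_sums=richness,
    )
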