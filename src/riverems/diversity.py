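"""Alpha diversity, Bray–Curtis beta dispersion, and section-wise inference.

Alpha metrics are per-site: taxonomic richness, Hurlbert rarefied
richness (expected taxa in a standard subsample of 100 individuals) and
Simpson's diversity 1 − Σp². Beta diversity is measured as multivariate
dispersion: each site's distance to its river-section centroid in the
principal-coordinate space of the Bray–Curtis dissimilarity matrix, with
the negative-eigenvalue ("imaginary") axes subtracted, exactly as the
homogeneity-of-dispersions procedure defines it. Between-section
differences are tested with one-way ANOVA and Tukey HSD.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from sklearn.base import BaseEstimator
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .ordination import full_pcoa

__all__ = [
    "richness",
    "rarefied_richness",
    "simpson",
    "bray_curtis",
    "BetaDispersion",
    "beta_dispersion",
    "anova_tukey",
    "diversity_summary",
]


def richness(abundance: pd.DataFrame) -> pd.Series:
    """Number of taxa with count > 0 at each site."""
    return (abundance > 0).sum(axis=1).rename("richness")


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_richness(counts, n: int = 100) -> float:
    """Hurlbert's expected richness in a random subsample of ``n`` individuals.

    ``E(S_n) = sum_i [1 - C(N - N_i, n) / C(N, n)]`` over taxa with
    ``N_i > 0``, where ``N`` is the site total. If the site holds fewer
    than ``n`` individuals the observed richness is returned and a
    warning is emitted (there is nothing to rarefy to).
    """
    if n <= 0:
        raise ValueError("subsample size must be positive")
    c = np.asarray(counts, dtype=np.int64)
    c = c[c > 0]
    N = int(c.sum())
    if N == 0:
        return 0.0
    if N < n:
        warnings.warn(
            f"site total {N} below rarefaction size {n}; returning observed richness"
        )
        return float(len(c))
    # C(N - N_i, n)/C(N, n), zero when N - N_i < n
    keep = (N - c) >= n
    ratio = np.zeros(len(c))
    ratio[keep] = np.exp(_log_comb(N - c[keep], n) - _log_comb(N, n))
    return float(np.sum(1.0 - ratio))


def simpson(counts) -> float:
    """Simpson's diversity 1 − Σ p_i² (probability two draws differ)."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        warnings.warn("empty site: Simpson's index undefined, returning NaN")
        return float("nan")
    p = c / total
    return float(1.0 - np.sum(p**2))


def bray_curtis(abundance: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarity Σ|u−v| / Σ(u+v) between sites."""
    A = abundance.to_numpy(dtype=float)
    if (A.sum(axis=1) == 0).sum() >= 2:
        raise ValueError("Bray-Curtis is undefined between two empty sites")
    d = squareform(pdist(A, metric="braycurtis"))
    return pd.DataFrame(d, index=abundance.index, columns=abundance.index)


class BetaDispersion(BaseEstimator):
    """Multivariate dispersion: distance to group centroid in PCoA space.

    ``fit(D, groups)`` decomposes the (possibly non-Euclidean)
    dissimilarity matrix by classical scaling, keeping positive- and
    negative-eigenvalue axes, places each group's centroid, and computes
    every site's distance to its own centroid as
    ``sqrt(max(d_real² − d_imag², 0))``. Group differences are tested
    with a one-way ANOVA F on the distances.

    Attributes
    ----------
    distances_ : pd.Series       per-site distance to own group centroid
    F_, p_value_ : float         one-way ANOVA across groups
    df_ : tuple                  (k − 1, N − k)
    """

    def fit(self, D, groups):
        ids = D.index if isinstance(D, pd.DataFrame) else pd.RangeIndex(len(D))
        groups = pd.Series(np.asarray(groups), index=ids, name="group")
        sizes = groups.value_counts()
        if len(sizes) < 2:
            raise ValueError("need at least two groups")
        if (sizes < 2).any():
            raise ValueError(f"groups of size 1: {sizes[sizes < 2].index.tolist()}")
        w, v = full_pcoa(np.asarray(D, dtype=float))
        tol = 1e-8 * max(1.0, abs(w).max())
        pos, neg = w > tol, w < -tol
        real = v[:, pos] * np.sqrt(w[pos])
        imag = v[:, neg] * np.sqrt(-w[neg])
        dist = np.empty(len(groups))
        for g in sizes.index:
            mask = (groups == g).to_numpy()
            d2 = ((real[mask] - real[mask].mean(axis=0)) ** 2).sum(axis=1)
            if imag.shape[1]:
                d2 = d2 - ((imag[mask] - imag[mask].mean(axis=0)) ** 2).sum(axis=1)
            dist[mask] = np.sqrt(np.clip(d2, 0.0, None))
        self.distances_ = pd.Series(dist, index=ids, name="dispersion")
        self.groups_ = groups
        samples = [dist[(groups == g).to_numpy()] for g in sizes.index]
        F, p = stats.f_oneway(*samples)
        self.F_ = float(F)
        self.p_value_ = float(p)
        self.df_ = (len(sizes) - 1, len(groups) - len(sizes))
        return self


def beta_dispersion(D, groups) -> BetaDispersion:
    """Convenience wrapper: fit :class:`BetaDispersion` on ``(D, groups)``."""
    return BetaDispersion().fit(D, groups)


def _compact_letters(levels, different: set[tuple]) -> dict:
    """Insert-and-absorb compact letter display.

    ``different`` holds unordered level pairs that are significantly
    different; levels sharing a letter are statistically indistinguishable.
    """
    letter_sets: list[set] = [set(levels)]
    for a, b in different:
        for s in list(letter_sets):
            if a in s and b in s:
                letter_sets.remove(s)
                sa, sb = s - {b}, s - {a}
                for cand in (sa, sb):
                    if not any(cand <= other for other in letter_sets):
                        letter_sets.append(cand)
    letter_sets.sort(key=lambda s: sorted(levels.index(x) for x in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lvl: "" for lvl in levels}
    for i, s in enumerate(letter_sets):
        for lvl in s:
            out[lvl] += alphabet[i]
    return out


def anova_tukey(values, groups, alpha: float = 0.05) -> dict:
    """One-way ANOVA across groups followed by Tukey HSD pairwise tests.

    Returns a dict with ``F``, ``df``, ``p``, a ``tukey`` DataFrame of
    pairwise comparisons, and ``letters`` (compact letter display: groups
    sharing a letter are not significantly different at ``alpha``).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least two values")
    if all(np.var(s) == 0 for s in samples):
        raise ValueError("zero within-group variance in every group")
    F, p = stats.f_oneway(*samples)
    hsd = pairwise_tukeyhsd(values, groups, alpha=alpha)
    tukey = pd.DataFrame(
        hsd.summary().data[1:], columns=[str(c) for c in hsd.summary().data[0]]
    )
    different = {
        (str(r["group1"]), str(r["group2"]))
        for _, r in tukey.iterrows()
        if bool(r["reject"])
    }
    letters = _compact_letters([str(l) for l in levels], different)
    return {
        "F": float(F),
        "df": (len(levels) - 1, len(values) - len(levels)),
        "p": float(p),
        "tukey": tukey,
        "letters": letters,
    }


def diversity_summary(
    abundance: pd.DataFrame, sections: pd.Series | None = None, rarefy_n: int = 100
) -> pd.DataFrame:
    """Per-site diversity table: richness, rarefied richness, Simpson."""
    rich = richness(abundance)
    out = pd.DataFrame(
        {
            "richness": rich,
            "rarefied_richness": [
                rarefied_richness(row, n=rarefy_n) for _, row in abundance.iterrows()
            ],
            "simpson": [simpson(row) for _, row in abundance.iterrows()],
        },
        index=abundance.index,
    )
    out["rarefaction_flag"] = abundance.sum(axis=1) < rarefy_n
    if sections is not None:
        out["section"] = sections.reindex(abundance.index)
    return out
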