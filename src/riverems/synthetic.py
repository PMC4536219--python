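"""Synthetic metacommunities with known idealised structure.

Sites sit on a latent gradient (positions 0 .. n_sites−1) and each taxon
occupies a contiguous range of it whose placement encodes the chosen
structure:

* ``clementsian`` — taxa come in groups sharing block boundaries, so
  communities turn over as compartments;
* ``gleasonian`` — range centres and widths are independent, so turnover
  is individualistic;
* ``nested`` — all ranges share one gradient end with ordered widths, so
  poor communities are subsets of rich ones;
* ``evenly_spaced`` — equal widths with equidistant boundaries
  (hyperdispersed range edges);
* ``checkerboard`` — mutually exclusive taxon pairs on complementary
  site subsets (no gradient structure at all);
* ``random`` — independent Bernoulli occurrences.

Each cell is then flipped with probability ``noise_eps`` (optionally
one-sided, presence→absence only, mimicking survey detection error).
Abundances conditional on presence are zero-truncated negative binomial,
and the environment table carries one driver variable that is an affine
function of the gradient plus noise, correlated nuisance variables,
coordinates, and catchment sizes spanning all three river sections.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "simulate_metacommunity",
    "simulate_environment",
    "simulate_abundance",
    "simulate_study",
]

STRUCTURES = (
    "clementsian",
    "gleasonian",
    "nested",
    "evenly_spaced",
    "checkerboard",
    "random",
)


@dataclass
class SyntheticConfig:
    """Recipe for one synthetic metacommunity and its covariates."""

    structure: str = "clementsian"
    n_sites: int = 40
    n_taxa: int = 50
    n_groups: int = 4  # clementsian compartments
    mean_range_width: int | None = None  # default: half the gradient
    noise_eps: float = 0.01  # per-cell flip probability
    one_sided_noise: bool = False  # flip presences only (detection error)
    prevalence: float = 0.3  # random structure occupancy
    abundance_mean: float = 20.0  # mean count where present
    abundance_dispersion: float = 1.0  # NB size parameter; smaller = noisier
    env_noise_sd: float = 0.5  # driver noise, gradient standardised to SD 1
    nuisance_corr: float = 0.3  # correlation of nuisance predictors w/ driver
    align_coords: bool = True  # x coordinate tracks the gradient
    seed: int = 0

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"structure must be one of {STRUCTURES}")
        if not 0 <= self.noise_eps < 0.5:
            raise ValueError("noise_eps must be in [0, 0.5)")
        if self.n_groups > self.n_taxa:
            raise ValueError("n_groups cannot exceed n_taxa")
        if self.structure == "checkerboard" and self.n_taxa % 2:
            raise ValueError("checkerboard needs an even number of taxa")

    def manifest(self) -> dict:
        return asdict(self)


def _ranges_to_matrix(starts, widths, n_sites, n_taxa):
    A = np.zeros((n_sites, n_taxa), dtype=np.int64)
    for j, (s, w) in enumerate(zip(starts, widths)):
        A[s : s + w, j] = 1
    return A


def simulate_metacommunity(cfg: SyntheticConfig):
    """Generate an incidence matrix with the configured structure.

    Returns ``(incidence DataFrame, gradient positions per site, group
    label per taxon)``. Group labels are the clementsian compartment
    index (zeros elsewhere).
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    S, T = cfg.n_sites, cfg.n_taxa
    # default range width S/4: wide enough to carry ordering signal, narrow
    # enough that the two range edges of a taxon stay independent draws
    width = cfg.mean_range_width or max(4, round(S / 4))
    width = min(width, S)
    groups = np.zeros(T, dtype=int)

    if cfg.structure == "clementsian":
        bounds = np.linspace(0, S, cfg.n_groups + 1).round().astype(int)
        groups = np.arange(T) % cfg.n_groups
        starts = bounds[groups]
        widths = bounds[groups + 1] - bounds[groups]
        A = _ranges_to_matrix(starts, widths, S, T)
    elif cfg.structure == "gleasonian":
        # independent ranges: width uniform on [w/2, 3w/2], start uniform on
        # the admissible interval, so range boundaries spread evenly along
        # the gradient (no shared structure between taxa)
        widths = rng.integers(
            max(2, width - width // 2), min(S, width + width // 2) + 1, size=T
        )
        starts = np.array([rng.integers(0, S - w + 1) for w in widths])
        A = _ranges_to_matrix(starts, widths, S, T)
    elif cfg.structure == "nested":
        widths = np.linspace(2, S, T).round().astype(int)
        A = _ranges_to_matrix(np.zeros(T, dtype=int), widths, S, T)
    elif cfg.structure == "evenly_spaced":
        w = min(width, S)
        starts = np.linspace(0, S - w, T).round().astype(int)
        A = _ranges_to_matrix(starts, np.full(T, w), S, T)
    elif cfg.structure == "checkerboard":
        # mutually exclusive species pairs: each pair claims a pool of
        # sites (spread evenly over the landscape) and splits it into two
        # complementary halves, one per member
        A = np.zeros((S, T), dtype=np.int64)
        load = np.zeros(S)
        k_lo, k_hi = max(2, S // 8), max(3, S // 4)
        for p in rng.permutation(T // 2):
            k = int(rng.integers(k_lo, k_hi + 1))
            pool = np.argsort(load + rng.uniform(0, 1e-6, S))[: 2 * k]
            pool = rng.permutation(pool)
            A[pool[:k], 2 * p] = 1
            A[pool[k:], 2 * p + 1] = 1
            load[pool] += 1
            groups[2 * p] = groups[2 * p + 1] = p
    else:  # random
        A = (rng.random((S, T)) < cfg.prevalence).astype(np.int64)

    if cfg.noise_eps > 0:
        flips = rng.random((S, T)) < cfg.noise_eps
        if cfg.one_sided_noise:
            flips &= A == 1
        A = np.where(flips, 1 - A, A)

    inc = pd.DataFrame(
        A,
        index=pd.Index([f"S{i:03d}" for i in range(S)], name="site_id"),
        columns=[f"T{j:03d}" for j in range(T)],
    )
    return inc, np.arange(S, dtype=float), groups


def simulate_environment(gradient: np.ndarray, cfg: SyntheticConfig) -> pd.DataFrame:
    """Environment table for sites on the latent gradient.

    The ``elevation`` column is the driver: an affine function of the
    gradient plus Gaussian noise of SD ``env_noise_sd`` (gradient
    standardised to unit SD). Nuisance predictors share correlation
    ``nuisance_corr`` with the driver; catchment sizes are log-uniform
    over 3–1000 km² so every river section is populated.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    S = len(gradient)
    g = (gradient - gradient.mean()) / max(gradient.std(), 1e-12)
    driver_latent = g + rng.normal(0, cfg.env_noise_sd, S)

    def correlated(rho, scale=1.0, loc=0.0):
        z = rng.normal(size=S)
        base = rho * driver_latent / max(driver_latent.std(), 1e-12)
        return loc + scale * (base + np.sqrt(max(1 - rho**2, 0.0)) * z)

    t = pd.DataFrame(index=pd.Index([f"S{i:03d}" for i in range(S)], name="site_id"))
    t["catch_size"] = np.exp(rng.uniform(np.log(3.0), np.log(1000.0), S))
    t["elevation"] = 200.0 + 60.0 * driver_latent
    t["agriculture"] = np.clip(correlated(cfg.nuisance_corr, 17.0, 53.0), 0, 100)
    t["forest"] = np.clip(correlated(-cfg.nuisance_corr, 17.0, 40.0), 0, 100)
    t["artificial"] = np.clip(correlated(cfg.nuisance_corr, 6.0, 6.0), 0, 100)
    t["ammonium"] = np.exp(correlated(cfg.nuisance_corr, 0.8, np.log(0.15)))
    t["chloride"] = np.exp(correlated(0.0, 0.9, np.log(40.0)))
    t["toc"] = np.clip(correlated(0.0, 1.1, 4.1), 0.5, None)
    if cfg.align_coords:
        t["x"] = 1000.0 * gradient + rng.normal(0, 500.0, S)
    else:
        t["x"] = rng.uniform(0, 1000.0 * S, S)
    t["y"] = rng.uniform(0, 1000.0 * S, S)
    return t


def simulate_abundance(incidence: pd.DataFrame, cfg: SyntheticConfig) -> pd.DataFrame:
    """Counts conditional on presence: zero-truncated negative binomial.

    Where present, counts are ``1 + NB(size=dispersion, mean=mean−1)``,
    so the configured mean is the mean of positive counts; absences stay
    zero, and converting back to incidence recovers the input exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2)))
    A = incidence.to_numpy()
    mean_pos = max(cfg.abundance_mean - 1.0, 1e-9)
    size = cfg.abundance_dispersion
    p = size / (size + mean_pos)
    counts = 1 + rng.negative_binomial(size, p, A.shape)
    return pd.DataFrame(
        np.where(A > 0, counts, 0), index=incidence.index, columns=incidence.columns
    )


def simulate_study(cfg: SyntheticConfig):
    """Full synthetic study: incidence, abundance, environment, gradient.

    Returns a dict with keys ``incidence``, ``abundance``, ``sites``,
    ``gradient``, ``groups`` and a ``manifest`` echoing the config.
    """
    inc, gradient, groups = simulate_metacommunity(cfg)
    return {
        "incidence": inc,
        "abundance": simulate_abundance(inc, cfg),
        "sites": simulate_environment(gradient, cfg),
        "gradient": gradient,
        "groups": groups,
        "manifest": cfg.manifest(),
    }
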