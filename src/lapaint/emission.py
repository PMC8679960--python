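"""Window plans and Bayesian emission probabilities.

The genome is cut into contiguous windows of L consecutive SNPs (the last
window on each chromosome may be shorter).  Within a window, markers are
treated as independent given the source population, so the window likelihood
for population k is the product of per-genotype likelihoods under k's allele
frequency.  The emission fed to the decoder is, by default, the Bayesian
posterior over populations with the individual's admixture proportions as the
prior; a plain-likelihood alternative is available.  All arithmetic after the
per-genotype step is in log-space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .panel import MISSING, GenotypeVector, ReferencePanel

logger = logging.getLogger(__name__)

#: Floor applied to zero prior entries before taking logs (soft prior).
PRIOR_FLOOR = 1e-9


@dataclass
class WindowPlan:
    """Partition of an ordered site list into windows of L consecutive SNPs.

    ``boundaries`` holds half-open index ranges [start, end) over the site
    list; windows are contiguous, non-overlapping, never span chromosomes,
    and cover every retained site.
    """

    L: int
    boundaries: list[tuple[int, int]]
    chroms: list[str]

    @property
    def n_windows(self) -> int:
        return len(self.boundaries)

    def window_sites(self, t: int) -> range:
        start, end = self.boundaries[t]
        return range(start, end)


def plan_windows(sites, L: int) -> WindowPlan:
    """Cut the site list into per-chromosome windows of L SNPs.

    Each chromosome contributes ceil(N_chrom / L) windows; only the last
    window per chromosome may hold fewer than L sites.
    """
    if L < 1:
        raise ValueError("window size L must be >= 1")
    boundaries: list[tuple[int, int]] = []
    chroms: list[str] = []
    i = 0
    n = len(sites)
    while i < n:
        chrom = sites[i].chrom
        j = i
        while j < n and sites[j].chrom == chrom:
            j += 1
        for start in range(i, j, L):
            boundaries.append((start, min(start + L, j)))
            chroms.append(chrom)
        i = j
    return WindowPlan(L=L, boundaries=boundaries, chroms=chroms)


@dataclass
class EmissionMatrix:
    """Window-level log emissions for the ancestry HMM.

    ``logpost`` rows normalize to 1 in linear space; ``loglik`` holds the raw
    window log-likelihoods; ``prior`` is the (possibly floored and
    renormalized) population prior used for the posterior.
    """

    logpost: np.ndarray
    loglik: np.ndarray
    prior: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.logpost.shape[0]

    @property
    def n_pops(self) -> int:
        return self.logpost.shape[1]


def genotype_loglik(g, f, mode: str = "diploid") -> np.ndarray:
    """Log-likelihood of genotype dosage(s) given allele frequency(ies).

    Diploid genotypes follow the Hardy-Weinberg binomial on the population
    alternate-allele frequency: P(g|f) = C(2,g) f^g (1-f)^(2-g).  Haploid
    alleles are Bernoulli: P(1|f) = f.  Missing genotypes contribute log
    probability 0 (they are skipped).

    Parameters are broadcast: ``g`` with shape (...,) against ``f`` with a
    compatible shape (e.g. per-site genotypes against a site-by-population
    frequency matrix).
    """
    g = np.asarray(g)
    f = np.asarray(f, dtype=float)
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    logf = np.log(f)
    log1mf = np.log1p(-f)
    if mode == "diploid":
        gb = g[..., None] if f.ndim > g.ndim else g
        out = np.where(
            gb == MISSING,
            0.0,
            gb * logf + (2 - gb) * log1mf + np.where(gb == 1, np.log(2.0), 0.0),
        )
    elif mode == "haploid":
        gb = g[..., None] if f.ndim > g.ndim else g
        out = np.where(gb == MISSING, 0.0, gb * logf + (1 - gb) * log1mf)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def window_loglik(g: np.ndarray, freqs: np.ndarray, mode: str) -> np.ndarray:
    """K-vector of log window likelihoods: sum of per-site log-likelihoods.

    ``g`` is a genotype slice of length <= L aligned with ``freqs`` of shape
    (len(g), K).  Missing genotypes are skipped.  A window where every
    genotype is missing yields a flat all-zero vector.
    """
    g = np.asarray(g)
    freqs = np.asarray(freqs, dtype=float)
    if g.size == 0:
        raise ValueError("empty window")
    if freqs.shape[0] != g.shape[0]:
        raise ValueError("frequency rows must align with genotype entries")
    per_site = genotype_loglik(g, freqs, mode)  # (L, K)
    if (g == MISSING).all():
        logger.warning("window with all genotypes missing: flat likelihood")
    return per_site.sum(axis=0)


def _prepare_prior(prior: np.ndarray, K: int, hard: bool) -> np.ndarray:
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (K,):
        raise ValueError(f"prior must have shape ({K},)")
    if (prior < 0).any():
        raise ValueError("prior entries must be >= 0")
    s = prior.sum()
    if abs(s - 1.0) > 1e-6:
        raise ValueError(f"prior must sum to 1 (got {s})")
    if not (prior > 0).any():
        raise ValueError("prior must have at least one positive entry")
    if not hard and (prior == 0).any():
        prior = np.maximum(prior, PRIOR_FLOOR)
        prior = prior / prior.sum()
    return prior


def posterior(loglik: np.ndarray, prior: np.ndarray,
              hard_prior: bool = False) -> np.ndarray:
    """Log posterior over populations via Bayes' rule in log-space.

    logpost_k = log(prior_k) + loglik_k - logsumexp_k(...).  Prior entries of
    exactly 0 are floored at PRIOR_FLOOR and the prior renormalized, unless
    ``hard_prior`` is set, in which case such populations get -inf posterior.
    """
    loglik = np.asarray(loglik, dtype=float)
    K = loglik.shape[-1]
    prior = _prepare_prior(prior, K, hard_prior)
    with np.errstate(divide="ignore"):
        logprior = np.log(prior)
    unnorm = logprior + loglik
    norm = logsumexp(unnorm, axis=-1, keepdims=True)
    if np.any(~np.isfinite(norm)):
        raise ValueError("degenerate posterior: all prior mass on populations "
                         "with -inf likelihood")
    return unnorm - norm


def compute_emissions(
    sample: GenotypeVector,
    panel: ReferencePanel,
    plan: WindowPlan,
    prior: np.ndarray | None = None,
    hard_prior: bool = False,
    likelihood_emission: bool = False,
) -> EmissionMatrix:
    """Window-level emission matrix for a sample against a reference panel.

    By default the emission is the Bayesian posterior with the admixture
    prior applied per window.  With ``likelihood_emission`` the prior enters
    only through the decoder's initial distribution and the emission is the
    likelihood normalized with a uniform prior (the textbook-HMM alternative).
    """
    K = panel.n_pops
    if sample.n_sites != panel.n_sites:
        raise ValueError("sample and panel site lists differ in length")
    if prior is None:
        prior = np.full(K, 1.0 / K)
    prior = _prepare_prior(prior, K, hard_prior)

    per_site = genotype_loglik(sample.g, panel.freq, sample.ploidy_mode)
    starts = np.array([b[0] for b in plan.boundaries])
    loglik = np.add.reduceat(per_site, starts, axis=0)

    post_prior = np.full(K, 1.0 / K) if likelihood_emission else prior
    logpost = posterior(loglik, post_prior, hard_prior=hard_prior)
    return EmissionMatrix(logpost=logpost, loglik=loglik, prior=prior)
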