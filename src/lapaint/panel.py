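"""Reference panels: VCF loading, allele-frequency estimation, LD pruning.

A reference panel holds smoothed alternate-allele frequencies for K putative
ancestral populations at a shared, ordered set of biallelic SNPs.  Frequencies
are kept strictly inside (0, 1) via a Jeffreys-style pseudocount so that all
downstream likelihood arithmetic can run in log-space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype / allele call.
MISSING: int = -1

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class Site:
    """A biallelic SNP identified by chromosome, 1-based position and alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class ReferencePanel:
    """Per-site alternate-allele frequencies for K ancestral populations.

    Attributes
    ----------
    sites : list of Site
        Ordered by (chrom, pos); unique positions.
    populations : list of str
        K population labels, fixing the column order of ``freq``.
    freq : ndarray, shape (N, K)
        Smoothed alternate-allele frequencies, strictly inside (0, 1).
    n_hap : ndarray, shape (K,)
        Number of reference haplotypes per population.
    """

    sites: list[Site]
    populations: list[str]
    freq: np.ndarray
    n_hap: np.ndarray

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.n_hap = np.asarray(self.n_hap)
        if self.freq.shape != (len(self.sites), len(self.populations)):
            raise ValueError(
                f"freq shape {self.freq.shape} does not match "
                f"{len(self.sites)} sites x {len(self.populations)} populations"
            )
        if self.freq.size and not (
            (self.freq > 0).all() and (self.freq < 1).all()
        ):
            raise ValueError("panel frequencies must lie strictly in (0, 1)")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_pops(self) -> int:
        return len(self.populations)

    def subset(self, idx: Sequence[int]) -> "ReferencePanel":
        """Panel restricted to the given site indices (order preserved)."""
        idx = np.asarray(idx, dtype=int)
        return ReferencePanel(
            sites=[self.sites[i] for i in idx],
            populations=list(self.populations),
            freq=self.freq[idx],
            n_hap=self.n_hap.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: chrom, pos, ref, alt, freq_<pop> columns."""
        data = {
            "chrom": [s.chrom for s in self.sites],
            "pos": [s.pos for s in self.sites],
            "ref": [s.ref for s in self.sites],
            "alt": [s.alt for s in self.sites],
        }
        for k, pop in enumerate(self.populations):
            data[f"freq_{pop}"] = self.freq[:, k]
        return pd.DataFrame(data)


@dataclass
class GenotypeVector:
    """Genotypes of one sample at the panel's sites.

    ``g`` holds alternate-allele dosages: {0, 1, 2, MISSING} in diploid mode,
    {0, 1, MISSING} in haploid mode.
    """

    sites: list[Site]
    g: np.ndarray
    ploidy_mode: str
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=np.int8)
        if self.ploidy_mode not in ("diploid", "haploid"):
            raise ValueError(f"unknown ploidy mode {self.ploidy_mode!r}")
        if len(self.g) != len(self.sites):
            raise ValueError("genotype vector length does not match site list")
        hi = 2 if self.ploidy_mode == "diploid" else 1
        bad = (self.g > hi) | ((self.g < 0) & (self.g != MISSING))
        if bad.any():
            raise ValueError(
                f"invalid genotype values for {self.ploidy_mode} mode: "
                f"{np.unique(self.g[bad])}"
            )

    @property
    def n_sites(self) -> int:
        return len(self.g)

    def subset(self, idx: Sequence[int]) -> "GenotypeVector":
        idx = np.asarray(idx, dtype=int)
        return GenotypeVector(
            sites=[self.sites[i] for i in idx],
            g=self.g[idx],
            ploidy_mode=self.ploidy_mode,
            sample_id=self.sample_id,
        )


def estimate_frequencies(
    alt_counts: np.ndarray,
    n_hap: np.ndarray,
    alpha: float = 0.5,
) -> np.ndarray:
    """Smoothed alternate-allele frequencies from per-population allele counts.

    freq = (alt_counts + alpha) / (n_hap + 2 * alpha), which keeps every
    frequency strictly inside (0, 1) for alpha > 0.  ``n_hap`` may be a per
    population vector or a per-site matrix of called haplotype counts.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0: zero frequencies break log-space")
    alt_counts = np.asarray(alt_counts, dtype=float)
    n_hap = np.asarray(n_hap, dtype=float)
    if (alt_counts < 0).any():
        raise ValueError("negative allele counts")
    if np.any(alt_counts > np.broadcast_to(n_hap, alt_counts.shape)):
        raise ValueError("alt_counts exceed haplotype counts")
    return (alt_counts + alpha) / (n_hap + 2.0 * alpha)


def _is_biallelic_snp(record: pysam.VariantRecord) -> bool:
    if record.alts is None or len(record.alts) != 1:
        return False
    ref, alt = record.ref, record.alts[0]
    return (
        ref is not None
        and alt is not None
        and len(ref) == 1
        and len(alt) == 1
        and ref.upper() in _VALID_BASES
        and alt.upper() in _VALID_BASES
    )


def _read_vcf_records(path: str | Path):
    """Yield (Site, record) for biallelic SNPs; duplicated positions dropped."""
    seen: set[tuple[str, int]] = set()
    with pysam.VariantFile(str(path)) as vcf:
        for record in vcf:
            if not _is_biallelic_snp(record):
                continue
            key = (record.chrom, record.pos)
            if key in seen:
                continue
            seen.add(key)
            site = Site(record.chrom, record.pos, record.ref.upper(),
                        record.alts[0].upper())
            yield site, record


def read_population_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample_id, population) -> {sample: population}."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed population map line: {line!r}")
            mapping[parts[0]] = parts[1]
    return mapping


def _counts_from_vcf(
    path: str | Path,
    sample_to_pop: Mapping[str, str] | None,
    populations: list[str],
) -> tuple[dict[tuple[str, int], Site], dict[tuple[str, int], np.ndarray],
           dict[tuple[str, int], np.ndarray]]:
    """Per-site alt-allele and called-haplotype counts per population."""
    pop_index = {p: k for k, p in enumerate(populations)}
    sites: dict[tuple[str, int], Site] = {}
    alt: dict[tuple[str, int], np.ndarray] = {}
    called: dict[tuple[str, int], np.ndarray] = {}
    K = len(populations)
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if sample_to_pop is None:
            raise ValueError("population assignment required")
        col = np.array(
            [pop_index[sample_to_pop[s]] if s in sample_to_pop else -1
             for s in samples]
        )
    for site, record in _read_vcf_records(path):
        a = np.zeros(K)
        c = np.zeros(K)
        for s, k in zip(record.samples.values(), col):
            if k < 0:
                continue
            for allele in s.allele_indices:
                if allele is None:
                    continue
                c[k] += 1
                if allele == 1:
                    a[k] += 1
        sites[site.key] = site
        alt[site.key] = a
        called[site.key] = c
    return sites, alt, called


def load_panel(
    vcf_paths: Mapping[str, str | Path] | str | Path,
    pop_map: Mapping[str, str] | str | Path | None = None,
    site_filter: Sequence[tuple[str, int]] | None = None,
    alpha: float = 0.5,
) -> ReferencePanel:
    """Build a ReferencePanel from reference-population VCFs.

    Parameters
    ----------
    vcf_paths
        Either a mapping {population label: single-population VCF path} or a
        single multi-sample VCF path (then ``pop_map`` is required).
    pop_map
        Sample-to-population assignment: a mapping or a two-column TSV path.
    site_filter
        Optional collection of (chrom, pos) keys to retain.
    alpha
        Pseudocount per allele class for frequency smoothing.

    Only biallelic SNPs present in *all* inputs are retained, ordered by
    (chrom, pos).  A population with zero genotyped samples is a fatal error.
    """
    if isinstance(vcf_paths, (str, Path)):
        if pop_map is None:
            raise ValueError("a multi-sample VCF requires a population map")
        mapping = (read_population_map(pop_map)
                   if isinstance(pop_map, (str, Path)) else dict(pop_map))
        populations = sorted(set(mapping.values()))
        with pysam.VariantFile(str(vcf_paths)) as vcf:
            present = set(vcf.header.samples) & set(mapping)
        for pop in populations:
            if not any(mapping[s] == pop for s in present):
                raise ValueError(f"population {pop!r} has zero samples in "
                                 f"{vcf_paths}")
        sites, alt, called = _counts_from_vcf(vcf_paths, mapping, populations)
        keys = set(sites)
    else:
        populations = list(vcf_paths.keys())
        per_pop = []
        keys = None
        for pop, path in vcf_paths.items():
            with pysam.VariantFile(str(path)) as vcf:
                samples = list(vcf.header.samples)
            if not samples:
                raise ValueError(f"population {pop!r} has zero samples in {path}")
            s, a, c = _counts_from_vcf(path, {x: pop for x in samples}, [pop])
            per_pop.append((s, a, c))
            keys = set(s) if keys is None else keys & set(s)
        if not keys:
            raise ValueError(
                "empty site intersection across inputs: "
                + ", ".join(str(p) for p in vcf_paths.values())
            )
        # Exclude sites whose REF/ALT disagree across inputs.
        keys = {k for k in keys
                if len({s[k] for s, _, _ in per_pop}) == 1}
        if not keys:
            raise ValueError("no site with consistent alleles across inputs")
        sites = {k: per_pop[0][0][k] for k in keys}
        alt = {}
        called = {}
        for key in keys:
            alt[key] = np.concatenate([a[key] for _, a, _ in per_pop])
            called[key] = np.concatenate([c[key] for _, _, c in per_pop])

    if site_filter is not None:
        keys &= set(site_filter)
    if not keys:
        raise ValueError("empty site intersection across inputs")

    # Require allele agreement across inputs implicitly via identical Site keys;
    # conflicting REF/ALT at a shared position would have been deduplicated per
    # file, so verify alleles match when merging.
    ordered = sorted(keys, key=lambda k: (k[0], k[1]))
    site_list = [sites[k] for k in ordered]
    alt_counts = np.vstack([alt[k] for k in ordered])
    called_counts = np.vstack([called[k] for k in ordered])
    if (called_counts == 0).any():
        # A site with no calls in some population: smoothing still yields 0.5.
        logger.warning("some sites have zero called haplotypes in a population")
    freq = estimate_frequencies(alt_counts, called_counts, alpha=alpha)
    n_hap = called_counts.max(axis=0)
    return ReferencePanel(site_list, populations, freq, n_hap)


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns, missing dropped pairwise."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xs = x[ok].astype(float)
    ys = y[ok].astype(float)
    vx = xs.var()
    vy = ys.var()
    if vx == 0.0 or vy == 0.0:
        return 0.0  # constant site: treated as unlinked
    cov = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return (cov * cov) / (vx * vy)


def ld_prune(
    genotypes: np.ndarray,
    window: int = 50,
    r2_max: float = 0.8,
    chroms: Sequence[str] | None = None,
) -> list[int]:
    """Greedy LD pruning of a site-by-sample dosage matrix.

    Scanning sites left to right, site i is dropped iff some earlier *kept*
    site j on the same chromosome, within ``window`` consecutive SNPs
    (index distance < window), has squared Pearson dosage correlation
    r^2 > ``r2_max``.  Dropped sites do not take part in later comparisons.
    Constant (zero-variance) sites are treated as r^2 = 0 with every partner.

    Parameters
    ----------
    genotypes : ndarray, shape (N, M)
        Dosages (0/1/2 or 0/1), MISSING allowed; rows are sites in genome order.
    chroms
        Optional per-site chromosome labels; windows never span chromosomes.

    Returns
    -------
    list of int
        Indices of retained sites, in input order.
    """
    genotypes = np.asarray(genotypes)
    n = genotypes.shape[0]
    if n < 2:
        return list(range(n))
    if window < 2:
        raise ValueError("window must be >= 2")
    kept: list[int] = []
    # kept indices within the trailing window, per chromosome
    for i in range(n):
        drop = False
        for j in reversed(kept):
            if i - j >= window:
                break
            if chroms is not None and chroms[i] != chroms[j]:
                break
            if _pairwise_r2(genotypes[j], genotypes[i]) > r2_max:
                drop = True
                break
        if not drop:
            kept.append(i)
    return kept
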