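"""Synthetic admixed genomes with known local-ancestry truth.

Reference populations are differentiated under the Balding-Nichols model: an
ancestral allele frequency p ~ Uniform(0.05, 0.95) per site, and each
population's frequency drawn Beta(p(1-F)/F, (1-p)(1-F)/F) so that the
expected differentiation equals FST = F.  Admixed haplotypes are Markov
mosaics: the ancestry label switches with a small per-SNP probability and the
destination is drawn from the true admixture proportions, which makes those
proportions the chain's stationary distribution.  Alleles are then drawn
Bernoulli from the ancestral population's frequency (sites independent given
ancestry, matching the within-window independence the decoder assumes).

Also provides scoring against the truth track and planted-enrichment count
tables for the pathway module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .panel import GenotypeVector, ReferencePanel, Site, estimate_frequencies
from .pipeline import AncestryPath, PhasedSample


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic admixed-genome experiment.

    Defaults give three moderately differentiated populations (FST = 0.2,
    typical of continental-scale human panels), 20,000 evenly spaced markers
    on one chromosome, 40 reference haplotypes per population, admixture
    proportions (0.5, 0.3, 0.2) and a per-SNP ancestry switch probability of
    5e-4 (mean tract length 2,000 SNPs, i.e. 40 windows of 50 SNPs).
    """

    K: int = 3
    n_sites: int = 20_000
    fst: float = 0.2
    switch_rate: float = 5e-4
    q_true: tuple[float, ...] = (0.5, 0.3, 0.2)
    n_ref_hap: int = 40
    seed: int = 0
    chrom: str = "1"
    spacing: int = 1000  # bp between consecutive markers

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError("FST must lie in (0, 1)")
        if not 0.0 <= self.switch_rate < 1.0:
            raise ValueError("switch_rate must lie in [0, 1)")
        q = np.asarray(self.q_true, dtype=float)
        if len(q) != self.K or (q < 0).any() or abs(q.sum() - 1.0) > 1e-8:
            raise ValueError("q_true must be K nonnegative proportions summing to 1")

    @property
    def populations(self) -> list[str]:
        return [f"POP{k + 1}" for k in range(self.K)]

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthTrack:
    """Per-haplotype, per-SNP true ancestry labels (values in 0..K-1)."""

    labels: np.ndarray  # (2, N) for a diploid individual
    populations: list[str]

    def segments(self, hap: int = 0) -> list[tuple[int, int, int]]:
        """Runs of constant ancestry as (start, end, label) index triples."""
        lab = self.labels[hap]
        breaks = np.flatnonzero(np.diff(lab) != 0) + 1
        bounds = np.concatenate([[0], breaks, [len(lab)]])
        return [(int(bounds[i]), int(bounds[i + 1]), int(lab[bounds[i]]))
                for i in range(len(bounds) - 1)]

    def fractions(self) -> np.ndarray:
        """Genome-wide label fractions across both haplotypes."""
        K = len(self.populations)
        flat = self.labels.ravel()
        return np.array([(flat == k).mean() for k in range(K)])


def simulate_panel(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ReferencePanel, dict[str, np.ndarray], np.ndarray]:
    """Simulate a differentiated reference panel.

    Returns the panel (frequencies estimated from the simulated reference
    haplotypes with the default pseudocount), the reference haplotypes per
    population (each an (n_ref_hap, N) 0/1 array), and the true population
    frequency matrix (N, K) used to generate them.
    """
    rng = config.rng() if rng is None else rng
    N, K, F = config.n_sites, config.K, config.fst
    p_anc = rng.uniform(0.05, 0.95, size=N)
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    true_freq = rng.beta(a[:, None], b[:, None], size=(N, K))
    # keep Bernoulli draws non-degenerate; the panel itself is re-smoothed
    true_freq = np.clip(true_freq, 1e-6, 1 - 1e-6)

    sites = [Site(config.chrom, (i + 1) * config.spacing, "A", "G")
             for i in range(N)]
    haps = {}
    alt_counts = np.empty((N, K))
    for k, pop in enumerate(config.populations):
        h = (rng.random((config.n_ref_hap, N)) < true_freq[:, k]).astype(np.int8)
        haps[pop] = h
        alt_counts[:, k] = h.sum(axis=0)
    freq = estimate_frequencies(alt_counts, np.full(K, config.n_ref_hap))
    panel = ReferencePanel(sites, config.populations, freq,
                           np.full(K, config.n_ref_hap))
    return panel, haps, true_freq


def _mosaic_labels(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """One haplotype's ancestry labels: a Markov mosaic over 0..K-1."""
    q = np.asarray(config.q_true)
    N = config.n_sites
    labels = np.empty(N, dtype=np.int8)
    labels[0] = rng.choice(config.K, p=q)
    switch = rng.random(N - 1) < config.switch_rate
    dest = rng.choice(config.K, size=N - 1, p=q)
    for i in range(1, N):
        labels[i] = dest[i - 1] if switch[i - 1] else labels[i - 1]
    return labels


def simulate_admixed(
    config: SimulationConfig,
    true_freq: np.ndarray,
    rng: np.random.Generator | None = None,
    sample_id: str = "ADMIXED1",
    homozygous: bool = False,
) -> tuple[PhasedSample, TruthTrack]:
    """Simulate one phased admixed individual with a known truth track.

    Each haplotype's ancestry is an independent Markov mosaic; alleles are
    Bernoulli draws from the true frequency of the local ancestral
    population.  With ``homozygous`` the second haplotype is an exact copy of
    the first (labels and alleles), producing a fully homozygous individual
    whose split "parents" are identical.
    """
    rng = config.rng() if rng is None else rng
    N = config.n_sites
    lab0 = _mosaic_labels(config, rng)
    hap0 = (rng.random(N) < true_freq[np.arange(N), lab0]).astype(np.int8)
    if homozygous:
        lab1, hap1 = lab0.copy(), hap0.copy()
    else:
        lab1 = _mosaic_labels(config, rng)
        hap1 = (rng.random(N) < true_freq[np.arange(N), lab1]).astype(np.int8)
    sites = [Site(config.chrom, (i + 1) * config.spacing, "A", "G")
             for i in range(N)]
    sample = PhasedSample(
        sites=sites, a0=hap0, a1=hap1,
        phased=np.ones(N, dtype=bool), sample_id=sample_id,
    )
    truth = TruthTrack(labels=np.vstack([lab0, lab1]),
                       populations=config.populations)
    return sample, truth


def write_vcf(samples: list[PhasedSample], path: str | Path) -> Path:
    """Write phased samples (sharing one site list) as an uncompressed VCF."""
    if not samples:
        raise ValueError("no samples to write")
    sites = samples[0].sites
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in dict.fromkeys(s.chrom for s in sites):
        max_pos = max(s.pos for s in sites if s.chrom == chrom)
        header.contigs.add(chrom, length=max_pos + 1)
    for s in samples:
        header.add_sample(s.sample_id)
    path = Path(path)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i, site in enumerate(sites):
            rec = vcf.new_record(contig=site.chrom, start=site.pos - 1,
                                 alleles=(site.ref, site.alt))
            for s in samples:
                a0 = None if s.a0[i] < 0 else int(s.a0[i])
                a1 = None if s.a1[i] < 0 else int(s.a1[i])
                rec.samples[s.sample_id]["GT"] = (a0, a1)
                rec.samples[s.sample_id].phased = bool(s.phased[i])
            vcf.write(rec)
    return path


def write_reference_vcf(haps: dict[str, np.ndarray], sites: list[Site],
                        path: str | Path) -> tuple[Path, Path]:
    """Write reference haplotypes as one multi-sample VCF plus population map.

    Haplotype pairs within a population are combined into pseudo-diploid
    samples (their pairing is arbitrary: only allele counts matter).
    """
    samples = []
    for pop, h in haps.items():
        n_hap, _ = h.shape
        for j in range(0, n_hap - 1, 2):
            samples.append(PhasedSample(
                sites=sites, a0=h[j], a1=h[j + 1],
                phased=np.ones(len(sites), dtype=bool),
                sample_id=f"{pop}_s{j // 2}",
            ))
    vcf_path = write_vcf(samples, path)
    map_path = Path(str(path) + ".popmap.tsv")
    with open(map_path, "w") as fh:
        for pop, h in haps.items():
            for j in range(0, h.shape[0] - 1, 2):
                fh.write(f"{pop}_s{j // 2}\t{pop}\n")
    return vcf_path, map_path


def project_windows_to_sites(path: AncestryPath,
                             populations: list[str]) -> np.ndarray:
    """Per-SNP predicted labels: each window's label copied to its SNPs."""
    if path.plan is None:
        raise ValueError("path carries no window plan")
    pop_index = {p: k for k, p in enumerate(populations)}
    n = path.plan.boundaries[-1][1]
    out = np.empty(n, dtype=np.int8)
    for (start, end), label in zip(path.plan.boundaries,
                                   path.windows["label"]):
        out[start:end] = pop_index[label]
    return out


def score_accuracy(
    predicted: AncestryPath,
    truth_labels: np.ndarray,
    populations: list[str],
) -> tuple[float, np.ndarray]:
    """Fraction of SNP positions whose projected window label matches truth.

    Returns the accuracy and a K x K confusion matrix (rows: truth,
    columns: prediction) of SNP counts.
    """
    pred = project_windows_to_sites(predicted, populations)
    truth_labels = np.asarray(truth_labels)
    if pred.shape != truth_labels.shape:
        raise ValueError("prediction and truth cover different site lists")
    K = len(populations)
    confusion = np.zeros((K, K), dtype=int)
    np.add.at(confusion, (truth_labels, pred), 1)
    accuracy = float((pred == truth_labels).mean())
    return accuracy, confusion


def simulate_pathway_counts(
    n_pathways: int,
    n_per_pathway: int | np.ndarray,
    p: float,
    planted: dict[int, float] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-pathway (nA, nB) SNP counts with optional planted enrichment.

    Each pathway i has n_i SNPs split Binomial(n_i, p_i) between groups A and
    B; under the null p_i = p for every pathway, and ``planted`` maps pathway
    indices to an additive shift of p_i (clipped to [0.01, 0.99]).
    """
    rng = np.random.default_rng() if rng is None else rng
    n_i = np.broadcast_to(np.asarray(n_per_pathway), (n_pathways,)).astype(int)
    p_i = np.full(n_pathways, float(p))
    for idx, delta in (planted or {}).items():
        p_i[idx] = np.clip(p_i[idx] + delta, 0.01, 0.99)
    nA = rng.binomial(n_i, p_i)
    return pd.DataFrame({
        "pathway_id": [f"path{i:04d}" for i in range(n_pathways)],
        "nA": nA,
        "nB": n_i - nA,
    })
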