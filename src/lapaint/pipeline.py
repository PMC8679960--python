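"""End-to-end orchestration: sample loading, modes, decoding, aggregation.

A sample VCF is intersected with the reference panel, windowed, converted to
emissions and decoded into a per-window ancestry path.  In diploid mode the
genotype dosages are analyzed directly; in haploid mode phased genotypes are
split into two pseudo-homozygous "parents" which are decoded separately.
Window labels are merged into segments, aggregated into genome-wide
proportions, and optionally compared with an externally supplied global
admixture (Q) vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .decoder import TransitionModel, build_transition_penalty, viterbi_decode
from .emission import EmissionMatrix, WindowPlan, compute_emissions, plan_windows
from .panel import MISSING, GenotypeVector, ReferencePanel, Site, _read_vcf_records

logger = logging.getLogger(__name__)


@dataclass
class QVector:
    """Global admixture proportions for one sample over K labeled populations."""

    sample_id: str
    labels: list[str]
    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if (self.q < 0).any():
            raise ValueError("admixture proportions must be >= 0")
        if abs(self.q.sum() - 1.0) > 1e-4:
            raise ValueError(f"admixture proportions must sum to 1 "
                             f"(got {self.q.sum()})")

    def reorder(self, labels: list[str]) -> "QVector":
        """Proportions re-ordered to match a target label order."""
        missing = set(labels) ^ set(self.labels)
        if missing:
            raise ValueError(
                f"population labels differ (symmetric difference: {sorted(missing)})"
            )
        idx = [self.labels.index(l) for l in labels]
        return QVector(self.sample_id, list(labels), self.q[idx])


@dataclass
class PhasedSample:
    """Raw per-site allele pairs for one sample, preserving phase.

    ``a0``/``a1`` hold the left/right allele (0, 1 or MISSING) of each GT;
    ``phased`` records whether the separator was '|'.
    """

    sites: list[Site]
    a0: np.ndarray
    a1: np.ndarray
    phased: np.ndarray
    sample_id: str

    def dosages(self) -> GenotypeVector:
        """Diploid alternate-allele dosages (missing if either allele is)."""
        g = np.where((self.a0 == MISSING) | (self.a1 == MISSING),
                     MISSING, self.a0 + self.a1).astype(np.int8)
        return GenotypeVector(self.sites, g, "diploid", self.sample_id)

    def subset(self, idx) -> "PhasedSample":
        idx = np.asarray(idx, dtype=int)
        return PhasedSample(
            sites=[self.sites[i] for i in idx],
            a0=self.a0[idx], a1=self.a1[idx], phased=self.phased[idx],
            sample_id=self.sample_id,
        )


@dataclass
class AncestryPath:
    """Decoded local-ancestry track for one sample (or haplotype).

    windows: DataFrame (chrom, start, end, label [, posterior columns]) with
    0-based half-open coordinates; segments: merged runs of identical label;
    aggregate: genome-wide fraction of windows per population.
    """

    windows: pd.DataFrame
    segments: pd.DataFrame
    aggregate: QVector
    emissions: EmissionMatrix | None = None
    plan: WindowPlan | None = None

    @property
    def labels(self) -> np.ndarray:
        return self.windows["label"].to_numpy()

    @property
    def n_switches(self) -> int:
        lab = self.windows["label"].to_numpy()
        same_chrom = self.windows["chrom"].to_numpy()
        return int(((lab[1:] != lab[:-1]) &
                    (same_chrom[1:] == same_chrom[:-1])).sum())


def read_qvector(path: str | Path, labels: list[str],
                 sample_ids: list[str] | None = None,
                 row: int = 0) -> QVector:
    """Read one Q-vector from a whitespace-delimited, headerless file.

    One sample per line, K proportions per line (supervised global-ancestry
    output dialect).  ``labels`` supplies the population order.
    """
    mat = np.loadtxt(path, ndmin=2)
    if mat.shape[1] != len(labels):
        raise ValueError(
            f"Q file has {mat.shape[1]} columns but {len(labels)} labels given"
        )
    sid = sample_ids[row] if sample_ids else f"sample{row}"
    return QVector(sid, list(labels), mat[row])


def load_phased_sample(path: str | Path,
                       sample: str | None = None) -> PhasedSample:
    """Read one sample's biallelic-SNP genotypes (with phase) from a VCF."""
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
    if not samples:
        raise ValueError(f"no samples in {path}")
    if sample is None:
        sample = samples[0]
    elif sample not in samples:
        raise ValueError(f"sample {sample!r} not found in {path}")
    sites, a0s, a1s, ph = [], [], [], []
    for site, record in _read_vcf_records(path):
        call = record.samples[sample]
        alleles = call.allele_indices
        if alleles is None or len(alleles) == 0:
            a0 = a1 = MISSING
            phased = False
        elif len(alleles) == 1:  # haploid record
            a0 = a1 = alleles[0] if alleles[0] is not None else MISSING
            phased = True
        else:
            a0 = alleles[0] if alleles[0] is not None else MISSING
            a1 = alleles[1] if alleles[1] is not None else MISSING
            phased = bool(call.phased)
        sites.append(site)
        a0s.append(a0)
        a1s.append(a1)
        ph.append(phased)
    return PhasedSample(sites, np.array(a0s, dtype=np.int8),
                        np.array(a1s, dtype=np.int8),
                        np.array(ph, dtype=bool), sample)


def split_phased_haplotypes(sample: PhasedSample) -> tuple[GenotypeVector, GenotypeVector]:
    """Split a phased diploid sample into two pseudo-homozygous haploid parents.

    Haplotype A takes the left allele of every phased GT, haplotype B the
    right.  Any heterozygous unphased record is a fatal error: without phase
    the allele columns are not haplotypes.
    """
    het = (sample.a0 != sample.a1)
    bad = het & ~sample.phased & (sample.a0 != MISSING) & (sample.a1 != MISSING)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        s = sample.sites[i]
        raise ValueError(
            f"unphased heterozygous genotype at {s.chrom}:{s.pos}; "
            "run diploid mode or phase the data first"
        )
    hap_a = GenotypeVector(sample.sites, sample.a0, "haploid",
                           f"{sample.sample_id}_hapA")
    hap_b = GenotypeVector(sample.sites, sample.a1, "haploid",
                           f"{sample.sample_id}_hapB")
    return hap_a, hap_b


def intersect_with_panel(sample: PhasedSample,
                         panel: ReferencePanel) -> tuple[PhasedSample, ReferencePanel]:
    """Restrict sample and panel to shared sites with matching alleles."""
    panel_idx = {s.key: (i, s) for i, s in enumerate(panel.sites)}
    keep_s, keep_p = [], []
    dropped = 0
    for i, s in enumerate(sample.sites):
        hit = panel_idx.get(s.key)
        if hit is None:
            continue
        j, ps = hit
        if ps.ref != s.ref or ps.alt != s.alt:
            dropped += 1
            continue
        keep_s.append(i)
        keep_p.append(j)
    if dropped:
        logger.warning("%d shared positions dropped for allele mismatch", dropped)
    if not keep_s:
        raise ValueError("no sites shared between sample and panel")
    return sample.subset(keep_s), panel.subset(keep_p)


def _windows_frame(plan: WindowPlan, sites: list[Site], labels: np.ndarray,
                   populations: list[str],
                   logpost: np.ndarray | None = None) -> pd.DataFrame:
    """Window table with 0-based half-open genomic coordinates.

    A window starts at (position of its first SNP - 1) and ends at the
    position of its last SNP.
    """
    rows = {
        "chrom": plan.chroms,
        "start": [sites[b[0]].pos - 1 for b in plan.boundaries],
        "end": [sites[b[1] - 1].pos for b in plan.boundaries],
        "label": [populations[k] for k in labels],
    }
    df = pd.DataFrame(rows)
    if logpost is not None:
        for k, pop in enumerate(populations):
            df[f"post_{pop}"] = np.exp(logpost[:, k])
    return df


def merge_segments(windows: pd.DataFrame) -> pd.DataFrame:
    """Merge consecutive same-label windows on a chromosome into segments."""
    segs = []
    cur = None
    for rec in windows.itertuples(index=False):
        if cur is not None and rec.chrom == cur["chrom"] and rec.label == cur["label"]:
            cur["end"] = rec.end
        else:
            if cur is not None:
                segs.append(cur)
            cur = {"chrom": rec.chrom, "start": rec.start,
                   "end": rec.end, "label": rec.label}
    if cur is not None:
        segs.append(cur)
    return pd.DataFrame(segs, columns=["chrom", "start", "end", "label"])


def aggregate(labels: np.ndarray, populations: list[str],
              sample_id: str = "sample") -> QVector:
    """Fraction of windows assigned to each ancestral population."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("no windows to aggregate")
    frac = np.array([(labels == k).mean() for k in range(len(populations))])
    return QVector(sample_id, list(populations), frac)


def compare_to_admixture(agg: QVector, q: QVector) -> tuple[float, float]:
    """Euclidean distance and Pearson correlation between two Q-vectors."""
    q = q.reorder(agg.labels)
    diff = agg.q - q.q
    euclid = float(np.sqrt((diff ** 2).sum()))
    if np.std(agg.q) == 0 or np.std(q.q) == 0:
        import warnings

        warnings.warn("zero-variance vector: Pearson correlation undefined")
        pearson = float("nan")
    else:
        pearson = float(np.corrcoef(agg.q, q.q)[0, 1])
    return euclid, pearson


def _decode_windows(emissions: EmissionMatrix, plan: WindowPlan,
                    model: TransitionModel) -> np.ndarray:
    """Viterbi path over windows, decoding each chromosome independently."""
    path = np.empty(plan.n_windows, dtype=int)
    start = 0
    for t in range(1, plan.n_windows + 1):
        if t == plan.n_windows or plan.chroms[t] != plan.chroms[start]:
            path[start:t] = viterbi_decode(emissions.logpost[start:t], model).path
            start = t
    return path


def _path_from_genotypes(gv: GenotypeVector, panel: ReferencePanel,
                         prior: np.ndarray | None,
                         model: TransitionModel, L: int,
                         hard_prior: bool,
                         likelihood_emission: bool) -> AncestryPath:
    plan = plan_windows(panel.sites, L)
    em = compute_emissions(gv, panel, plan, prior=prior, hard_prior=hard_prior,
                           likelihood_emission=likelihood_emission)
    model = TransitionModel(A=model.A, pi=em.prior, penalty=model.penalty,
                            source=model.source)
    path = _decode_windows(em, plan, model)
    windows = _windows_frame(plan, panel.sites, path, panel.populations,
                             em.logpost)
    segments = merge_segments(windows)
    agg = aggregate(path, panel.populations, gv.sample_id)
    logger.info("%s: %d windows, %d switches, missing rate %.3f",
                gv.sample_id, plan.n_windows,
                int((np.diff(path) != 0).sum()),
                float((gv.g == MISSING).mean()))
    return AncestryPath(windows=windows, segments=segments, aggregate=agg,
                        emissions=em, plan=plan)


def run_sample(
    sample: PhasedSample | GenotypeVector,
    panel: ReferencePanel,
    mode: str = "diploid",
    q: QVector | None = None,
    L: int = 50,
    penalty: float = 10000.0,
    transition: TransitionModel | None = None,
    uniform_prior: bool = False,
    hard_prior: bool = False,
    likelihood_emission: bool = False,
) -> AncestryPath | tuple[AncestryPath, AncestryPath]:
    """Decode local ancestry for one sample.

    The prior over populations is the supplied Q-vector when given (and
    ``uniform_prior`` is not set), else uniform.  In haploid mode the phased
    sample is split into two pseudo-homozygous parents, each decoded
    separately under the *diploid* sample's Q-vector prior; a pair of paths
    is returned.  Decoding restarts from the initial distribution on every
    chromosome.
    """
    if mode not in ("diploid", "haploid"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(sample, PhasedSample):
        sample, panel = intersect_with_panel(sample, panel)

    prior = None
    if q is not None and not uniform_prior:
        prior = q.reorder(panel.populations).q
    if transition is None:
        transition = build_transition_penalty(panel.n_pops, penalty)

    if mode == "diploid":
        gv = sample.dosages() if isinstance(sample, PhasedSample) else sample
        if gv.ploidy_mode != "diploid":
            raise ValueError("diploid mode requires diploid genotypes")
        return _path_from_genotypes(gv, panel, prior, transition, L,
                                    hard_prior, likelihood_emission)

    if not isinstance(sample, PhasedSample):
        raise ValueError("haploid mode requires phased sample records")
    hap_a, hap_b = split_phased_haplotypes(sample)
    return (
        _path_from_genotypes(hap_a, panel, prior, transition, L,
                             hard_prior, likelihood_emission),
        _path_from_genotypes(hap_b, panel, prior, transition, L,
                             hard_prior, likelihood_emission),
    )


def write_outputs(path: AncestryPath, prefix: str | Path) -> dict[str, Path]:
    """Write window table (TSV), segments (BED4) and aggregate (Q) files."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    out = {
        "windows": Path(f"{prefix}.windows.tsv"),
        "segments": Path(f"{prefix}.segments.bed"),
        "Q": Path(f"{prefix}.Q"),
    }
    path.windows.to_csv(out["windows"], sep="\t", index=False)
    path.segments.to_csv(out["segments"], sep="\t", index=False, header=False)
    np.savetxt(out["Q"], path.aggregate.q[None, :], fmt="%.6f")
    return out


def read_windows(path: str | Path) -> pd.DataFrame:
    """Read back a window table written by :func:`write_outputs`."""
    return pd.read_csv(path, sep="\t")
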