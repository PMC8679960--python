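"""Differential pathway-enrichment scores from per-pathway SNP counts.

Given per-pathway counts of SNPs attributable to two groups of populations
(A and B), each pathway's share p_i = nA_i / (nA_i + nB_i) is compared with
the genome-wide expectation p = nA / (nA + nB) by a continuity-corrected
one-proportion z-score.  Computed separately for synonymous (DSSE) and
nonsynonymous (DNSE) SNP classes; a pathway is called differentially
enriched when its BH-adjusted nonsynonymous p-value clears the significance
threshold *and* its nonsynonymous raw p-value is smaller than the
corresponding synonymous one — nonsynonymous signal must exceed the
pathway's background of synonymous turnover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("pathway_id", "nA", "nB")


@dataclass
class PathwayCountTable:
    """Per-pathway SNP counts (nA, nB) for one SNP class.

    ``totals`` are the column sums over all pathways of the class.
    """

    table: pd.DataFrame
    snp_class: str = "nonsynonymous"

    def __post_init__(self) -> None:
        missing = set(REQUIRED_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"count table lacks columns: {sorted(missing)}")
        if len(self.table) == 0:
            raise ValueError("empty count table")
        if (self.table[["nA", "nB"]] < 0).to_numpy().any():
            raise ValueError("counts must be >= 0")

    @property
    def nA(self) -> int:
        return int(self.table["nA"].sum())

    @property
    def nB(self) -> int:
        return int(self.table["nB"].sum())


def dse_score(nA_i, nB_i, nA: int, nB: int):
    """Continuity-corrected enrichment z-score(s) for pathway counts.

    p = nA / (nA + nB) is the genome-wide fraction of group-A SNPs and
    p_i = nA_i / (nA_i + nB_i) the pathway's fraction.  The score is
    ((p - p_i) + cc) / sqrt(p (1 - p) / n_i) with n_i = nA_i + nB_i and the
    continuity correction cc = ±1/(2 n_i) taken toward zero; when
    |p - p_i| <= 1/(2 n_i) the score is exactly 0.

    Returns (p, p_i, z); accepts scalars or aligned arrays.  Pathways with
    n_i = 0 yield NaN (and are skipped with a warning by the caller).
    """
    if nA + nB <= 0:
        raise ValueError("total counts must be positive")
    p = nA / (nA + nB)
    if p <= 0.0 or p >= 1.0:
        raise ValueError("degenerate totals: genome-wide fraction is 0 or 1")
    nA_i = np.asarray(nA_i, dtype=float)
    nB_i = np.asarray(nB_i, dtype=float)
    n_i = nA_i + nB_i
    with np.errstate(divide="ignore", invalid="ignore"):
        p_i = nA_i / n_i
        diff = p - p_i
        cc = 1.0 / (2.0 * n_i)
        shrunk = np.sign(diff) * np.maximum(np.abs(diff) - cc, 0.0)
        z = shrunk / np.sqrt(p * (1.0 - p) / n_i)
    z = np.where(n_i > 0, z, np.nan)
    p_i = np.where(n_i > 0, p_i, np.nan)
    if np.ndim(nA_i) == 0:
        return float(p), float(p_i), float(z)
    return p, p_i, z


def _score_class(counts: PathwayCountTable) -> pd.DataFrame:
    df = counts.table.copy()
    n_i = df["nA"] + df["nB"]
    if (n_i == 0).any():
        logger.warning("%d pathways with zero counts skipped",
                       int((n_i == 0).sum()))
        df = df[n_i > 0].copy()
        if len(df) == 0:
            raise ValueError("no pathway with positive counts")
    p, p_i, z = dse_score(df["nA"].to_numpy(), df["nB"].to_numpy(),
                          counts.nA, counts.nB)
    raw = 2.0 * stats.norm.sf(np.abs(z))
    # Corrections over the m pathways of this class.
    bonf = multipletests(raw, method="bonferroni")[1]
    bh = multipletests(raw, method="fdr_bh")[1]
    return pd.DataFrame({
        "pathway_id": df["pathway_id"].to_numpy(),
        "nA": df["nA"].to_numpy(),
        "nB": df["nB"].to_numpy(),
        "p_overall": p,
        "p_pathway": p_i,
        "score": z,
        "p_raw": raw,
        "p_bonferroni": bonf,
        "p_bh": bh,
    })


def enrichment_test(
    synonymous: PathwayCountTable | pd.DataFrame,
    nonsynonymous: PathwayCountTable | pd.DataFrame,
    alpha: float = 0.005,
) -> pd.DataFrame:
    """Paired DSSE/DNSE enrichment test over all pathways.

    Both tables are scored independently (multiple-testing corrections use
    the number of pathways within each class), outer-joined on pathway id
    with zero-filled counts, and a pathway is flagged significant iff its
    BH-adjusted nonsynonymous p-value is below ``alpha`` and its raw
    nonsynonymous p-value is below the raw synonymous p-value.

    Returns one row per pathway with both classes' scores and the flag,
    sorted by nonsynonymous BH-adjusted p-value.
    """
    if isinstance(synonymous, pd.DataFrame):
        synonymous = PathwayCountTable(synonymous, "synonymous")
    if isinstance(nonsynonymous, pd.DataFrame):
        nonsynonymous = PathwayCountTable(nonsynonymous, "nonsynonymous")
    syn = _score_class(synonymous).add_suffix("_syn").rename(
        columns={"pathway_id_syn": "pathway_id"})
    nsyn = _score_class(nonsynonymous).add_suffix("_nonsyn").rename(
        columns={"pathway_id_nonsyn": "pathway_id"})
    only = set(syn["pathway_id"]) ^ set(nsyn["pathway_id"])
    if only:
        logger.warning("%d pathways present in one class only (zero-filled)",
                       len(only))
    merged = syn.merge(nsyn, on="pathway_id", how="outer")
    # A pathway absent from one class has no score there: its raw p is NaN
    # and the paired rule cannot be satisfied.
    merged["significant"] = (
        (merged["p_bh_nonsyn"] < alpha)
        & (merged["p_raw_nonsyn"] < merged["p_raw_syn"])
    ).fillna(False)
    return merged.sort_values("p_bh_nonsyn", kind="stable").reset_index(drop=True)


def read_count_table(path, snp_class: str = "nonsynonymous") -> PathwayCountTable:
    """Read a per-pathway count TSV (pathway_id, nA, nB)."""
    df = pd.read_csv(path, sep="\t")
    return PathwayCountTable(df, snp_class)


def write_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)
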