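"""Sex-chromosome assembly contiguity scoring and X-inactivation skew.

Contiguity is scored by partitioning the reference sex chromosome into fixed
windows (default 1 Mbp), masking out excluded regions (PAR, centromere,
Yq12-style heterochromatin), and asking of each remaining window whether the
union of assembly-to-reference alignment blocks covers at least 95% of it
with no more than three distinct contigs touching it.

X-inactivation (XCI) skew uses haplotype-resolved CpG methylation: the
inactive X is methylated at CpG islands, so in a skewed sample the two
haplotypes separate in mean island methylation. The skew index is the
difference of genome-wide haplotype means (maternal minus paternal) over CpG
islands ± a flank; positive values mean the maternal X is preferentially
inactivated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

PAF_COLUMNS = [
    "qname", "qlen", "qstart", "qend", "strand",
    "tname", "tlen", "tstart", "tend", "nmatch", "alnlen", "mapq",
]


@dataclass(frozen=True)
class AlignmentInterval:
    """One aligned block of a contig on the reference (0-based half-open)."""

    contig: str
    target_chrom: str
    target_start: int
    target_end: int

    def __post_init__(self):
        if self.target_end <= self.target_start:
            raise ValueError("empty alignment block")


def read_paf(path, target_chrom: Optional[str] = None) -> list:
    """Read the first 12 PAF columns into alignment blocks."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if target_chrom is not None and f[5] != target_chrom:
                continue
            out.append(AlignmentInterval(f[0], f[5], int(f[7]), int(f[8])))
    return out


@dataclass
class WindowCoverageResult:
    windows: pd.DataFrame  # start, end, masked, coverage, n_contigs, qualified
    fraction: float  # qualified / unmasked windows (NaN when no unmasked window)
    n_qualified: int
    n_unmasked: int

    @property
    def defined(self) -> bool:
        return self.n_unmasked > 0


def _union_length(blocks: list) -> int:
    total = 0
    last_end = None
    for s, e in sorted(blocks):
        if last_end is None or s >= last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


def window_qualification(
    alignments: Sequence[AlignmentInterval],
    chrom_length: int,
    window: int = 1_000_000,
    min_overlap: float = 0.95,
    max_contigs: int = 3,
    masks: Sequence[tuple] = (),
    chrom: Optional[str] = None,
) -> WindowCoverageResult:
    """Score fixed windows of the chromosome for assembly contiguity.

    A window overlapping any mask interval is excluded from the denominator.
    A window qualifies iff the union of alignment blocks covers at least
    ``min_overlap`` of it and at most ``max_contigs`` distinct contigs
    overlap it.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if chrom is not None:
        alignments = [a for a in alignments if a.target_chrom == chrom]
    rows = []
    n_qual = n_unmasked = 0
    for ws in range(0, chrom_length, window):
        we = min(ws + window, chrom_length)
        masked = any(ms < we and ws < me for ms, me in masks)
        blocks = []
        contigs = set()
        for a in alignments:
            s, e = max(a.target_start, ws), min(a.target_end, we)
            if s < e:
                blocks.append((s, e))
                contigs.add(a.contig)
        cov = _union_length(blocks) / (we - ws)
        qualified = (not masked) and cov >= min_overlap and len(contigs) <= max_contigs
        if not masked:
            n_unmasked += 1
            n_qual += qualified
        rows.append((ws, we, masked, cov, len(contigs), qualified))
    df = pd.DataFrame(rows, columns=["start", "end", "masked", "coverage", "n_contigs", "qualified"])
    frac = n_qual / n_unmasked if n_unmasked else float("nan")
    return WindowCoverageResult(windows=df, fraction=frac, n_qualified=n_qual, n_unmasked=n_unmasked)


# ---------------------------------------------------------------------------
# XCI skew


def read_bedmethyl(source: Union[str, pd.DataFrame]) -> pd.DataFrame:
    """Normalise a bedMethyl table to chrom/start/end/coverage/pct (pct in 0-1).

    Accepts the minimal 5-column layout (chrom, start, end, coverage,
    percent) or the modkit pileup layout (coverage in column 10, percent in
    column 11); the percent scale (0-1 vs 0-100) is auto-detected.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", header=None, comment="#")
    if df.shape[1] >= 11:
        cov_col, pct_col = 9, 10
    elif df.shape[1] >= 5:
        cov_col, pct_col = 3, 4
    else:
        raise ValueError("bedMethyl needs >= 5 columns")
    out = df.iloc[:, [0, 1, 2, cov_col, pct_col]].copy()
    out.columns = ["chrom", "start", "end", "coverage", "pct"]
    out["pct"] = out["pct"].astype(float)
    if out["pct"].max() > 1.5:
        out["pct"] /= 100.0
    return out


@dataclass(frozen=True)
class SkewResult:
    sample: str
    islands_used: int
    hap_mean_mat: float
    hap_mean_pat: float
    skew_index: float  # maternal minus paternal mean methylation
    classification: str  # balanced / skewed_maternal_inactive / skewed_paternal_inactive


def xci_skew(
    meth_mat: Union[str, pd.DataFrame],
    meth_pat: Union[str, pd.DataFrame],
    islands: Sequence[tuple],
    flank: int = 5000,
    min_cov: int = 5,
    skew_threshold: float = 0.20,
    sample: str = "",
) -> tuple:
    """Per-CpG-island haplotype methylation means and a genome-wide skew call.

    For each island ± ``flank``, the mean methylation per haplotype is taken
    over CpGs with coverage >= ``min_cov``; islands lacking a qualifying CpG
    on either haplotype are excluded (counted). The haplotype mean is the
    unweighted mean over used islands; classification compares
    ``|skew_index|`` against ``skew_threshold``.
    """
    mat = read_bedmethyl(meth_mat)
    pat = read_bedmethyl(meth_pat)
    per_hap = []
    for df in (mat, pat):
        ok = df[df["coverage"] >= min_cov].sort_values(["chrom", "start"])
        per_hap.append({c: g for c, g in ok.groupby("chrom")})

    rows = []
    for chrom, s, e in islands:
        lo, hi = max(0, s - flank), e + flank
        means = []
        ns = []
        for hap in per_hap:
            g = hap.get(chrom)
            if g is None:
                means.append(np.nan)
                ns.append(0)
                continue
            sel = g[(g["start"] >= lo) & (g["start"] < hi)]
            ns.append(len(sel))
            means.append(sel["pct"].mean() if len(sel) else np.nan)
        rows.append((chrom, s, e, means[0], means[1], min(ns)))
    per_island = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "mean_meth_maternal", "mean_meth_paternal", "n_cpg_used"]
    )
    used = per_island.dropna(subset=["mean_meth_maternal", "mean_meth_paternal"])
    used = used[used["n_cpg_used"] > 0]
    if len(used):
        hm = float(used["mean_meth_maternal"].mean())
        hp = float(used["mean_meth_paternal"].mean())
    else:
        hm = hp = float("nan")
    skew = hm - hp
    if np.isnan(skew) or abs(skew) < skew_threshold:
        cls = "balanced"
    elif skew > 0:
        cls = "skewed_maternal_inactive"
    else:
        cls = "skewed_paternal_inactive"
    return per_island, SkewResult(
        sample=sample,
        islands_used=int(len(used)),
        hap_mean_mat=hm,
        hap_mean_pat=hp,
        skew_index=float(skew),
        classification=cls,
    )
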