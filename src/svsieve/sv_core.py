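"""SV data model, VCF I/O, pairwise matching, callerset validation and cohort collapse.

The matching rule mirrors the breakpoint/size/sequence criteria used by
Truvari-style SV comparison: two records match when they share type and
chromosome, their start positions lie within ``refdist``, their size ratio
meets ``pctsize``, their sequences (insertions/deletions with explicit
sequence) meet ``pctseq`` by normalized edit similarity, and — when enabled —
their spans reciprocally overlap by ``pctovl``.

Cohort collapse merges exact connected components of the match relation
within a ``refdist``-bounded sliding window, so the row partition is
order-independent and can be checked against a brute-force all-pairs oracle.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np
import pysam
from intervaltree import IntervalTree

from .config import ABSENT, HEMI, HET, HOM, MISSING

log = logging.getLogger(__name__)

SVTYPES = ("INS", "DEL", "INV")


@dataclass
class SVRecord:
    """One structural variant call (0-based half-open coordinates).

    ``end == start`` for insertions; ``end - start == svlen`` for deletions
    and inversions. ``seq`` is the inserted sequence (INS) or the deleted
    reference sequence (DEL); absent for symbolic calls and inversions.
    """

    sv_id: str
    chrom: str
    start: int
    end: int
    svtype: str
    svlen: int
    seq: Optional[str] = None
    qual: Optional[float] = None
    source_caller: str = ""
    genotype: int = field(default=HET, compare=False)
    support: Optional[frozenset] = field(default=None, compare=False)

    def validate(self, sizemin: int = 50) -> None:
        if self.svtype not in SVTYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.end < self.start:
            raise ValueError(f"{self.sv_id}: end < start")
        if self.svtype in ("DEL", "INV") and self.end - self.start != self.svlen:
            raise ValueError(f"{self.sv_id}: span != svlen for {self.svtype}")
        if self.svlen < sizemin:
            raise ValueError(f"{self.sv_id}: svlen {self.svlen} < {sizemin}")

    @property
    def span(self) -> tuple[int, int]:
        """Reference footprint used for interval queries (min width 1)."""
        return self.start, max(self.end, self.start + 1)

    def key(self) -> tuple:
        return (self.chrom, self.start, self.svtype, self.svlen, self.seq or "")


@dataclass(frozen=True)
class MatchParams:
    """Thresholds governing when two SV records are the same allele."""

    pctseq: float = 0.90
    pctsize: float = 0.90
    pctovl: Optional[float] = None  # None disables reciprocal-overlap check
    refdist: int = 500
    sizemin: int = 50
    sizemax: int = 1_000_000

    def __post_init__(self):
        if self.sizemin > self.sizemax:
            raise ValueError("sizemin > sizemax")
        for name in ("pctseq", "pctsize"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0,1]")


@dataclass(frozen=True)
class MatchDecision:
    matched: bool
    size_similarity: float
    seq_similarity: Optional[float]
    start_distance: int
    reciprocal_overlap: Optional[float]
    seq_fallback: bool = False  # sequence unavailable; size-only comparison


def seq_similarity(a: str, b: str) -> float:
    """Normalized edit similarity: 1 - editdistance / max(len)."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    la, lb = a_end - a_start, b_end - b_start
    if la <= 0 or lb <= 0:
        return 0.0
    return min(inter / la, inter / lb)


def sv_match(a: SVRecord, b: SVRecord, p: MatchParams) -> MatchDecision:
    """Decide whether two SV records represent the same allele.

    Symmetric in (a, b). A chromosome or type mismatch is a non-match, not
    an error. Inversions are matched on size/breakpoint/overlap only; records
    lacking sequence fall back to size-only matching (flagged).
    """
    dist = abs(a.start - b.start)
    sizesim = min(a.svlen, b.svlen) / max(a.svlen, b.svlen)

    ovl: Optional[float] = None
    if p.pctovl is not None:
        if a.svtype == "INS" or b.svtype == "INS":
            ovl = 1.0 if dist <= p.refdist else 0.0
        else:
            ovl = reciprocal_overlap(*a.span, *b.span)

    ok = (
        a.svtype == b.svtype
        and a.chrom == b.chrom
        and dist <= p.refdist
        and sizesim >= p.pctsize
        and p.sizemin <= a.svlen <= p.sizemax
        and p.sizemin <= b.svlen <= p.sizemax
    )
    if ok and p.pctovl is not None and ovl is not None and ovl < p.pctovl:
        ok = False

    ssim: Optional[float] = None
    fallback = False
    if ok and p.pctseq > 0 and a.svtype != "INV":
        if a.seq and b.seq:
            ssim = seq_similarity(a.seq, b.seq)
            if ssim < p.pctseq:
                ok = False
        else:
            fallback = True  # size-only comparison for sequence-less records
    return MatchDecision(ok, sizesim, ssim, dist, ovl, fallback)


# ---------------------------------------------------------------------------
# VCF I/O


@dataclass
class CohortSVTable:
    """Nonredundant SV rows x sample genotype codes (see :mod:`svsieve.config`)."""

    rows: list
    samples: list
    genotypes: np.ndarray  # (n_rows, n_samples) int8
    support: Optional[list] = None  # per row: {sample: frozenset(callers)}

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.rows), len(self.samples)):
            raise ValueError("genotype matrix shape mismatch")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def to_callsets(self) -> dict:
        """Per-sample carrier callsets (records tagged with their genotype)."""
        out: dict[str, list[SVRecord]] = {s: [] for s in self.samples}
        for i, rec in enumerate(self.rows):
            for j, s in enumerate(self.samples):
                g = int(self.genotypes[i, j])
                if g in (HET, HOM, HEMI):
                    out[s].append(replace(rec, genotype=g))
        return out


_GT_TO_TUPLE = {
    ABSENT: (0, 0),
    HET: (0, 1),
    HOM: (1, 1),
    HEMI: (1,),
    MISSING: (None, None),
}


def _code_from_gt(alleles: tuple, alt_index: int) -> int:
    if alleles is None or all(a is None for a in alleles):
        return MISSING
    n_alt = sum(1 for a in alleles if a == alt_index)
    if len(alleles) == 1:
        return HEMI if n_alt == 1 else ABSENT
    if n_alt == 0:
        return ABSENT
    return HET if n_alt == 1 else HOM


def _infer_record(rec, alt_i: int, alt: str, sizemin: int) -> Optional[SVRecord]:
    """Build one SVRecord from one ALT of a VCF line; None if unusable."""
    info = rec.info
    svtype = None
    if "SVTYPE" in info:
        v = info["SVTYPE"]
        svtype = v[alt_i] if isinstance(v, tuple) else v
    seq = None
    svlen = None
    if alt and alt[0] != "<":
        ref = rec.ref or ""
        if len(alt) > len(ref):
            svtype = svtype or "INS"
            seq = alt[len(ref):] if alt.startswith(ref) else alt[1:]
        elif len(ref) > len(alt):
            svtype = svtype or "DEL"
            seq = ref[len(alt):] if ref.startswith(alt) else ref[1:]
        svlen = len(seq) if seq else None
    elif alt:
        svtype = svtype or alt.strip("<>").split(":")[0]
    if "SVLEN" in info:
        v = info["SVLEN"]
        if isinstance(v, tuple):
            v = v[min(alt_i, len(v) - 1)]
        svlen = abs(int(v))
    if svtype not in SVTYPES or not svlen:
        return None
    start = rec.start
    end = start if svtype == "INS" else start + svlen
    if svlen < sizemin:
        return None
    return SVRecord(
        sv_id=f"{rec.id or rec.chrom + '_' + str(rec.pos)}"
        + (f".{alt_i + 1}" if len(rec.alts or ()) > 1 else ""),
        chrom=rec.chrom,
        start=start,
        end=end,
        svtype=svtype,
        svlen=svlen,
        seq=seq,
        qual=rec.qual,
    )


def read_sv_vcf(path: str, sizemin: int = 50) -> CohortSVTable:
    """Read a (possibly multi-sample, possibly multiallelic) SV VCF.

    Multiallelic lines split into one biallelic row per ALT. Records with
    neither SVLEN nor an explicit sequence are skipped with a logged count.
    """
    rows: list[SVRecord] = []
    gts: list[list[int]] = []
    skipped = 0
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            for alt_i, alt in enumerate(rec.alts or ()):
                sv = _infer_record(rec, alt_i, alt, sizemin)
                if sv is None:
                    skipped += 1
                    continue
                rows.append(sv)
                gts.append(
                    [
                        _code_from_gt(rec.samples[s].get("GT"), alt_i + 1)
                        for s in samples
                    ]
                )
    if skipped:
        log.warning("read_sv_vcf(%s): skipped %d unusable record(s)", path, skipped)
    gt = np.array(gts, dtype=np.int8) if gts else np.zeros((0, len(samples)), np.int8)
    return CohortSVTable(rows=rows, samples=samples, genotypes=gt)


def write_sv_vcf(
    table: CohortSVTable,
    path: str,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    haploid: Optional[np.ndarray] = None,
    index: bool = False,
) -> str:
    """Write the table as a sorted VCF 4.2 (bgzipped + tabix-indexed if ``.gz``).

    ``haploid`` is an optional boolean (n_rows, n_samples) mask: emit
    single-allele GT calls (male non-PAR X / Y loci).
    """
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">')
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for t in SVTYPES:
        header.add_line(f'##ALT=<ID={t},Description="{t}">')
    lengths: dict[str, int] = dict(chrom_lengths or {})
    for rec in table.rows:
        need = rec.end + 1000
        if lengths.get(rec.chrom, 0) < need:
            lengths.setdefault(rec.chrom, 0)
            lengths[rec.chrom] = max(lengths[rec.chrom], need)
    for c in sorted(lengths):
        header.contigs.add(c, length=lengths[c])
    for s in table.samples:
        header.add_sample(s)

    order = sorted(range(table.n_rows), key=lambda i: (table.rows[i].chrom, table.rows[i].start, table.rows[i].sv_id))
    gz = path.endswith(".gz")
    with pysam.VariantFile(path, "wz" if gz else "w", header=header) as out:
        for i in order:
            sv = table.rows[i]
            if sv.seq and sv.svtype == "INS":
                alleles = ("N", "N" + sv.seq)
            elif sv.seq and sv.svtype == "DEL":
                alleles = ("N" + sv.seq, "N")
            else:
                alleles = ("N", f"<{sv.svtype}>")
            rec = out.new_record(
                contig=sv.chrom,
                start=sv.start,
                stop=max(sv.end, sv.start + 1),
                alleles=alleles,
                id=sv.sv_id,
            )
            rec.info["SVTYPE"] = sv.svtype
            rec.info["SVLEN"] = sv.svlen if sv.svtype != "DEL" else -sv.svlen
            if sv.qual is not None:
                rec.qual = sv.qual
            for j, s in enumerate(table.samples):
                code = int(table.genotypes[i, j])
                gt = _GT_TO_TUPLE[code]
                if haploid is not None and haploid[i, j] and code in (ABSENT, HEMI):
                    gt = (1,) if code == HEMI else (0,)
                rec.samples[s]["GT"] = gt
                rec.samples[s].phased = False
            out.write(rec)
    if gz and index:
        pysam.tabix_index(path, preset="vcf", force=True)
    return path


# ---------------------------------------------------------------------------
# callerset validation, blacklist, collapse


class _Window:
    """Per-(chrom, svtype) start-sorted record lists for refdist queries."""

    def __init__(self, records: Iterable[SVRecord]):
        self.by_key: dict[tuple, tuple[list[int], list[SVRecord]]] = {}
        groups: dict[tuple, list[SVRecord]] = {}
        for r in records:
            groups.setdefault((r.chrom, r.svtype), []).append(r)
        for k, recs in groups.items():
            recs.sort(key=lambda r: r.start)
            self.by_key[k] = ([r.start for r in recs], recs)

    def near(self, rec: SVRecord, refdist: int) -> list[SVRecord]:
        starts, recs = self.by_key.get((rec.chrom, rec.svtype), ([], []))
        lo = bisect_left(starts, rec.start - refdist)
        hi = bisect_right(starts, rec.start + refdist)
        return recs[lo:hi]


def validate_callersets(
    primary: Sequence[SVRecord],
    supporting: Sequence[Sequence[SVRecord]],
    p: MatchParams,
) -> list[SVRecord]:
    """Keep primary records confirmed by >=1 record in >=1 supporting callset.

    Each validated record is returned with ``support`` set to the callers
    (``source_caller`` values) that confirmed it.
    """
    if not supporting:
        raise ValueError("at least one supporting callset required")
    windows = [_Window(cs) for cs in supporting]
    out = []
    for rec in primary:
        callers = set()
        for k, w in enumerate(windows):
            for cand in w.near(rec, p.refdist):
                if sv_match(rec, cand, p).matched:
                    callers.add(cand.source_caller or f"supporting_{k}")
                    break
        if callers:
            out.append(replace(rec, support=frozenset(callers)))
    return out


def build_interval_trees(intervals: Iterable[tuple]) -> dict:
    """(chrom, start, end[, ...]) tuples -> per-chromosome IntervalTree."""
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        chrom, start, end = iv[0], int(iv[1]), int(iv[2])
        if end <= start:
            continue
        trees.setdefault(chrom, IntervalTree()).addi(start, end, iv[3:] or None)
    return trees


def exclude_blacklist(svs: Sequence[SVRecord], blacklist) -> list[SVRecord]:
    """Drop SVs whose footprint intersects any blacklist interval."""
    trees = blacklist if isinstance(blacklist, dict) else build_interval_trees(blacklist)
    kept = []
    removed = 0
    for sv in svs:
        s, e = sv.span
        t = trees.get(sv.chrom)
        if t is not None and t.overlap(s, e):
            removed += 1
        else:
            kept.append(sv)
    if removed:
        log.info("exclude_blacklist: removed %d of %d SVs", removed, len(svs))
    return kept


class UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)

    def groups(self) -> dict:
        out: dict[int, list[int]] = {}
        for i in range(len(self.parent)):
            out.setdefault(self.find(i), []).append(i)
        return out


def _mergeable(a: SVRecord, sa: str, b: SVRecord, sb: str, p: MatchParams) -> bool:
    """Match test plus the intra-sample rule: never merge two heterozygous
    calls of the same sample (they are two distinct alleles)."""
    if sa == sb and a.genotype == HET and b.genotype == HET and a is not b:
        return False
    return sv_match(a, b, p).matched


def cluster_records(entries: Sequence[tuple], p: MatchParams) -> list:
    """Connected-component labels for (SVRecord, sample) entries under the
    match relation (with the intra-sample het rule). Labels are arbitrary
    but consistent: equal label == same component."""
    idx = sorted(
        range(len(entries)),
        key=lambda i: (entries[i][0].chrom, entries[i][0].svtype, entries[i][0].start),
    )
    uf = UnionFind(len(entries))
    for a_pos, i in enumerate(idx):
        ra, sa = entries[i]
        for j in idx[a_pos + 1:]:
            rb, sb = entries[j]
            if (rb.chrom, rb.svtype) != (ra.chrom, ra.svtype) or rb.start - ra.start > p.refdist:
                break
            if _mergeable(ra, sa, rb, sb, p):
                uf.union(i, j)
    return [uf.find(i) for i in range(len(entries))]


def collapse_cohort(
    callsets: Mapping[str, Sequence[SVRecord]],
    p: MatchParams,
    keep: str = "common",
    samples: Optional[Sequence[str]] = None,
) -> CohortSVTable:
    """Merge per-sample callsets into a nonredundant cohort genotype table.

    Connected components of the match relation (within a refdist-bounded
    window on sorted starts) collapse to one representative row chosen by
    ``keep``: ``common`` (the allele carried by most samples), ``maxqual``
    (highest QUAL) or ``first`` (leftmost); ties break leftmost, then by
    lexicographic sv_id.
    """
    if keep not in ("common", "maxqual", "first"):
        raise ValueError(f"unknown keep policy {keep!r}")
    sample_order = list(samples) if samples is not None else sorted(callsets)
    for s in callsets:
        if s not in sample_order:
            raise ValueError(f"callset sample {s!r} not declared")

    entries: list[tuple[SVRecord, str]] = []
    for s, recs in callsets.items():
        entries.extend((r, s) for r in recs)
    labels = cluster_records(entries, p)
    components: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        components.setdefault(lab, []).append(i)

    rows: list[SVRecord] = []
    genotypes: list[list[int]] = []
    support: list[dict] = []
    si = {s: j for j, s in enumerate(sample_order)}
    for members in components.values():
        group = [entries[m] for m in members]
        rep = _pick_representative(group, keep)
        row_gt = [ABSENT] * len(sample_order)
        row_sup: dict[str, set] = {}
        per_sample: dict[str, list[SVRecord]] = {}
        for rec, s in group:
            per_sample.setdefault(s, []).append(rec)
        for s, recs in per_sample.items():
            best = max(recs, key=lambda r: (r.qual if r.qual is not None else float("-inf")))
            row_gt[si[s]] = best.genotype if best.genotype != MISSING else MISSING
            row_sup[s] = set()
            for r in recs:
                if r.support:
                    row_sup[s] |= set(r.support)
                elif r.source_caller:
                    row_sup[s].add(r.source_caller)
        rows.append(replace(rep, genotype=HET))
        genotypes.append(row_gt)
        support.append(row_sup)

    order = sorted(range(len(rows)), key=lambda i: (rows[i].chrom, rows[i].start, rows[i].sv_id))
    gt = (
        np.array(genotypes, dtype=np.int8)[order]
        if rows
        else np.zeros((0, len(sample_order)), np.int8)
    )
    return CohortSVTable(
        rows=[rows[i] for i in order],
        samples=sample_order,
        genotypes=gt,
        support=[support[i] for i in order],
    )


def _pick_representative(group: list, keep: str) -> SVRecord:
    def tiebreak(rec: SVRecord):
        return (rec.start, rec.sv_id)

    if keep == "first":
        return min((r for r, _ in group), key=tiebreak)
    if keep == "maxqual":
        return min(
            (r for r, _ in group),
            key=lambda r: (-(r.qual if r.qual is not None else float("-inf")),) + tiebreak(r),
        )
    # common: allele identity carried by the most samples
    carriers: dict[tuple, set] = {}
    first_rec: dict[tuple, SVRecord] = {}
    for rec, s in group:
        k = rec.key()
        carriers.setdefault(k, set()).add(s)
        if k not in first_rec or tiebreak(rec) < tiebreak(first_rec[k]):
            first_rec[k] = rec
    best_key = min(carriers, key=lambda k: (-len(carriers[k]),) + tiebreak(first_rec[k]))
    return first_rec[best_key]


def redundant_pairs(table: CohortSVTable, p: MatchParams) -> list:
    """All row pairs that still match under ``p`` (nonredundancy check)."""
    pairs = []
    w = _Window(table.rows)
    seen = set()
    for i, rec in enumerate(table.rows):
        for cand in w.near(rec, p.refdist):
            if cand is rec:
                continue
            key = tuple(sorted((rec.sv_id, cand.sv_id)))
            if key in seen:
                continue
            seen.add(key)
            if sv_match(rec, cand, p).matched:
                pairs.append((rec, cand))
    return pairs
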