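"""Evidence cascade for Mendelian-discordant (low-confidence) rare SV calls.

A child call that deviates from Mendelian expectation is usually either a
true de novo event or a parental dropout (the parent carries the allele but
the validated callset missed it). The cascade re-examines each call with
progressively cheaper-to-trust evidence, in a fixed order; the first decisive
step wins:

1. parental raw-callset match (relaxed matching against pre-validation calls)
2. re-genotyping consistency across the family
3. parental read support (>= ``min_reads`` reads within the size-deviation cap)
4. tandem-repeat allele-length outlier scan

Anything still undecided is exported for manual review, never guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import ABSENT, CARRIER_CODES, MISSING
from .rare_filter import mendelian_classify
from .sv_core import MatchParams, SVRecord, _Window, sv_match

RELAXED_PARENT_MATCH = MatchParams(pctseq=0.9, pctsize=0.9, refdist=500)

STATUSES = ("TRANSMITTED_CONFIRMED", "DENOVO_CONFIRMED", "UNRESOLVED_MANUAL")
STEPS = ("parental_match", "regenotype", "read_support", "tr_outlier", "none")


@dataclass
class EvidenceBundle:
    """Precomputed evidence tables consumed by the cascade.

    read_support maps (sample, sv_id) -> list of (size deviation fraction,
    read count); a key that is present with an empty list means the sample
    was queried and no supporting read was found.
    """

    parental_raw_callsets: Mapping[str, Sequence[SVRecord]] = field(default_factory=dict)
    read_support: Mapping[tuple, list] = field(default_factory=dict)
    allele_lengths: Mapping[tuple, tuple] = field(default_factory=dict)  # (sample, tr_locus) -> (a1, a2)
    regenotype_calls: Mapping[tuple, int] = field(default_factory=dict)  # (sample, sv_id) -> genotype code
    sv_quality: Mapping[str, float] = field(default_factory=dict)  # optional external per-SV quality


@dataclass(frozen=True)
class CurationVerdict:
    sv_id: str
    child: str
    status: str
    deciding_step: str

    def __post_init__(self):
        if (self.deciding_step == "none") != (self.status == "UNRESOLVED_MANUAL"):
            raise ValueError("deciding_step == none iff status == UNRESOLVED_MANUAL")


def parental_support_match(
    child_sv: SVRecord,
    parental_raw_callsets: Mapping[str, Sequence[SVRecord]],
    relaxed: MatchParams = RELAXED_PARENT_MATCH,
) -> set:
    """Parents whose raw (pre-validation) callsets contain a match."""
    hits = set()
    for parent, callset in parental_raw_callsets.items():
        for cand in _Window(callset).near(child_sv, relaxed.refdist):
            if sv_match(child_sv, cand, relaxed).matched:
                hits.add(parent)
                break
    return hits


def regenotype_consistency(
    child_sv: SVRecord,
    child: str,
    parents: tuple,
    regenotype_calls: Mapping[tuple, int],
    cc: str = "AUTO",
    child_sex: str = "F",
) -> Optional[bool]:
    """True/False when re-genotyped calls exist for the whole family
    (child consistent with parents under Mendelian rules); None when any
    member lacks a re-genotyped call (step skipped)."""
    fa, mo = parents
    calls = [regenotype_calls.get((s, child_sv.sv_id)) for s in (child, fa, mo)]
    if any(c is None for c in calls):
        return None
    cg, fg, mg = calls
    return mendelian_classify(cg, fg, mg, cc, child_sex) == "HC"


def read_support_check(
    sv: SVRecord,
    support_entries: Optional[list],
    size_dev_max: float = 0.5,
    min_reads: int = 1,
) -> Optional[bool]:
    """Supported iff >= ``min_reads`` reads deviate by <= ``size_dev_max``
    from the SV size, counted in a dynamic window of max(svlen, 500) bp
    around the breakpoint. None when the sample was never queried."""
    if support_entries is None:
        return None
    n = sum(count for dev, count in support_entries if dev <= size_dev_max)
    return n >= min_reads


def tr_outlier_scan(
    allele_lengths: Mapping[tuple, tuple],
    ped,
    z_thresh: float = 3.0,
    require_max: bool = True,
    min_population: int = 20,
) -> pd.DataFrame:
    """Scan tandem-repeat allele lengths for child expansion outliers.

    For each child the population distribution is built from control alleles
    and the alleles of parents OUTSIDE the child's own family (the candidate
    transmitting parent must not mask the expansion). A child allele is an
    expansion outlier iff it exceeds population mean + z_thresh * SD and
    (when ``require_max``) the maximum control allele. The origin is the
    family parent whose matching allele is within 10% of the child's outlier
    allele; "denovo" when no parent carries a matching length.
    """
    loci = sorted({locus for (_, locus) in allele_lengths})
    children = set(ped.children)
    family_of = {}
    for fid, members in ped.families:
        for m in members:
            family_of[m.sample_id] = fid
    out = []
    for locus in loci:
        by_sample = {
            s: pair for (s, loc), pair in allele_lengths.items() if loc == locus
        }
        ctrl_alleles = [
            al for s in ped.control_ids for al in by_sample.get(s, ()) if al is not None
        ]
        for child in sorted(children):
            pair = by_sample.get(child)
            if pair is None:
                continue
            fam = family_of[child]
            pop_samples = [
                s for s in list(ped.control_ids) + list(ped.parent_ids)
                if s in by_sample and family_of.get(s) != fam
            ]
            if len(pop_samples) < min_population:
                continue
            pop = np.asarray(
                [al for s in pop_samples for al in by_sample[s] if al is not None], float
            )
            sd = pop.std(ddof=1)
            if sd == 0:
                continue  # zero variance: no outlier call possible
            cutoff = pop.mean() + z_thresh * sd
            pop_max = max(ctrl_alleles) if ctrl_alleles else pop.max()
            for al in pair:
                if al is None or al <= cutoff or (require_max and al <= pop_max):
                    continue
                fa, mo = ped.parents_of(child)
                origin = "denovo"
                best = None
                for parent, label in ((fa, "father"), (mo, "mother")):
                    ppair = allele_lengths.get((parent, locus))
                    if not ppair:
                        continue
                    for pal in ppair:
                        if pal is None or pal == 0:
                            continue
                        rel = abs(pal - al) / max(pal, al)
                        if rel <= 0.10 and (best is None or rel < best[0]):
                            best = (rel, label)
                if best is not None:
                    origin = best[1]
                out.append(
                    {
                        "locus": locus,
                        "child": child,
                        "allele_length": al,
                        "pop_mean": pop.mean(),
                        "pop_sd": sd,
                        "pop_max": pop_max,
                        "origin": origin,
                    }
                )
    return pd.DataFrame(
        out,
        columns=["locus", "child", "allele_length", "pop_mean", "pop_sd", "pop_max", "origin"],
    )


DEFAULT_STEPS = ("parental_match", "regenotype", "read_support", "tr_outlier")


def curate(
    unresolved: pd.DataFrame,
    evidence: EvidenceBundle,
    ped,
    sv_records: Mapping[str, SVRecord],
    steps: Sequence[str] = DEFAULT_STEPS,
    relaxed: MatchParams = RELAXED_PARENT_MATCH,
    tr_loci_by_sv: Optional[Mapping[str, str]] = None,
    size_dev_max: float = 0.5,
    min_reads: int = 1,
) -> list:
    """Run the ordered evidence cascade over UNRESOLVED rare-table entries.

    ``unresolved`` needs sv_id/child/genotype/chrom_class columns. The first
    decisive step wins; rows no step can decide come back UNRESOLVED_MANUAL.
    """
    tr_outliers = None
    sexes = ped.sexes
    verdicts = []
    for e in unresolved.itertuples():
        sv = sv_records[e.sv_id]
        fa, mo = ped.parents_of(e.child)
        status, step = None, None
        for s in steps:
            if s == "parental_match":
                family_raw = {
                    p: evidence.parental_raw_callsets[p]
                    for p in (fa, mo)
                    if p in evidence.parental_raw_callsets
                }
                if family_raw and parental_support_match(sv, family_raw, relaxed):
                    status, step = "TRANSMITTED_CONFIRMED", s
            elif s == "regenotype":
                ok = regenotype_consistency(
                    sv, e.child, (fa, mo), evidence.regenotype_calls,
                    getattr(e, "chrom_class", "AUTO"), sexes[e.child],
                )
                if ok is not None:
                    fg = evidence.regenotype_calls[(fa, sv.sv_id)]
                    mg = evidence.regenotype_calls[(mo, sv.sv_id)]
                    cg = evidence.regenotype_calls[(e.child, sv.sv_id)]
                    if ok and (fg in CARRIER_CODES or mg in CARRIER_CODES):
                        status, step = "TRANSMITTED_CONFIRMED", s
                    elif fg == ABSENT and mg == ABSENT and cg in CARRIER_CODES:
                        # re-genotyping confirms the parents are reference
                        status, step = "DENOVO_CONFIRMED", s
            elif s == "read_support":
                sup = [
                    read_support_check(
                        sv, evidence.read_support.get((p, sv.sv_id)), size_dev_max, min_reads
                    )
                    for p in (fa, mo)
                ]
                if any(x is True for x in sup):
                    status, step = "TRANSMITTED_CONFIRMED", s
                elif all(x is False for x in sup):
                    status, step = "DENOVO_CONFIRMED", s
            elif s == "tr_outlier":
                if tr_loci_by_sv and e.sv_id in tr_loci_by_sv and evidence.allele_lengths:
                    if tr_outliers is None:
                        tr_outliers = tr_outlier_scan(evidence.allele_lengths, ped)
                    locus = tr_loci_by_sv[e.sv_id]
                    hit = tr_outliers[
                        (tr_outliers["locus"] == locus) & (tr_outliers["child"] == e.child)
                    ]
                    if len(hit):
                        origin = hit.iloc[0]["origin"]
                        status = (
                            "DENOVO_CONFIRMED" if origin == "denovo" else "TRANSMITTED_CONFIRMED"
                        )
                        step = s
            else:
                raise ValueError(f"unknown curation step {s!r}")
            if status is not None:
                break
        if status is None:
            status, step = "UNRESOLVED_MANUAL", "none"
        verdicts.append(CurationVerdict(e.sv_id, e.child, status, step))
    return verdicts


def review_sheet(verdicts: Sequence[CurationVerdict], path=None) -> pd.DataFrame:
    """Tab-separated export of calls still requiring manual inspection."""
    df = pd.DataFrame(
        [
            {"sv_id": v.sv_id, "child": v.child, "status": v.status, "deciding_step": v.deciding_step}
            for v in verdicts
            if v.status == "UNRESOLVED_MANUAL"
        ],
        columns=["sv_id", "child", "status", "deciding_step"],
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
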