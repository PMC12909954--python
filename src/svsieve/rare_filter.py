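"""Pangenome-control filtering, zygosity categories, Mendelian confidence,
variant-origin classes, MAF, discovery curves and MAF-capture estimation.

"Rare" here means: carried by at least one child of the cohort and absent
from every population control in the merged nonredundant table — with the
sex-chromosome refinement that a child's X/Y variant is only compared
against controls of the same sex. Origin classes follow the trio logic of
rare-variant studies: de novo (both parents reference), private inherited
(the allele is seen in exactly one parent across the whole parental
population), and private biallelic homozygous (child homozygous, inherited
from two heterozygous parents, family-unique among parents).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import (
    ABSENT,
    CARRIER_CODES,
    DEFAULT_PAR,
    FEMALE,
    HEMI,
    HET,
    HOM,
    MALE,
    MISSING,
    dosage,
    in_par,
    is_x,
    is_y,
)
from .sv_core import CohortSVTable, MatchParams, SVRecord, _Window, cluster_records, sv_match

log = logging.getLogger(__name__)

CATEGORIES = ("AUTO_HET", "AUTO_HOM", "X_HET", "X_HOM", "X_HEMI", "Y_HEMI")
ORIGINS = ("DENOVO", "PRIVATE_INHERITED", "PRIVATE_BIALLELIC_HOM", "INHERITED_OTHER", "UNRESOLVED")


def chrom_class(chrom: str, pos: int, par=DEFAULT_PAR) -> str:
    """AUTO / X / Y; pseudoautosomal loci count as AUTO."""
    if in_par(chrom, pos, par):
        return "AUTO"
    if is_x(chrom):
        return "X"
    if is_y(chrom):
        return "Y"
    return "AUTO"


@dataclass
class RareSVTable:
    """One entry per (SV row, carrier child) pair surviving control filtering."""

    table: CohortSVTable
    entries: pd.DataFrame  # sv_id,row,child,genotype,chrom_class,category,confidence,origin

    def __len__(self) -> int:
        return len(self.entries)

    def per_child_counts(self) -> pd.Series:
        return self.entries.groupby("child").size()

    def record(self, row: int) -> SVRecord:
        return self.table.rows[row]

    def to_tsv(self, path) -> str:
        self.entries.to_csv(path, sep="\t", index=False)
        return str(path)


def pangenome_filter(
    table: CohortSVTable,
    children: Sequence[str],
    controls: Sequence[str],
    sexes: Mapping[str, str],
    par=DEFAULT_PAR,
) -> RareSVTable:
    """Keep (row, child) carrier pairs with no control carrier.

    Autosomal (and PAR) rows are compared against all controls; non-PAR X/Y
    rows only against controls of the carrier child's sex.
    """
    for s in itertools.chain(children, controls):
        if s not in table.samples:
            raise ValueError(f"sample {s!r} not in table columns")
    ci = [table.sample_index(s) for s in children]
    ki = [table.sample_index(s) for s in controls]
    gt = table.genotypes
    child_carrier = np.isin(gt[:, ci], CARRIER_CODES)
    ctrl_carrier = np.isin(gt[:, ki], CARRIER_CODES)
    ctrl_sex = np.array([sexes[s] for s in controls])

    removed = {"AUTO": 0, "X": 0, "Y": 0}
    recs = []
    for i, rec in enumerate(table.rows):
        cc = chrom_class(rec.chrom, rec.start, par)
        carriers = np.nonzero(child_carrier[i])[0]
        for j in carriers:
            child = children[j]
            if cc == "AUTO":
                hit = ctrl_carrier[i].any()
            else:
                hit = ctrl_carrier[i][ctrl_sex == sexes[child]].any()
            if hit:
                removed[cc] += 1
            else:
                recs.append(
                    (rec.sv_id, i, child, int(gt[i, table.sample_index(child)]), cc)
                )
    log.info("pangenome_filter: removed carrier pairs per class: %s", removed)
    entries = pd.DataFrame(
        recs, columns=["sv_id", "row", "child", "genotype", "chrom_class"]
    )
    for col in ("category", "confidence", "origin"):
        entries[col] = pd.Series([None] * len(entries), dtype=object)
    return RareSVTable(table=table, entries=entries)


# ---------------------------------------------------------------------------
# zygosity categories


def zygosity_category(cc: str, sex: str, genotype: int) -> tuple:
    """(category, flag); flag notes a sex/zygosity inconsistency."""
    if cc == "AUTO":
        return ("AUTO_HOM" if genotype == HOM else "AUTO_HET"), None
    if cc == "Y":
        return "Y_HEMI", (None if sex == MALE and genotype == HEMI else "y_inconsistent")
    # X non-PAR
    if sex == MALE:
        flag = None if genotype == HEMI else "male_x_diploid_genotype"
        return "X_HEMI", flag
    return ("X_HOM" if genotype == HOM else "X_HET"), None


def classify_zygosity_categories(rare: RareSVTable, sexes: Mapping[str, str]) -> dict:
    """Label every entry with one of the six categories.

    Returns both tallies: per carrier pair and per unique SV (an SV carried
    by several children counts once per category it realises).
    """
    cats, flags = [], []
    for e in rare.entries.itertuples():
        cat, flag = zygosity_category(e.chrom_class, sexes[e.child], e.genotype)
        cats.append(cat)
        flags.append(flag)
    rare.entries["category"] = cats
    n_flagged = sum(f is not None for f in flags)
    if n_flagged:
        log.warning("classify_zygosity_categories: %d inconsistent genotype(s) flagged", n_flagged)
    pair_counts = rare.entries.groupby("category").size().to_dict()
    uniq = rare.entries.drop_duplicates(["sv_id", "category"])
    unique_counts = uniq.groupby("category").size().to_dict()
    return {
        "pair_counts": {c: pair_counts.get(c, 0) for c in CATEGORIES},
        "unique_counts": {c: unique_counts.get(c, 0) for c in CATEGORIES},
        "flags": flags,
    }


# ---------------------------------------------------------------------------
# Mendelian confidence


def _alleles(gt: int) -> Optional[frozenset]:
    """Transmittable allele set for a parental genotype; None when missing."""
    if gt == MISSING:
        return None
    if gt == ABSENT:
        return frozenset({0})
    if gt == HET:
        return frozenset({0, 1})
    return frozenset({1})  # HOM or HEMI


def mendelian_classify(
    child_gt: int,
    father_gt: int,
    mother_gt: int,
    cc: str = "AUTO",
    child_sex: str = FEMALE,
) -> str:
    """HC iff the child genotype is producible from the parents (sex-aware)."""
    fa, mo = _alleles(father_gt), _alleles(mother_gt)
    if child_gt == MISSING:
        return "LC"
    want = dosage(child_gt)
    if cc == "Y":
        # only the father transmits; the mother has no Y (structurally missing)
        if child_sex != MALE or fa is None:
            return "LC"
        return "HC" if want in fa else "LC"
    if cc == "X" and child_sex == MALE:
        # sons receive their X from the mother only
        if mo is None:
            return "LC"
        return "HC" if want in mo else "LC"
    # diploid: autosome, PAR, or female X
    if fa is None or mo is None:
        return "LC"
    producible = {f + m for f in fa for m in mo}
    return "HC" if want in producible else "LC"


def mendelian_classify_table(rare: RareSVTable, ped) -> float:
    """Fill the confidence column; return cohort concordance HC/(HC+LC)."""
    table = rare.table
    si = {s: i for i, s in enumerate(table.samples)}
    conf = []
    sexes = ped.sexes
    for e in rare.entries.itertuples():
        fa_id, mo_id = ped.parents_of(e.child)
        fgt = int(table.genotypes[e.row, si[fa_id]]) if fa_id in si else MISSING
        mgt = int(table.genotypes[e.row, si[mo_id]]) if mo_id in si else MISSING
        conf.append(mendelian_classify(e.genotype, fgt, mgt, e.chrom_class, sexes[e.child]))
    rare.entries["confidence"] = conf
    n_hc = sum(c == "HC" for c in conf)
    return n_hc / len(conf) if conf else float("nan")


# ---------------------------------------------------------------------------
# origin classes


def classify_variant_origin(rare: RareSVTable, ped) -> pd.Series:
    """Assign DENOVO / PRIVATE_INHERITED / PRIVATE_BIALLELIC_HOM /
    INHERITED_OTHER to HC entries (LC entries become UNRESOLVED).

    "Private" counts the transmitting parent: the allele is observed exactly
    once among ALL parents of the cohort.
    """
    table = rare.table
    si = {s: i for i, s in enumerate(table.samples)}
    parent_cols = [si[p] for p in ped.parent_ids if p in si]
    pgt = table.genotypes[:, parent_cols]
    parent_allele_count = np.array([sum(dosage(int(g)) for g in row) for row in pgt])
    parent_carrier_n = np.isin(pgt, CARRIER_CODES).sum(axis=1)

    sexes = ped.sexes
    origins = []
    for e in rare.entries.itertuples():
        fa_id, mo_id = ped.parents_of(e.child)
        fgt = int(table.genotypes[e.row, si[fa_id]])
        mgt = int(table.genotypes[e.row, si[mo_id]])
        # transmitting parents for this locus/child (sex-aware)
        if e.chrom_class == "Y" and sexes[e.child] == MALE:
            transmitting = (fgt,)
        elif e.chrom_class == "X" and sexes[e.child] == MALE:
            transmitting = (mgt,)
        else:
            transmitting = (fgt, mgt)
        # the de novo pattern is recognised before the LC gate: a true de novo
        # is by definition Mendelian-discordant
        if (
            all(g == ABSENT for g in transmitting)
            and fgt not in CARRIER_CODES
            and mgt not in CARRIER_CODES
        ):
            origins.append("DENOVO")
            continue
        if e.confidence == "LC":
            origins.append("UNRESOLVED")
            continue
        if (
            e.genotype == HOM
            and fgt == HET
            and mgt == HET
            and parent_carrier_n[e.row] == 2
        ):
            origins.append("PRIVATE_BIALLELIC_HOM")
        elif parent_allele_count[e.row] == 1 and dosage(fgt) + dosage(mgt) == 1:
            origins.append("PRIVATE_INHERITED")
        else:
            origins.append("INHERITED_OTHER")
    rare.entries["origin"] = origins
    return rare.entries["origin"]


def denovo_recovery(rare: RareSVTable, truth) -> dict:
    """Sensitivity/precision of the DENOVO calls against the simulator truth."""
    called = {
        (e.child, e.sv_id)
        for e in rare.entries.itertuples()
        if e.origin == "DENOVO"
    }
    true = {
        (child, lid)
        for child, lids in truth.denovo_events.items()
        for lid in lids
    }
    tp = len(called & true)
    sens = tp / len(true) if true else float("nan")
    prec = tp / len(called) if called else float("nan")
    return {
        "sensitivity": sens,
        "precision": prec,
        "n_true": len(true),
        "n_called": len(called),
        "false_positives": len(called - true),
    }


# ---------------------------------------------------------------------------
# MAF


def compute_maf(
    table: CohortSVTable,
    sexes: Mapping[str, str],
    par=DEFAULT_PAR,
) -> pd.DataFrame:
    """Folded minor allele frequency per row; hemizygous samples count one
    allele, diploid two; missing genotypes are excluded from the
    denominator."""
    from .config import ploidy as _ploidy

    out = []
    for i, rec in enumerate(table.rows):
        ac = an = 0
        for j, s in enumerate(table.samples):
            g = int(table.genotypes[i, j])
            if g == MISSING:
                continue
            pl = _ploidy(rec.chrom, rec.start, sexes.get(s, FEMALE), par)
            if pl == 0:
                continue
            an += pl
            ac += min(dosage(g), pl)
        f = ac / an if an else float("nan")
        out.append((rec.sv_id, ac, an, min(f, 1.0 - f) if an else float("nan")))
    return pd.DataFrame(out, columns=["sv_id", "allele_count", "allele_number", "maf"])


# ---------------------------------------------------------------------------
# discovery curves & MAF capture


def discovery_curve(
    callsets: Mapping[str, Sequence[SVRecord]],
    strata: Mapping[str, str],
    n_perm: int,
    p: MatchParams,
    seed: int = 0,
) -> dict:
    """Per-stratum cumulative nonredundant SV counts over random sample
    orderings (mean and min-max band across permutations)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    entries = [(r, s) for s, recs in callsets.items() for r in recs]
    labels = cluster_records(entries, p)
    clusters_by_sample: dict[str, set] = {s: set() for s in callsets}
    for (rec, s), lab in zip(entries, labels):
        clusters_by_sample[s].add(lab)

    rng = np.random.default_rng(seed)
    result = {}
    for stratum in sorted(set(strata.values())):
        members = [s for s in callsets if strata.get(s) == stratum]
        curves = np.zeros((n_perm, len(members)), dtype=np.int64)
        for k in range(n_perm):
            order = rng.permutation(len(members))
            seen: set = set()
            for x, oi in enumerate(order):
                seen |= clusters_by_sample[members[oi]]
                curves[k, x] = len(seen)
        result[stratum] = pd.DataFrame(
            {
                "n_samples": np.arange(1, len(members) + 1),
                "mean": curves.mean(axis=0),
                "min": curves.min(axis=0),
                "max": curves.max(axis=0),
            }
        )
    return result


def maf_capture(
    small_table: CohortSVTable,
    large_table: CohortSVTable,
    maf_bins: Sequence[float],
    p: MatchParams,
    sexes: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Fraction of large-panel SVs matched by any small-panel SV, per MAF bin
    (MAF computed on the large panel)."""
    sexes = sexes or {s: FEMALE for s in large_table.samples}
    maf = compute_maf(large_table, sexes)["maf"].to_numpy()
    window = _Window(small_table.rows)
    captured = np.zeros(large_table.n_rows, bool)
    for i, rec in enumerate(large_table.rows):
        for cand in window.near(rec, p.refdist):
            if sv_match(rec, cand, p).matched:
                captured[i] = True
                break
    bins = pd.cut(maf, bins=list(maf_bins), include_lowest=True, right=True)
    df = pd.DataFrame({"bin": bins, "captured": captured, "maf": maf})
    g = df.groupby("bin", observed=False)
    return pd.DataFrame(
        {
            "bin": [str(b) for b in g.size().index],
            "n": g.size().to_numpy(),
            "captured": g["captured"].sum().to_numpy(),
            "fraction": g["captured"].mean().to_numpy(),
        }
    )
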