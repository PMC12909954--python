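"""Interval-based functional annotation of rare SVs and candidate prioritization.

Annotation uses any-overlap (>=1 bp) semantics; insertions are intersected as
a point at the insertion coordinate. Functional classes partition the SV set
with precedence EXON > INTRON > INTER, where EXON includes UTR overlap.
Candidate rules follow the usual rare-disease triage: de novo events hitting
coding or regulatory sequence of risk genes, private biallelic homozygotes in
risk genes or brain regulatory DNA, and any rare SV in constrained
(Gnocchi >= 4) promoter sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .sv_core import SVRecord, build_interval_trees

SOURCE_CLASSES = (
    "REG_ENCODE",
    "REG_BRAIN",
    "TF_CLUSTER",
    "TR_CATALOG",
    "GNOCCHI",
    "PROMOTER",
    "BLACKLIST",
    "OTHER",
)

FUNCTIONAL_CLASSES = ("EXON", "INTRON", "INTER")


@dataclass
class AnnotationTrack:
    """A named, labeled interval set (0-based half-open)."""

    name: str
    source_class: str
    intervals: list  # (chrom, start, end[, value, label])

    def __post_init__(self):
        if self.source_class not in SOURCE_CLASSES:
            raise ValueError(f"unknown source_class {self.source_class!r}")
        self._trees = None

    @property
    def trees(self) -> dict:
        if self._trees is None:
            self._trees = build_interval_trees(self.intervals)
        return self._trees

    @classmethod
    def from_bed(cls, path, name: str, source_class: str, value_col: Optional[int] = None):
        ivs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.rstrip("\n").split("\t")
                iv = [f[0], int(f[1]), int(f[2])]
                if value_col is not None and len(f) > value_col:
                    iv.append(float(f[value_col]))
                ivs.append(tuple(iv))
        return cls(name=name, source_class=source_class, intervals=ivs)


@dataclass
class Gene:
    name: str
    chrom: str
    start: int
    end: int
    exons: list = field(default_factory=list)  # [(start, end)]
    utrs: list = field(default_factory=list)
    ndd: bool = False
    sfari_score: Optional[int] = None
    pli: Optional[float] = None

    @property
    def is_risk(self) -> bool:
        return self.ndd or self.sfari_score is not None


@dataclass
class GeneModel:
    genes: list

    def __post_init__(self):
        self._span_trees: dict[str, IntervalTree] = {}
        self._exon_trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            self._span_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, max(g.end, g.start + 1), g)
            for s, e in list(g.exons) + list(g.utrs):
                self._exon_trees.setdefault(g.chrom, IntervalTree()).addi(s, max(e, s + 1), g)

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list:
        t = self._span_trees.get(chrom)
        return sorted({iv.data.name for iv in t.overlap(start, end)}) if t else []

    def exonic_genes(self, chrom: str, start: int, end: int) -> list:
        t = self._exon_trees.get(chrom)
        return sorted({iv.data.name for iv in t.overlap(start, end)}) if t else []

    def by_name(self) -> dict:
        return {g.name: g for g in self.genes}

    def risk_genes_near(self, chrom: str, start: int, end: int, flank: int) -> list:
        t = self._span_trees.get(chrom)
        if t is None:
            return []
        hits = t.overlap(max(0, start - flank), end + flank)
        return sorted({iv.data.name for iv in hits if iv.data.is_risk})


def _footprint(sv: SVRecord) -> tuple:
    if sv.svtype == "INS":
        return sv.start, sv.start + 1
    return sv.span


def intersect_tracks(
    svs: Sequence[SVRecord],
    tracks: Iterable[AnnotationTrack],
) -> pd.DataFrame:
    """Per-SV boolean flag per track, plus max Gnocchi score over overlapped
    score intervals (NaN when no overlap)."""
    tracks = list(tracks)
    out: dict = {"sv_id": [sv.sv_id for sv in svs]}
    flags = {t.name: np.zeros(len(svs), bool) for t in tracks}
    gmax = np.full(len(svs), np.nan)
    for i, sv in enumerate(svs):
        s, e = _footprint(sv)
        for t in tracks:
            tree = t.trees.get(sv.chrom)
            if tree is None:
                continue
            hits = tree.overlap(s, e)
            if hits:
                flags[t.name][i] = True
                if t.source_class == "GNOCCHI":
                    vals = [h.data[0] for h in hits if h.data]
                    if vals:
                        gmax[i] = max(vals) if np.isnan(gmax[i]) else max(gmax[i], *vals)
    out.update(flags)
    out["gnocchi_max"] = gmax
    return pd.DataFrame(out)


def functional_category(sv: SVRecord, gene_model: GeneModel) -> str:
    """EXON (incl. UTR) > INTRON (within a gene span) > INTER."""
    s, e = _footprint(sv)
    if gene_model.exonic_genes(sv.chrom, s, e):
        return "EXON"
    if gene_model.genes_overlapping(sv.chrom, s, e):
        return "INTRON"
    return "INTER"


def annotate_svs(
    svs: Sequence[SVRecord],
    tracks: Iterable[AnnotationTrack],
    gene_model: GeneModel,
    risk_flank: int = 50_000,
) -> pd.DataFrame:
    """Full annotation table: functional class, per-class flags, gene links.

    ``REG`` is the union of ENCODE-style regulatory tracks; ``brainREG`` the
    union of brain-derived tracks; ``near_risk_gene`` means within
    ``risk_flank`` bp of an NDD/SFARI-flagged gene span.
    """
    tracks = list(tracks)
    flag_table = intersect_tracks(svs, tracks)
    by_class: dict[str, list] = {}
    for t in tracks:
        by_class.setdefault(t.source_class, []).append(t.name)

    def class_flag(cls: str) -> np.ndarray:
        names = by_class.get(cls, [])
        if not names:
            return np.zeros(len(svs), bool)
        return np.logical_or.reduce([flag_table[n].to_numpy() for n in names])

    genes_by_name = gene_model.by_name()
    rows = []
    for sv in svs:
        s, e = _footprint(sv)
        fclass = functional_category(sv, gene_model)
        overlapping = gene_model.genes_overlapping(sv.chrom, s, e)
        exonic = gene_model.exonic_genes(sv.chrom, s, e)
        rows.append(
            {
                "functional_class": fclass,
                "genes": ";".join(overlapping),
                "NDD_gene": any(genes_by_name[g].ndd for g in overlapping),
                "SFARI_gene": any(genes_by_name[g].sfari_score is not None for g in overlapping),
                "exon_ndd": any(genes_by_name[g].ndd for g in exonic),
                "exon_sfari": any(genes_by_name[g].sfari_score is not None for g in exonic),
                "near_risk_gene": bool(gene_model.risk_genes_near(sv.chrom, s, e, risk_flank)),
            }
        )
    ann = pd.concat([flag_table, pd.DataFrame(rows)], axis=1)
    ann["REG"] = class_flag("REG_ENCODE")
    ann["brainREG"] = class_flag("REG_BRAIN")
    ann["TF"] = class_flag("TF_CLUSTER")
    ann["promoter"] = class_flag("PROMOTER")
    ann["TR"] = class_flag("TR_CATALOG")
    return ann


def annotation_gain(
    base_flags: Sequence[bool],
    added_flags: Sequence[bool],
) -> tuple:
    """(n_base, n_added_only, percent_increase to nearest integer).

    ``n_added_only`` counts items flagged by the added class but not the
    base class; the percentage is relative to the base count.
    """
    base = np.asarray(base_flags, bool)
    added = np.asarray(added_flags, bool)
    n_base = int(base.sum())
    n_added_only = int((added & ~base).sum())
    if n_base == 0:
        return n_base, n_added_only, float("nan")
    pct = int(np.floor(100.0 * n_added_only / n_base + 0.5))  # round half-up
    return n_base, n_added_only, pct


def prioritize(
    entries: pd.DataFrame,
    annotations: pd.DataFrame,
    gnocchi_min: float = 4.0,
) -> pd.DataFrame:
    """Rank rare SV x child entries under three rule groups.

    A: de novo AND (exonic in an NDD gene OR regulatory (REG/brainREG/TF)
       near a risk gene);
    B: private biallelic homozygous AND (SFARI gene OR REG/brainREG);
    C: any rare SV with max Gnocchi >= ``gnocchi_min`` AND a promoter overlap.

    ``entries`` needs sv_id/child/origin columns; ``annotations`` is keyed by
    sv_id. Every candidate carries its rule trail.
    """
    ann = annotations.set_index("sv_id")
    out = []
    for e in entries.itertuples():
        if e.sv_id not in ann.index:
            continue
        a = ann.loc[e.sv_id]
        reg_any = bool(a["REG"] or a["brainREG"] or a["TF"])
        rules = []
        if e.origin == "DENOVO":
            if a["functional_class"] == "EXON" and a["exon_ndd"]:
                rules.append("A:denovo_exon_ndd")
            elif reg_any and a["near_risk_gene"]:
                rules.append("A:denovo_regulatory_near_risk_gene")
        if e.origin == "PRIVATE_BIALLELIC_HOM" and (
            a["SFARI_gene"] or a["REG"] or a["brainREG"]
        ):
            rules.append("B:biallelic_hom_risk")
        if (
            not np.isnan(a["gnocchi_max"])
            and a["gnocchi_max"] >= gnocchi_min
            and a["promoter"]
        ):
            rules.append("C:constrained_promoter")
        if rules:
            out.append(
                {
                    "sv_id": e.sv_id,
                    "child": e.child,
                    "origin": e.origin,
                    "functional_class": a["functional_class"],
                    "genes": a["genes"],
                    "rules": ";".join(rules),
                    "rule_group": rules[0].split(":")[0],
                }
            )
    cols = ["sv_id", "child", "origin", "functional_class", "genes", "rules", "rule_group"]
    df = pd.DataFrame(out, columns=cols)
    return df.sort_values(["rule_group", "sv_id", "child"]).reset_index(drop=True)
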