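"""Fixture generators: annotation tracks, read support, TR allele lengths,
assembly-alignment PAFs and haplotype methylation (all seed-deterministic).

These generators emit the side evidence the pipeline consumes — BED tracks,
per-sample read-support and tandem-repeat allele-length tables consistent
with the simulated true genotypes, PAF alignment blocks with configurable
window gaps, and per-female bedMethyl pairs whose island methylation is
binomial around the haplotype mean implied by the X-inactivation skew.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotationTrack, Gene, GeneModel
from .config import CARRIER_CODES, FEMALE
from .sv_core import SVRecord

#: bulk methylation level of CpG islands on the inactive / active X
METH_INACTIVE = 0.80
METH_ACTIVE = 0.10


def write_bed(intervals: Sequence[tuple], path) -> str:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")
    return str(path)


def simulate_gene_model(
    chrom_lengths: Mapping[str, int],
    rng: np.random.Generator,
    gene_spacing: int = 500_000,
    gene_length: int = 100_000,
    ndd_fraction: float = 0.10,
    sfari_fraction: float = 0.08,
) -> GeneModel:
    """Regularly spaced genes with random exon structure and risk flags."""
    genes = []
    k = 0
    for chrom in sorted(chrom_lengths):
        for gs in range(gene_spacing, chrom_lengths[chrom] - gene_length, gene_spacing):
            k += 1
            n_exons = int(rng.integers(4, 12))
            positions = np.sort(rng.choice(np.arange(0, gene_length - 400, 400), n_exons, replace=False))
            exons = [(gs + int(p), gs + int(p) + int(rng.integers(100, 350))) for p in positions]
            utrs = [(gs, gs + 200), (gs + gene_length - 200, gs + gene_length)]
            genes.append(
                Gene(
                    name=f"GENE{k:04d}",
                    chrom=chrom,
                    start=gs,
                    end=gs + gene_length,
                    exons=exons,
                    utrs=utrs,
                    ndd=bool(rng.random() < ndd_fraction),
                    sfari_score=int(rng.integers(1, 4)) if rng.random() < sfari_fraction else None,
                )
            )
    return GeneModel(genes=genes)


def _random_intervals(rng, chrom_lengths, n_per_mb: float, length_range=(200, 2000), value=None):
    ivs = []
    for chrom in sorted(chrom_lengths):
        n = int(round(n_per_mb * chrom_lengths[chrom] / 1e6))
        starts = np.sort(rng.integers(0, chrom_lengths[chrom] - length_range[1], n))
        lens = rng.integers(*length_range, size=n)
        for s, L in zip(starts, lens):
            iv = [chrom, int(s), int(s + L)]
            if value == "gnocchi":
                iv.append(round(float(rng.normal(0.0, 2.0)), 3))
            ivs.append(tuple(iv))
    return ivs


def simulate_annotation_tracks(
    chrom_lengths: Mapping[str, int],
    seed: int = 0,
    out_dir=None,
) -> dict:
    """Gene model + regulatory / TR / blacklist / Gnocchi / promoter tracks.

    Returns {"gene_model": GeneModel, "tracks": [AnnotationTrack...],
    "paths": {...}} (paths only when ``out_dir`` given).
    """
    rng = np.random.default_rng(seed)
    gene_model = simulate_gene_model(chrom_lengths, rng)
    promoters = [(g.chrom, max(0, g.start - 2000), g.start, g.name) for g in gene_model.genes]
    tracks = [
        AnnotationTrack("encode_reg", "REG_ENCODE", _random_intervals(rng, chrom_lengths, 8.0)),
        AnnotationTrack("brainreg", "REG_BRAIN", _random_intervals(rng, chrom_lengths, 5.0)),
        AnnotationTrack("tf_clusters", "TF_CLUSTER", _random_intervals(rng, chrom_lengths, 3.0)),
        AnnotationTrack("tr_catalog", "TR_CATALOG", _random_intervals(rng, chrom_lengths, 4.0, (50, 500))),
        AnnotationTrack(
            "gnocchi", "GNOCCHI", _random_intervals(rng, chrom_lengths, 6.0, (800, 1200), value="gnocchi")
        ),
        AnnotationTrack("promoters", "PROMOTER", promoters),
        AnnotationTrack(
            "blacklist", "BLACKLIST", _random_intervals(rng, chrom_lengths, 0.2, (50_000, 200_000))
        ),
    ]
    out: dict = {"gene_model": gene_model, "tracks": tracks, "paths": {}}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        gene_rows = [
            (
                g.chrom,
                g.start,
                g.end,
                g.name,
                ("NDD" if g.ndd else ".") + (f";SFARI={g.sfari_score}" if g.sfari_score else ""),
            )
            for g in gene_model.genes
        ]
        out["paths"]["genes"] = write_bed(gene_rows, out_dir / "genes.bed")
        exon_rows = [(g.chrom, s, e, g.name) for g in gene_model.genes for s, e in g.exons + g.utrs]
        out["paths"]["exons"] = write_bed(exon_rows, out_dir / "exons.bed")
        for t in tracks:
            out["paths"][t.name] = write_bed(t.intervals, out_dir / f"{t.name}.bed")
    return out


def simulate_read_support(
    sim,
    sv_ids: Sequence[str],
    samples: Sequence[str],
    noise: float = 0.0,
    seed: int = 0,
    mean_reads: float = 3.0,
) -> dict:
    """(sample, sv_id) -> [(size deviation, read count), ...] consistent with
    true genotypes: true carriers get low-deviation support; non-carriers get
    either nothing (key present, empty list) or, with probability ``noise``,
    an artifactual high-deviation entry."""
    rng = np.random.default_rng(seed)
    li = sim.locus_index()
    si = {s: j for j, s in enumerate(sim.samples)}
    out: dict = {}
    for sv_id in sv_ids:
        row = li[sv_id]
        for s in samples:
            g = int(sim.true_gt[row, si[s]])
            entries = []
            if g in CARRIER_CODES:
                dev = min(abs(rng.normal(0.0, 0.05)), 0.45)
                entries.append((float(dev), 1 + int(rng.poisson(mean_reads))))
            elif noise > 0 and rng.random() < noise:
                entries.append((float(rng.uniform(0.55, 1.0)), 1))
            out[(s, sv_id)] = entries
    return out


def simulate_regenotype_calls(
    sim, sv_ids: Sequence[str], samples: Sequence[str], error_rate: float = 0.0, seed: int = 0
) -> dict:
    """(sample, sv_id) -> re-genotyped code; equals truth except random flips
    to 'absent' at ``error_rate`` (mimics re-genotyper dropout)."""
    rng = np.random.default_rng(seed)
    li = sim.locus_index()
    si = {s: j for j, s in enumerate(sim.samples)}
    out = {}
    for sv_id in sv_ids:
        for s in samples:
            g = int(sim.true_gt[li[sv_id], si[s]])
            if error_rate > 0 and g in CARRIER_CODES and rng.random() < error_rate:
                g = 0
            out[(s, sv_id)] = g
    return out


def simulate_tr_allele_lengths(
    ped,
    n_loci: int = 10,
    expansions: Optional[Sequence[tuple]] = None,
    base_mean: float = 300.0,
    base_sd: float = 20.0,
    expansion_factor: float = 3.0,
    seed: int = 0,
) -> tuple:
    """Tandem-repeat allele-length tables over the whole cohort.

    Parents/controls draw both alleles from N(base_mean, base_sd); children
    inherit one allele from each parent. ``expansions`` is a list of
    (child, locus_index, origin) with origin in {"father", "mother",
    "denovo"}: the child's (and, for inherited origins, the parent's
    matching) allele is replaced by an expanded length. Returns
    (allele_lengths dict, truth list of (locus_id, child, origin)).
    """
    rng = np.random.default_rng(seed)
    loci = [f"tr{k:03d}" for k in range(n_loci)]
    lengths: dict = {}
    for ind in ped.iter_samples():
        if ind.role in ("proband", "sibling"):
            continue
        for locus in loci:
            pair = np.maximum(rng.normal(base_mean, base_sd, 2), 10.0)
            lengths[(ind.sample_id, locus)] = (float(pair[0]), float(pair[1]))
    for ind in ped.iter_samples():
        if ind.role not in ("proband", "sibling"):
            continue
        fa, mo = ped.parents_of(ind.sample_id)
        for locus in loci:
            a = lengths[(fa, locus)][int(rng.integers(0, 2))]
            b = lengths[(mo, locus)][int(rng.integers(0, 2))]
            lengths[(ind.sample_id, locus)] = (a, b)
    truth = []
    for child, locus_idx, origin in expansions or ():
        locus = loci[locus_idx]
        expanded = base_mean * expansion_factor + float(rng.normal(0, 2))
        a, b = lengths[(child, locus)]
        lengths[(child, locus)] = (a, expanded)
        if origin in ("father", "mother"):
            parent = dict(zip(("father", "mother"), ped.parents_of(child)))[origin]
            pa, _ = lengths[(parent, locus)]
            lengths[(parent, locus)] = (pa, expanded)
        truth.append((locus, child, origin))
    return lengths, truth


def simulate_paf(
    chrom: str,
    chrom_length: int,
    out_path,
    window: int = 1_000_000,
    gap_fraction: float = 0.0,
    gap_windows: Optional[Sequence[int]] = None,
    masks: Sequence[tuple] = (),
    fragmented_windows: Optional[Sequence[int]] = None,
    seed: int = 0,
) -> dict:
    """Assembly-to-reference alignment blocks with controlled window gaps.

    Unmasked windows are fully covered by a single contig except: gapped
    windows (chosen by index or drawn at ``gap_fraction``) get one block
    covering only half the window, and ``fragmented_windows`` are tiled by
    four short contigs (they fail the contig cap despite full coverage).
    Returns the truth: which unmasked windows qualify.
    """
    rng = np.random.default_rng(seed)
    n_windows = -(-chrom_length // window)
    wins = []
    for k in range(n_windows):
        ws, we = k * window, min((k + 1) * window, chrom_length)
        masked = any(ms < we and ws < me for ms, me in masks)
        wins.append((k, ws, we, masked))
    unmasked = [k for k, _, _, m in wins if not m]
    if gap_windows is None:
        n_gap = int(round(gap_fraction * len(unmasked)))
        gap_windows = sorted(rng.choice(unmasked, size=n_gap, replace=False)) if n_gap else []
    gap_set = set(gap_windows)
    frag_set = set(fragmented_windows or ())

    lines = []
    contig_i = 0

    def add_block(name, ts, te):
        qlen = te - ts
        lines.append(
            "\t".join(
                str(x)
                for x in (name, qlen, 0, qlen, "+", chrom, chrom_length, ts, te, qlen, qlen, 60)
            )
        )

    for k, ws, we, masked in wins:
        if masked:
            continue
        if k in frag_set:
            quarter = (we - ws) // 4
            for q in range(4):
                contig_i += 1
                add_block(f"contig_{contig_i}", ws + q * quarter, ws + (q + 1) * quarter)
        elif k in gap_set:
            contig_i += 1
            add_block(f"contig_{contig_i}", ws, ws + (we - ws) // 2)
        else:
            contig_i += 1
            add_block(f"contig_{contig_i}", ws, we)
    with open(out_path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
    qualified = [k for k in unmasked if k not in gap_set and k not in frag_set]
    return {
        "path": str(out_path),
        "n_unmasked": len(unmasked),
        "qualified_windows": qualified,
        "expected_fraction": len(qualified) / len(unmasked) if unmasked else float("nan"),
    }


def simulate_methylation(
    out_dir,
    sample: str,
    skew: float,
    chrom: str = "chrX",
    n_islands: int = 889,
    island_length: int = 1000,
    island_spacing: int = 30_000,
    cpgs_per_island: int = 10,
    coverage: int = 20,
    meth_high: float = METH_INACTIVE,
    meth_low: float = METH_ACTIVE,
    seed: int = 0,
) -> dict:
    """Two bedMethyl files for one female: ``skew`` is the fraction of cells
    in which the MATERNAL X is inactive, so the bulk maternal island
    methylation is skew*high + (1-skew)*low and the expected skew index is
    (2*skew - 1) * (meth_high - meth_low)."""
    if not 0.0 <= skew <= 1.0:
        raise ValueError("skew must be in [0,1]")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    islands = [
        (chrom, 10_000 + k * island_spacing, 10_000 + k * island_spacing + island_length)
        for k in range(n_islands)
    ]
    m_mat = skew * meth_high + (1.0 - skew) * meth_low
    m_pat = (1.0 - skew) * meth_high + skew * meth_low
    paths = {}
    for hap, m in (("maternal", m_mat), ("paternal", m_pat)):
        rows = []
        for c, s, e in islands:
            step = island_length // cpgs_per_island
            for cp in range(cpgs_per_island):
                pos = s + cp * step
                k = int(rng.binomial(coverage, m))
                rows.append(f"{c}\t{pos}\t{pos + 1}\t{coverage}\t{100.0 * k / coverage:.4f}")
        path = out_dir / f"{sample}.{hap}.bedmethyl"
        path.write_text("\n".join(rows) + "\n")
        paths[hap] = str(path)
    islands_path = out_dir / "cpg_islands.bed"
    write_bed(islands, islands_path)
    return {
        "maternal": paths["maternal"],
        "paternal": paths["paternal"],
        "islands": [tuple(i) for i in islands],
        "islands_path": str(islands_path),
        "expected_skew_index": (2.0 * skew - 1.0) * (meth_high - meth_low),
    }


def simulate_tracks_and_evidence(
    sim,
    skew: Optional[Mapping[str, float]] = None,
    gap_spec: Optional[dict] = None,
    seed: int = 0,
    out_dir=".",
) -> dict:
    """One-stop fixture emission for a simulated cohort.

    Writes annotation tracks, a chrX PAF with the requested gap structure,
    per-female haplotype bedMethyl pairs, read-support tables for parents at
    every child-carried locus, and a cohort TR allele-length table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {}
    manifest["annotation"] = simulate_annotation_tracks(sim.chrom_lengths, seed=seed, out_dir=out_dir / "tracks")

    gap_spec = gap_spec or {}
    manifest["paf"] = simulate_paf(
        "chrX",
        sim.chrom_lengths.get("chrX", 30_000_000),
        out_dir / "assembly_chrX.paf",
        gap_fraction=gap_spec.get("gap_fraction", 0.0),
        gap_windows=gap_spec.get("gap_windows"),
        masks=gap_spec.get("masks", ()),
        fragmented_windows=gap_spec.get("fragmented_windows"),
        seed=seed + 1,
    )

    skew = skew or {}
    manifest["methylation"] = {}
    for k, (s, frac) in enumerate(sorted(skew.items())):
        manifest["methylation"][s] = simulate_methylation(
            out_dir / "methylation", s, frac, seed=seed + 10 + k
        )

    child_cols = [sim.samples.index(c) for c in sim.ped.children]
    carried = np.isin(sim.true_gt[:, child_cols], CARRIER_CODES).any(axis=1)
    sv_ids = [L.locus_id for keep, L in zip(carried, sim.loci) if keep]
    manifest["read_support"] = simulate_read_support(
        sim, sv_ids, sim.ped.parent_ids, seed=seed + 100
    )
    lengths, tr_truth = simulate_tr_allele_lengths(sim.ped, seed=seed + 200)
    manifest["allele_lengths"] = lengths
    manifest["tr_truth"] = tr_truth

    rs_path = out_dir / "read_support.tsv"
    pd.DataFrame(
        [
            (s, sv, dev, cnt)
            for (s, sv), entries in manifest["read_support"].items()
            for dev, cnt in entries
        ],
        columns=["sample", "sv_id", "size_deviation", "read_count"],
    ).to_csv(rs_path, sep="\t", index=False)
    al_path = out_dir / "tr_allele_lengths.tsv"
    pd.DataFrame(
        [(s, locus, a, b) for (s, locus), (a, b) in lengths.items()],
        columns=["sample", "locus", "allele1", "allele2"],
    ).to_csv(al_path, sep="\t", index=False)
    manifest["read_support_path"] = str(rs_path)
    manifest["allele_lengths_path"] = str(al_path)
    return manifest
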