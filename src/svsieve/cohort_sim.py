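"""Synthetic cohort generator: population SV pool, pedigree transmission, files.

The generator emulates the structure of a long-read family SV study: a
population pool of insertions/deletions/inversions (>=50 bp) with the
characteristic bimodal insertion-size spectrum (Alu-scale ~300 bp and
LINE-scale ~6 kbp modes), ancestry-stratified allele frequencies (African
samples more diverse than non-African), Hardy-Weinberg founder genotypes,
Mendelian transmission with sex-chromosome rules (hemizygous males on
non-PAR X and Y), injected de novo events, and configurable genotyping
errors. Every stochastic choice flows from one integer seed, so outputs are
byte-identical across runs.

All ground truth (de novo events, injected errors, per-allele parental
origin) is recorded in a :class:`TruthSet` so downstream classification can
be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .config import (
    ABSENT,
    DEFAULT_PAR,
    FEMALE,
    HEMI,
    HET,
    HOM,
    MALE,
    MISSING,
    in_par,
    ploidy,
)
from .sv_core import CohortSVTable, SVRecord, write_sv_vcf

#: compact simulated genome; sex chromosomes keep the GRCh38 PAR1 interval
#: inside range so pseudoautosomal handling is exercised.
DEFAULT_CHROM_LENGTHS = {
    "chr1": 60_000_000,
    "chr2": 50_000_000,
    "chr3": 40_000_000,
    "chrX": 30_000_000,
    "chrY": 10_000_000,
}

#: insertion-size mixture: (weight, kind, params). Lognormal components are
#: centred on the two retrotransposon modes; the uniform tail covers larger
#: events. Sizes are clipped to the >=50 bp SV definition.
DEFAULT_SIZE_MIX = (
    (0.55, "lognormal", (math.log(300.0), 0.25)),
    (0.30, "lognormal", (math.log(6000.0), 0.25)),
    (0.15, "uniform", (50, 20_000)),
)

#: allele-frequency model per ancestry stratum: ("beta", a, b) or ("point", af)
DEFAULT_AF_MODEL = {
    "AFR": ("beta", 0.3, 1.5),
    "nonAFR": ("beta", 0.2, 2.0),
}

DEFAULT_SVTYPE_WEIGHTS = {"INS": 0.48, "DEL": 0.48, "INV": 0.04}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class PopulationSVLocus:
    """One segregating SV in the simulated population."""

    locus_id: str
    chrom: str
    pos: int
    svtype: str
    svlen: int
    alt_seq: Optional[str]  # inserted sequence (INS only)
    af_afr: float
    af_nonafr: float
    del_seq: Optional[str] = None  # deleted reference sequence (DEL only)

    def af(self, population: str) -> float:
        return self.af_afr if population == "AFR" else self.af_nonafr

    def to_record(self) -> SVRecord:
        end = self.pos if self.svtype == "INS" else self.pos + self.svlen
        return SVRecord(
            sv_id=self.locus_id,
            chrom=self.chrom,
            start=self.pos,
            end=end,
            svtype=self.svtype,
            svlen=self.svlen,
            seq=self.alt_seq if self.svtype == "INS" else self.del_seq,
        )


@dataclass(frozen=True)
class Individual:
    sample_id: str
    family_id: str  # "" for unrelated controls
    role: str  # father / mother / proband / sibling / control
    sex: str  # F / M
    population: str  # AFR / nonAFR


@dataclass
class PedigreeSpec:
    """Families (trio or quad) plus unrelated controls."""

    families: list  # list[(family_id, list[Individual])]
    controls: list  # list[Individual]

    def __post_init__(self):
        seen = set()
        for fid, members in self.families:
            roles = [m.role for m in members]
            if roles.count("father") != 1 or roles.count("mother") != 1:
                raise ValueError(f"family {fid}: exactly one father and one mother required")
            n_children = sum(r in ("proband", "sibling") for r in roles)
            if not 1 <= n_children <= 2 or len(members) != 2 + n_children:
                raise ValueError(f"family {fid}: trio or quad structure only")
            for m in members:
                if m.role == "father" and m.sex != MALE:
                    raise ValueError(f"family {fid}: father must be male")
                if m.role == "mother" and m.sex != FEMALE:
                    raise ValueError(f"family {fid}: mother must be female")
        for ind in self.iter_samples():
            if ind.sample_id in seen:
                raise ValueError(f"duplicate sample_id {ind.sample_id!r}")
            seen.add(ind.sample_id)

    def iter_samples(self):
        for _, members in self.families:
            yield from members
        yield from self.controls

    @property
    def samples(self) -> list:
        return [m.sample_id for m in self.iter_samples()]

    @property
    def sexes(self) -> dict:
        return {m.sample_id: m.sex for m in self.iter_samples()}

    @property
    def populations(self) -> dict:
        return {m.sample_id: m.population for m in self.iter_samples()}

    @property
    def children(self) -> list:
        return [m.sample_id for m in self.iter_samples() if m.role in ("proband", "sibling")]

    @property
    def control_ids(self) -> list:
        return [m.sample_id for m in self.controls]

    @property
    def parent_ids(self) -> list:
        return [m.sample_id for m in self.iter_samples() if m.role in ("father", "mother")]

    def parents_of(self, child: str) -> tuple:
        for fid, members in self.families:
            ids = {m.role: m.sample_id for m in members}
            if child in [m.sample_id for m in members if m.role in ("proband", "sibling")]:
                return ids["father"], ids["mother"]
        raise KeyError(child)

    def role_of(self, sample: str) -> str:
        for m in self.iter_samples():
            if m.sample_id == sample:
                return m.role
        raise KeyError(sample)

    @classmethod
    def standard(
        cls,
        n_quads: int = 5,
        n_trios: int = 0,
        n_controls: int = 100,
        afr_fraction: float = 0.3,
        seed: int = 0,
    ) -> "PedigreeSpec":
        """A deterministic generic cohort: quads first, then trios, then controls."""
        rng = np.random.default_rng(seed)
        families = []
        for i in range(n_quads + n_trios):
            fid = f"fam{i + 1:03d}"
            pop = "AFR" if rng.random() < afr_fraction else "nonAFR"
            members = [
                Individual(f"{fid}_fa", fid, "father", MALE, pop),
                Individual(f"{fid}_mo", fid, "mother", FEMALE, pop),
                Individual(f"{fid}_p1", fid, "proband", FEMALE if rng.random() < 0.5 else MALE, pop),
            ]
            if i < n_quads:
                members.append(
                    Individual(f"{fid}_s1", fid, "sibling", FEMALE if rng.random() < 0.5 else MALE, pop)
                )
            families.append((fid, members))
        controls = [
            Individual(
                f"ctrl{i + 1:04d}",
                "",
                "control",
                FEMALE if rng.random() < 0.5 else MALE,
                "AFR" if rng.random() < afr_fraction else "nonAFR",
            )
            for i in range(n_controls)
        ]
        return cls(families=families, controls=controls)

    def write_tsv(self, path) -> str:
        with open(path, "w") as fh:
            fh.write("sample\tfamily\trole\tsex\tpopulation\n")
            for m in self.iter_samples():
                fh.write(f"{m.sample_id}\t{m.family_id or '.'}\t{m.role}\t{m.sex}\t{m.population}\n")
        return str(path)

    @classmethod
    def read_tsv(cls, path) -> "PedigreeSpec":
        fams: dict[str, list] = {}
        controls = []
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("sample")
            for line in fh:
                sid, fid, role, sex, pop = line.rstrip("\n").split("\t")
                ind = Individual(sid, "" if fid == "." else fid, role, sex, pop)
                if role == "control":
                    controls.append(ind)
                else:
                    fams.setdefault(ind.family_id, []).append(ind)
        return cls(families=sorted(fams.items()), controls=controls)


@dataclass
class TruthSet:
    """Ground truth recorded by the simulator for recovery scoring."""

    denovo_events: dict = field(default_factory=dict)  # child -> set(locus_ids)
    genotype_errors: list = field(default_factory=list)  # (sample, locus_id, true, emitted)
    transmission_map: dict = field(default_factory=dict)  # (child, locus_id) -> origin


@dataclass
class SimulatedCohort:
    """Genotype matrices (true and emitted) over pool + de novo loci."""

    loci: list  # list[PopulationSVLocus]
    ped: PedigreeSpec
    samples: list
    true_gt: np.ndarray  # (n_loci, n_samples) int8
    gt: np.ndarray  # emitted genotypes
    chrom_lengths: dict

    def locus_index(self) -> dict:
        return {loc.locus_id: i for i, loc in enumerate(self.loci)}


# ---------------------------------------------------------------------------
# pool


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _draw_sizes(rng: np.random.Generator, n: int, size_mix) -> np.ndarray:
    weights = np.array([w for w, _, _ in size_mix], float)
    weights /= weights.sum()
    comp = rng.choice(len(size_mix), size=n, p=weights)
    sizes = np.empty(n, dtype=np.int64)
    for k, (_, kind, params) in enumerate(size_mix):
        m = comp == k
        if not m.any():
            continue
        if kind == "lognormal":
            mu, sigma = params
            sizes[m] = np.round(rng.lognormal(mu, sigma, m.sum())).astype(np.int64)
        elif kind == "uniform":
            lo, hi = params
            sizes[m] = rng.integers(lo, hi + 1, m.sum())
        else:
            raise ValueError(f"unknown size component {kind!r}")
    return np.maximum(sizes, 50)


def _draw_afs(rng: np.random.Generator, n: int, spec) -> np.ndarray:
    kind = spec[0]
    if kind == "beta":
        return rng.beta(spec[1], spec[2], n)
    if kind == "point":
        return np.full(n, float(spec[1]))
    raise ValueError(f"unknown AF model {kind!r}")


def simulate_sv_pool(
    n_loci: int,
    size_mix=DEFAULT_SIZE_MIX,
    af_model: Mapping = DEFAULT_AF_MODEL,
    chrom_lengths: Mapping[str, int] = DEFAULT_CHROM_LENGTHS,
    seed: int = 0,
    svtype_weights: Mapping[str, float] = DEFAULT_SVTYPE_WEIGHTS,
    with_sequences: bool = True,
) -> list:
    """Draw a population SV pool, sorted by (chrom, pos), deterministic in seed.

    Loci are placed on a 1 kbp grid (one locus per slot) so that distinct loci
    never fall within the default 500 bp breakpoint-match radius of each
    other: truth stays unambiguous for collapse and recovery tests.
    """
    if n_loci < 0:
        raise ValueError("n_loci must be >= 0")
    if not chrom_lengths:
        raise ValueError("chrom_lengths must be nonempty")
    rng = np.random.default_rng(seed)
    if n_loci == 0:
        return []

    chroms = sorted(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], float)
    counts = rng.multinomial(n_loci, lens / lens.sum())

    types = list(svtype_weights)
    tw = np.array([svtype_weights[t] for t in types], float)
    tw /= tw.sum()

    loci: list[PopulationSVLocus] = []
    i0 = 0
    for c, count in zip(chroms, counts):
        if count == 0:
            continue
        # avoid the Y PAR so chrY loci are cleanly hemizygous in males
        lo_slot = 1
        if c == "chrY":
            lo_slot = DEFAULT_PAR["chrY"][0][1] // 1000 + 2
        n_slots = chrom_lengths[c] // 1000 - 2
        if n_slots - lo_slot < count:
            raise ValueError(f"{c}: too many loci for chromosome length")
        slots = np.sort(rng.choice(np.arange(lo_slot, n_slots), size=count, replace=False))
        pos = slots * 1000 + rng.integers(0, 400, count)
        svt = rng.choice(len(types), size=count, p=tw)
        sizes = _draw_sizes(rng, count, size_mix)
        af_a = _draw_afs(rng, count, af_model["AFR"])
        af_n = _draw_afs(rng, count, af_model["nonAFR"])
        for k in range(count):
            t = types[svt[k]]
            size = int(sizes[k])
            alt = del_ = None
            if with_sequences and t == "INS":
                alt = _random_seq(rng, size)
            elif with_sequences and t == "DEL":
                del_ = _random_seq(rng, size)
            loci.append(
                PopulationSVLocus(
                    locus_id=f"sv{(i0 + k):06d}",
                    chrom=c,
                    pos=int(pos[k]),
                    svtype=t,
                    svlen=size,
                    alt_seq=alt,
                    af_afr=float(af_a[k]),
                    af_nonafr=float(af_n[k]),
                    del_seq=del_,
                )
            )
        i0 += count
    loci.sort(key=lambda L: (L.chrom, L.pos))
    return loci


# ---------------------------------------------------------------------------
# cohort genotypes


def _ploidy_vectors(loci, par=DEFAULT_PAR):
    pf = np.array([ploidy(L.chrom, L.pos, FEMALE, par) for L in loci], np.int8)
    pm = np.array([ploidy(L.chrom, L.pos, MALE, par) for L in loci], np.int8)
    x_mask = np.array(
        [L.chrom == "chrX" and not in_par(L.chrom, L.pos, par) for L in loci]
    )
    y_mask = np.array([L.chrom == "chrY" for L in loci])
    aut_mask = ~(x_mask | y_mask)
    return pf, pm, x_mask, y_mask, aut_mask


def _founder_haps(rng, af, plo):
    n = len(af)
    a = np.where(plo >= 1, (rng.random(n) < af).astype(np.int8), np.int8(-9))
    b = np.where(plo == 2, (rng.random(n) < af).astype(np.int8), np.int8(-9))
    return a, b


def _code_from_haps(a, b):
    slots = (a >= 0).astype(np.int8) + (b >= 0).astype(np.int8)
    dos = (a == 1).astype(np.int8) + (b == 1).astype(np.int8)
    code = dos.copy()  # diploid: dosage == code (ABSENT/HET/HOM)
    code[(slots == 1) & (dos == 1)] = HEMI
    code[slots == 0] = MISSING
    return code


def simulate_cohort(
    pool: Sequence[PopulationSVLocus],
    ped: PedigreeSpec,
    denovo_rate: float = 0.3,
    error_rate: float = 0.0,
    seed: int = 0,
    chrom_lengths: Mapping[str, int] = DEFAULT_CHROM_LENGTHS,
    par=DEFAULT_PAR,
) -> tuple:
    """Simulate genotypes for every pedigree member; returns (cohort, truth).

    Founders are drawn under Hardy-Weinberg from their stratum AF (one allele
    on male non-PAR X and on Y); children receive one allele from each parent
    uniformly at random with sex-chromosome constraints (sons: maternal X,
    paternal Y). De novo events are fresh loci (absent from the pool and all
    founders) injected per child at Poisson(``denovo_rate``); emitted
    genotypes differ from truth only by recorded error flips.
    """
    if denovo_rate < 0:
        raise ValueError("denovo_rate must be >= 0")
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0,1]")
    samples = ped.samples
    if samples and not pool:
        raise ValueError("pool must be nonempty for a nonempty pedigree")
    rng = np.random.default_rng(seed)

    # --- de novo loci, injected as extra pool rows with AF 0
    children = ped.children
    denovo_loci: list[PopulationSVLocus] = []
    denovo_owner: list[str] = []
    used_slots = {c: set() for c in chrom_lengths}
    for L in pool:
        used_slots.setdefault(L.chrom, set()).add(L.pos // 1000)
    dn_chroms = [c for c in sorted(chrom_lengths) if c != "chrY"]
    dn_lens = np.array([chrom_lengths[c] for c in dn_chroms], float)
    for child in children:
        for k in range(rng.poisson(denovo_rate)):
            c = dn_chroms[rng.choice(len(dn_chroms), p=dn_lens / dn_lens.sum())]
            while True:
                slot = int(rng.integers(2, chrom_lengths[c] // 1000 - 2))
                # keep >=1 kbp from every existing locus
                if not ({slot - 1, slot, slot + 1} & used_slots[c]):
                    break
            used_slots[c].add(slot)
            size = int(_draw_sizes(rng, 1, DEFAULT_SIZE_MIX)[0])
            t = ["INS", "DEL"][int(rng.integers(0, 2))]
            seq = _random_seq(rng, size)
            denovo_loci.append(
                PopulationSVLocus(
                    locus_id=f"dn_{child}_{k}",
                    chrom=c,
                    pos=slot * 1000 + int(rng.integers(0, 400)),
                    svtype=t,
                    svlen=size,
                    alt_seq=seq if t == "INS" else None,
                    af_afr=0.0,
                    af_nonafr=0.0,
                    del_seq=seq if t == "DEL" else None,
                )
            )
            denovo_owner.append(child)

    loci = list(pool) + denovo_loci
    n = len(loci)
    pf, pm, x_mask, y_mask, aut_mask = _ploidy_vectors(loci, par)
    af_by_pop = {
        pop: np.array([L.af(pop) for L in loci]) for pop in ("AFR", "nonAFR")
    }

    haps: dict[str, tuple] = {}
    # founders (parents and controls) in pedigree order
    for ind in ped.iter_samples():
        if ind.role in ("proband", "sibling"):
            continue
        plo = pf if ind.sex == FEMALE else pm
        haps[ind.sample_id] = _founder_haps(rng, af_by_pop[ind.population], plo)

    truth = TruthSet()
    sexes = ped.sexes
    for ind in ped.iter_samples():
        if ind.role not in ("proband", "sibling"):
            continue
        fa_id, mo_id = ped.parents_of(ind.sample_id)
        fa_a, fa_b = haps[fa_id]
        mo_a, mo_b = haps[mo_id]
        pick_f = rng.integers(0, 2, n)
        pick_m = rng.integers(0, 2, n)
        pat = np.full(n, -9, np.int8)
        pat[aut_mask] = np.where(pick_f, fa_b, fa_a)[aut_mask]
        if ind.sex == FEMALE:
            pat[x_mask] = fa_a[x_mask]  # father's single X
        else:
            pat[y_mask] = fa_a[y_mask]  # father's Y
        mat = np.full(n, -9, np.int8)
        mm = aut_mask | x_mask
        mat[mm] = np.where(pick_m, mo_b, mo_a)[mm]
        haps[ind.sample_id] = (pat, mat)

    # de novo alleles: one new allele on an available haplotype of the child
    for li, (dn, child) in enumerate(zip(denovo_loci, denovo_owner), start=len(pool)):
        pat, mat = haps[child]
        slots = [arr for arr in (pat, mat) if arr[li] >= 0]
        target = slots[int(rng.integers(0, len(slots)))] if len(slots) > 1 else slots[0]
        target[li] = 1
        truth.denovo_events.setdefault(child, set()).add(dn.locus_id)

    true_gt = np.empty((n, len(samples)), np.int8)
    for j, s in enumerate(samples):
        true_gt[:, j] = _code_from_haps(*haps[s])

    # transmission origins for child carrier alleles
    for child in children:
        pat, mat = haps[child]
        codes = true_gt[:, samples.index(child)]
        carrier = np.isin(codes, (HET, HOM, HEMI))
        dn_ids = truth.denovo_events.get(child, set())
        for li in np.nonzero(carrier)[0]:
            lid = loci[li].locus_id
            if lid in dn_ids:
                truth.transmission_map[(child, lid)] = "denovo"
            elif pat[li] == 1 and mat[li] == 1:
                truth.transmission_map[(child, lid)] = "both"
            elif pat[li] == 1:
                truth.transmission_map[(child, lid)] = "father"
            else:
                truth.transmission_map[(child, lid)] = "mother"

    gt = true_gt.copy()
    if error_rate > 0:
        flips = (rng.random(gt.shape) < error_rate) & (gt != MISSING)
        hap_locus = np.broadcast_to(((pf == 1) | (pm == 1))[:, None], gt.shape)
        sex_hap = np.array([(pm if sexes[s] == MALE else pf) for s in samples]).T == 1
        for li, sj in zip(*np.nonzero(flips)):
            old = int(gt[li, sj])
            if old == HET:
                new = HOM if rng.random() < 0.5 else ABSENT
            elif old == HOM:
                new = HET
            elif old == HEMI:
                new = ABSENT
            elif old == ABSENT and sex_hap[li, sj]:
                new = HEMI
            else:
                new = HET
            gt[li, sj] = new
            truth.genotype_errors.append((samples[sj], loci[li].locus_id, old, new))

    cohort = SimulatedCohort(
        loci=loci,
        ped=ped,
        samples=samples,
        true_gt=true_gt,
        gt=gt,
        chrom_lengths=dict(chrom_lengths),
    )
    return cohort, truth


def cohort_table(sim: SimulatedCohort, use_true: bool = False) -> CohortSVTable:
    """Bridge a simulated cohort to the nonredundant genotype-table form."""
    rows = [L.to_record() for L in sim.loci]
    gt = (sim.true_gt if use_true else sim.gt).copy()
    return CohortSVTable(rows=rows, samples=list(sim.samples), genotypes=gt)


# ---------------------------------------------------------------------------
# file emission


def _haploid_mask(sim: SimulatedCohort, sample_ids, par=DEFAULT_PAR) -> np.ndarray:
    pf, pm, *_ = _ploidy_vectors(sim.loci, par)
    sexes = sim.ped.sexes
    cols = [(pm if sexes[s] == MALE else pf) == 1 for s in sample_ids]
    return np.stack(cols, axis=1)


def _subset_table(sim: SimulatedCohort, sample_ids) -> tuple:
    idx = [sim.samples.index(s) for s in sample_ids]
    gt = sim.gt[:, idx]
    carrier = np.isin(gt, (HET, HOM, HEMI)).any(axis=1)
    rows = [L.to_record() for keep, L in zip(carrier, sim.loci) if keep]
    table = CohortSVTable(rows=rows, samples=list(sample_ids), genotypes=gt[carrier])
    hap = _haploid_mask(sim, sample_ids)[carrier]
    return table, hap


def write_cohort(
    sim: SimulatedCohort,
    out_dir,
    caller_dropout: float = 0.0,
    callers: Sequence[str] = ("pav", "pbsv", "sniffles"),
    seed: int = 0,
    index: bool = True,
    callerset_samples: Optional[Sequence[str]] = None,
) -> dict:
    """Write per-family and control multi-sample VCFs plus per-sample
    per-caller replicate VCFs.

    The first caller is the primary (assembly-based) callset and keeps every
    carrier record; each additional caller independently drops each record
    with probability ``caller_dropout``, which exercises callerset
    validation with an analytically known survival rate.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    suffix = ".vcf.gz" if index else ".vcf"
    manifest: dict = {"families": {}, "callersets": {}}

    for fid, members in sim.ped.families:
        ids = [m.sample_id for m in members]
        table, hap = _subset_table(sim, ids)
        path = str(out / f"family_{fid}{suffix}")
        write_sv_vcf(table, path, sim.chrom_lengths, haploid=hap, index=index)
        manifest["families"][fid] = path
    if sim.ped.controls:
        ids = sim.ped.control_ids
        table, hap = _subset_table(sim, ids)
        path = str(out / f"controls{suffix}")
        write_sv_vcf(table, path, sim.chrom_lengths, haploid=hap, index=index)
        manifest["controls"] = path

    cs_dir = out / "callersets"
    targets = list(callerset_samples) if callerset_samples is not None else list(sim.samples)
    if targets:
        cs_dir.mkdir(exist_ok=True)
    for s in targets:
        table, hap = _subset_table(sim, [s])
        for k, caller in enumerate(callers):
            if k == 0 or caller_dropout == 0.0:
                keep = np.ones(table.n_rows, bool)
            else:
                keep = rng.random(table.n_rows) >= caller_dropout
            sub = CohortSVTable(
                rows=[r for r, kp in zip(table.rows, keep) if kp],
                samples=[s],
                genotypes=table.genotypes[keep],
            )
            path = str(cs_dir / f"{s}.{caller}{suffix}")
            write_sv_vcf(sub, path, sim.chrom_lengths, haploid=hap[keep], index=index)
            manifest["callersets"][(s, caller)] = path

    ped_path = str(out / "pedigree.tsv")
    sim.ped.write_tsv(ped_path)
    manifest["pedigree"] = ped_path
    return manifest


# fixture generators live in ._tracks; re-exported here as part of the
# simulation surface
from ._tracks import (  # noqa: E402
    simulate_annotation_tracks,
    simulate_methylation,
    simulate_paf,
    simulate_read_support,
    simulate_regenotype_calls,
    simulate_tr_allele_lengths,
    simulate_tracks_and_evidence,
)
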