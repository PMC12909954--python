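"""Shared constants: genotype codes, sexes, pseudoautosomal regions, ploidy rules.

Genotype codes are small integers so cohort-scale matrices stay ``int8``:

===========  =====  =========================================
code         value  meaning
===========  =====  =========================================
``MISSING``   -1    no call / not assayed
``ABSENT``     0    reference genotype (0/0 or 0)
``HET``        1    heterozygous (0/1)
``HOM``        2    homozygous alternate (1/1)
``HEMI``       3    hemizygous carrier (1 on a haploid locus)
===========  =====  =========================================
"""

from __future__ import annotations

MISSING = -1
ABSENT = 0
HET = 1
HOM = 2
HEMI = 3

GT_NAMES = {MISSING: "missing", ABSENT: "absent", HET: "het", HOM: "hom", HEMI: "hemi"}

#: carrier codes: the sample bears at least one alternate allele
CARRIER_CODES = (HET, HOM, HEMI)

FEMALE = "F"
MALE = "M"

#: default pseudoautosomal regions, GRCh38, 0-based half-open.
#: PAR loci behave autosomally (diploid in males).
DEFAULT_PAR = {
    "chrX": ((0, 2_781_479), (155_701_383, 156_030_895)),
    "chrY": ((0, 2_781_479), (56_887_902, 57_217_415)),
}


def normalize_chrom(chrom: str) -> str:
    return chrom if chrom.startswith("chr") else "chr" + chrom


def is_x(chrom: str) -> bool:
    return normalize_chrom(chrom) == "chrX"


def is_y(chrom: str) -> bool:
    return normalize_chrom(chrom) == "chrY"


def in_par(chrom: str, pos: int, par=DEFAULT_PAR) -> bool:
    for start, end in par.get(normalize_chrom(chrom), ()):
        if start <= pos < end:
            return True
    return False


def ploidy(chrom: str, pos: int, sex: str, par=DEFAULT_PAR) -> int:
    """Copy number of the locus in a sample of the given sex.

    0 means the sample has no copy (e.g. a chrY locus in a female).
    """
    c = normalize_chrom(chrom)
    if c == "chrY":
        if in_par(c, pos, par):
            return 2 if sex == MALE else 0
        return 1 if sex == MALE else 0
    if c == "chrX" and sex == MALE and not in_par(c, pos, par):
        return 1
    return 2


def dosage(code: int) -> int:
    """Alternate-allele count carried under a genotype code (missing -> 0)."""
    if code == HET or code == HEMI:
        return 1
    if code == HOM:
        return 2
    return 0
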