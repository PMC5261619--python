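"""Family-quartet conventions shared across the pipeline.

The study design is a quartet: two parents and two affected siblings
(one male, one female). Sample identifiers are fixed so that every
stage can address members by role rather than by file-specific names.
"""

from __future__ import annotations

FATHER = "FATHER"
MOTHER = "MOTHER"
SIB_M = "SIB_M"
SIB_F = "SIB_F"

MEMBERS: tuple[str, str, str, str] = (FATHER, MOTHER, SIB_M, SIB_F)
PARENTS: tuple[str, str] = (FATHER, MOTHER)
SIBLINGS: tuple[str, str] = (SIB_M, SIB_F)

#: Male members carry a single allele on non-pseudoautosomal X.
MALE_MEMBERS: frozenset[str] = frozenset({FATHER, SIB_M})

# hg19 X-chromosome pseudoautosomal regions (1-based inclusive).
# Inside these intervals males are diploid; outside them male X
# genotypes are hemizygous (single allele).
PAR_REGIONS_HG19: tuple[tuple[int, int], ...] = (
    (60_001, 2_699_520),      # PAR1
    (154_931_044, 155_260_560),  # PAR2
)

X_NAMES = frozenset({"X", "chrX"})


def is_x(chrom: str) -> bool:
    return chrom in X_NAMES


def in_par(chrom: str, pos: int, par_regions=PAR_REGIONS_HG19) -> bool:
    """True if (chrom, pos) falls in an X pseudoautosomal region."""
    if not is_x(chrom):
        return False
    return any(lo <= pos <= hi for lo, hi in par_regions)


def is_hemizygous_locus(chrom: str, pos: int, member: str) -> bool:
    """Male, X, non-PAR: the locus carries a single allele."""
    return member in MALE_MEMBERS and is_x(chrom) and not in_par(chrom, pos)
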