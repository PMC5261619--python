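"""Quartet exome variant filter cascade and sibling partition.

Annotated variants flow through four filters, in the order the analysis
applies them:

qc_filter              every quartet member has depth >= 20, genotype
                       quality >= 20 and supporting base quality >= 30
rarity_filter          every *present* population frequency <= 0.01;
                       variants with all frequencies missing are novel
                       and kept
consequence_filter     nonsynonymous SNVs, small indels (frameshift or
                       not), stop gain/loss and splice-site changes
deleteriousness_filter conservation score >= 2 and a deleterious or
                       possibly-deleterious category, each applied only
                       when the annotation is present

Survivors are classified by inheritance (de novo when both parents are
homozygous reference; hemizygous for male non-PAR X) and partitioned
into variants shared by both siblings, exclusive to one, de novo per
child, and hemizygous-X in the male.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .quartet import (
    FATHER, MOTHER, SIB_M, SIB_F, MEMBERS, SIBLINGS, is_hemizygous_locus,
)

KEPT_CONSEQUENCES = frozenset(
    {
        "nonsynonymous_snv",
        "frameshift_indel",
        "nonframeshift_indel",
        "stopgain",
        "stoploss",
        "splicing",
    }
)
ALL_CONSEQUENCES = KEPT_CONSEQUENCES | {"synonymous", "other"}

DELETERIOUS_KEEP = frozenset({"deleterious", "possibly_deleterious"})

# inheritance classes
DE_NOVO = "de_novo"
INHERITED_PATERNAL = "inherited_paternal"
INHERITED_MATERNAL = "inherited_maternal"
INHERITED_BOTH = "inherited_both"
HEMIZYGOUS_X = "hemizygous_x"
MENDELIAN_ERROR = "mendelian_error"
NOT_CARRIED = "not_carried"


@dataclass(frozen=True)
class GenotypeCall:
    """One member's genotype at one locus.

    ``alleles`` holds allele indexes: (0, 1) for a heterozygote, a
    1-tuple for a hemizygous male X call. ``base_q`` is the phred-scaled
    quality of the supporting bases.
    """

    alleles: tuple[int, ...]
    depth: int
    gq: int
    base_q: int

    def __post_init__(self) -> None:
        if self.depth < 0 or self.gq < 0:
            raise ValueError("depth and gq must be non-negative")
        if not 1 <= len(self.alleles) <= 2:
            raise ValueError("expected 1 or 2 alleles")

    @property
    def carries_alt(self) -> bool:
        return any(a > 0 for a in self.alleles)

    @property
    def hom_ref(self) -> bool:
        return all(a == 0 for a in self.alleles)


@dataclass
class AnnotatedVariant:
    """One bi-allelic locus with quartet genotypes and annotations.

    The three population frequencies correspond to the three reference
    panels consulted for rarity (``None`` = not observed, i.e. novel).
    ``conservation`` is a GERP-style score; ``deleteriousness`` a
    PolyPhen-style category.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    freq_db1: float | None = None
    freq_db2: float | None = None
    freq_db3: float | None = None
    conservation: float | None = None
    deleteriousness: str | None = None
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        for f in self.frequencies:
            if f is not None and not 0 <= f <= 1:
                raise ValueError(f"allele frequency {f} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def frequencies(self) -> tuple[float | None, float | None, float | None]:
        return (self.freq_db1, self.freq_db2, self.freq_db3)

    def genotype(self, member: str) -> GenotypeCall | None:
        return self.genotypes.get(member)


@dataclass
class DropLog:
    """Per-filter record of why variants were removed."""

    entries: list[tuple[tuple, str, str]] = field(default_factory=list)

    def add(self, variant: AnnotatedVariant, stage: str, reason: str) -> None:
        self.entries.append((variant.key, stage, reason))

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, stage, _ in self.entries:
            out[stage] = out.get(stage, 0) + 1
        return out


def qc_filter(
    variants: list[AnnotatedVariant],
    min_depth: int = 20,
    min_gq: int = 20,
    min_base_q: int = 30,
    log: DropLog | None = None,
) -> list[AnnotatedVariant]:
    """Keep variants where all four members meet the call-quality bars
    (thresholds inclusive). A member without a genotype record fails."""
    kept = []
    for v in variants:
        ok = True
        for m in MEMBERS:
            g = v.genotype(m)
            if g is None:
                ok = False
                if log:
                    log.add(v, "qc", f"missing genotype for {m}")
                break
            if g.depth < min_depth or g.gq < min_gq or g.base_q < min_base_q:
                ok = False
                if log:
                    log.add(v, "qc", f"{m} below depth/gq/base_q threshold")
                break
        if ok:
            kept.append(v)
    return kept


def rarity_filter(
    variants: list[AnnotatedVariant],
    maf_max: float = 0.01,
    log: DropLog | None = None,
) -> list[AnnotatedVariant]:
    """Keep rare variants: every present frequency <= maf_max. Variants
    absent from all panels (all frequencies missing) are novel — kept."""
    kept = []
    for v in variants:
        present = [f for f in v.frequencies if f is not None]
        if all(f <= maf_max for f in present):
            kept.append(v)
        elif log:
            log.add(v, "rarity", f"frequency above {maf_max}")
    return kept


def consequence_filter(
    variants: list[AnnotatedVariant],
    strict: bool = False,
    log: DropLog | None = None,
) -> list[AnnotatedVariant]:
    """Keep protein-affecting consequences: nonsynonymous SNVs, small
    indels, stop gain/loss, splicing. Unknown strings drop (or raise
    with strict=True)."""
    kept = []
    for v in variants:
        if v.consequence in KEPT_CONSEQUENCES:
            kept.append(v)
        elif v.consequence not in ALL_CONSEQUENCES and strict:
            raise ValueError(f"unknown consequence {v.consequence!r} at {v.key}")
        elif log:
            log.add(v, "consequence", v.consequence)
    return kept


def deleteriousness_filter(
    variants: list[AnnotatedVariant],
    min_conservation: float = 2.0,
    log: DropLog | None = None,
) -> list[AnnotatedVariant]:
    """Keep variants conserved and predicted damaging, each criterion
    applied only when its annotation is present ("if present" rule):
    conservation missing or >= min_conservation, AND category missing or
    deleterious/possibly_deleterious."""
    kept = []
    for v in variants:
        cons_ok = v.conservation is None or v.conservation >= min_conservation
        del_ok = v.deleteriousness is None or v.deleteriousness in DELETERIOUS_KEEP
        if cons_ok and del_ok:
            kept.append(v)
        elif log:
            log.add(v, "deleteriousness",
                    "conservation" if not cons_ok else "category")
    return kept


def classify_inheritance(variant: AnnotatedVariant, child: str) -> str:
    """Inheritance class of the alt allele in one child.

    de novo requires both parents homozygous reference; a male non-PAR X
    alt with a carrier mother is hemizygous_x; otherwise the class
    follows which parent carries the alt. A child alt absent from both
    parents when a parent is not hom-ref is a Mendelian inconsistency.
    """
    g_child = variant.genotype(child)
    g_fa = variant.genotype(FATHER)
    g_mo = variant.genotype(MOTHER)
    if g_child is None or g_fa is None or g_mo is None:
        raise ValueError(f"missing quartet genotype at {variant.key}")
    if not g_child.carries_alt:
        return NOT_CARRIED
    if is_hemizygous_locus(variant.chrom, variant.pos, child):
        if g_mo.carries_alt:
            return HEMIZYGOUS_X
        if g_mo.hom_ref and g_fa.hom_ref:
            return DE_NOVO
        return MENDELIAN_ERROR
    fa_alt, mo_alt = g_fa.carries_alt, g_mo.carries_alt
    if fa_alt and mo_alt:
        return INHERITED_BOTH
    if fa_alt:
        return INHERITED_PATERNAL
    if mo_alt:
        return INHERITED_MATERNAL
    if g_fa.hom_ref and g_mo.hom_ref:
        return DE_NOVO
    return MENDELIAN_ERROR


@dataclass
class VariantPartition:
    """Post-cascade variants split by sibling sharing and inheritance."""

    shared: list[AnnotatedVariant] = field(default_factory=list)
    male_exclusive: list[AnnotatedVariant] = field(default_factory=list)
    female_exclusive: list[AnnotatedVariant] = field(default_factory=list)
    de_novo_male: list[AnnotatedVariant] = field(default_factory=list)
    de_novo_female: list[AnnotatedVariant] = field(default_factory=list)
    hemizygous_x_male: list[AnnotatedVariant] = field(default_factory=list)

    _GROUPS = ("shared", "male_exclusive", "female_exclusive",
               "de_novo_male", "de_novo_female", "hemizygous_x_male")

    def tallies(self) -> dict[str, dict[str, int]]:
        """Per-group consequence tallies."""
        out = {}
        for name in self._GROUPS:
            tally: dict[str, int] = {}
            for v in getattr(self, name):
                tally[v.consequence] = tally.get(v.consequence, 0) + 1
            out[name] = tally
        return out

    def counts(self) -> dict[str, int]:
        return {name: len(getattr(self, name)) for name in self._GROUPS}

    @property
    def total_inherited(self) -> int:
        """Grand total of the rare inherited heterozygous partition."""
        return len(self.shared) + len(self.male_exclusive) + len(self.female_exclusive)


def partition_siblings(
    variants: list[AnnotatedVariant],
    log: DropLog | None = None,
) -> VariantPartition:
    """Partition post-cascade variants by sibling carrier status.

    De novo and hemizygous-X variants are routed to their own lists;
    the remaining inherited variants split into shared (both siblings
    carry the alt) and exclusive (exactly one does). Variants carried by
    neither child are excluded.
    """
    part = VariantPartition()
    for v in variants:
        cls = {child: classify_inheritance(v, child) for child in SIBLINGS}
        carried = [c for c in SIBLINGS if cls[c] != NOT_CARRIED]
        if not carried:
            if log:
                log.add(v, "partition", "carried by neither sibling")
            continue
        if cls[SIB_M] == HEMIZYGOUS_X:
            part.hemizygous_x_male.append(v)
            continue
        if cls[SIB_M] == DE_NOVO and SIB_M in carried:
            part.de_novo_male.append(v)
            continue
        if cls[SIB_F] == DE_NOVO and SIB_F in carried:
            part.de_novo_female.append(v)
            continue
        if len(carried) == 2:
            part.shared.append(v)
        elif carried[0] == SIB_M:
            part.male_exclusive.append(v)
        else:
            part.female_exclusive.append(v)
    return part


def run_cascade(
    variants: list[AnnotatedVariant],
    min_depth: int = 20,
    min_gq: int = 20,
    min_base_q: int = 30,
    maf_max: float = 0.01,
    min_conservation: float = 2.0,
    log: DropLog | None = None,
) -> list[AnnotatedVariant]:
    """Apply the four filters in order; returns the surviving variants."""
    v = qc_filter(variants, min_depth, min_gq, min_base_q, log=log)
    v = rarity_filter(v, maf_max, log=log)
    v = consequence_filter(v, log=log)
    v = deleteriousness_filter(v, min_conservation, log=log)
    return v


# ---------------------------------------------------------------------------
# I/O: VCF + annotation sidecar, merged table, partition outputs


ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "consequence",
    "freq_db1", "freq_db2", "freq_db3", "conservation", "deleteriousness",
]


def read_quartet_vcf(vcf_path: str, annotation_path: str) -> list[AnnotatedVariant]:
    """Load a quartet VCF (GT:DP:GQ:BQ per sample) with its tab-separated
    annotation sidecar keyed by chrom/pos/ref/alt.

    Multi-allelic records are decomposed into one bi-allelic record per
    alt allele; genotype allele indexes are remapped to 0/1 against that
    alt. Records without a sidecar annotation row are skipped.
    """
    import pysam

    ann = pd.read_csv(annotation_path, sep="\t", dtype={"chrom": str})
    ann_index = {
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)): r
        for r in ann.itertuples(index=False)
    }

    out: list[AnnotatedVariant] = []
    with pysam.VariantFile(vcf_path) as vcf:
        samples = list(vcf.header.samples)
        missing = set(MEMBERS) - set(samples)
        if missing:
            raise ValueError(f"VCF missing quartet samples: {sorted(missing)}")
        for rec in vcf:
            for alt_i, alt in enumerate(rec.alts or (), start=1):
                key = (str(rec.chrom), int(rec.pos), str(rec.ref), str(alt))
                row = ann_index.get(key)
                if row is None:
                    continue
                genos = {}
                for m in MEMBERS:
                    s = rec.samples[m]
                    gt = s.get("GT")
                    if gt is None or any(a is None for a in gt):
                        continue
                    alleles = tuple(1 if a == alt_i else 0 for a in gt)
                    genos[m] = GenotypeCall(
                        alleles=alleles,
                        depth=int(s.get("DP") or 0),
                        gq=int(s.get("GQ") or 0),
                        base_q=int(s.get("BQ") or 0),
                    )
                out.append(
                    AnnotatedVariant(
                        chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                        gene=str(row.gene),
                        consequence=str(row.consequence),
                        freq_db1=_maybe_float(row.freq_db1),
                        freq_db2=_maybe_float(row.freq_db2),
                        freq_db3=_maybe_float(row.freq_db3),
                        conservation=_maybe_float(row.conservation),
                        deleteriousness=_maybe_str(row.deleteriousness),
                        genotypes=genos,
                    )
                )
    return out


def _maybe_float(x) -> float | None:
    if x is None or (isinstance(x, float) and pd.isna(x)) or x in ("", "NA", "."):
        return None
    return float(x)


def _maybe_str(x) -> str | None:
    if x is None or (isinstance(x, float) and pd.isna(x)) or x in ("", "NA", "."):
        return None
    return str(x)


def partition_to_frames(part: VariantPartition) -> dict[str, pd.DataFrame]:
    frames = {}
    for name in VariantPartition._GROUPS:
        rows = [
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "gene": v.gene, "consequence": v.consequence,
                "freq_db1": v.freq_db1, "freq_db2": v.freq_db2,
                "freq_db3": v.freq_db3, "conservation": v.conservation,
                "deleteriousness": v.deleteriousness,
            }
            for v in getattr(part, name)
        ]
        frames[name] = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    return frames


def write_partition(part: VariantPartition, out_dir: str) -> None:
    """Write one TSV per partition group plus a JSON tally summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in partition_to_frames(part).items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    summary = {
        "counts": part.counts(),
        "tallies": part.tallies(),
        "total_inherited": part.total_inherited,
    }
    (out / "partition_summary.json").write_text(json.dumps(summary, indent=2))
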