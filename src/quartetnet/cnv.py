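"""Copy-number analysis from array-CGH probe log2 ratios.

Probes measure the log2 ratio of test vs reference intensities; runs of
consecutive probes above +0.3 (gains) or below -0.3 (losses) become
copy-number segments. Child segments are classified de novo vs inherited
by reciprocal overlap against parental calls, then filtered to de novo,
genic, >100 kb segments with a clinically concerning pathogenicity label.

Coordinates are 1-based inclusive throughout; BED input is converted on
read (BED is 0-based half-open).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

GAIN = "gain"
LOSS = "loss"

DE_NOVO = "de_novo"
INHERITED = "inherited"
UNKNOWN = "unknown"

#: pathogenicity labels retained by the default CNV filter
PATHOGENIC_KEEP = frozenset({"uncertain", "likely_pathogenic", "pathogenic"})


@dataclass
class CnvSegment:
    """A contiguous copy-number gain or loss interval (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    state: str  # gain | loss
    n_probes: int = 0
    member: str = ""
    inheritance: str = UNKNOWN
    pathogenicity: str = "unlabeled"
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.state not in (GAIN, LOSS):
            raise ValueError(f"unknown state {self.state!r}")


def segment_length(seg: CnvSegment) -> int:
    """Span of a segment in base pairs, end - start.

    Matches the convention under which chr4:71552-4673343 prints as a
    4.6-Mb duplication and chr8:176814-928886 as a 752-kb deletion.
    """
    if seg.start > seg.end:
        raise ValueError("start > end")
    return seg.end - seg.start


def format_length(bp: int) -> str:
    """Human-readable length: '4.6 Mb', '752 kb', '340 bp'."""
    if bp >= 1_000_000:
        return f"{bp / 1_000_000:.1f} Mb"
    if bp >= 1_000:
        return f"{round(bp / 1_000):d} kb"
    return f"{bp} bp"


def call_segments(
    probes: pd.DataFrame,
    gain_thr: float = 0.3,
    loss_thr: float = -0.3,
    min_probes: int = 3,
    member: str = "",
) -> list[CnvSegment]:
    """Threshold-run segmentation of a probe track.

    Maximal runs of >= ``min_probes`` consecutive probes on one
    chromosome all above ``gain_thr`` (or all below ``loss_thr``) become
    one segment spanning the first to the last probe position.

    ``probes`` needs columns chrom, pos, log2ratio, sorted by
    (chrom, pos) within each chromosome.
    """
    if not (gain_thr > 0 > loss_thr):
        raise ValueError("require gain_thr > 0 > loss_thr")
    if probes.empty:
        return []
    required = {"chrom", "pos", "log2ratio"}
    if not required.issubset(probes.columns):
        raise ValueError(f"probe table must have columns {sorted(required)}")
    if not probes["log2ratio"].map(math.isfinite).all():
        raise ValueError("non-finite log2 ratio in probe track")

    segments: list[CnvSegment] = []
    for chrom, track in probes.groupby("chrom", sort=False):
        pos = track["pos"].to_numpy()
        if (pos[1:] < pos[:-1]).any():
            raise ValueError(f"probe track not sorted by position on {chrom}")
        ratio = track["log2ratio"].to_numpy()
        state = [GAIN if r > gain_thr else LOSS if r < loss_thr else None for r in ratio]
        i = 0
        while i < len(state):
            if state[i] is None:
                i += 1
                continue
            j = i
            while j + 1 < len(state) and state[j + 1] == state[i]:
                j += 1
            if j - i + 1 >= min_probes:
                segments.append(
                    CnvSegment(
                        chrom=str(chrom),
                        start=int(pos[i]),
                        end=int(pos[j]),
                        state=state[i],
                        n_probes=j - i + 1,
                        member=member,
                    )
                )
            i = j + 1
    segments.sort(key=lambda s: (s.chrom, s.start, s.end))
    return segments


def reciprocal_overlap(a: CnvSegment, b: CnvSegment) -> float:
    """Smaller of the two mutual overlap fractions (0 when disjoint)."""
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    if inter <= 0:
        return 0.0
    len_a = a.end - a.start + 1
    len_b = b.end - b.start + 1
    return min(inter / len_a, inter / len_b)


def classify_inheritance(
    child_segs: list[CnvSegment],
    father_segs: list[CnvSegment],
    mother_segs: list[CnvSegment],
    min_reciprocal_overlap: float = 0.5,
) -> list[CnvSegment]:
    """Label each child segment inherited or de novo.

    A child segment is inherited when a same-state parental segment
    reciprocally overlaps it by at least ``min_reciprocal_overlap``
    (copy-number evidence only: a parental balanced rearrangement is
    copy-neutral and invisible here).
    """
    parental = list(father_segs) + list(mother_segs)
    out = []
    for seg in child_segs:
        inherited = any(
            p.state == seg.state
            and reciprocal_overlap(seg, p) >= min_reciprocal_overlap
            for p in parental
        )
        out.append(replace(seg, inheritance=INHERITED if inherited else DE_NOVO))
    return out


def load_gene_intervals(path: str, bed: bool | None = None) -> pd.DataFrame:
    """Read gene annotation intervals into a (chrom, start, end, gene) frame.

    ``bed=True`` converts 0-based half-open BED coordinates to the
    1-based inclusive convention used internally; files named *.bed are
    auto-detected.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene"],
        usecols=[0, 1, 2, 3],
        dtype={"chrom": str, "start": int, "end": int, "gene": str},
    )
    if bed is None:
        bed = str(path).endswith(".bed")
    if bed:
        df["start"] = df["start"] + 1
    return df


def map_genes(seg: CnvSegment, gene_intervals: pd.DataFrame) -> list[str]:
    """Symbols of all genes whose interval intersects the segment.

    Intervals are 1-based inclusive on both sides, so a gene starting at
    seg.end + 1 does not intersect. Result is deduplicated and sorted.
    """
    hits = gene_intervals[
        (gene_intervals["chrom"] == seg.chrom)
        & (gene_intervals["start"] <= seg.end)
        & (gene_intervals["end"] >= seg.start)
    ]
    return sorted(set(hits["gene"]))


def filter_cnvs(
    segs: list[CnvSegment],
    gene_map: pd.DataFrame,
    min_size: int = 100_000,
    allowed_pathogenicity: frozenset[str] = PATHOGENIC_KEEP,
) -> list[CnvSegment]:
    """Keep de novo genic segments larger than ``min_size`` (strict >)
    with pathogenicity in the allowed set; populates the genes field.
    """
    if gene_map is None:
        raise ValueError("gene_map is required to assess genic overlap")
    kept = []
    for seg in segs:
        if seg.inheritance != DE_NOVO:
            continue
        if segment_length(seg) <= min_size:
            continue
        if seg.pathogenicity not in allowed_pathogenicity:
            continue
        genes = map_genes(seg, gene_map)
        if not genes:
            continue
        kept.append(replace(seg, genes=genes))
    return kept


SEGMENT_COLUMNS = [
    "chrom", "start", "end", "state", "n_probes",
    "member", "inheritance", "pathogenicity", "genes",
]


def segments_to_frame(segs: list[CnvSegment]) -> pd.DataFrame:
    rows = [
        [s.chrom, s.start, s.end, s.state, s.n_probes, s.member,
         s.inheritance, s.pathogenicity, ",".join(s.genes)]
        for s in segs
    ]
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def frame_to_segments(df: pd.DataFrame) -> list[CnvSegment]:
    return [
        CnvSegment(
            chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            state=str(r.state), n_probes=int(r.n_probes), member=str(r.member),
            inheritance=str(r.inheritance), pathogenicity=str(r.pathogenicity),
            genes=[g for g in str(r.genes).split(",") if g],
        )
        for r in df.itertuples(index=False)
    ]
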