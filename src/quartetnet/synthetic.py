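"""Synthetic quartet data with planted ground truth.

Emulates the statistical structure the analysis assumes — a family
quartet (two parents, an affected male and female sibling) carrying:

* rare inherited deleterious heterozygous variants, some shared by both
  siblings and some exclusive to one (defaults 102 / 125 / 85, the
  partition the study design reports);
* de novo variants (parents homozygous reference);
* hemizygous X variants in the male with a carrier mother;
* two copy-number segments transmitted as an unbalanced translocation —
  a terminal duplication plus a terminal deletion in both children with
  copy-neutral parents;
* a protein-interaction edge list with planted hub / bridge / broker
  genes, real edges at confidence >= 0.4 and decoy edges below it.

Every non-planted "noise" variant is constructed to fail exactly one
named filter, so each filter has single-cause fixtures and a pipeline
that applies all filters recovers exactly the planted partition.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .quartet import FATHER, MOTHER, SIB_M, SIB_F, MEMBERS
from .variants import AnnotatedVariant, GenotypeCall

# noise failure modes, one filter each, cycled deterministically
NOISE_MODES = (
    "qc_depth", "qc_gq", "qc_base_q",
    "rarity", "consequence", "conservation", "deleteriousness",
)

_CONSEQUENCE_WEIGHTS = {
    "nonsynonymous_snv": 0.88,
    "frameshift_indel": 0.04,
    "nonframeshift_indel": 0.02,
    "stopgain": 0.03,
    "stoploss": 0.01,
    "splicing": 0.02,
}

_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))


@dataclass
class QuartetSpec:
    """Study conditions for one synthetic quartet.

    Defaults mirror the study design: a quartet sequenced to ~35x mean
    depth, a rare-variant partition of 102 shared / 125 male-exclusive /
    85 female-exclusive deleterious inherited variants, 3 hemizygous X
    variants in the male, a low de novo rate, and an unbalanced
    translocation (terminal 4p gain + terminal 8p loss) in both
    children.
    """

    seed: int = 0
    n_variants: int = 2000
    n_genes: int = 600
    de_novo_rate: float = 0.0005
    shared_inherited_count: int = 102
    male_exclusive_count: int = 125
    female_exclusive_count: int = 85
    hemizygous_x_count: int = 3
    maf_rare_max: float = 0.01
    depth_mean: float = 35.0
    gq_mean: float = 60.0
    # (chrom, start, end, state, carriers)
    cnv_plan: list[tuple] = field(default_factory=lambda: [
        ("chr4", 71_552, 4_673_343, "gain", (SIB_M, SIB_F)),
        ("chr8", 176_814, 928_886, "loss", (SIB_M, SIB_F)),
    ])
    chrom_lengths: dict = field(default_factory=lambda: {
        "chr1": 8_000_000, "chr4": 6_000_000, "chr8": 2_000_000,
    })
    probe_spacing: int = 25_000
    probe_sigma: float = 0.1
    network_model: str = "block"  # scale-free | block | custom
    planted_roles: dict = field(default_factory=dict)  # gene -> hub|bridge|broker
    n_network_genes: int = 120
    custom_edges: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = (
            self.n_variants, self.n_genes, self.shared_inherited_count,
            self.male_exclusive_count, self.female_exclusive_count,
            self.hemizygous_x_count,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if not 0 < self.maf_rare_max < 1:
            raise ValueError("maf_rare_max must be in (0, 1)")
        if not 0 <= self.de_novo_rate <= 1:
            raise ValueError("de_novo_rate must be a proportion")
        per_member: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, state, carriers in self.cnv_plan:
            if start > end:
                raise ValueError(f"CNV interval {chrom}:{start}-{end} inverted")
            if chrom not in self.chrom_lengths:
                raise ValueError(f"CNV chromosome {chrom} not declared")
            if state not in ("gain", "loss"):
                raise ValueError(f"unknown CNV state {state!r}")
            for m in carriers:
                key = f"{m}:{chrom}"
                for s0, e0 in per_member.setdefault(key, []):
                    if start <= e0 and end >= s0:
                        raise ValueError(f"overlapping planted CNVs for {m} on {chrom}")
                per_member[key].append((start, end))

    @property
    def gene_pool(self) -> list[str]:
        return [f"GENE{i:04d}" for i in range(1, self.n_genes + 1)]


@dataclass
class PlantedTruth:
    """Ground-truth labels for everything the generator planted."""

    # variant key "chrom:pos:ref:alt" -> inheritance label
    # (de_novo | inherited_paternal | inherited_maternal | hemizygous_x | noise)
    variant_labels: dict = field(default_factory=dict)
    # variant key -> sharing label (shared | male_only | female_only | none)
    sharing_labels: dict = field(default_factory=dict)
    # variant key -> the single filter each noise variant fails
    noise_modes: dict = field(default_factory=dict)
    # per planted segment: member, chrom, start, end, state, label
    segment_labels: list = field(default_factory=list)
    # gene -> hub | bridge | broker
    gene_roles: dict = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.sharing_labels.values():
            out[lab] = out.get(lab, 0) + 1
        return out

    def to_json(self, path: str) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list))


def _vkey(v: AnnotatedVariant) -> str:
    return f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}"


def _call(rng, depth_mean, gq_mean, alleles) -> GenotypeCall:
    # planted calls sit comfortably above every QC bar
    return GenotypeCall(
        alleles=alleles,
        depth=max(25, int(round(rng.normal(depth_mean, 5)))),
        gq=max(30, int(round(rng.normal(gq_mean, 8)))),
        base_q=max(33, int(round(rng.normal(38, 2)))),
    )


def _passing_annotations(rng, spec: QuartetSpec) -> dict:
    """Annotation fields that survive every annotation filter."""
    names = list(_CONSEQUENCE_WEIGHTS)
    probs = np.array(list(_CONSEQUENCE_WEIGHTS.values()))
    consequence = str(rng.choice(names, p=probs / probs.sum()))
    if rng.random() < 0.3:
        freqs = (None, None, None)  # novel: absent from all panels
    else:
        freqs = tuple(float(rng.uniform(1e-4, spec.maf_rare_max)) for _ in range(3))
    return {
        "consequence": consequence,
        "freq_db1": freqs[0], "freq_db2": freqs[1], "freq_db3": freqs[2],
        "conservation": float(rng.uniform(2.0, 6.0)),
        "deleteriousness": str(rng.choice(["deleterious", "possibly_deleterious"])),
    }


def generate_quartet_variants(spec: QuartetSpec) -> tuple[list[AnnotatedVariant], PlantedTruth]:
    """Emit the quartet variant table plus its planted truth.

    Planted variants obey Mendelian transmission (except de novo ones)
    and pass every filter; noise variants each violate exactly one.
    """
    rng = np.random.default_rng((spec.seed, 1))
    truth = PlantedTruth()
    n_dn_m = int(rng.binomial(spec.n_variants, spec.de_novo_rate))
    n_dn_f = int(rng.binomial(spec.n_variants, spec.de_novo_rate))
    planted_total = (
        spec.shared_inherited_count + spec.male_exclusive_count
        + spec.female_exclusive_count + spec.hemizygous_x_count
        + n_dn_m + n_dn_f
    )
    if planted_total > spec.n_variants:
        raise ValueError(
            f"planted counts ({planted_total}) exceed n_variants ({spec.n_variants})"
        )

    genes = itertools.cycle(spec.gene_pool)
    pos_counter = itertools.count(1_000_000, 997)
    # X positions start past PAR1 so male calls there are truly hemizygous
    x_pos_counter = itertools.count(3_000_000, 991)
    bases = ("A", "C", "G", "T")

    def new_variant(chrom: str, ann: dict, genotypes: dict) -> AnnotatedVariant:
        pos = next(x_pos_counter if chrom == "chrX" else pos_counter)
        ref, alt = rng.choice(bases, size=2, replace=False)
        return AnnotatedVariant(
            chrom=chrom, pos=pos, ref=str(ref), alt=str(alt),
            gene=next(genes), genotypes=genotypes, **ann,
        )

    variants: list[AnnotatedVariant] = []

    def het(member_set, rng=rng):
        """Quartet genotypes: alt inherited from one random parent into
        the given carrier children."""
        donor = FATHER if rng.random() < 0.5 else MOTHER
        g = {}
        for m in MEMBERS:
            if m == donor:
                g[m] = _call(rng, spec.depth_mean, spec.gq_mean, (0, 1))
            elif m in member_set:
                g[m] = _call(rng, spec.depth_mean, spec.gq_mean, (0, 1))
            else:
                g[m] = _call(rng, spec.depth_mean, spec.gq_mean, (0, 0))
        label = "inherited_paternal" if donor == FATHER else "inherited_maternal"
        return g, label

    def plant(carriers, sharing):
        chrom = str(rng.choice(_AUTOSOMES))
        g, label = het(carriers)
        v = new_variant(chrom, _passing_annotations(rng, spec), g)
        variants.append(v)
        truth.variant_labels[_vkey(v)] = label
        truth.sharing_labels[_vkey(v)] = sharing

    for _ in range(spec.shared_inherited_count):
        plant({SIB_M, SIB_F}, "shared")
    for _ in range(spec.male_exclusive_count):
        plant({SIB_M}, "male_only")
    for _ in range(spec.female_exclusive_count):
        plant({SIB_F}, "female_only")

    # hemizygous X in the male: carrier mother, haploid alt in the son
    for _ in range(spec.hemizygous_x_count):
        g = {
            FATHER: _call(rng, spec.depth_mean, spec.gq_mean, (0,)),
            MOTHER: _call(rng, spec.depth_mean, spec.gq_mean, (0, 1)),
            SIB_M: _call(rng, spec.depth_mean, spec.gq_mean, (1,)),
            SIB_F: _call(rng, spec.depth_mean, spec.gq_mean, (0, 0)),
        }
        v = new_variant("chrX", _passing_annotations(rng, spec), g)
        # positions from the counter stay outside both PARs by construction
        variants.append(v)
        truth.variant_labels[_vkey(v)] = "hemizygous_x"
        truth.sharing_labels[_vkey(v)] = "male_only"

    # de novo: parents homozygous reference
    for child, n_dn in ((SIB_M, n_dn_m), (SIB_F, n_dn_f)):
        for _ in range(n_dn):
            g = {
                m: _call(rng, spec.depth_mean, spec.gq_mean,
                         (0, 1) if m == child else (0, 0))
                for m in MEMBERS
            }
            v = new_variant(str(rng.choice(_AUTOSOMES)), _passing_annotations(rng, spec), g)
            variants.append(v)
            truth.variant_labels[_vkey(v)] = "de_novo"
            truth.sharing_labels[_vkey(v)] = "male_only" if child == SIB_M else "female_only"

    # noise: each fails exactly one named filter
    n_noise = spec.n_variants - planted_total
    for i in range(n_noise):
        mode = NOISE_MODES[i % len(NOISE_MODES)]
        carriers = {SIB_M} if rng.random() < 0.5 else {SIB_F}
        g, _ = het(carriers)
        ann = _passing_annotations(rng, spec)
        if mode == "qc_depth":
            member = str(rng.choice(MEMBERS))
            g[member] = GenotypeCall(g[member].alleles, int(rng.integers(0, 20)),
                                     g[member].gq, g[member].base_q)
        elif mode == "qc_gq":
            member = str(rng.choice(MEMBERS))
            g[member] = GenotypeCall(g[member].alleles, g[member].depth,
                                     int(rng.integers(0, 20)), g[member].base_q)
        elif mode == "qc_base_q":
            member = str(rng.choice(MEMBERS))
            g[member] = GenotypeCall(g[member].alleles, g[member].depth,
                                     g[member].gq, int(rng.integers(0, 30)))
        elif mode == "rarity":
            ann["freq_db2"] = float(rng.uniform(0.02, 0.5))
        elif mode == "consequence":
            ann["consequence"] = str(rng.choice(["synonymous", "other"]))
        elif mode == "conservation":
            ann["conservation"] = float(rng.uniform(-3.0, 1.99))
        elif mode == "deleteriousness":
            ann["deleteriousness"] = "benign"
        v = new_variant(str(rng.choice(_AUTOSOMES)), ann, g)
        variants.append(v)
        truth.variant_labels[_vkey(v)] = "noise"
        truth.sharing_labels[_vkey(v)] = "none"
        truth.noise_modes[_vkey(v)] = mode

    variants.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    return variants, truth


# ---------------------------------------------------------------------------
# probe tracks


_GAIN_SHIFT = float(np.log2(3 / 2))   # one extra copy on a diploid background
_LOSS_SHIFT = -1.0                    # one lost copy: log2(1/2)


def generate_probe_track(spec: QuartetSpec) -> dict[str, pd.DataFrame]:
    """Per-member probe tables (chrom, pos, log2ratio).

    Baseline ratios are Normal(0, sigma); probes inside a planted gain
    are re-centered at +log2(3/2) ~ +0.58, inside a loss at -1, for
    carrier members only.
    """
    tracks: dict[str, pd.DataFrame] = {}
    for m_i, member in enumerate(MEMBERS):
        rng = np.random.default_rng((spec.seed, 2, m_i))
        frames = []
        for chrom in sorted(spec.chrom_lengths):
            length = spec.chrom_lengths[chrom]
            pos = np.arange(spec.probe_spacing, length + 1, spec.probe_spacing)
            ratio = rng.normal(0.0, spec.probe_sigma, size=pos.size)
            for c, start, end, state, carriers in spec.cnv_plan:
                if c != chrom or member not in carriers:
                    continue
                inside = (pos >= start) & (pos <= end)
                shift = _GAIN_SHIFT if state == "gain" else _LOSS_SHIFT
                ratio[inside] += shift
            frames.append(pd.DataFrame(
                {"chrom": chrom, "pos": pos, "log2ratio": np.round(ratio, 4)}
            ))
        tracks[member] = pd.concat(frames, ignore_index=True)
    return tracks


def planted_segment_truth(spec: QuartetSpec) -> list[dict]:
    out = []
    for chrom, start, end, state, carriers in spec.cnv_plan:
        for m in carriers:
            label = "transmitted" if m in (SIB_M, SIB_F) else "parental"
            out.append({"member": m, "chrom": chrom, "start": start,
                        "end": end, "state": state, "label": label})
    return out


# ---------------------------------------------------------------------------
# interaction network


def generate_network(spec: QuartetSpec) -> tuple[pd.DataFrame, dict[str, str]]:
    """Edge list (geneA, geneB, combined_score) with planted roles.

    Real edges get confidence in [0.4, 1]; decoy edges in [0.05, 0.4).
    Role planting: a hub is wired to many otherwise-unconnected genes; a
    bridge is the sole connector between two dense blocks.
    """
    if spec.n_genes < 3:
        raise ValueError("need at least 3 genes")
    rng = np.random.default_rng((spec.seed, 3))
    n = min(spec.n_network_genes, spec.n_genes)
    # stride across the pool so network genes span every variant slice
    step = max(1, spec.n_genes // n)
    genes = spec.gene_pool[::step][:n]
    unknown = set(spec.planted_roles) - set(spec.gene_pool)
    if unknown:
        raise ValueError(f"planted roles reference unknown genes: {sorted(unknown)}")

    roles = dict(spec.planted_roles)
    g = nx.Graph()
    g.add_nodes_from(genes)

    if spec.network_model == "custom":
        g.add_edges_from((a, b) for a, b in spec.custom_edges if a != b)
    elif spec.network_model == "scale-free":
        ba = nx.barabasi_albert_graph(n, 2, seed=int(rng.integers(2**31)))
        relabel = dict(enumerate(genes))
        g = nx.relabel_nodes(ba, relabel)
    elif spec.network_model == "block":
        # two dense blocks joined only through a planted bridge gene
        reserved = [x for x in genes if x not in roles][: 1]
        bridge = next((x for x, r in roles.items() if r == "bridge"), None)
        if bridge is None:
            bridge = reserved[0]
            roles[bridge] = "bridge"
        rest = [x for x in genes if x != bridge]
        half = len(rest) // 2
        blocks = (rest[:half], rest[half:])
        for block in blocks:
            for i, a in enumerate(block):
                for b in block[i + 1:]:
                    if rng.random() < 0.5:
                        g.add_edge(a, b)
            # keep each block connected
            for a, b in zip(block, block[1:]):
                g.add_edge(a, b)
        g.add_edge(bridge, blocks[0][0])
        g.add_edge(bridge, blocks[1][0])
    else:
        raise ValueError(f"unknown network model {spec.network_model!r}")

    # wire planted hubs/brokers to otherwise-unconnected partners
    for gene, role in roles.items():
        if gene not in g:
            g.add_node(gene)
        if role in ("hub", "broker"):
            spokes = [x for x in genes if x != gene][:20]
            for s in spokes:
                g.add_edge(gene, s)

    rows = [
        (a, b, float(np.round(rng.uniform(0.4, 1.0), 3)))
        for a, b in sorted(tuple(sorted(e)) for e in g.edges)
    ]
    # decoys: absent pairs at sub-threshold confidence
    existing = {tuple(sorted(e)) for e in g.edges}
    n_decoys = max(5, len(rows) // 10)
    added = 0
    while added < n_decoys:
        a, b = rng.choice(genes, size=2, replace=False)
        pair = tuple(sorted((str(a), str(b))))
        if pair in existing:
            continue
        existing.add(pair)
        rows.append((pair[0], pair[1], float(np.round(rng.uniform(0.05, 0.399), 3))))
        added += 1
    edges = pd.DataFrame(rows, columns=["geneA", "geneB", "combined_score"])
    edges = edges.sort_values(["geneA", "geneB"]).reset_index(drop=True)
    return edges, roles


# ---------------------------------------------------------------------------
# writers (plain-text formats only)


def write_vcf(variants: list[AnnotatedVariant], vcf_path: str, ann_path: str) -> None:
    """Write the quartet VCF (GT:DP:GQ:BQ) and its annotation sidecar."""
    chroms = sorted({v.chrom for v in variants})
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=BQ,Number=1,Type=Integer,Description="Supporting base quality">',
    ]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(MEMBERS))
    ann_rows = []
    for v in sorted(variants, key=lambda x: (x.chrom, x.pos, x.ref, x.alt)):
        cells = []
        for m in MEMBERS:
            g = v.genotype(m)
            if g is None:
                cells.append("./.:.:.:.")
                continue
            gt = "/".join(str(a) for a in g.alleles)
            cells.append(f"{gt}:{g.depth}:{g.gq}:{g.base_q}")
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT:DP:GQ:BQ\t"
            + "\t".join(cells)
        )
        ann_rows.append({
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "gene": v.gene, "consequence": v.consequence,
            "freq_db1": _na(v.freq_db1), "freq_db2": _na(v.freq_db2),
            "freq_db3": _na(v.freq_db3), "conservation": _na(v.conservation),
            "deleteriousness": _na(v.deleteriousness),
        })
    Path(vcf_path).write_text("\n".join(lines) + "\n")
    pd.DataFrame(ann_rows).to_csv(ann_path, sep="\t", index=False, na_rep="NA")


def _na(x):
    return "NA" if x is None else x


def write_probe_tracks(tracks: dict[str, pd.DataFrame], out_dir: str) -> dict[str, str]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for member, df in tracks.items():
        p = out / f"probes_{member}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[member] = str(p)
    return paths


def write_edge_list(edges: pd.DataFrame, path: str) -> None:
    edges.to_csv(path, sep="\t", index=False)
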