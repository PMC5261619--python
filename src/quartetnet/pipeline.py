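"""End-to-end orchestration: CNV calls -> variant partition -> per-sibling
gene networks -> broker/bridge roles -> enrichment -> structured report.

All thresholds live on :class:`PipelineConfig` with the analysis
defaults baked in (log2-ratio +/-0.3, 100 kb, MAF 0.01, depth 20, GQ 20,
base quality 30, conservation 2, interaction confidence 0.4, role
percentile 95). Every threshold is logged at run start so the cascade is
auditable, and per-filter drop counts are kept so a filtering waterfall
can be reconstructed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import cnv as cnv_mod
from . import enrichment as enr_mod
from . import network as net_mod
from . import synthetic as syn_mod
from . import variants as var_mod
from .quartet import FATHER, MOTHER, SIB_M, SIB_F, MEMBERS, SIBLINGS

log = logging.getLogger("quartetnet")


@dataclass
class PipelineConfig:
    """Input paths plus every stage threshold, with analysis defaults."""

    # inputs
    vcf: str = ""
    annotations: str = ""
    probe_dir: str = ""
    gene_intervals: str = ""
    brain_genes: str = ""
    edges: str = ""
    categories: str = ""
    pathogenicity_labels: str = ""
    out_dir: str = "quartetnet_out"
    seed: int = 0
    # CNV thresholds
    gain_thr: float = 0.3
    loss_thr: float = -0.3
    min_probes: int = 3
    min_cnv_size: int = 100_000
    min_reciprocal_overlap: float = 0.5
    # variant thresholds
    min_depth: int = 20
    min_gq: int = 20
    min_base_q: int = 30
    maf_max: float = 0.01
    min_conservation: float = 2.0
    # network thresholds
    min_confidence: float = 0.4
    role_percentile: float = 95.0
    # enrichment
    n_permutations: int = 2000
    apply_brain_filter: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage(name: str):
    """Decorator: surface stage name on any error, per the abort contract."""
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


@_stage("cnv")
def _cnv_stage(config: PipelineConfig) -> dict:
    gene_map = cnv_mod.load_gene_intervals(config.gene_intervals)
    labels = None
    if config.pathogenicity_labels:
        labels = pd.read_csv(config.pathogenicity_labels, sep="\t", dtype={"chrom": str})
    calls: dict[str, list] = {}
    for member in MEMBERS:
        track = pd.read_csv(
            Path(config.probe_dir) / f"probes_{member}.tsv", sep="\t",
            dtype={"chrom": str},
        )
        calls[member] = cnv_mod.call_segments(
            track, config.gain_thr, config.loss_thr, config.min_probes, member=member
        )
    retained: dict[str, list] = {}
    for child in SIBLINGS:
        classified = cnv_mod.classify_inheritance(
            calls[child], calls[FATHER], calls[MOTHER],
            config.min_reciprocal_overlap,
        )
        classified = [apply_pathogenicity(s, labels) for s in classified]
        retained[child] = cnv_mod.filter_cnvs(
            classified, gene_map, config.min_cnv_size
        )
    return {"calls": calls, "retained": retained, "gene_map": gene_map}


def apply_pathogenicity(seg, labels: pd.DataFrame | None, min_ro: float = 0.5):
    """Label a segment from a (chrom, start, end, pathogenicity) table by
    best reciprocal overlap; unmatched segments stay 'unlabeled'."""
    if labels is None:
        return seg
    best, best_ro = None, 0.0
    for row in labels.itertuples(index=False):
        if str(row.chrom) != seg.chrom:
            continue
        other = cnv_mod.CnvSegment(str(row.chrom), int(row.start), int(row.end),
                                   seg.state)
        ro = cnv_mod.reciprocal_overlap(seg, other)
        if ro >= min_ro and ro > best_ro:
            best, best_ro = str(row.pathogenicity), ro
    return dataclasses.replace(seg, pathogenicity=best or "unlabeled")


@_stage("variants")
def _variant_stage(config: PipelineConfig) -> dict:
    variants = var_mod.read_quartet_vcf(config.vcf, config.annotations)
    drop_log = var_mod.DropLog()
    surviving = var_mod.run_cascade(
        variants,
        min_depth=config.min_depth, min_gq=config.min_gq,
        min_base_q=config.min_base_q, maf_max=config.maf_max,
        min_conservation=config.min_conservation, log=drop_log,
    )
    partition = var_mod.partition_siblings(surviving, log=drop_log)
    return {"n_input": len(variants), "partition": partition, "drop_log": drop_log}


@_stage("network")
def _network_stage(config: PipelineConfig, partition, cnv_retained) -> dict:
    edges = net_mod.load_edge_list(config.edges)
    brain = None
    if config.apply_brain_filter and config.brain_genes:
        brain = {
            line.strip() for line in Path(config.brain_genes).read_text().splitlines()
            if line.strip()
        }
    shared_genes = {v.gene for v in partition.shared}
    per_sibling = {}
    for child in SIBLINGS:
        cnv_genes = {g for seg in cnv_retained[child] for g in seg.genes}
        if child == SIB_M:
            excl = (
                {v.gene for v in partition.male_exclusive}
                | {v.gene for v in partition.de_novo_male}
                | {v.gene for v in partition.hemizygous_x_male}
            )
        else:
            excl = (
                {v.gene for v in partition.female_exclusive}
                | {v.gene for v in partition.de_novo_female}
            )
        gene_list = net_mod.assemble_gene_list(
            child, cnv_genes, shared_genes, excl, brain
        )
        net = net_mod.build_network(edges, gene_list.universe, config.min_confidence)
        component = net_mod.biggest_component(net)
        records = None
        if component.number_of_nodes() >= 2:
            records = net_mod.classify_roles(
                net_mod.centralities(component), config.role_percentile
            )
        per_sibling[child] = {
            "gene_list": gene_list,
            "network": net,
            "stats": net_mod.summary_stats(net),
            "component": component,
            "records": records,
        }
    comparison = net_mod.compare_components(
        set(per_sibling[SIB_M]["component"].nodes),
        set(per_sibling[SIB_F]["component"].nodes),
    )
    return {"edges": edges, "per_sibling": per_sibling, "comparison": comparison}


@_stage("enrichment")
def _enrichment_stage(config: PipelineConfig, net_result) -> dict:
    edges = net_result["edges"]
    background = nx.Graph()
    conf = edges["combined_score"].to_numpy()
    for (a, b), c in zip(zip(edges["geneA"], edges["geneB"]), conf):
        if a != b and c >= config.min_confidence:
            background.add_edge(a, b)
    out: dict[str, dict] = {}
    for child, data in net_result["per_sibling"].items():
        gene_set = set(data["network"].nodes) & set(background.nodes)
        entry: dict = {}
        if len(gene_set) >= 2 and background.number_of_nodes() > len(gene_set):
            res = enr_mod.edge_enrichment(
                gene_set, background, "permutation",
                n_permutations=config.n_permutations, seed=config.seed,
            )
            entry["edge_enrichment"] = dataclasses.asdict(res)
        if config.categories:
            cats = enr_mod.load_categories(config.categories)
            universe = set(background.nodes) | gene_set
            ora = enr_mod.over_representation(gene_set, cats, universe)
            entry["over_representation"] = ora.to_dict(orient="records")
        out[child] = entry
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and write the structured report.

    Returns the report dict; intermediates land under ``config.out_dir``.
    Deterministic given config + seed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("thresholds: %s", json.dumps(config.to_dict(), sort_keys=True))

    cnv_res = _cnv_stage(config)
    var_res = _variant_stage(config)
    net_res = _network_stage(config, var_res["partition"], cnv_res["retained"])
    enr_res = _enrichment_stage(config, net_res)

    # intermediates
    for member, segs in cnv_res["calls"].items():
        cnv_mod.segments_to_frame(segs).to_csv(
            out_dir / f"cnv_calls_{member}.tsv", sep="\t", index=False)
    for child, segs in cnv_res["retained"].items():
        cnv_mod.segments_to_frame(segs).to_csv(
            out_dir / f"cnv_retained_{child}.tsv", sep="\t", index=False)
    var_mod.write_partition(var_res["partition"], str(out_dir / "partition"))
    for child, data in net_res["per_sibling"].items():
        if data["records"] is not None:
            net_mod.centrality_report(data["records"], sibling=child).to_csv(
                out_dir / f"centrality_{child}.tsv", sep="\t")

    part = var_res["partition"]
    report = {
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "thresholds": config.to_dict(),
        },
        "variants": {
            "n_input": var_res["n_input"],
            "partition_counts": part.counts(),
            "total_inherited": part.total_inherited,
            "tallies": part.tallies(),
            "filter_drop_counts": var_res["drop_log"].counts(),
        },
        "cnv": {
            child: cnv_mod.segments_to_frame(segs).to_dict(orient="records")
            for child, segs in cnv_res["retained"].items()
        },
        "networks": {
            child: {
                "stats": data["stats"],
                "component_size": data["component"].number_of_nodes(),
                "brokers": _role_genes(data["records"], ("broker", "both")),
                "bridges": _role_genes(data["records"], ("bridge", "both")),
            }
            for child, data in net_res["per_sibling"].items()
        },
        "sibling_comparison": {
            "shared": sorted(net_res["comparison"]["shared"]),
            "exclusive_male": sorted(net_res["comparison"]["exclusive_a"]),
            "exclusive_female": sorted(net_res["comparison"]["exclusive_b"]),
            "counts": {k: len(v) for k, v in net_res["comparison"].items()},
        },
        "enrichment": enr_res,
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    (out_dir / "report.txt").write_text(render_report(report))
    return report


def _role_genes(records, roles: tuple[str, ...]) -> list[str]:
    if records is None:
        return []
    return sorted(records.index[records["role"].isin(roles)])


def render_report(report: dict) -> str:
    """Human-readable summary of the structured report."""
    lines = ["quartetnet analysis report", "=" * 30]
    v = report["variants"]
    lines.append(f"input variants: {v['n_input']}")
    lines.append(f"partition: {json.dumps(v['partition_counts'])}")
    lines.append(f"total rare inherited (shared+exclusive): {v['total_inherited']}")
    lines.append(f"per-filter drops: {json.dumps(v['filter_drop_counts'])}")
    for child, nw in report["networks"].items():
        lines.append(f"[{child}] network {json.dumps(nw['stats'])}")
        lines.append(f"[{child}] biggest component: {nw['component_size']} genes")
        lines.append(f"[{child}] brokers: {', '.join(nw['brokers']) or '-'}")
        lines.append(f"[{child}] bridges: {', '.join(nw['bridges']) or '-'}")
    c = report["sibling_comparison"]["counts"]
    lines.append(
        f"components share {c['shared']} genes; "
        f"{c['exclusive_a']} exclusive to male, {c['exclusive_b']} to female"
    )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# fixture generation


def make_fixture(seed: int, out_dir: str, spec: syn_mod.QuartetSpec | None = None) -> PipelineConfig:
    """Write a complete small synthetic dataset and its pipeline config.

    Emits the quartet VCF + annotation sidecar, per-member probe tracks,
    the interaction edge list, gene intervals, a brain-expressed gene
    list, pathogenicity labels for called segments, gene-set categories,
    the planted-truth JSON and a ready-to-run config.yaml.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if spec is None:
        spec = syn_mod.QuartetSpec(seed=seed)

    variants, truth = syn_mod.generate_quartet_variants(spec)
    syn_mod.write_vcf(variants, str(out / "quartet.vcf"), str(out / "annotations.tsv"))
    tracks = syn_mod.generate_probe_track(spec)
    syn_mod.write_probe_tracks(tracks, str(out))
    edges, roles = syn_mod.generate_network(spec)
    syn_mod.write_edge_list(edges, str(out / "edges.tsv"))
    truth.segment_labels = syn_mod.planted_segment_truth(spec)
    truth.gene_roles = roles
    truth.to_json(str(out / "truth.json"))

    # gene intervals: tile each declared chromosome; CNV regions genic
    rows = []
    pool = iter(spec.gene_pool)
    for chrom in sorted(spec.chrom_lengths):
        length = spec.chrom_lengths[chrom]
        for start in range(50_000, length - 150_000, 200_000):
            try:
                gene = next(pool)
            except StopIteration:
                break
            rows.append((chrom, start, start + 150_000, gene))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"]).to_csv(
        out / "gene_intervals.tsv", sep="\t", index=False, header=False)

    # brain list: everything but a tail of the pool, to exercise the filter
    brain = spec.gene_pool[: int(len(spec.gene_pool) * 0.95)]
    (out / "brain_genes.txt").write_text("\n".join(brain) + "\n")

    # planted CNVs are the clinically concerning ones
    pd.DataFrame(
        [(c, s, e, "pathogenic") for c, s, e, _state, _m in spec.cnv_plan],
        columns=["chrom", "start", "end", "pathogenicity"],
    ).to_csv(out / "pathogenicity.tsv", sep="\t", index=False)

    # simple categories over the gene pool for over-representation
    cats = []
    for i, gene in enumerate(spec.gene_pool):
        cats.append((f"CATEGORY_{i % 8}", gene))
    pd.DataFrame(cats, columns=["category", "gene"]).to_csv(
        out / "categories.tsv", sep="\t", index=False, header=False)

    config = PipelineConfig(
        vcf=str(out / "quartet.vcf"),
        annotations=str(out / "annotations.tsv"),
        probe_dir=str(out),
        gene_intervals=str(out / "gene_intervals.tsv"),
        brain_genes=str(out / "brain_genes.txt"),
        edges=str(out / "edges.tsv"),
        categories=str(out / "categories.tsv"),
        pathogenicity_labels=str(out / "pathogenicity.tsv"),
        out_dir=str(out / "results"),
        seed=seed,
    )
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return config
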