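"""End-to-end pipeline: simulate/load -> DE -> interactions -> triple network
-> competing-pair network (DCCN) -> topology/hubs/module -> enrichment.

Every stage writes its table or network under the output directory and the
run ends with ``manifest.json`` recording the applied thresholds, the seed
and a SHA-256 digest per output file; the manifest hash is deterministic for
identical (config, seed).  Empty intermediate results degrade gracefully:
downstream stages emit empty outputs and the run completes with warnings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cerna, enrichment, expression, synth, topology, triple
from .interactions import InteractionSet, load_interactions

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """One reproducible run: either synthetic mode (a SynthConfig) or real
    inputs (counts+sample sheet per class, or precomputed DE tables, plus an
    interaction TSV and optionally a GMT)."""

    outdir: str | Path = "results/run"
    seed: int = 0
    synthetic: synth.SynthConfig | None = None
    counts: dict[str, str] = field(default_factory=dict)  # class -> counts TSV
    sample_sheet: str | None = None
    de_tables: dict[str, str] = field(default_factory=dict)  # class -> DE TSV
    interactions_path: str | None = None
    gmt_path: str | None = None
    de_thresholds: expression.DEThresholds = field(default_factory=expression.DEThresholds)
    energy_cutoff: float = -20.0
    cerna_alpha: float = 0.05
    universe: int | str = "interactions"
    hub_k: int = 10
    enrich_max_fdr: float = 0.05
    enrich_max_p: float = 0.01

    def validate(self) -> None:
        real = bool(self.counts or self.de_tables)
        if self.synthetic is not None and real:
            raise ValueError("choose exactly one of synthetic mode or real inputs")
        if self.synthetic is None and not real:
            raise ValueError("no inputs: set synthetic= or counts=/de_tables=")
        for p in [
            *self.counts.values(),
            *self.de_tables.values(),
            *(x for x in (self.sample_sheet, self.interactions_path, self.gmt_path) if x),
        ]:
            if not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            sy = raw["synthetic"]
            if "nb_mean_range" in sy:
                sy["nb_mean_range"] = tuple(sy["nb_mean_range"])
            raw["synthetic"] = synth.SynthConfig(**sy)
        if "de_thresholds" in raw:
            raw["de_thresholds"] = expression.DEThresholds(**raw["de_thresholds"])
        return cls(**raw)

    def _hashable(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("outdir")  # where outputs land must not change what they are
        return d


@dataclass
class RunReport:
    counts: dict[str, int]
    hubs: list[str]
    module_genes: list[str]
    enrichment: pd.DataFrame
    files: dict[str, str]
    manifest_hash: str
    warnings: list[str]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _empty(path: Path, header: str) -> None:
    path.write_text(header)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage in order and write all artifacts plus a manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    files: dict[str, Path] = {}
    stats: dict[str, int] = {}

    # ---- stage 1: inputs (simulate or load) -------------------------------
    truth = None
    gmt_path = config.gmt_path
    if config.synthetic is not None:
        scfg = dataclasses.replace(config.synthetic, seed=config.seed)
        matrices, truth = synth.generate_counts(scfg)
        inter_set = synth.generate_interactions(scfg, truth)
        gene_sets = synth.generate_gene_sets(scfg, truth)
        for cls, mat in matrices.items():
            p = outdir / f"counts_{cls}.tsv"
            mat.write_tsv(p)
            files[f"counts_{cls}"] = p
        sheet = outdir / "samples.tsv"
        sheet.write_text(
            "sample_id\tgroup\n"
            + "".join(f"{s}\t{g}\n" for s, g in matrices["mRNA"].groups.items())
        )
        files["samples"] = sheet
        ip = outdir / "interactions.tsv"
        inter_set.to_tsv(ip)
        files["interactions_input"] = ip
        gp = outdir / "gene_sets.gmt"
        gene_sets.to_gmt(gp)
        files["gene_sets"] = gp
        tp = outdir / "ground_truth.json"
        truth.to_json(tp)
        files["ground_truth"] = tp
        interactions_path = ip
        gmt_path = gp
    else:
        matrices = {
            cls: expression.read_counts(path, config.sample_sheet, cls)
            for cls, path in config.counts.items()
        }
        interactions_path = config.interactions_path

    # ---- stage 2: DE ------------------------------------------------------
    de_frames = []
    if config.de_tables:
        for cls, path in config.de_tables.items():
            de_frames.append(expression.read_de_table(path))
    else:
        for cls, mat in matrices.items():
            filtered = expression.filter_low_counts(mat, min_count=2)
            stats[f"n_{cls}_after_low_count"] = len(filtered.values)
            de_frames.append(expression.test_de(filtered))
    de_all = pd.concat(de_frames, ignore_index=True) if de_frames else pd.DataFrame(
        columns=["feature_id", "feature_class", "log2fc", "p_value", "status"]
    )
    de_sets: dict[str, dict[str, str]] = {c: {} for c in ("mRNA", "miRNA", "circRNA")}
    if len(de_all):
        _, _, de_all = expression.filter_de(de_all, config.de_thresholds)
        for row in de_all.itertuples():
            if row.status != "NS":
                de_sets[row.feature_class][row.feature_id] = row.status
    de_path = outdir / "de_table.tsv"
    de_all.to_csv(de_path, sep="\t", index=False)
    files["de_table"] = de_path
    for cls in de_sets:
        stats[f"n_de_{cls}"] = len(de_sets[cls])
    if not any(de_sets.values()):
        warnings.append("no differentially expressed features; networks will be empty")

    # ---- stage 3: interactions -------------------------------------------
    if interactions_path is not None:
        inter = load_interactions(interactions_path, energy_cutoff=config.energy_cutoff)
    else:
        inter = InteractionSet(records=pd.DataFrame(columns=["mirna_id", "target_id", "target_class"]))
        warnings.append("no interaction table supplied")
    stats["n_interactions_after_energy_filter"] = len(inter)
    fp = outdir / "interactions_filtered.tsv"
    inter.to_tsv(fp)
    files["interactions_filtered"] = fp

    # ---- stage 4: triple network -----------------------------------------
    net = triple.build_triple_network(
        de_sets["miRNA"], de_sets["circRNA"], de_sets["mRNA"], inter
    )
    stats.update({f"triple_{k}": v for k, v in net.summary().items()})
    net.to_sif(outdir / "triple_network.sif")
    net.to_graphml(outdir / "triple_network.graphml")
    files["triple_sif"] = outdir / "triple_network.sif"
    files["triple_graphml"] = outdir / "triple_network.graphml"
    if net.n_edges == 0:
        warnings.append("triple network empty")

    # ---- stage 5: competing pairs / DCCN ---------------------------------
    universe = inter if config.universe == "interactions" else config.universe
    if net.n_edges and len(inter):
        dccn = cerna.build_dccn(net, universe=universe, alpha=config.cerna_alpha)
        dccn.write_pairs_tsv(outdir / "competing_pairs.tsv")
        dccn.to_sif(outdir / "dccn.sif")
        dccn.to_graphml(outdir / "dccn.graphml")
        g = dccn.graph
    else:
        dccn = None
        _empty(outdir / "competing_pairs.tsv",
               "circ_id\tmrna_id\tm\tt\tn\tr\tp_value\tshared_ids\tfdr\n")
        _empty(outdir / "dccn.sif", "")
        import networkx as nx

        g = nx.Graph()
        nx.write_graphml(g, outdir / "dccn.graphml")
        warnings.append("DCCN empty")
    files["competing_pairs"] = outdir / "competing_pairs.tsv"
    files["dccn_sif"] = outdir / "dccn.sif"
    files["dccn_graphml"] = outdir / "dccn.graphml"
    stats["dccn_n_edges"] = g.number_of_edges()
    stats["dccn_n_circ"] = sum(1 for _, d in g.nodes(data=True) if d.get("kind") == "circRNA")
    stats["dccn_n_mrna"] = sum(1 for _, d in g.nodes(data=True) if d.get("kind") == "mRNA")

    # ---- stage 6: topology, hubs, module ---------------------------------
    topo = topology.compute_centralities(g)
    topo.to_csv(outdir / "topology.tsv", sep="\t", index=False)
    files["topology"] = outdir / "topology.tsv"
    comparison = {}
    try:
        fit = topology.fit_power_law([d for _, d in g.degree()])
        comparison["power_law"] = {
            "slope": fit.slope,
            "r_squared": fit.r_squared,
            "n_points": fit.n_points,
            "distribution": fit.distribution,
        }
    except ValueError as exc:
        warnings.append(f"power-law fit unavailable: {exc}")
    if not topo.empty and {"circRNA", "mRNA"} <= set(topo["node_class"]):
        for metric in ("degree", "betweenness", "closeness"):
            cmp_res = topology.compare_classes(topo, metric, "circRNA", "mRNA")
            comparison[metric] = dataclasses.asdict(cmp_res)
    (outdir / "topology_comparison.json").write_text(
        json.dumps(comparison, indent=1, sort_keys=True)
    )
    files["topology_comparison"] = outdir / "topology_comparison.json"

    hubs = topology.select_hubs(topo, k=config.hub_k) if not topo.empty else []
    (outdir / "hubs.txt").write_text("".join(f"{h}\n" for h in hubs))
    files["hubs"] = outdir / "hubs.txt"
    stats["n_hubs"] = len(hubs)

    module_genes: list[str] = []
    if hubs:
        hub_circ = [h for h in hubs if g.nodes[h].get("kind") == "circRNA"] or hubs
        module = topology.extract_module(g, hub_circ)
        import networkx as nx

        nx.write_graphml(module.graph, outdir / "key_module.graphml")
        module_genes = module.genes()
        stats["module_n_nodes"] = len(module.node_ids)
        stats["module_n_edges"] = module.n_edges
    else:
        import networkx as nx

        nx.write_graphml(nx.Graph(), outdir / "key_module.graphml")
        warnings.append("no hubs; key module empty")
    files["key_module"] = outdir / "key_module.graphml"
    (outdir / "module_genes.txt").write_text("".join(f"{x}\n" for x in module_genes))
    files["module_genes"] = outdir / "module_genes.txt"
    stats["module_n_genes"] = len(module_genes)

    # ---- stage 7: enrichment ---------------------------------------------
    enr_cols = "term\tname\tk\tK\tn\tN\tp_value\tfdr\thit_ids\n"
    enr = pd.DataFrame()
    if module_genes and gmt_path is not None:
        coll = enrichment.GeneSetCollection.from_gmt(gmt_path)
        try:
            enr = enrichment.enrich(module_genes, coll)
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            sig = enrichment.filter_significant(
                enr, max_fdr=config.enrich_max_fdr, max_p=config.enrich_max_p
            )
            sig.to_csv(outdir / "enrichment_significant.tsv", sep="\t", index=False)
            stats["n_terms_significant"] = len(sig)
        except ValueError as exc:
            warnings.append(f"enrichment skipped: {exc}")
            _empty(outdir / "enrichment.tsv", enr_cols)
            _empty(outdir / "enrichment_significant.tsv", enr_cols)
    else:
        if gmt_path is None:
            warnings.append("no gene sets supplied; enrichment skipped")
        _empty(outdir / "enrichment.tsv", enr_cols)
        _empty(outdir / "enrichment_significant.tsv", enr_cols)
    files["enrichment"] = outdir / "enrichment.tsv"
    files["enrichment_significant"] = outdir / "enrichment_significant.tsv"

    # ---- manifest ---------------------------------------------------------
    digests = {name: _sha256(p) for name, p in sorted(files.items())}
    manifest = {
        "config": config._hashable(),
        "seed": config.seed,
        "stats": stats,
        "warnings": warnings,
        "files": digests,
    }
    payload = json.dumps(manifest, sort_keys=True, default=str)
    manifest_hash = hashlib.sha256(payload.encode()).hexdigest()
    manifest["manifest_hash"] = manifest_hash
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))

    for w in warnings:
        logger.warning(w)
    return RunReport(
        counts=stats,
        hubs=hubs,
        module_genes=module_genes,
        enrichment=enr,
        files={k: str(v) for k, v in files.items()},
        manifest_hash=manifest_hash,
        warnings=warnings,
    )
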