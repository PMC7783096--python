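"""End-to-end orchestration of the synthetic census pipeline.

One config drives simulate -> census -> phylogeny -> genome_map -> expression
-> coexpression and a machine-readable report.  A single master seed
deterministically derives per-stage seeds, so two runs with the same config
produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import census, coexpression, expression, genome_map, phylogeny, simulate

log = logging.getLogger("genefam.pipeline")


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


_DEFAULT_ARCHITECTURES = (
    ("SP", "LRR", "MD", "TMD", "PK"),
    ("SP", "MLD", "LRR", "TMD", "PK"),
    ("SP", "MLD", "TMD", "PK"),
    ("SP", "MLD", "LRR"),
    ("MD", "Kin"),
    ("SP", "LRR", "MD", "TMD", "PK"),  # same pattern as clade 1: split by divergence
)

_DEFAULT_TISSUES = (
    "leaf_young",
    "leaf_mature",
    "leaf_stressed",
    "root",
    "phloem",
    "cambium",
    "xylem_sw",
    "maturation",
)


@dataclass
class PipelineConfig:
    """Every stage parameter with a default; round-trips losslessly to YAML."""

    seed: int = 1
    # family / census
    architectures: tuple = _DEFAULT_ARCHITECTURES
    genes_per_clade: tuple = (8, 6, 5, 4, 3, 4)
    substitution_rate: float = 0.02
    clade_divergence: float = 0.08
    background_genes: int = 40
    min_identity: float = 0.7
    mld_gap: int = 120
    # layout / genome map
    n_chromosomes: int = 6
    chromosome_length: int = 8_000_000
    planted_clusters: tuple = (
        ("Chr01", 3, 2, 250_000),
        ("Chr02", 2, 0, 250_000),
        ("Chr03", 4, 3, 250_000),
        ("Chr04", 2, 1, 250_000),
    )
    scaffold_fraction: float = 0.13
    max_intervening: int = 8
    max_gap: int = 250_000
    # phylogeny
    distance_correction: str = "poisson"
    n_bootstrap: int = 100
    min_support: float = 60.0
    min_size: int = 2
    # expression
    tissues: tuple = _DEFAULT_TISSUES
    replicates: int = 3
    dispersion: float = 0.05
    experiments: tuple = (("atlas", 1.0), ("wood", 1.3))
    peak_mean: float = 150.0
    base_mean: float = 8.0
    module_mean: float = 60.0
    module_size: int = 5
    latent_sd: float = 0.9
    expression_background_genes: int = 120
    # coexpression; 5 bins suit the short synthetic series (the module default
    # of 10 assumes a longer profile series)
    bins: int = 5
    z_threshold: float = 5.0

    def to_dict(self) -> dict:
        return _tuples_to_lists(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = dict(data)
        for key in ("architectures", "planted_clusters", "experiments"):
            if key in kwargs:
                kwargs[key] = tuple(tuple(x) for x in kwargs[key])
        for key in ("genes_per_clade", "tissues"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _tuples_to_lists(obj):
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    return obj


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(5)
    return {
        "proteome": int(state[0]),
        "layout": int(state[1]),
        "counts": int(state[2]),
        "bootstrap": int(state[3]),
        "profiles": int(state[4]),
    }


def _truth_alignment(
    sequences: dict[str, str], hits: pd.DataFrame
) -> phylogeny.Alignment:
    """Slot-aligned matrix of planted domain residues.

    Domain copies are substitution-only mutations of fixed-length consensi, so
    every k-th instance of a token occupies one fixed column block; proteins
    lacking a slot get gaps there.  This stands in for the externally built
    multiple alignment the phylogeny stage normally consumes.
    """
    per_protein: dict[str, dict[tuple[str, int], str]] = {}
    slot_width: dict[tuple[str, int], int] = {}
    for pid, grp in hits.groupby("protein", sort=False):
        occ: dict[str, int] = {}
        slots = {}
        for r in grp.sort_values("start").itertuples():
            k = occ.get(r.token, 0)
            occ[r.token] = k + 1
            piece = sequences[pid][int(r.start) - 1 : int(r.end)]
            slots[(r.token, k)] = piece
            slot_width[(r.token, k)] = max(slot_width.get((r.token, k), 0), len(piece))
        per_protein[pid] = slots
    slot_order = sorted(slot_width)
    taxa, rows = [], []
    for pid, slots in per_protein.items():
        row = "".join(
            slots.get(slot, "").ljust(slot_width[slot], "-") for slot in slot_order
        )
        taxa.append(pid)
        rows.append(row)
    return phylogeny.Alignment(tuple(taxa), tuple(rows))


def _build_mean_profile(config: PipelineConfig, family_ids: list[str], profile_seed: int = 0):
    """Planted tissue profiles plus two co-expression modules on flat genes.

    Background expression genes pad the matrix so CLR row statistics have a
    stable reference distribution (as they would in a transcriptome-wide run).
    """
    tissues = list(config.tissues)
    n_module = 2 * config.module_size
    if n_module + 2 > len(family_ids):
        raise ValueError("family too small for the planted modules")
    module_genes = family_ids[-n_module:]
    profile = {}
    for i, gid in enumerate(family_ids):
        if gid in module_genes:
            profile[gid] = [config.module_mean] * len(tissues)
        else:
            row = [config.base_mean] * len(tissues)
            row[i % len(tissues)] = config.peak_mean
            profile[gid] = row
    rng = np.random.default_rng(profile_seed)
    for i in range(config.expression_background_genes):
        row = rng.uniform(5.0, 40.0, len(tissues))
        row[rng.integers(len(tissues))] *= rng.uniform(2.0, 6.0)
        profile[f"EXP{i + 1:04d}"] = list(row)
    mean_profile = pd.DataFrame.from_dict(profile, orient="index", columns=tissues)
    half = config.module_size
    mod_a = tuple(module_genes[:half])
    mod_b = tuple(module_genes[half:])
    modules = (
        simulate.PlantedModule("M1", mod_a, tuple([1] * half)),
        # one anti-correlated member exercises the edge-sign rule
        simulate.PlantedModule("M2", mod_b, tuple([1] * (half - 1) + [-1])),
    )
    return mean_profile, modules


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run every stage on synthetic inputs; return (and optionally write) the report."""
    seeds = _stage_seeds(config.seed)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stage_seeds": seeds, "parameters": config.to_dict()}

    # ----- simulate ---------------------------------------------------------
    try:
        log.info("simulate: proteome seed=%d", seeds["proteome"])
        models = simulate.default_domain_models(min_identity=config.min_identity)
        fam_spec = simulate.FamilySpec(
            architectures=config.architectures,
            genes_per_clade=config.genes_per_clade,
            substitution_rate=config.substitution_rate,
            background_genes=config.background_genes,
            clade_divergence=config.clade_divergence,
        )
        proteome = simulate.generate_proteome(fam_spec, models, seeds["proteome"])
        family = proteome.proteins[proteome.proteins.clade != ""]
        family_ids = list(family.protein)
        layout = simulate.LayoutSpec(
            chromosomes=tuple(
                (f"Chr{i + 1:02d}", config.chromosome_length)
                for i in range(config.n_chromosomes)
            ),
            planted_clusters=tuple(
                simulate.PlantedCluster(*pc) for pc in config.planted_clusters
            ),
            scaffold_fraction=config.scaffold_fraction,
        )
        genome = simulate.generate_gene_models(family_ids, layout, seeds["layout"])
        mean_profile, modules = _build_mean_profile(config, family_ids, seeds["profiles"])
        expr_spec = simulate.ExpressionSpec(
            tissues=config.tissues,
            experiments=config.experiments,
            mean_profile=mean_profile,
            dispersion=config.dispersion,
            replicates=config.replicates,
            seed=seeds["counts"],
            modules=modules,
            latent_sd=config.latent_sd,
        )
        sim_counts = simulate.generate_counts(expr_spec)
    except Exception as exc:
        raise PipelineError("simulate", exc) from exc

    report["simulate"] = {
        "family_size": len(family_ids),
        "background_proteins": int((proteome.proteins.clade == "").sum()),
        "planted_clusters": [list(members) for _, members in genome.clusters],
    }

    # ----- census -----------------------------------------------------------
    try:
        log.info("census: %d proteins", len(proteome.proteins))
        arch_df, hits_df = census.annotate_proteins(
            ((pid, proteome.sequences[pid]) for pid in proteome.proteins.protein),
            models,
            mld_gap=config.mld_gap,
        )
    except Exception as exc:
        raise PipelineError("census", exc) from exc

    merged_truth = family.merge(arch_df, on="protein")
    arch_ok = (
        merged_truth.architecture_x == merged_truth.architecture_y
    ).mean() if len(merged_truth) else 0.0
    superclade_truth = {
        row.protein: census.classify_superclade(row.architecture.split("-"))
        for row in family.itertuples()
    }
    supercl_ok = (
        merged_truth.apply(
            lambda r: superclade_truth[r.protein] == r.superclade, axis=1
        ).mean()
        if len(merged_truth)
        else 0.0
    )
    fam_arch = arch_df[arch_df.protein.isin(family_ids)]
    superclade_counts = fam_arch.superclade.value_counts().sort_index().to_dict()
    report["census"] = {
        "architecture_recovery": float(arch_ok),
        "superclade_recovery": float(supercl_ok),
        "superclade_counts": {k: int(v) for k, v in superclade_counts.items()},
    }

    # ----- phylogeny --------------------------------------------------------
    try:
        aln = _truth_alignment(dict(proteome.sequences), proteome.hits)
        log.info(
            "phylogeny: %d taxa x %d columns, %d bootstrap replicates",
            len(aln.taxa), aln.n_columns, config.n_bootstrap,
        )
        tree = phylogeny.bootstrap_support(
            aln, config.n_bootstrap, seeds["bootstrap"], config.distance_correction
        )
        partition = phylogeny.extract_clades(
            tree, min_support=config.min_support, min_size=config.min_size
        )
    except Exception as exc:
        raise PipelineError("phylogeny", exc) from exc

    planted_clades = [
        frozenset(family[family.clade == c].protein)
        for c in sorted(family.clade.unique())
    ]
    # a planted clade is recovered when it is a supported subtree of the tree
    # (the *maximal* partition may legitimately merge clades under a supported
    # backbone node, so the partition itself is reported separately)
    all_taxa = frozenset(tree.taxa)
    supported_sets = {
        frozenset(node.leaves())
        for node in tree.internal_nodes()
        if node.support is not None and node.support >= config.min_support
    }
    supported_sets |= {all_taxa - s for s in supported_sets}
    clade_recovery = sum(1 for s in planted_clades if s in supported_sets) / len(
        planted_clades
    )
    report["phylogeny"] = {
        "n_clades": len(partition.clades),
        "n_orphans": len(partition.orphans),
        "clade_recovery": float(clade_recovery),
        "clades": [
            {
                "id": c.clade_id,
                "size": len(c.members),
                "support": c.support,
                "members": list(c.members),
            }
            for c in partition.clades
        ],
    }

    # ----- genome map -------------------------------------------------------
    try:
        gene_models = genome_map.read_gff(genome.gff)
        rule = genome_map.ClusterRule(config.max_intervening, config.max_gap)
        clusters = genome_map.detect_tandem_clusters(family_ids, gene_models, rule)
        fam_models = [g for g in gene_models if g.gene_id in set(family_ids)]
        localization = genome_map.localization_summary(fam_models)
    except Exception as exc:
        raise PipelineError("genome_map", exc) from exc

    planted_sets = {frozenset(members) for _, members in genome.clusters}
    detected_sets = {frozenset(c.members) for c in clusters}
    cluster_recovery = (
        sum(1 for s in planted_sets if s in detected_sets) / len(planted_sets)
        if planted_sets
        else 1.0
    )
    superclade_of = dict(zip(fam_arch.protein, fam_arch.superclade))
    intron_max: dict[str, int] = {}
    for g in fam_models:
        sc = superclade_of.get(g.gene_id, "Unclassified")
        intron_max[sc] = max(intron_max.get(sc, 0), genome_map.count_introns(g))
    report["genome_map"] = {
        "clusters": [
            {
                "id": c.cluster_id,
                "seqid": c.seqid,
                "size": len(c.members),
                "span": c.span,
                "members": list(c.members),
            }
            for c in clusters
        ],
        "cluster_recovery": float(cluster_recovery),
        "localization": localization,
        "intron_max_per_superclade": dict(sorted(intron_max.items())),
    }

    # ----- expression -------------------------------------------------------
    try:
        merged = expression.merge_experiments(dict(sim_counts.counts))
        family_matrix = merged.loc[family_ids]
        scores = expression.score_genes(
            family_matrix, sim_counts.metadata, config.tissues
        )
        order = expression.heatmap_order(
            family_matrix, scores.peak_tissue, config.tissues
        )
    except Exception as exc:
        raise PipelineError("expression", exc) from exc

    module_genes = {g for m in sim_counts.modules for g in m.genes}
    specific = [g for g in family_ids if g not in module_genes]
    peak_ok = float(
        np.mean(
            [scores.loc[g, "peak_tissue"] == sim_counts.peak_tissue[g] for g in specific]
        )
    )
    report["expression"] = {
        "n_genes": int(family_matrix.shape[0]),
        "n_samples": int(merged.shape[1]),
        "tau_mean": float(scores.tau.mean()),
        "tau_min": float(scores.tau.min()),
        "tau_max": float(scores.tau.max()),
        "peak_group_sizes": {t: len(genes) for t, genes in order},
        "peak_recovery_specific": peak_ok,
    }

    # ----- coexpression -----------------------------------------------------
    try:
        series = merged[sim_counts.metadata["sample"].tolist()]
        guides = sorted(m.genes[0] for m in sim_counts.modules)
        net = coexpression.guide_network(
            series, guides, z_threshold=config.z_threshold, bins=config.bins
        )
    except Exception as exc:
        raise PipelineError("coexpression", exc) from exc

    per_guide = {}
    for g in guides:
        touching = net.edges[(net.edges.source == g) | (net.edges.target == g)]
        per_guide[g] = {
            "degree": int(len(touching)),
            "positive": int((touching.sign == "+").sum()),
            "negative": int((touching.sign == "-").sum()),
        }
    truth_edges = set()
    for m in sim_counts.modules:
        g = m.genes[0]
        truth_edges |= {frozenset((g, other)) for other in m.genes[1:]}
    found_edges = {frozenset((r.source, r.target)) for r in net.edges.itertuples()}
    recall = (
        len(truth_edges & found_edges) / len(truth_edges) if truth_edges else 1.0
    )
    precision = (
        len(truth_edges & found_edges) / len(found_edges) if found_edges else 1.0
    )
    report["coexpression"] = {
        "per_guide": per_guide,
        "isolated_guides": list(net.isolated_guides),
        "guide_edge_recall": float(recall),
        "guide_edge_precision": float(precision),
        "n_edges": int(len(net.edges)),
    }

    if out is not None:
        _write_outputs(
            out, proteome, genome, sim_counts, arch_df, hits_df, tree, partition,
            clusters, merged, scores, order, net, report,
        )
    return report


def _write_outputs(
    out: Path, proteome, genome, sim_counts, arch_df, hits_df, tree, partition,
    clusters, merged, scores, order, net, report,
) -> None:
    (out / "proteome.fasta").write_text(proteome.fasta)
    proteome.proteins.to_csv(out / "truth_proteins.tsv", sep="\t", index=False)
    proteome.hits.to_csv(out / "truth_hits.tsv", sep="\t", index=False)
    (out / "genes.gff3").write_text(genome.gff)
    genome.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    for exp, df in sim_counts.counts.items():
        df.to_csv(out / f"counts_{exp}.tsv", sep="\t", index_label="gene")
    sim_counts.metadata.to_csv(out / "samples.tsv", sep="\t", index=False)
    sim_counts.peak_tissue.to_frame().to_csv(
        out / "truth_peaks.tsv", sep="\t", index_label="gene"
    )
    arch_df.to_csv(out / "architectures.tsv", sep="\t", index=False)
    hits_df.to_csv(out / "domain_hits.tsv", sep="\t", index=False)
    (out / "tree.nwk").write_text(tree.newick() + "\n")
    phylogeny.clades_to_frame(partition).to_csv(out / "clades.tsv", sep="\t", index=False)
    genome_map_frame = genome_map.clusters_to_frame(clusters)
    genome_map_frame.to_csv(out / "clusters.tsv", sep="\t", index=False)
    merged.to_csv(out / "expression.tsv", sep="\t", index_label="gene")
    scores.to_csv(out / "tau.tsv", sep="\t")
    rows = [
        {"gene": g, "group": t, "position": i}
        for t, genes in order
        for i, g in enumerate(genes)
    ]
    pd.DataFrame(rows, columns=["gene", "group", "position"]).to_csv(
        out / "heatmap_order.tsv", sep="\t", index=False
    )
    net.edges.to_csv(out / "coexpression_edges.tsv", sep="\t", index=False)
    coexpression.export_graphml(net, out / "network.graphml")
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
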