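"""Pipeline orchestration and clade-level summaries.

Ties the modules together: simulate or load genomes, filter, discover core
families over the guide taxonomy, build the core-gene and functional trees,
compare them, compute per-clade COG-category enrichment and phylogenetic
alpha-diversity, and emit a clade summary table.  Also houses the rank
correlation between alpha-diversity and core-set size, and the packaged
published clade-overview table it can be evaluated on.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import core_discovery, functional_profiles, genome_io, guide_taxonomy
from . import phylo_trees, synthetic_pangenome, tree_comparison
from .homology_search import SearchParams

logger = logging.getLogger(__name__)


def spearman_rho(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: rho undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def load_table1() -> pd.DataFrame:
    """The packaged clade-overview table (32 clades with >= 30 genomes)."""
    with resources.files("coregenes.data").joinpath("table1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def table1_spearman() -> tuple[float, float]:
    """Spearman rho between alpha-diversity and core-family counts (packaged table)."""
    t = load_table1()
    return spearman_rho(t["alpha_diversity"], t["n_core_families"])


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping or a YAML file path")
    return config


def run_pipeline(config, out_dir: str | Path) -> dict:
    """Run the whole analysis; write artifacts into ``out_dir``.

    The config either names input directories (``genomes_dir``, ``taxonomy``,
    ``annotations``) or a ``simulate`` block for a synthetic scenario.  All
    stages are deterministic given the seed.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    params = SearchParams(**cfg.get("search", {}))

    # --- stage: inputs -----------------------------------------------------
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        tax = synthetic_pangenome.balanced_taxonomy(
            sim.pop("n_clades", 3), sim.pop("genomes_per_clade", 3))
        counts = sim.pop("n_core_per_clade", {"root": 3})
        counts = {
            (tid if tid in tax.index else tid): n for tid, n in counts.items()
        }
        scfg = synthetic_pangenome.SimulationConfig(
            taxonomy=tax, n_core_per_clade=counts,
            seed=sim.pop("seed", seed), **sim)
        genomes_list, truth, ann = synthetic_pangenome.simulate(scfg)
        genomes = {g.genome_id: g for g in genomes_list}
    elif "genomes_dir" in cfg:
        tax = guide_taxonomy.load_taxonomy(cfg["taxonomy"])
        genomes = {}
        for fa in sorted(Path(cfg["genomes_dir"]).glob("*.ffn")):
            gid = fa.stem
            genomes[gid] = genome_io.read_gene_fasta(fa, gid)
        ann = functional_profiles.CogAnnotation.from_tsv(cfg["annotations"]) \
            if cfg.get("annotations") else functional_profiles.CogAnnotation()
        truth = None
    else:
        raise ValueError("config missing 'simulate' or 'genomes_dir'")

    # --- stage: input filters ---------------------------------------------
    fcfg = genome_io.InputFilterConfig(**cfg.get("filters", {}))
    filtered: dict[str, genome_io.GenomeGeneSet] = {}
    reports = []
    for gid in sorted(genomes):
        res, rep = genome_io.apply_input_filters(genomes[gid], fcfg)
        reports.append(rep)
        if res != genome_io.REJECTED:
            filtered[gid] = res
    genome_io.write_filter_report(reports, out / "filter_report.tsv")
    if not filtered:
        raise RuntimeError("stage filters: all genomes rejected")

    tax = guide_taxonomy.prune_to_genomes(tax, set(filtered))

    # --- stage: core discovery --------------------------------------------
    result = core_discovery.run_recursive(tax, filtered, params)
    core_discovery.write_core_table(result, out / "core_families.tsv")
    (out / "core_summary.json").write_text(
        json.dumps(core_discovery.summary(result), indent=1, sort_keys=True))

    gene_index = {g.gene_id: g for gs in filtered.values() for g in gs.genes}

    # --- stage: trees ------------------------------------------------------
    # core-gene tree: representatives of the widest retained family
    final = result.final_families()
    tree_core = None
    widest = max(final, key=lambda f: (f.n_genomes, f.family_id), default=None)
    if widest is not None and widest.n_genomes >= 3:
        seqs = {g: gene_index[rep].seq
                for g, rep in sorted(widest.representative.items())}
        dm = phylo_trees.pairwise_seq_distances(seqs, params)
        tree_core = phylo_trees.midpoint_root(phylo_trees.build_nj_tree(dm))
        phylo_trees.write_newick(tree_core, out / "core_tree.nwk")

    tree_func = None
    matrix = functional_profiles.build_cog_matrix(
        [filtered[g] for g in sorted(filtered)], ann)
    if matrix.shape[1]:
        matrix = functional_profiles.filter_low_abundance_columns(
            matrix, cfg.get("cog_min_fraction", 0.10))
        functional_profiles.write_matrix_tsv(matrix, out / "cog_matrix.tsv")
        if matrix.shape[0] >= 3:
            tree_func = functional_profiles.functional_tree(matrix)
            phylo_trees.write_newick(tree_func, out / "functional_tree.nwk")

    # --- stage: tree comparison -------------------------------------------
    comparison = None
    if tree_core is not None and tree_func is not None \
            and widest.n_genomes == len(filtered):
        res = tree_comparison.permutation_pvalue(
            tree_core, tree_func,
            n_perm=int(cfg.get("n_perm", 1000)), seed=seed,
            percentile=float(cfg.get("percentile", 10.0)))
        comparison = {
            "distance": res.distance, "p_value": res.p_value,
            "n_permutations": res.n_permutations,
            "null_mean": res.null_mean, "null_sd": res.null_sd,
            "seed": res.seed,
        }
        (out / "tree_comparison.json").write_text(
            json.dumps(comparison, indent=1, sort_keys=True))

    # --- stage: enrichment and clade summary -------------------------------
    background = sorted(gene_index)
    ref_tree = tree_core if tree_core is not None else tree_func
    rows = []
    enrich_lines = ["clade_id\tcategory\tk\tn\tK\tN\tp_value\tenriched"]
    for cid in guide_taxonomy.postorder_clades(tax):
        cs = result.sets.get(cid)
        if cs is None:
            continue
        retained = cs.retained()
        members = guide_taxonomy.genomes_under(tax, cid)
        alpha = np.nan
        if ref_tree is not None:
            tips = {t.name for t in ref_tree.tips()}
            if members <= tips:
                alpha = phylo_trees.alpha_diversity(ref_tree, members)
        summary_set = core_discovery.CladeCoreSet(cid, retained, cs.n_genomes)
        enr = functional_profiles.category_enrichment(summary_set, ann, background)
        by_cat = {e.category: e for e in enr}
        n_s = sum(
            1 for f in retained
            if functional_profiles.assign_family_category(f, ann) == "S")
        jkl = sum(by_cat[c].percent for c in "JKL" if c in by_cat)
        o_pct = by_cat["O"].percent if "O" in by_cat else 0.0
        rows.append({
            "clade_id": cid,
            "alpha_diversity": alpha,
            "n_genomes": cs.n_genomes,
            "n_core_families": len(retained),
            "n_S_cogs": n_s,
            "jkl_percent": round(jkl, 1),
            "jkl_enriched": int(any(
                by_cat[c].enriched for c in "JKL" if c in by_cat)),
            "o_percent": round(o_pct, 1),
            "o_enriched": int(by_cat["O"].enriched if "O" in by_cat else False),
        })
        for e in enr:
            enrich_lines.append(
                f"{cid}\t{e.category}\t{e.k}\t{e.n}\t{e.K}\t{e.N}\t"
                f"{e.p_value:.6g}\t{int(e.enriched)}")
    (out / "enrichment.tsv").write_text("\n".join(enrich_lines) + "\n")
    summary_df = pd.DataFrame(rows)
    summary_df.to_csv(out / "clade_summary.tsv", sep="\t", index=False)

    rho = None
    with_alpha = summary_df.dropna(subset=["alpha_diversity"])
    if (len(with_alpha) >= 3
            and with_alpha["alpha_diversity"].nunique() > 1
            and with_alpha["n_core_families"].nunique() > 1):
        rho = spearman_rho(with_alpha["alpha_diversity"],
                           with_alpha["n_core_families"])

    outcome = {
        "n_genomes_retained": len(filtered),
        "n_clades": len(result.sets),
        "n_final_families": len(final),
        "comparison": comparison,
        "spearman": rho,
    }
    if truth is not None:
        outcome["truth_eval"] = synthetic_pangenome.truth_eval(result, truth)
    (out / "pipeline_outcome.json").write_text(
        json.dumps(outcome, indent=1, sort_keys=True))
    return outcome
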