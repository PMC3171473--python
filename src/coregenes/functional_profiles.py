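"""COG abundance profiles, functional phylogenies and category enrichment.

Each genome is summarized by the number of genes it carries in each COG
family.  Sparse families (column sum below 10% of the number of genomes) are
dropped, and the genomes are hierarchically clustered with average linkage on
Manhattan distances — a functional phylogeny grouping organisms by shared
functional potential rather than sequence similarity.  Core families are
assigned to the single-letter COG functional category covering at least half
of their members, and per-clade category enrichment uses the upper-tail
hypergeometric test at p < 0.05 against the background of all annotated
genes (no multiple-testing correction, by design; Benjamini-Hochberg is
available as an option).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom
from skbio import TreeNode

from .core_discovery import CladeCoreSet, CoreFamily
from .genome_io import GenomeGeneSet
from .phylo_trees import midpoint_root

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"

COG_CATEGORIES = set("JAKLBDYVTMNZWUOCGEFHIPQRS")


@dataclass(frozen=True)
class CogEntry:
    cog_id: str
    category: str  # one or more single-letter codes, e.g. "K" or "KT"


class CogAnnotation:
    """Mapping gene_id -> (COG family, category letters); genes may be absent."""

    def __init__(self, entries: dict[str, CogEntry] | None = None):
        self.entries: dict[str, CogEntry] = dict(entries or {})

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.entries

    def __getitem__(self, gene_id: str) -> CogEntry:
        return self.entries[gene_id]

    def get(self, gene_id: str):
        return self.entries.get(gene_id)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CogAnnotation":
        entries = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            gene_id, cog, cat = line.rstrip("\n").split("\t")[:3]
            entries[gene_id] = CogEntry(cog, cat)
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["gene_id\tcog_family\tcategory"]
        for gid in sorted(self.entries):
            e = self.entries[gid]
            lines.append(f"{gid}\t{e.cog_id}\t{e.category}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    k: int          # core genes in category
    n: int          # core genes annotated to any category
    K: int          # background genes in category
    N: int          # background annotated genes
    p_value: float
    enriched: bool  # p < 0.05
    percent: float  # 100 * k / n


def build_cog_matrix(
    genomes: list[GenomeGeneSet], ann: CogAnnotation
) -> pd.DataFrame:
    """Genomes x COG-families count matrix; unannotated genes are ignored."""
    rows = {}
    for gs in genomes:
        counts: dict[str, int] = {}
        for g in gs.genes:
            e = ann.get(g.gene_id)
            if e is not None:
                counts[e.cog_id] = counts.get(e.cog_id, 0) + 1
        rows[gs.genome_id] = counts
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    # genomes with no annotated genes must keep an all-zero row
    df = df.reindex([gs.genome_id for gs in genomes]).fillna(0).astype(int)
    df = df.reindex(sorted(df.columns), axis=1)
    df.index.name = "genome_id"
    return df


def filter_low_abundance_columns(
    m: pd.DataFrame, fraction: float = 0.10
) -> pd.DataFrame:
    """Keep COG columns whose total abundance is >= fraction * n_genomes.

    The cut is strict ("summing to less than" the threshold is removed), so a
    column summing to exactly the threshold is kept.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    threshold = fraction * len(m.index)
    kept = m.loc[:, m.sum(axis=0) >= threshold]
    if kept.shape[1] == 0:
        raise ValueError("all columns removed by the abundance filter")
    return kept


def functional_tree(m: pd.DataFrame) -> TreeNode:
    """Functional phylogeny: average-linkage clustering on Manhattan distances.

    The dendrogram becomes an ultrametric tree whose tip-to-tip path
    distances reproduce the cophenetic (merge-height) distances; it is then
    midpoint-rooted like the sequence-based trees.  Rows are processed in
    label order so the result is deterministic under row permutation.
    """
    if len(m.index) < 3:
        raise ValueError("need at least 3 genomes")
    m = m.sort_index()
    labels = list(m.index)
    z = linkage(pdist(m.values, metric="cityblock"), method="average")
    tree = _linkage_to_tree(z, labels)
    return midpoint_root(tree)


def _linkage_to_tree(z: np.ndarray, labels: list[str]) -> TreeNode:
    n = len(labels)
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    heights = [0.0] * n
    for a, b, h, _cnt in z:
        a, b = int(a), int(b)
        parent = TreeNode()
        # ultrametric: tips sit at height 0, a merge at height h implies
        # tip-to-tip cophenetic distance h, i.e. half-heights per side
        nodes[a].length = (h - heights[a]) / 2.0
        nodes[b].length = (h - heights[b]) / 2.0
        parent.extend([nodes[a], nodes[b]])
        nodes.append(parent)
        heights.append(h)
    return nodes[-1]


def _category_weights(category: str) -> dict[str, float]:
    letters = list(category)
    w = 1.0 / len(letters)
    return {l: w for l in letters}


def assign_family_category(family: CoreFamily, ann: CogAnnotation) -> str:
    """COG category of a core family, or UNASSIGNED.

    A family belongs to the category annotating at least half of its members;
    multi-letter codes contribute fractionally (1/len per letter).  A tie at
    exactly one half between two categories leaves the family unassigned.
    """
    weights: dict[str, float] = {}
    for gid in family.members:
        e = ann.get(gid)
        if e is None:
            continue
        for letter, w in _category_weights(e.category).items():
            weights[letter] = weights.get(letter, 0.0) + w
    if not weights:
        return UNASSIGNED
    size = len(family.members)
    fractions = {l: w / size for l, w in weights.items()}
    best = max(fractions.values())
    if best < 0.5:
        return UNASSIGNED
    winners = sorted(l for l, f in fractions.items() if f == best)
    if len(winners) > 1:
        logger.warning(
            "family %s: category tie %s at fraction %.3f; unassigned",
            family.family_id, winners, best,
        )
        return UNASSIGNED
    return winners[0]


def _gene_categories(ann: CogAnnotation, gene_ids) -> dict[str, set[str]]:
    """category letter -> set of annotated genes carrying it (integral membership)."""
    out: dict[str, set[str]] = {}
    for gid in gene_ids:
        e = ann.get(gid)
        if e is None:
            continue
        for letter in e.category:
            out.setdefault(letter, set()).add(gid)
    return out


def category_enrichment(
    core_set: CladeCoreSet,
    ann: CogAnnotation,
    background_gene_ids,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of COG categories in a core set.

    Population: the N annotated background genes; successes: the K background
    genes carrying the category; draws: the n core member genes annotated to
    any category; observed: k of them in the category.  Gene copies (not
    families) are counted.  ``bh_correct`` applies Benjamini-Hochberg before
    flagging (off by default).
    """
    core_genes = sorted({gid for f in core_set.families for gid in f.members})
    annotated_core = [g for g in core_genes if ann.get(g) is not None]
    n = len(annotated_core)
    if n == 0:
        return []
    background = [g for g in background_gene_ids if ann.get(g) is not None]
    N = len(background)
    bg_by_cat = _gene_categories(ann, background)
    core_by_cat = _gene_categories(ann, annotated_core)
    results = []
    for cat in sorted(bg_by_cat):
        K = len(bg_by_cat[cat])
        k = len(core_by_cat.get(cat, ()))
        p = float(hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(
                category=cat, k=k, n=n, K=K, N=N,
                p_value=p, enriched=False, percent=100.0 * k / n,
            )
        )
    pvals = np.array([r.p_value for r in results])
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        flags = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    else:
        flags = pvals < alpha
    results = [
        EnrichmentResult(r.category, r.k, r.n, r.K, r.N, r.p_value,
                         bool(f), r.percent)
        for r, f in zip(results, flags)
    ]
    return results


def write_matrix_tsv(m: pd.DataFrame, path: str | Path) -> None:
    m.to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
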