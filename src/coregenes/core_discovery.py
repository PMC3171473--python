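"""Recursive, bottom-up identification of core gene families per clade.

Starting at the terminal nodes of the guide taxonomy, each genome's genes are
grouped into families by within-genome homology (connected components of the
self-search hit graph), which captures paralogs.  Ascending the taxonomy, a
database is built from the member genes of every direct child's families and
each child's members are searched against it; child families linked by at
least one qualifying hit are merged (single linkage), and a merged component
that includes at least one family from every direct child — and therefore,
transitively, at least one gene in every genome of the clade — becomes a core
family of the clade.  Promoted families are consumed: each gene belongs to at
most one family over the whole run, the one at the highest clade it reached.
The recursion along a path stops as soon as a clade yields no core families.

Independent sibling clades can be processed in any order (or concurrently)
with identical results; the implementation is serial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .genome_io import GeneRecord, GenomeGeneSet
from .guide_taxonomy import GuideTaxonomy, TaxonNode, genomes_under
from .homology_search import SearchParams, build_database, pair_score, search

logger = logging.getLogger(__name__)


@dataclass
class CoreFamily:
    """One clade's ubiquitous gene family: orthologs plus captured paralogs."""

    family_id: str
    clade_id: str
    members: tuple[str, ...]  # gene ids, sorted
    per_genome: dict[str, tuple[str, ...]]  # genome_id -> member gene ids
    representative: dict[str, str] = field(default_factory=dict)
    #: family_id of the parent-clade family that absorbed this one, if any
    promoted_into: str | None = None

    @property
    def n_genomes(self) -> int:
        return len(self.per_genome)

    def __post_init__(self):
        if not all(v for v in self.per_genome.values()):
            raise ValueError(
                f"family {self.family_id}: some genome has zero members"
            )
        for g, rep in self.representative.items():
            if rep not in self.per_genome[g]:
                raise ValueError(
                    f"family {self.family_id}: representative {rep} not a member"
                )


@dataclass
class CladeCoreSet:
    clade_id: str
    families: list[CoreFamily]
    n_genomes: int

    @property
    def n_families(self) -> int:
        return len(self.families)

    def retained(self) -> list[CoreFamily]:
        """Families not absorbed into an ancestor clade's family."""
        return [f for f in self.families if f.promoted_into is None]


@dataclass
class CoreRunResult:
    sets: dict[str, CladeCoreSet]
    log: list[str] = field(default_factory=list)

    def final_families(self) -> list[CoreFamily]:
        out = []
        for cs in self.sets.values():
            out.extend(cs.retained())
        return out

    @property
    def consumed(self) -> set[str]:
        return {gid for f in self.final_families() for gid in f.members}


def _components_to_families(
    clade_id: str,
    components: list[list[str]],
    gene_genome: dict[str, str],
) -> list[CoreFamily]:
    comps = sorted((sorted(c) for c in components), key=lambda c: c[0])
    families = []
    for i, members in enumerate(comps):
        per_genome: dict[str, list[str]] = {}
        for gid in members:
            per_genome.setdefault(gene_genome[gid], []).append(gid)
        families.append(
            CoreFamily(
                family_id=f"{clade_id}:{i:04d}",
                clade_id=clade_id,
                members=tuple(members),
                per_genome={g: tuple(v) for g, v in sorted(per_genome.items())},
            )
        )
    return families


def leaf_cores(genome: GenomeGeneSet, params: SearchParams | None = None) -> CladeCoreSet:
    """Group one genome's genes into families by within-genome homology.

    Families are connected components of the self-search hit graph; genes
    without within-genome homologs form singleton families.  Every retained
    gene lands in exactly one family.
    """
    params = params or SearchParams()
    graph = nx.Graph()
    graph.add_nodes_from(g.gene_id for g in genome.genes)
    if len(genome.genes) > 1:
        db = build_database(genome.genes, word_size=params.word_size)
        for hit in search(genome.genes, db, params):
            graph.add_edge(hit.query_id, hit.subject_id)
    gene_genome = {g.gene_id: genome.genome_id for g in genome.genes}
    families = _components_to_families(
        genome.genome_id, list(nx.connected_components(graph)), gene_genome
    )
    return CladeCoreSet(clade_id=genome.genome_id, families=families, n_genomes=1)


def clade_cores(
    clade_id: str,
    child_sets: list[CladeCoreSet],
    gene_index: dict[str, GeneRecord],
    params: SearchParams | None = None,
) -> CladeCoreSet:
    """Merge direct children's core families into the clade's core families.

    A merged component qualifies as a core family only if it contains at
    least one family from every direct child; qualifying components consume
    their constituent child families (marking them ``promoted_into``).
    """
    params = params or SearchParams()
    n_genomes = sum(cs.n_genomes for cs in child_sets)
    if any(cs.n_families == 0 for cs in child_sets):
        return CladeCoreSet(clade_id=clade_id, families=[], n_genomes=n_genomes)

    if len(child_sets) == 1:
        # singleton chain: the child's families carry up unchanged
        families = []
        for i, fam in enumerate(
            sorted(child_sets[0].families, key=lambda f: f.members[0])
        ):
            promoted = CoreFamily(
                family_id=f"{clade_id}:{i:04d}",
                clade_id=clade_id,
                members=fam.members,
                per_genome=fam.per_genome,
            )
            fam.promoted_into = promoted.family_id
            families.append(promoted)
        return CladeCoreSet(clade_id=clade_id, families=families,
                            n_genomes=n_genomes)

    family_of: dict[str, str] = {}
    child_of: dict[str, int] = {}
    all_genes: list[GeneRecord] = []
    fam_by_id: dict[str, CoreFamily] = {}
    for ci, cs in enumerate(child_sets):
        for fam in cs.families:
            fam_by_id[fam.family_id] = fam
            child_of[fam.family_id] = ci
            for gid in fam.members:
                family_of[gid] = fam.family_id
                all_genes.append(gene_index[gid])

    db = build_database(all_genes, word_size=params.word_size)
    graph = nx.Graph()
    graph.add_nodes_from(fam_by_id)
    for hit in search(all_genes, db, params):
        fq, fs = family_of[hit.query_id], family_of[hit.subject_id]
        if fq != fs:
            graph.add_edge(fq, fs)

    n_children = len(child_sets)
    qualifying: list[list[str]] = []
    for comp in nx.connected_components(graph):
        if len({child_of[f] for f in comp}) == n_children:
            qualifying.append(sorted(comp))
    qualifying.sort(key=lambda fams: min(fam_by_id[f].members[0] for f in fams))

    families: list[CoreFamily] = []
    gene_genome = {g.gene_id: g.genome_id for g in all_genes}
    for i, fam_ids in enumerate(qualifying):
        members = sorted({gid for f in fam_ids for gid in fam_by_id[f].members})
        per_genome: dict[str, list[str]] = {}
        for gid in members:
            per_genome.setdefault(gene_genome[gid], []).append(gid)
        new = CoreFamily(
            family_id=f"{clade_id}:{i:04d}",
            clade_id=clade_id,
            members=tuple(members),
            per_genome={g: tuple(v) for g, v in sorted(per_genome.items())},
        )
        for f in fam_ids:
            fam_by_id[f].promoted_into = new.family_id
        families.append(new)
    return CladeCoreSet(clade_id=clade_id, families=families, n_genomes=n_genomes)


def run_recursive(
    tax: GuideTaxonomy,
    genomes: dict[str, GenomeGeneSet],
    params: SearchParams | None = None,
    select_representatives: bool = True,
) -> CoreRunResult:
    """Run core discovery over the whole guide taxonomy (postorder).

    Terminal nodes holding several genomes are treated as clades over
    per-genome units: each genome first gets its own leaf family set
    (recorded under its genome id), then the terminal node merges them like
    any internal clade.
    """
    params = params or SearchParams()
    gene_index: dict[str, GeneRecord] = {}
    for gs in genomes.values():
        for g in gs.genes:
            if g.gene_id in gene_index:
                raise ValueError(f"gene id {g.gene_id} occurs in two genomes")
            gene_index[g.gene_id] = g

    result = CoreRunResult(sets={})

    def visit(node: TaxonNode) -> CladeCoreSet:
        if node.is_terminal:
            leaf_sets = []
            for gid in node.genome_ids:
                if gid not in genomes:
                    raise KeyError(f"taxonomy genome {gid} has no gene set")
                ls = leaf_cores(genomes[gid], params)
                leaf_sets.append(ls)
            if len(leaf_sets) == 1:
                cs = leaf_sets[0]
                if cs.clade_id != node.taxon_id:
                    # record the per-genome set under the taxon's id
                    cs = CladeCoreSet(node.taxon_id, cs.families, cs.n_genomes)
                    for i, fam in enumerate(cs.families):
                        fam.family_id = f"{node.taxon_id}:{i:04d}"
                        fam.clade_id = node.taxon_id
                result.sets[node.taxon_id] = cs
                return cs
            for ls in leaf_sets:
                result.sets[ls.clade_id] = ls
            cs = clade_cores(node.taxon_id, leaf_sets, gene_index, params)
        else:
            child_sets = [visit(c) for c in node.children]
            cs = clade_cores(node.taxon_id, child_sets, gene_index, params)
        if cs.n_families == 0:
            msg = f"stop: no core families at clade {node.taxon_id}"
            result.log.append(msg)
            logger.info(msg)
        result.sets[node.taxon_id] = cs
        return cs

    visit(tax.root)
    if select_representatives:
        for fam in result.final_families():
            select_representative(fam, gene_index)
    return result


def select_representative(
    family: CoreFamily,
    gene_index: dict[str, GeneRecord],
) -> CoreFamily:
    """Pick one member per genome for tree building.

    Genomes with a single member use it directly.  For genomes with paralogs,
    the paralog most similar (mean best local-alignment score) to the members
    from unambiguous single-member genomes wins — the most conserved variant.
    If every genome is multi-member, the medoid by mean intra-family score is
    used.  Ties break by highest single comparison score, then gene id.
    """
    singles = [mems[0] for g, mems in sorted(family.per_genome.items())
               if len(mems) == 1]
    for genome_id, mems in sorted(family.per_genome.items()):
        if len(mems) == 1:
            family.representative[genome_id] = mems[0]
            continue
        if singles:
            refs = [r for r in singles if r not in mems]
        else:
            refs = []
        scored = []
        for cand in sorted(mems):
            others = refs if refs else [m for m in family.members if m != cand]
            scores = [
                pair_score(gene_index[cand], gene_index[o]) for o in others
            ]
            mean = sum(scores) / len(scores) if scores else 0.0
            best_single = max(scores) if scores else 0.0
            scored.append((-mean, -best_single, cand))
        scored.sort()
        family.representative[genome_id] = scored[0][2]
    return family


def write_core_table(result: CoreRunResult, path) -> None:
    """TSV of final family membership (clade, family, genome, gene, is_representative)."""
    lines = ["clade_id\tfamily_id\tgenome_id\tgene_id\tis_representative"]
    for fam in sorted(result.final_families(), key=lambda f: f.family_id):
        for genome_id, mems in fam.per_genome.items():
            rep = fam.representative.get(genome_id)
            for gid in mems:
                lines.append(
                    f"{fam.clade_id}\t{fam.family_id}\t{genome_id}\t{gid}\t"
                    f"{int(gid == rep)}"
                )
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")


def summary(result: CoreRunResult) -> dict[str, dict[str, int]]:
    """clade_id -> {n_families (formed), n_retained, n_genomes}."""
    return {
        cid: {
            "n_families": cs.n_families,
            "n_retained": len(cs.retained()),
            "n_genomes": cs.n_genomes,
        }
        for cid, cs in result.sets.items()
    }
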