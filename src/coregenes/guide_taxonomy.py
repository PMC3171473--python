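"""The guide taxonomy: a rooted clade tree over genomes.

The recursion that discovers core genes is ordered by a user-supplied guide
tree (e.g. the NCBI Taxonomy), not by an inferred phylogeny.  Genomes sit at
terminal nodes which may occur at unequal depths, matching how real
taxonomies assign sequenced genomes to strains, species or occasionally
higher ranks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

from skbio import TreeNode


@dataclass
class TaxonNode:
    taxon_id: str
    name: str = ""
    rank: str = ""
    children: list["TaxonNode"] = field(default_factory=list)
    genome_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.name:
            self.name = self.taxon_id

    @property
    def is_terminal(self) -> bool:
        return not self.children

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self


@dataclass
class GuideTaxonomy:
    root: TaxonNode
    index: dict[str, TaxonNode] = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self._reindex()
        self._validate()

    def _reindex(self):
        self.index = {}
        for node in self.root.postorder():
            if node.taxon_id in self.index:
                raise ValueError(f"duplicate taxon_id {node.taxon_id}")
            self.index[node.taxon_id] = node

    def _validate(self):
        seen: set[str] = set()
        for node in self.root.postorder():
            if node.genome_ids and node.children:
                raise ValueError(
                    f"node {node.taxon_id} has both genomes and children"
                )
            for g in node.genome_ids:
                if g in seen:
                    raise ValueError(f"genome {g} listed at two terminal nodes")
                seen.add(g)

    def node(self, taxon_id: str) -> TaxonNode:
        try:
            return self.index[taxon_id]
        except KeyError:
            raise KeyError(f"unknown taxon_id {taxon_id!r}") from None


def load_taxonomy(source: str | Path) -> GuideTaxonomy:
    """Load a guide taxonomy from a lineage TSV or a Newick file.

    TSV rows are ``genome_id<TAB>rank1<TAB>rank2...`` root-to-leaf; shared
    lineage prefixes merge into internal nodes.  Newick leaves are genome ids.
    """
    path = Path(source)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"empty taxonomy source {path}")
    if text.startswith("(") or text.endswith(";"):
        return taxonomy_from_newick(text)
    rows = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"lineage row needs >=2 columns: {line!r}")
        rows.append((parts[0], parts[1:]))
    return taxonomy_from_lineages(rows)


def taxonomy_from_lineages(rows: list[tuple[str, list[str]]]) -> GuideTaxonomy:
    """Build a taxonomy from (genome_id, root-to-leaf lineage) rows."""
    if not rows:
        raise ValueError("no lineage rows")
    lineage_of: dict[str, tuple[str, ...]] = {}
    for genome_id, lineage in rows:
        lineage = tuple(lineage)
        if genome_id in lineage_of and lineage_of[genome_id] != lineage:
            raise ValueError(f"genome {genome_id} listed under two lineages")
        lineage_of[genome_id] = lineage

    roots = {lin[0] for lin in lineage_of.values()}
    if len(roots) > 1:
        # implicit super-root joining distinct top-level lineages
        lineage_of = {g: ("__root__",) + lin for g, lin in lineage_of.items()}

    nodes: dict[tuple[str, ...], TaxonNode] = {}

    def get_node(prefix: tuple[str, ...]) -> TaxonNode:
        if prefix not in nodes:
            node = TaxonNode(taxon_id="/".join(prefix), name=prefix[-1])
            nodes[prefix] = node
            if len(prefix) > 1:
                get_node(prefix[:-1]).children.append(node)
        return nodes[prefix]

    for genome_id in lineage_of:  # insertion order kept: deterministic
        lineage = lineage_of[genome_id]
        for i in range(1, len(lineage) + 1):
            get_node(lineage[:i])
        leaf = nodes[lineage]
        leaf.genome_ids.append(genome_id)

    root = nodes[min(nodes, key=len)]
    return GuideTaxonomy(root=root)


def taxonomy_from_newick(text: str) -> GuideTaxonomy:
    """Convert a Newick tree (leaves = genome ids) into a guide taxonomy."""
    tree = TreeNode.read([text])
    counter = itertools.count()

    def convert(sk_node) -> TaxonNode:
        if sk_node.is_tip():
            gid = str(sk_node.name)
            return TaxonNode(taxon_id=f"t_{gid}", name=gid, genome_ids=[gid])
        tid = str(sk_node.name) if sk_node.name else f"clade{next(counter)}"
        node = TaxonNode(taxon_id=tid, name=tid)
        node.children = [convert(c) for c in sk_node.children]
        return node

    return GuideTaxonomy(root=convert(tree))


def postorder_clades(tax: GuideTaxonomy) -> list[str]:
    """Taxon ids in postorder: every node after all its descendants."""
    return [n.taxon_id for n in tax.root.postorder()]


def genomes_under(tax: GuideTaxonomy, taxon_id: str) -> set[str]:
    """All genome ids in the subtree rooted at ``taxon_id``."""
    node = tax.node(taxon_id)
    out: set[str] = set()
    for n in node.postorder():
        out.update(n.genome_ids)
    return out


def prune_to_genomes(tax: GuideTaxonomy, keep: set[str]) -> GuideTaxonomy:
    """Drop rejected genomes and any node left without genomes underneath.

    Nodes with a single surviving child are retained: a clade of one genome
    still receives a core set, consistent with leaf handling.
    """

    def rebuild(node: TaxonNode) -> TaxonNode | None:
        if node.is_terminal:
            kept = [g for g in node.genome_ids if g in keep]
            if not kept:
                return None
            return TaxonNode(node.taxon_id, node.name, node.rank,
                             genome_ids=kept)
        children = [c for c in (rebuild(ch) for ch in node.children) if c]
        if not children:
            return None
        return TaxonNode(node.taxon_id, node.name, node.rank, children=children)

    root = rebuild(tax.root)
    if root is None:
        raise ValueError("no genomes left after pruning")
    return GuideTaxonomy(root=root)


def to_newick(tax: GuideTaxonomy) -> str:
    """Newick rendering of the taxonomy (terminal nodes expand to genomes)."""

    def render(node: TaxonNode) -> str:
        if node.is_terminal:
            if len(node.genome_ids) == 1:
                return node.genome_ids[0]
            return "(" + ",".join(node.genome_ids) + ")" + node.taxon_id.replace("/", "_")
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}){node.taxon_id.replace('/', '_')}"

    return render(tax.root) + ";"
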