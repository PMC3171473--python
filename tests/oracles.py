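"""Independent reference implementations used only as test oracles."""

from __future__ import annotations

import numpy as np
import networkx as nx

from coregenes.guide_taxonomy import GuideTaxonomy, TaxonNode, genomes_under
from coregenes.homology_search import (MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND,
                                       SearchParams, build_database, evalue,
                                       revcomp, search)

NEG = -10 ** 9


def sw_local(a: str, b: str):
    """Smith-Waterman with affine gaps (Gotoh), pure DP with traceback.

    Scoring: match +2, mismatch -3, a gap of length k costs 5 + 2k.  Returns
    (score, aln_len, identities) of the best local alignment.  Deliberately
    independent of the package's seed-and-extend implementation.
    """
    n, m = len(a), len(b)
    open_cost = GAP_OPEN + GAP_EXTEND  # first gap base
    ext = GAP_EXTEND
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in a (left)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in b (up)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 left, 3 up
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    best = (0, 0, 0)
    for i in range(1, n + 1):
        sub = np.where((bb == aa[i - 1]) & (aa[i - 1] != ord("N")),
                       MATCH, MISMATCH)
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] - ext, H[i][j - 1] - open_cost)
            F[i][j] = max(F[i - 1][j] - ext, H[i - 1][j] - open_cost)
            diag = H[i - 1][j - 1] + sub[j - 1]
            h = max(0, diag, E[i][j], F[i][j])
            H[i][j] = h
            if h == 0:
                ptr[i][j] = 0
            elif h == diag:
                ptr[i][j] = 1
            elif h == E[i][j]:
                ptr[i][j] = 2
            else:
                ptr[i][j] = 3
            if h > best[0]:
                best = (int(h), i, j)
    score, i, j = best
    aln_len = 0
    ident = 0
    while i > 0 and j > 0 and H[i][j] > 0:
        p = ptr[i][j]
        if p == 0:
            break
        aln_len += 1
        if p == 1:
            if a[i - 1] == b[j - 1] and a[i - 1] != "N":
                ident += 1
            i -= 1
            j -= 1
        elif p == 2:
            j -= 1
        else:
            i -= 1
    return score, aln_len, ident


def sw_hit(a: str, b: str, params: SearchParams, db_len: int | None = None):
    """Oracle hit decision for a gene pair under the search thresholds."""
    db_len = db_len if db_len is not None else len(b)
    cands = [sw_local(a, b)]
    if params.both_strands:
        cands.append(sw_local(revcomp(a), b))
    score, aln_len, ident = max(cands)
    if aln_len < params.min_aln_len:
        return None
    if evalue(score, len(a), db_len) > params.evalue_max:
        return None
    return score, aln_len, ident


def topdown_core_partition(
    tax: GuideTaxonomy,
    genomes: dict,
    params: SearchParams,
) -> dict[str, set[frozenset]]:
    """Brute-force core partition: all-vs-all hits + top-down exclusivity.

    All genes are searched against a single database of every gene; at each
    clade (root first), connected components of the hit graph over the
    not-yet-assigned genes of its genomes become core families iff they touch
    every genome under the clade.  Terminal nodes holding several genomes are
    expanded into per-genome units, mirroring the recursion's bookkeeping.
    Completely independent of the recursion's bottom-up family merging.
    """
    genome_of = {}
    all_genes = []
    for gs in genomes.values():
        for g in gs.genes:
            genome_of[g.gene_id] = g.genome_id
            all_genes.append(g)
    db = build_database(all_genes, word_size=params.word_size)
    graph = nx.Graph()
    graph.add_nodes_from(genome_of)
    for h in search(all_genes, db, params):
        graph.add_edge(h.query_id, h.subject_id)

    partition: dict[str, set[frozenset]] = {}

    def visit(node, clade_id: str, members: set[str], available: set[str]):
        pool = {g for g in available if genome_of[g] in members}
        sub = graph.subgraph(pool)
        core = [
            frozenset(c) for c in nx.connected_components(sub)
            if {genome_of[g] for g in c} == members
        ]
        partition[clade_id] = set(core)
        taken = {g for c in core for g in c}
        remaining = available - taken
        if node is None:
            return
        if node.is_terminal:
            if len(node.genome_ids) > 1:
                for gid in node.genome_ids:
                    visit(None, gid, {gid}, remaining)
        else:
            for child in node.children:
                visit(child, child.taxon_id,
                      genomes_under(tax, child.taxon_id) & set(genomes),
                      remaining)

    visit(tax.root, tax.root.taxon_id,
          genomes_under(tax, tax.root.taxon_id) & set(genomes),
          set(genome_of))
    return partition


def result_partition(result) -> dict[str, set[frozenset]]:
    """Per-clade retained family member sets from a recursion result."""
    return {
        cid: {frozenset(f.members) for f in cs.retained()}
        for cid, cs in result.sets.items()
    }
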