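"""Sequence-based trees over genomes: distances, neighbor joining, rooting,
normalization, phylogenetic alpha-diversity and inter/intra distance ratios.

Trees are :class:`skbio.TreeNode` objects with genome ids at the tips.  The
deterministic built-in path is pairwise alignment distances + neighbor
joining; an adapter to external MUSCLE/FastTree-style maximum-likelihood
inference can be substituted upstream since every downstream computation only
consumes a tree.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from pathlib import Path

import numpy as np
from Bio import Align
from skbio import DistanceMatrix, TreeNode

from .homology_search import (GAP_EXTEND, GAP_OPEN, MATCH, MISMATCH,
                              SearchParams, evalue, revcomp, _ALIGNER)


def _free_end_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = MATCH
    a.mismatch_score = MISMATCH
    a.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    a.extend_gap_score = -GAP_EXTEND
    a.end_insertion_score = 0.0
    a.end_deletion_score = 0.0
    return a


_GLOCAL = _free_end_aligner()


def pairwise_seq_distances(
    seqs: dict[str, str],
    params: SearchParams | None = None,
) -> DistanceMatrix:
    """p-distance matrix from best pairwise alignments (global, free end gaps).

    d = 1 - identity over the aligned core (terminal free gaps excluded).  A
    pair whose best local alignment fails the homology-search significance
    thresholds (minimum alignment length and e-value) counts as unalignable
    and gets distance 1.0.
    """
    params = params or SearchParams()
    labels = list(seqs)
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[labels[i]], seqs[labels[j]]
            # significance gate on the best local alignment, either strand
            gate = _ALIGNER.align(a, b)
            gate_rc = _ALIGNER.align(revcomp(a), b)
            best = max(gate, gate_rc, key=lambda alns: alns.score)
            al = best[0]
            c = al.counts()
            loc_len = c.identities + c.mismatches + c.internal_gaps
            if (loc_len < params.min_aln_len
                    or evalue(al.score, len(a), len(b)) > params.evalue_max):
                d[i, j] = d[j, i] = 1.0
                continue
            if best is gate_rc:
                a = revcomp(a)
            gl = _GLOCAL.align(a, b)[0]
            cc = gl.counts()
            core = cc.identities + cc.mismatches + cc.internal_gaps
            ident = cc.identities / core if core else 0.0
            d[i, j] = d[j, i] = 1.0 - ident
    return DistanceMatrix(d, labels)


def build_nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Deterministic neighbor joining.

    Ties in the Q criterion break by label order.  Negative branch length
    estimates are clamped to zero with the deficit shifted onto the sister
    branch, preserving the pair's summed length.  On additive matrices the
    input distances are recovered exactly.
    """
    labels = list(dm.ids)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    if len(labels) == 2:
        half = dm[0, 1] / 2.0
        t = TreeNode()
        t.extend([TreeNode(name=labels[0], length=half),
                  TreeNode(name=labels[1], length=half)])
        return t

    def clamp(li: float, lj: float) -> tuple[float, float]:
        # clamp negatives to zero, shifting the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    nodes = [TreeNode(name=l) for l in labels]
    d = np.array(dm.data, dtype=float)
    active = list(range(len(labels)))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        cands = np.argwhere(q <= q.min() + 1e-12)
        # deterministic tie-break: lowest pair of positions (creation/label order)
        i, j = min((int(a), int(b)) for a, b in cands if a < b)
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (totals[i] - totals[j]) / (2.0 * (m - 2))
        li, lj = clamp(li, dij - li)
        parent = TreeNode()
        nodes[ai].length = float(li)
        nodes[aj].length = float(lj)
        parent.extend([nodes[ai], nodes[aj]])
        new_idx = len(nodes)
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k not in (ai, aj):
                d[new_idx, k] = d[k, new_idx] = 0.5 * (d[ai, k] + d[aj, k] - dij)
        active = [k for k in active if k not in (ai, aj)] + [new_idx]

    # final unrooted trifurcation via the three-point formula
    ai, aj, ak = active
    root = TreeNode()
    la = 0.5 * (d[ai, aj] + d[ai, ak] - d[aj, ak])
    lb = 0.5 * (d[ai, aj] + d[aj, ak] - d[ai, ak])
    lc = 0.5 * (d[ai, ak] + d[aj, ak] - d[ai, aj])
    nodes[ai].length = float(max(la, 0.0))
    nodes[aj].length = float(max(lb, 0.0))
    nodes[ak].length = float(max(lc, 0.0))
    root.extend([nodes[ai], nodes[aj], nodes[ak]])
    return root


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest tip-to-tip path.

    If every branch length is zero (or missing) the root is placed at the
    topological midpoint of the longest edge-count path, with a warning.
    """
    tree = tree.copy()
    lengths = [n.length for n in tree.traverse() if n.length is not None]
    if not lengths or max(lengths) == 0:
        warnings.warn("all branch lengths zero; rooting at topological midpoint")
        for n in tree.traverse():
            if not n.is_root():
                n.length = 1.0
        rooted = tree.root_at_midpoint()
        for n in rooted.traverse():
            if not n.is_root():
                n.length = 0.0
        return rooted
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tree.root_at_midpoint()


def leaf_path_distances(tree: TreeNode) -> DistanceMatrix:
    """Shortest-path branch-length distance between every pair of tips."""
    tips = sorted(t.name for t in tree.tips())
    if len(tips) < 2:
        raise ValueError("need at least 2 leaves")
    return tree.tip_tip_distances().filter(tips)


def total_branch_length(tree: TreeNode) -> float:
    return float(sum(n.length or 0.0 for n in tree.traverse() if not n.is_root()))


def normalize_total_length(tree: TreeNode) -> TreeNode:
    """Scale every branch so the total branch length equals 1."""
    total = total_branch_length(tree)
    if total <= 0:
        raise ValueError("total branch length must be > 0")
    out = tree.copy()
    for n in out.traverse():
        if not n.is_root() and n.length is not None:
            n.length = n.length / total
    return out


def alpha_diversity(ref_tree: TreeNode, members: set[str] | list[str]) -> float:
    """Total branch length of the subtree under the MRCA of ``members``.

    All branches strictly below the most recent common ancestor count; the
    MRCA's own stem branch does not.  A single member gives 0.
    """
    members = sorted(set(members))
    tips = {t.name for t in ref_tree.tips()}
    unknown = set(members) - tips
    if unknown:
        raise KeyError(f"members not in tree: {sorted(unknown)}")
    if len(members) == 1:
        return 0.0
    mrca = ref_tree.lca(members)
    return float(sum(n.length or 0.0 for n in mrca.traverse() if n is not mrca))


def inter_intra_ratio(
    tree: TreeNode,
    group_a: set[str] | list[str],
    group_b: set[str] | list[str],
):
    """Average inter-group vs pooled intra-group tip distance ratio.

    Returns ``(ratio, (inter_mean, inter_sd), (intraA_mean, intraA_sd),
    (intraB_mean, intraB_sd))``; sds are population sds.  Meant to be used on
    a total-branch-length-normalized tree so ratios are comparable across
    trees.
    """
    a = sorted(set(group_a))
    b = sorted(set(group_b))
    if set(a) & set(b):
        raise ValueError("groups overlap")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 members")
    dm = leaf_path_distances(tree)
    inter = np.array([dm[x, y] for x in a for y in b])
    intra_a = np.array([dm[x, y] for i, x in enumerate(a) for y in a[i + 1:]])
    intra_b = np.array([dm[x, y] for i, x in enumerate(b) for y in b[i + 1:]])
    intra_pooled = np.concatenate([intra_a, intra_b])
    ratio = float(inter.mean() / intra_pooled.mean())
    return (
        ratio,
        (float(inter.mean()), float(inter.std())),
        (float(intra_a.mean()), float(intra_a.std())),
        (float(intra_b.mean()), float(intra_b.std())),
    )


def fasttree_backend(seqs: dict[str, str]) -> TreeNode:
    """Adapter: MAFFT alignment + FastTree ML inference, midpoint-ready.

    Requires ``mafft`` and the FastTree executable on PATH; raises
    ``RuntimeError`` otherwise.
    """
    ft = shutil.which("fasttree") or shutil.which("FastTree")
    mafft = shutil.which("mafft")
    if ft is None or mafft is None:
        raise RuntimeError("mafft/fasttree not found on PATH")
    with tempfile.TemporaryDirectory() as td:
        fa = Path(td) / "seqs.fasta"
        fa.write_text("".join(f">{k}\n{v}\n" for k, v in seqs.items()))
        aln = subprocess.run([mafft, "--auto", "--quiet", str(fa)],
                             capture_output=True, text=True, check=True)
        alnfile = Path(td) / "aln.fasta"
        alnfile.write_text(aln.stdout)
        tree = subprocess.run([ft, "-nt", "-quiet", str(alnfile)],
                              capture_output=True, text=True, check=True)
        return TreeNode.read([tree.stdout.strip()])


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path))


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path))
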