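"""Gene-panel characterisation and p-distance neighbor-joining phylogeny.

Covers the descriptive genetics around a curated gene panel: ORF
translation with UTR bookkeeping (full length = 5'UTR + ORF + 3'UTR;
protein aa = ORF/3 - 1 with the stop included), average-mass molecular
weight, per-gene panel summaries with differential-expression status, and
protein trees built by neighbor joining on pairwise p-distances with
partial-deletion column filtering and nonparametric bootstrap support.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from gonadiso.core_io import PanelAnnotation, Transcript, TranscriptSet
from gonadiso.lncrna import OrfRecord, find_longest_orf

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
GAP_CHARS = set("-.")


# ---------------------------------------------------------------------------
# Translation and protein characterisation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    id: str
    protein: str
    utr5_len: int
    orf_len: int
    utr3_len: int

    @property
    def length_aa(self) -> int:
        return len(self.protein)

    @property
    def full_length(self) -> int:
        return self.utr5_len + self.orf_len + self.utr3_len

    @property
    def molecular_weight_kda(self) -> float:
        return protein_mw(self.protein)


def translate_orf(orf: OrfRecord, t: Transcript) -> ProteinRecord:
    """Standard-code translation of an ORF; stop excluded from the protein.

    UTR lengths fall out of the ORF position: 5'UTR = start offset, 3'UTR =
    remainder after the ORF (stop codon included in the ORF span).
    """
    if orf.end > t.length or orf.length % 3 != 0:
        raise ValueError("ORF out of bounds or length not divisible by 3")
    cds = t.seq[orf.start:orf.end]
    aa = str(Seq(cds).translate())
    if orf.has_stop:
        if not aa.endswith("*"):
            raise ValueError(f"ORF of {t.id!r} does not end in a stop codon")
        aa = aa[:-1]
    if "*" in aa:
        raise ValueError(f"internal stop codon in ORF of {t.id!r}")
    return ProteinRecord(t.id, aa, orf.start, orf.length, t.length - orf.end)


def protein_mw(protein: str) -> float:
    """Molecular weight in kDa (average residue masses + one water)."""
    bad = set(protein) - STANDARD_AA
    if bad:
        raise ValueError(f"nonstandard residue(s) {sorted(bad)!r}")
    return ProteinAnalysis(protein).molecular_weight() / 1000.0


# ---------------------------------------------------------------------------
# Panel summarisation
# ---------------------------------------------------------------------------

@dataclass
class PanelGeneSummary:
    gene: str
    members: list[str]
    n_unigenes: int
    n_with_orf: int
    length_min: int
    length_max: int
    de_call: str            # up_<group> | not_DE
    log2fc: float
    tissue_specific: bool


def summarize_panel(annotations: PanelAnnotation, ts: TranscriptSet,
                    de=None, orf_aa_min: int = 1) -> list[PanelGeneSummary]:
    """Per gene symbol: member/ORF counts, length range, DE direction.

    The DE direction reported for a gene is that of its representative
    transcript — the member with the largest |log2FC|, tissue-specific
    ("inf") members ranking above any finite fold change.
    """
    by_gene: dict[str, list[str]] = {}
    for tid, sym in annotations.symbols.items():
        if tid not in ts:
            raise ValueError(f"panel annotation references unknown transcript {tid!r}")
        by_gene.setdefault(sym, []).append(tid)
    out = []
    for gene in sorted(by_gene):
        members = sorted(by_gene[gene])
        lengths = [ts[m].length for m in members]
        with_orf = 0
        for m in members:
            orf = find_longest_orf(ts[m])
            if orf is not None and orf.protein_length >= orf_aa_min:
                with_orf += 1
        call, fc, spec = "not_DE", 0.0, False
        if de is not None:
            tab = de.table
            present = [m for m in members if m in tab.index]
            if present:
                def rank(m):
                    row = tab.loc[m]
                    return (bool(row["tissue_specific"]), abs(row["log2fc"]))
                rep = max(present, key=rank)
                row = tab.loc[rep]
                call = str(row["call"])
                fc = float(row["log2fc"])
                spec = bool(row["tissue_specific"])
        out.append(PanelGeneSummary(gene, members, len(members), with_orf,
                                    min(lengths), max(lengths), call, fc, spec))
    return out


# ---------------------------------------------------------------------------
# p-distance with partial deletion
# ---------------------------------------------------------------------------

def p_distance(a: str, b: str) -> tuple[float, int]:
    """Proportion of differing sites; columns with a gap in either sequence
    are excluded pairwise."""
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    used = 0
    diff = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        used += 1
        if x != y:
            diff += 1
    if used == 0:
        raise ValueError("no usable (gap-free) sites between sequences")
    return diff / used, used


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    sites_used: np.ndarray | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def read_alignment_fasta(path) -> dict[str, str]:
    aln = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    lengths = {len(s) for s in aln.values()}
    if len(lengths) > 1:
        raise ValueError("alignment sequences have unequal lengths")
    return aln


def filter_columns(alignment: dict[str, str], coverage: float = 0.95) -> dict[str, str]:
    """Partial-deletion treatment: drop columns whose non-gap fraction is
    below ``coverage`` before pairwise comparison."""
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    ids = list(alignment)
    cols = []
    n = len(ids)
    length = len(next(iter(alignment.values())))
    for j in range(length):
        nongap = sum(1 for i in ids if alignment[i][j] not in GAP_CHARS)
        if nongap / n >= coverage:
            cols.append(j)
    return {i: "".join(alignment[i][j] for j in cols) for i in ids}


def distance_matrix(alignment: dict[str, str],
                    partial_deletion_coverage: float = 0.95) -> DistanceMatrix:
    filtered = filter_columns(alignment, partial_deletion_coverage)
    ids = sorted(filtered)
    n = len(ids)
    d = np.zeros((n, n))
    used = np.zeros((n, n), dtype=int)
    for i, j in itertools.combinations(range(n), 2):
        dist, s = p_distance(filtered[ids[i]], filtered[ids[j]])
        d[i, j] = d[j, i] = dist
        used[i, j] = used[j, i] = s
    return DistanceMatrix(ids, d, used)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class PhyloNode:
    name: str | None = None
    children: list = field(default_factory=list)  # (PhyloNode, branch_length)
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c._nwk()}:{bl:.6f}" for c, bl in self.children)
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label}"

    def leaf_distances(self) -> pd.DataFrame:
        """Path-length matrix between all leaves."""
        adj: dict[int, list[tuple[int, float]]] = {}
        leaf_of: dict[int, str] = {}

        def build(node):
            nid = id(node)
            adj.setdefault(nid, [])
            if not node.children:
                leaf_of[nid] = node.name
            for c, bl in node.children:
                cid = id(c)
                adj[nid].append((cid, bl))
                adj.setdefault(cid, []).append((nid, bl))
                build(c)

        build(self)
        leaves = sorted(leaf_of.values())
        name_to_id = {v: k for k, v in leaf_of.items()}
        n = len(leaves)
        mat = np.zeros((n, n))
        for i, name in enumerate(leaves):
            # Dijkstra is overkill on a tree; simple DFS accumulation
            start = name_to_id[name]
            seen = {start: 0.0}
            stack = [start]
            while stack:
                u = stack.pop()
                for v, bl in adj[u]:
                    if v not in seen:
                        seen[v] = seen[u] + bl
                        stack.append(v)
            for j, other in enumerate(leaves):
                mat[i, j] = seen[name_to_id[other]]
        return pd.DataFrame(mat, index=leaves, columns=leaves)

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions (one side per internal edge),
        canonicalised as the side not containing the first leaf name."""
        all_leaves = sorted(self.leaves())
        ref = all_leaves[0]
        out: set[frozenset] = set()

        def walk(node):
            for c, _ in node.children:
                side = frozenset(c.leaves())
                if 1 < len(side) < len(all_leaves) - 1:
                    if ref in side:
                        side = frozenset(all_leaves) - side
                    out.add(side)
                walk(c)

        walk(self)
        return out


def nj_tree(d: DistanceMatrix) -> PhyloNode:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    Deterministic: ties in Q are broken by the lexicographically smallest
    (name_i, name_j) pair.  Negative branch lengths are clamped to zero
    with the deficit moved to the sibling edge.
    """
    n = len(d.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    nodes: dict[str, PhyloNode] = {t: PhyloNode(name=t) for t in d.ids}
    dist: dict[frozenset, float] = {}
    for i, j in itertools.combinations(range(n), 2):
        dist[frozenset((d.ids[i], d.ids[j]))] = float(d.matrix[i, j])
    active = sorted(d.ids)
    counter = 0
    while len(active) > 3:
        m = len(active)
        totals = {a: sum(dist[frozenset((a, b))] for b in active if b != a)
                  for a in active}
        best = None
        for a, b in itertools.combinations(active, 2):
            q = (m - 2) * dist[frozenset((a, b))] - totals[a] - totals[b]
            key = (q, min(a, b), max(a, b))
            if best is None or key < best:
                best = key
        _, a, b = best
        dab = dist[frozenset((a, b))]
        la = 0.5 * dab + (totals[a] - totals[b]) / (2 * (m - 2))
        lb = dab - la
        la, lb = _clamp_pair(la, lb)
        new_name = f"__internal{counter}"
        counter += 1
        nodes[new_name] = PhyloNode(children=[(nodes[a], la), (nodes[b], lb)])
        for c in active:
            if c in (a, b):
                continue
            dist[frozenset((new_name, c))] = 0.5 * (
                dist[frozenset((a, c))] + dist[frozenset((b, c))] - dab)
        active = sorted([c for c in active if c not in (a, b)] + [new_name])
    a, b, c = active
    dab = dist[frozenset((a, b))]
    dac = dist[frozenset((a, c))]
    dbc = dist[frozenset((b, c))]
    la = max((dab + dac - dbc) / 2, 0.0)
    lb = max((dab + dbc - dac) / 2, 0.0)
    lc = max((dac + dbc - dab) / 2, 0.0)
    return PhyloNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    if la < 0:
        lb += la  # move the deficit to the sibling edge
        la = 0.0
    if lb < 0:
        la += lb
        lb = 0.0
    return max(la, 0.0), max(lb, 0.0)


def bootstrap_support(alignment: dict[str, str], n_reps: int = 100,
                      seed: int = 0,
                      partial_deletion_coverage: float = 0.95) -> PhyloNode:
    """Site-resampling bootstrap; support = % of replicate NJ trees
    containing each internal bipartition of the full-data tree."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree(distance_matrix(alignment, partial_deletion_coverage))
    targets = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    ids = sorted(alignment)
    length = len(alignment[ids[0]])
    for _ in range(n_reps):
        cols = np.sort(rng.integers(0, length, size=length))
        resampled = {i: "".join(alignment[i][j] for j in cols) for i in ids}
        try:
            rep_tree = nj_tree(distance_matrix(resampled,
                                               partial_deletion_coverage))
        except ValueError:
            continue  # degenerate resample (no usable sites for some pair)
        rep_bps = rep_tree.bipartitions()
        for bp in targets:
            if bp in rep_bps:
                targets[bp] += 1

    def annotate(node):
        for c, _ in node.children:
            side = frozenset(c.leaves())
            all_leaves = sorted(tree.leaves())
            if 1 < len(side) < len(all_leaves) - 1:
                canon = side if all_leaves[0] not in side \
                    else frozenset(all_leaves) - side
                if canon in targets:
                    c.support = 100.0 * targets[canon] / n_reps
            annotate(c)

    annotate(tree)
    return tree
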