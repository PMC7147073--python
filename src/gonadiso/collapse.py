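"""Greedy identity clustering of transcripts (redundancy collapse).

Mirrors CD-HIT-EST's strategy at a stated cutoff (default 0.99): sequences
are sorted longest first and each joins the first existing cluster whose
representative it matches at or above the threshold, otherwise it founds a
new cluster.  Identity is matches / alignment-length of the best semiglobal
alignment of the shorter sequence onto the longer, so contained fragments
collapse.  A shared-k-mer prefilter skips hopeless pairs without changing
results (equivalence enforced by tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from gonadiso.core_io import Transcript, TranscriptSet


@dataclass
class Cluster:
    representative: str
    members: dict[str, float] = field(default_factory=dict)  # id -> identity

    def __post_init__(self) -> None:
        self.members.setdefault(self.representative, 1.0)


def pairwise_identity(a: Transcript, b: Transcript) -> float:
    """Fraction of matching columns in the optimal semiglobal alignment.

    The shorter sequence is aligned onto the longer with free end gaps on the
    longer (infix alignment); identity = matched columns / alignment columns.
    Symmetric by construction.  N never counts as a match.
    """
    if not a.seq or not b.seq:
        raise ValueError("empty sequence")
    short, long_ = (a.seq, b.seq) if len(a.seq) <= len(b.seq) else (b.seq, a.seq)
    res = edlib.align(short, long_, mode="HW", task="path")
    matches = 0
    alen = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            alen += n
            if ch == "=":
                matches += n
    # edlib treats N as an ordinary symbol; N=N columns are reported as
    # matches but must not count (alphabet contract).
    if "N" in short:
        loc = res["locations"][0]
        window = long_[loc[0]:loc[1] + 1]
        if "N" in window:
            matches -= _n_match_correction(short, long_, res)
    return matches / alen if alen else 0.0


def _n_match_correction(short: str, long_: str, res: dict) -> int:
    """Count N=N columns in the edlib alignment path."""
    i = 0
    j = res["locations"][0][0]
    n_matches = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            for k in range(n):
                if short[i + k] == "N" and long_[j + k] == "N":
                    n_matches += 1
            i += n
            j += n
        elif ch == "X":
            i += n
            j += n
        elif ch == "I":  # insertion in query (short)
            i += n
        elif ch == "D":
            j += n
    return n_matches


def _kmer_set(seq: str, k: int = 12) -> set[str]:
    return {seq[i:i + k] for i in range(0, len(seq) - k + 1)}


def cluster_collapse(ts: TranscriptSet, threshold: float = 0.99,
                     prefilter: bool = True,
                     min_shared_kmers: int = 5
                     ) -> tuple[list[Cluster], TranscriptSet]:
    """Greedy longest-first collapse at an identity threshold.

    Order is re-derived internally (length descending, ties lexicographic by
    id), so the result is invariant to input permutation.  Returns the
    clusters in founding order and the collapsed set of representatives.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(ts, key=lambda t: (-t.length, t.id))
    clusters: list[Cluster] = []
    reps: list[Transcript] = []
    kmers: list[set[str]] = []
    for t in ordered:
        tk = _kmer_set(t.seq) if prefilter else None
        placed = False
        for ci, rep in enumerate(reps):
            if prefilter:
                # a member at >= threshold identity must share many 12-mers;
                # the bound is loose on purpose — it must never flip a result.
                # Low-complexity sequences can have fewer distinct 12-mers
                # than the bound, so cap it by the smaller k-mer set.
                need = min(min_shared_kmers, len(tk), len(kmers[ci]))
                if len(tk & kmers[ci]) < need:
                    continue
            ident = pairwise_identity(t, rep)
            if ident >= threshold:
                clusters[ci].members[t.id] = ident
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative=t.id))
            reps.append(t)
            kmers.append(tk if prefilter else set())
    collapsed = TranscriptSet((ts[c.representative] for c in clusters),
                              provenance="collapsed")
    return clusters, collapsed


def write_cluster_table(clusters: list[Cluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster\tis_representative\tmember\tidentity\n")
        for ci, cl in enumerate(clusters):
            for mid, ident in cl.members.items():
                rep = int(mid == cl.representative)
                fh.write(f"{ci}\t{rep}\t{mid}\t{ident:.6f}\n")
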