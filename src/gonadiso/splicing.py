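"""Reference-free alternative-splicing event calling.

Without a genome, an internal splice difference between two full-length
transcripts shows up as a pairwise alignment that splits into exactly two
high-scoring segment pairs (HSPs) separated by a gap on one of the
molecules.  A transcript pair is called an AS event when all of:

1. both sequences are longer than 1000 bp and the alignment yields exactly
   two qualifying HSPs;
2. the gap between the HSPs on the gapped sequence exceeds 100 bp and lies
   at least 100 bp from the 5' end and from the 3' end on both sequences
   (i.e. each HSP provides at least 100 bp of aligned flank);
3. the HSPs overlap by at most 5 bp on either sequence.

Scoring defaults are BLASTN-like: match +1, mismatch -2, gap open -5,
gap extend -2 (a length-L gap costs 5 + 2L), minimum HSP score 50.
Coordinates are 0-based half-open in memory and 1-based inclusive in files.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from gonadiso.core_io import Transcript, TranscriptSet

MIN_SEQ_LEN = 1000
MIN_GAP = 100
MIN_FLANK = 100
MAX_OVERLAP = 5
MIN_HSP_SCORE = 50.0

MATCH = 1
MISMATCH = -2
GAP_OPEN = -5
GAP_EXTEND = -2


@dataclass(frozen=True)
class HSP:
    """A local alignment block; intervals are 0-based half-open."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    score: float
    identity: float

    def __post_init__(self) -> None:
        if self.a_start >= self.a_end or self.b_start >= self.b_end:
            raise ValueError("HSP intervals must be non-empty")


@dataclass(frozen=True)
class ASEvent:
    """An accepted transcript pair with two HSPs evidencing one internal gap."""

    id_a: str
    id_b: str
    hsps: tuple[HSP, HSP]
    gap_len: int
    dist_5prime: int   # min over both sequences of gap distance to the 5' end
    dist_3prime: int   # min over both sequences of gap distance to the 3' end
    overlap: int       # max signed overlap between HSPs on either sequence

    @property
    def pair(self) -> frozenset:
        return frozenset((self.id_a, self.id_b))


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = MATCH
    al.mismatch_score = MISMATCH
    # Biopython charges open+extend for the first gap base
    al.open_gap_score = GAP_OPEN + GAP_EXTEND
    al.extend_gap_score = GAP_EXTEND
    return al


# A gap run longer than this inside one optimal local alignment is split
# into separate HSPs: a BLAST-like X-dropoff extension would never bridge a
# gap costing 5 + 2L > ~65, while short indels (sequencing noise) stay
# bridged within a single HSP.
SPLIT_GAP_LEN = 30


def _segment_score(query: str, subject: str,
                   blocks: list[tuple[tuple[int, int], tuple[int, int]]]) -> tuple[float, float]:
    """Score and identity of a run of co-linear aligned blocks."""
    score = 0.0
    matches = 0
    cols = 0
    prev = None
    for (sa, ea), (sb, eb) in blocks:
        if prev is not None:
            ga = sa - prev[0]
            gb = sb - prev[1]
            gap = max(ga, gb)
            if gap > 0:
                score += GAP_OPEN + GAP_EXTEND * gap
        for k in range(ea - sa):
            qa, qb = query[sa + k], subject[sb + k]
            if qa == qb and qa != "N":
                score += MATCH
                matches += 1
            else:
                score += MISMATCH
            cols += 1
        prev = (ea, eb)
    return score, (matches / cols if cols else 0.0)


def local_align_hsps(a: Transcript, b: Transcript,
                     min_hsp_score: float = MIN_HSP_SCORE,
                     max_hsps: int = 3,
                     split_gap_len: int = SPLIT_GAP_LEN) -> list[HSP]:
    """Maximal local alignments between a and b, non-overlapping on a.

    Found iteratively: take the best local alignment, split it into HSPs at
    internal gap runs longer than ``split_gap_len``, mask its footprint on
    sequence a, and realign, until the score drops below ``min_hsp_score``
    or ``max_hsps`` blocks are collected (three suffice to reject a pair,
    since the event criteria require exactly two).  Returned in
    a-coordinate order.
    """
    if not a.seq or not b.seq:
        raise ValueError("empty sequence")
    al = _aligner()
    query = a.seq
    hsps: list[HSP] = []
    while len(hsps) < max_hsps:
        score = al.score(query, b.seq)
        if score < min_hsp_score:
            break
        aln = al.align(query, b.seq)[0]
        blocks_a, blocks_b = aln.aligned
        pairs = [((int(sa), int(ea)), (int(sb), int(eb)))
                 for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b)]
        # split at long gap runs (on either sequence)
        segments: list[list] = [[pairs[0]]]
        for prev, cur in zip(pairs, pairs[1:]):
            jump = max(cur[0][0] - prev[0][1], cur[1][0] - prev[1][1])
            if jump > split_gap_len:
                segments.append([cur])
            else:
                segments[-1].append(cur)
        for seg in segments:
            seg_score, ident = _segment_score(query, b.seq, seg)
            if seg_score < min_hsp_score:
                continue
            a_start, a_end = seg[0][0][0], seg[-1][0][1]
            b_start, b_end = seg[0][1][0], seg[-1][1][1]
            hsps.append(HSP(a_start, a_end, b_start, b_end, seg_score, ident))
        # mask the full consumed query span with a symbol matching nothing
        a_start, a_end = pairs[0][0][0], pairs[-1][0][1]
        query = query[:a_start] + "#" * (a_end - a_start) + query[a_end:]
    hsps.sort(key=lambda h: (h.a_start, h.b_start))
    return hsps[:max_hsps]


def call_as_event(a: Transcript, b: Transcript,
                  hsps: list[HSP] | None = None,
                  min_len: int = MIN_SEQ_LEN, min_gap: int = MIN_GAP,
                  flank: int = MIN_FLANK, max_overlap: int = MAX_OVERLAP,
                  min_hsp_score: float = MIN_HSP_SCORE) -> ASEvent | None:
    """Apply the three AS criteria to a transcript pair.

    Returns the accepted event or None; absence of an event is a normal
    outcome.  The gap is measured on the sequence where the two HSPs are
    discontiguous (the larger of the two inter-HSP distances).
    """
    if a.length <= min_len or b.length <= min_len:
        return None
    if hsps is None:
        hsps = local_align_hsps(a, b, min_hsp_score=min_hsp_score)
    if len(hsps) != 2:
        return None
    h1, h2 = hsps
    # signed inter-HSP distance on each sequence; negative = overlap
    gap_a = h2.a_start - h1.a_end
    gap_b = h2.b_start - h1.b_end
    if h2.b_start < h1.b_start:
        # HSPs cross on b: not a collinear internal gap
        return None
    overlap = max(-gap_a, -gap_b, 0)
    if overlap > max_overlap:
        return None
    gap = max(gap_a, gap_b)
    if gap <= min_gap:
        return None
    # distance of the gap (the inter-HSP junction) to each sequence end
    d5 = min(h1.a_end, h1.b_end)
    d3 = min(a.length - h2.a_start, b.length - h2.b_start)
    if d5 < flank or d3 < flank:
        return None
    return ASEvent(a.id, b.id, (h1, h2), gap, d5, d3, overlap)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(0, len(seq) - k + 1)}


def as_catalog(ts: TranscriptSet, min_len: int = MIN_SEQ_LEN,
               min_gap: int = MIN_GAP, flank: int = MIN_FLANK,
               max_overlap: int = MAX_OVERLAP,
               min_hsp_score: float = MIN_HSP_SCORE,
               prefilter: bool = True, prefilter_k: int = 12,
               prefilter_min_shared: int = 30
               ) -> tuple[list[ASEvent], dict[str, int]]:
    """Test all unordered transcript pairs once and tally isoform counts.

    The isoform count of a transcript is 1 + its number of distinct partners
    in accepted events.  A shared-k-mer prefilter (k=12, >= 30 shared) skips
    unrelated pairs; at the noise levels the caller targets (<= 1%
    substitutions) it cannot drop a pair that would pass the criteria,
    which the tests enforce by comparing against the unfiltered catalog.
    """
    items = sorted(ts, key=lambda t: t.id)
    kmers = {t.id: _kmer_set(t.seq, prefilter_k) for t in items} if prefilter else {}
    events: list[ASEvent] = []
    partners: dict[str, set[str]] = {t.id: set() for t in items}
    for i, a in enumerate(items):
        for b in items[i + 1:]:
            if a.length <= min_len or b.length <= min_len:
                continue
            if prefilter:
                need = min(prefilter_min_shared,
                           len(kmers[a.id]), len(kmers[b.id]))
                if len(kmers[a.id] & kmers[b.id]) < need:
                    continue
            ev = call_as_event(a, b, min_len=min_len, min_gap=min_gap,
                               flank=flank, max_overlap=max_overlap,
                               min_hsp_score=min_hsp_score)
            if ev is not None:
                events.append(ev)
                partners[a.id].add(b.id)
                partners[b.id].add(a.id)
    counts = {tid: 1 + len(p) for tid, p in partners.items()}
    return events, counts


def isoform_histogram(counts: dict[str, int]) -> dict[str, int]:
    """Bin per-transcript isoform counts into {1, 2-10, >10}."""
    bins = {"1": 0, "2-10": 0, ">10": 0}
    for c in counts.values():
        if c == 1:
            bins["1"] += 1
        elif c <= 10:
            bins["2-10"] += 1
        else:
            bins[">10"] += 1
    return bins
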