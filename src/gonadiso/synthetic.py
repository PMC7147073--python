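"""Synthetic transcript sets and count matrices with planted ground truth.

Emulates, at desk scale, the structure of a full-length gonad transcriptome:
transcript families sharing a parent sequence with internal deletions
(isoform variants), near-duplicate redundant copies, coding vs noncoding
sequence composition, and two-group negative-binomial read counts
(testis-like vs ovary-like replicate structure, 3 vs 4 by default) with
planted group-specific and fold-change effects.

Every generated transcript has exactly one truth record, so each downstream
stage has a recoverable target.  All outputs are deterministic under a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from gonadiso.core_io import CountMatrix, SampleDesign, Transcript, TranscriptSet

# AS-detectability thresholds mirrored from the splicing stage defaults:
# both sequences > 1000 bp, gap > 100 bp, block >= 100 bp from both ends.
MIN_SEQ_LEN = 1000
MIN_GAP = 100
MIN_FLANK = 100


@dataclass
class TruthRecord:
    transcript_id: str
    family: str
    relation: str          # "parent" | "deletion" | "duplicate" | "coding" | "noncoding"
    gap_interval: tuple[int, int] | None = None   # 0-based half-open, on parent
    detectable: bool | None = None                # AS criteria satisfied vs parent
    duplicate_identity: float | None = None
    within_cluster_threshold: bool | None = None
    coding: bool | None = None
    orf_interval: tuple[int, int] | None = None
    effect: str = "none"   # "none" | "group_specific" | "log2fc"
    log2fc: float = 0.0    # group B mean relative to group A (log2)
    specific_group: str | None = None


@dataclass
class SyntheticTruth:
    records: dict[str, TruthRecord] = field(default_factory=dict)
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def add(self, rec: TruthRecord) -> None:
        if rec.transcript_id in self.records:
            raise ValueError(f"duplicate truth record for {rec.transcript_id!r}")
        self.records[rec.transcript_id] = rec

    def __getitem__(self, tid: str) -> TruthRecord:
        return self.records[tid]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records.values()])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def generate_transcript_set(n_families: int, length_range: tuple[int, int] = (1200, 3000),
                            seed: int = 0) -> tuple[TranscriptSet, SyntheticTruth]:
    """Generate ``n_families`` unrelated parent transcripts.

    Lengths are uniform over ``length_range``; composition is i.i.d. uniform
    over ACGT, so unrelated parents share no detectable homology.
    """
    lo, hi = length_range
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if lo < 300:
        raise ValueError("minimum transcript length is 300 bp")
    if hi < lo:
        raise ValueError("invalid length range")
    rng = np.random.default_rng(seed)
    ts = TranscriptSet(provenance="synthetic")
    truth = SyntheticTruth(seed=seed, params={"n_families": n_families,
                                              "length_range": (lo, hi)})
    for i in range(n_families):
        length = int(rng.integers(lo, hi + 1))
        tid = f"fam{i:04d}_parent"
        ts.add(Transcript(tid, _random_seq(rng, length)))
        truth.add(TruthRecord(tid, family=f"fam{i:04d}", relation="parent"))
    return ts, truth


def plant_isoforms(parents: TranscriptSet, truth: SyntheticTruth,
                   k_per_parent: int = 1, gap_range: tuple[int, int] = (120, 400),
                   flank_min: int = 150, seed: int = 0,
                   sub_rate: float = 0.0) -> tuple[TranscriptSet, SyntheticTruth]:
    """Derive deletion isoforms from each parent, recording AS detectability.

    Each variant is its parent with one contiguous internal deletion.  The
    deletion interval is drawn from ``gap_range`` and placed so both flanks
    are at least ``flank_min`` bp; ``gap_range`` may include sub-100 bp gaps
    to plant negatives.  ``sub_rate`` adds i.i.d. substitution noise to the
    variant.  Truth records whether the pair (parent, variant) satisfies all
    AS criteria.
    """
    rng = np.random.default_rng(seed)
    out = TranscriptSet(provenance="synthetic")
    for t in parents:
        out.add(t)
    for t in list(parents):
        fam = truth[t.id].family
        for k in range(k_per_parent):
            lo, hi = gap_range
            max_gap = t.length - 2 * flank_min
            if max_gap < lo:
                raise ValueError(
                    f"parent {t.id!r} ({t.length} bp) too short for gap >= {lo}"
                    f" with flanks {flank_min}")
            gap = int(rng.integers(lo, min(hi, max_gap) + 1))
            start = int(rng.integers(flank_min, t.length - flank_min - gap + 1))
            seq = t.seq[:start] + t.seq[start + gap:]
            if sub_rate > 0:
                arr = np.array(list(seq))
                hits = rng.random(len(arr)) < sub_rate
                repl = np.array(list("ACGT"))[rng.integers(0, 4, hits.sum())]
                arr[hits] = repl  # may silently keep the same base; rate is approximate
                seq = "".join(arr)
            vid = f"{fam}_iso{k}"
            out.add(Transcript(vid, seq))
            variant_len = t.length - gap
            flank_right = t.length - (start + gap)
            detectable = (
                t.length > MIN_SEQ_LEN and variant_len > MIN_SEQ_LEN
                and gap > MIN_GAP
                and start >= MIN_FLANK and flank_right >= MIN_FLANK
            )
            truth.add(TruthRecord(vid, family=fam, relation="deletion",
                                  gap_interval=(start, start + gap),
                                  detectable=detectable))
    return out, truth


def plant_duplicates(parents: TranscriptSet, truth: SyntheticTruth,
                     q: float = 0.995, seed: int = 0,
                     threshold: float = 0.99) -> tuple[TranscriptSet, SyntheticTruth]:
    """Add one point-substituted near-duplicate per parent at identity ~q."""
    if not 0.5 <= q <= 1:
        raise ValueError("duplicate identity q must be in [0.5, 1]")
    rng = np.random.default_rng(seed)
    out = TranscriptSet(provenance="synthetic")
    for t in parents:
        out.add(t)
    bases = np.array(list("ACGT"))
    for t in list(parents):
        fam = truth[t.id].family
        arr = np.array(list(t.seq))
        hits = rng.random(len(arr)) < (1 - q)
        for i in np.flatnonzero(hits):
            arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
        did = f"{t.id}_dup"
        out.add(Transcript(did, "".join(arr)))
        realized = 1.0 - hits.sum() / len(arr)
        truth.add(TruthRecord(did, family=fam, relation="duplicate",
                              duplicate_identity=realized,
                              within_cluster_threshold=realized >= threshold))
    return out, truth


def default_design(n_a: int = 3, n_b: int = 4,
                   group_a: str = "testis", group_b: str = "ovary") -> SampleDesign:
    """The study's replicate structure: three testes and four ovaries."""
    groups = {f"{group_a}_{i+1}": group_a for i in range(n_a)}
    groups.update({f"{group_b}_{i+1}": group_b for i in range(n_b)})
    return SampleDesign(groups)


def plant_effects(truth: SyntheticTruth, ids: list[str], seed: int = 0,
                  frac_specific: float = 0.05, frac_fc: float = 0.1,
                  log2fc: float = 3.0) -> SyntheticTruth:
    """Assign group effects: group-specific, fixed |log2FC| (random sign), or none."""
    rng = np.random.default_rng(seed)
    ids = list(ids)
    rng.shuffle(ids)
    n_spec = int(round(frac_specific * len(ids)))
    n_fc = int(round(frac_fc * len(ids)))
    for tid in ids[:n_spec]:
        rec = truth[tid]
        rec.effect = "group_specific"
        rec.specific_group = "B" if rng.random() < 0.5 else "A"
    for tid in ids[n_spec:n_spec + n_fc]:
        rec = truth[tid]
        rec.effect = "log2fc"
        rec.log2fc = log2fc if rng.random() < 0.5 else -log2fc
    return truth


def simulate_counts(truth: SyntheticTruth, design: SampleDesign,
                    nb_dispersion: float = 0.1,
                    depth_range: tuple[float, float] = (8e5, 1.2e6),
                    seed: int = 0) -> CountMatrix:
    """Simulate a two-group negative-binomial count matrix from the truth.

    Per-transcript baselines are log-uniform; sample library-size factors are
    log-uniform in [0.7, 1.3] (modest realistic depth variation).  A
    transcript with effect "log2fc" has group-B mean scaled by 2**log2fc;
    "group_specific" transcripts have mean zero in the off group.
    ``nb_dispersion`` = 0 gives Poisson counts.
    """
    if nb_dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    ids = list(truth.records)
    n = len(ids)
    samples = design.samples
    ga, gb = design.group_labels
    depth = rng.uniform(*depth_range)
    # relative abundance: log-uniform baselines normalised to the target depth
    base = np.exp(rng.uniform(np.log(1.0), np.log(100.0), size=n))
    base *= depth / base.sum()
    size_factors = np.exp(rng.uniform(np.log(0.7), np.log(1.3), len(samples)))
    counts = np.zeros((n, len(samples)), dtype=np.int64)
    group_of = [design.groups[s] for s in samples]
    for i, tid in enumerate(ids):
        rec = truth[tid]
        for j, s in enumerate(samples):
            mu = base[i] * size_factors[j]
            if rec.effect == "log2fc" and group_of[j] == gb:
                mu *= 2.0 ** rec.log2fc
            if rec.effect == "group_specific":
                on = gb if rec.specific_group == "B" else ga
                if group_of[j] != on:
                    mu = 0.0
            if mu == 0.0:
                counts[i, j] = 0
            elif nb_dispersion == 0:
                counts[i, j] = rng.poisson(mu)
            else:
                # NB with mean mu, variance mu + phi*mu^2
                r = 1.0 / nb_dispersion
                p = r / (r + mu)
                counts[i, j] = rng.negative_binomial(r, p)
    df = pd.DataFrame(counts, index=ids, columns=samples)
    return CountMatrix(df)


# ---------------------------------------------------------------------------
# Coding / noncoding sequence generation
# ---------------------------------------------------------------------------

# Codon preference used to give coding ORFs a biased (coding-like) hexamer
# profile: per amino acid, codons and sampling weights loosely following
# vertebrate usage.  Stop codons are excluded inside ORFs.
_CODING_CODONS: Mapping[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "A": (("GCC", "GCT", "GCA", "GCG"), (0.4, 0.3, 0.2, 0.1)),
    "R": (("AGA", "AGG", "CGC", "CGG"), (0.3, 0.25, 0.25, 0.2)),
    "N": (("AAC", "AAT"), (0.55, 0.45)),
    "D": (("GAC", "GAT"), (0.55, 0.45)),
    "C": (("TGC", "TGT"), (0.55, 0.45)),
    "Q": (("CAG", "CAA"), (0.7, 0.3)),
    "E": (("GAG", "GAA"), (0.6, 0.4)),
    "G": (("GGC", "GGA", "GGG", "GGT"), (0.35, 0.25, 0.25, 0.15)),
    "H": (("CAC", "CAT"), (0.6, 0.4)),
    "I": (("ATC", "ATT", "ATA"), (0.5, 0.35, 0.15)),
    "L": (("CTG", "CTC", "TTG", "CTT"), (0.4, 0.25, 0.2, 0.15)),
    "K": (("AAG", "AAA"), (0.6, 0.4)),
    "M": (("ATG",), (1.0,)),
    "F": (("TTC", "TTT"), (0.55, 0.45)),
    "P": (("CCC", "CCT", "CCA", "CCG"), (0.35, 0.3, 0.25, 0.1)),
    "S": (("AGC", "TCC", "TCT", "AGT"), (0.3, 0.3, 0.2, 0.2)),
    "T": (("ACC", "ACA", "ACT", "ACG"), (0.4, 0.25, 0.25, 0.1)),
    "W": (("TGG",), (1.0,)),
    "Y": (("TAC", "TAT"), (0.6, 0.4)),
    "V": (("GTG", "GTC", "GTT", "GTA"), (0.45, 0.25, 0.2, 0.1)),
}
_AA = list(_CODING_CODONS)
_STOPS = ("TAA", "TAG", "TGA")


def _coding_orf(rng: np.random.Generator, n_aa: int) -> str:
    codons = ["ATG"]
    for aa in rng.choice(_AA, size=n_aa - 1):
        opts, w = _CODING_CODONS[aa]
        codons.append(str(rng.choice(opts, p=np.array(w) / sum(w))))
    codons.append(str(rng.choice(_STOPS)))
    return "".join(codons)


def generate_coding_noncoding(n_each: int, orf_aa_range: tuple[int, int] = (300, 500),
                              total_len_range: tuple[int, int] = (1200, 2400),
                              seed: int = 0,
                              max_noncoding_orf_aa: int = 100
                              ) -> tuple[TranscriptSet, SyntheticTruth]:
    """Generate composition-matched coding and noncoding transcripts.

    Coding transcripts embed a stop-free ORF (ATG..stop) of the requested
    amino-acid length with biased codon usage, flanked by random UTRs.
    Noncoding transcripts are mononucleotide-composition-matched to the
    coding set but lack its codon periodicity: bases are drawn i.i.d. from
    the coding set's empirical base frequencies and stop codons are then
    planted wherever needed to cap the longest ORF at
    ``max_noncoding_orf_aa`` (stop insertion rather than shuffling keeps the
    composition signal controllable independently of ORF length).
    """
    rng = np.random.default_rng(seed)
    ts = TranscriptSet(provenance="synthetic")
    truth = SyntheticTruth(seed=seed, params={"n_each": n_each,
                                              "orf_aa_range": orf_aa_range})
    from gonadiso.lncrna import find_longest_orf  # local import: avoid cycle

    base_counts = {b: 1 for b in "ACGT"}
    for i in range(n_each):
        n_aa = int(rng.integers(*orf_aa_range))
        orf = _coding_orf(rng, n_aa)
        total = max(int(rng.integers(*total_len_range)), len(orf) + 60)
        utr5 = int(rng.integers(20, total - len(orf) - 20))
        utr3 = total - len(orf) - utr5
        seq = _random_seq(rng, utr5) + orf + _random_seq(rng, utr3)
        for b in "ACGT":
            base_counts[b] += seq.count(b)
        tid = f"coding{i:04d}"
        ts.add(Transcript(tid, seq))
        truth.add(TruthRecord(tid, family=tid, relation="coding", coding=True,
                              orf_interval=(utr5, utr5 + len(orf))))
    bases = np.array(list("ACGT"))
    freqs = np.array([base_counts[b] for b in "ACGT"], dtype=float)
    freqs /= freqs.sum()
    for i in range(n_each):
        total = int(rng.integers(*total_len_range))
        tid = f"noncoding{i:04d}"
        t = Transcript(tid, "".join(bases[rng.choice(4, size=total, p=freqs)]))
        orf_rec = find_longest_orf(t)
        while orf_rec is not None and orf_rec.protein_length > max_noncoding_orf_aa:
            s = list(t.seq)
            mid = orf_rec.start + 3 * (orf_rec.protein_length // 2)
            s[mid:mid + 3] = list(_STOPS[rng.integers(0, 3)])
            t = Transcript(tid, "".join(s))
            orf_rec = find_longest_orf(t)
        ts.add(t)
        truth.add(TruthRecord(tid, family=tid, relation="noncoding", coding=False))
    return ts, truth
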