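"""Domain types and file IO shared by every pipeline stage.

Transcripts are full-length cDNA sequences ("unigenes"): sense strand,
alphabet {A, C, G, T, N}.  Coordinates in files are 1-based inclusive
(BLAST-style HSP reporting); in-memory intervals are 0-based half-open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class Transcript:
    """A single full-length transcript (unigene)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if not self.seq:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"transcript {self.id!r}: invalid character(s) {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


class TranscriptSet:
    """Ordered collection of transcripts with unique ids.

    ``provenance`` tags where the set came from: "raw", "collapsed" or
    "synthetic".
    """

    def __init__(self, transcripts: Iterable[Transcript] = (),
                 provenance: str = "raw") -> None:
        self.provenance = provenance
        self._by_id: dict[str, Transcript] = {}
        for t in transcripts:
            self.add(t)

    def add(self, t: Transcript) -> None:
        if t.id in self._by_id:
            raise ValueError(f"duplicate transcript id {t.id!r}")
        self._by_id[t.id] = t

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self._by_id.values())

    def __contains__(self, tid: str) -> bool:
        return tid in self._by_id

    def __getitem__(self, tid: str) -> Transcript:
        return self._by_id[tid]

    @property
    def ids(self) -> list[str]:
        return list(self._by_id)

    def lengths(self) -> pd.Series:
        return pd.Series({t.id: t.length for t in self}, name="length")


@dataclass(frozen=True)
class SampleDesign:
    """Maps sample ids to exactly two tissue-group labels."""

    groups: Mapping[str, str]  # sample id -> group label

    def __post_init__(self) -> None:
        labels = set(self.groups.values())
        if len(labels) != 2:
            raise ValueError(f"design must have exactly two groups, got {sorted(labels)}")

    @property
    def samples(self) -> list[str]:
        return list(self.groups)

    @property
    def group_labels(self) -> tuple[str, str]:
        seen: list[str] = []
        for g in self.groups.values():
            if g not in seen:
                seen.append(g)
        return seen[0], seen[1]

    def samples_of(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    @classmethod
    def read(cls, path: str | Path) -> "SampleDesign":
        df = pd.read_csv(path, sep=None, engine="python", header=None,
                         names=["sample", "group"], dtype=str, comment="#")
        return cls(dict(zip(df["sample"], df["group"])))

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s, g in self.groups.items():
                fh.write(f"{s}\t{g}\n")


class CountMatrix:
    """Transcripts x samples matrix of nonnegative integer read counts."""

    def __init__(self, counts: pd.DataFrame) -> None:
        if (counts.values < 0).any():
            raise ValueError("negative count in matrix")
        self.df = counts.astype("int64")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    def library_sizes(self) -> pd.Series:
        return self.df.sum(axis=0)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.df.to_csv(path, sep=sep, index_label="transcript")


@dataclass
class PathwayMap:
    """Pathway (or GO term) id -> member transcript ids, with a universe."""

    pathways: Mapping[str, frozenset]
    universe: frozenset

    def __post_init__(self) -> None:
        self.pathways = {k: frozenset(v) for k, v in self.pathways.items()}
        self.universe = frozenset(self.universe) | frozenset().union(*self.pathways.values()) \
            if self.pathways else frozenset(self.universe)
        for pid, members in self.pathways.items():
            if not members:
                raise ValueError(f"pathway {pid!r} is empty")

    @classmethod
    def read(cls, path: str | Path) -> "PathwayMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["pathway", "member"],
                         dtype=str, comment="#")
        grouped = {p: frozenset(sub["member"]) for p, sub in df.groupby("pathway")}
        return cls(grouped, frozenset(df["member"]))


@dataclass
class PanelAnnotation:
    """Transcript id -> curated gene symbol (e.g. Foxl2), one symbol each."""

    symbols: Mapping[str, str]  # transcript id -> gene symbol
    accessions: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def read(cls, path: str | Path) -> "PanelAnnotation":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        cols = list(df.columns)
        sym = dict(zip(df[cols[0]], df[cols[1]]))
        acc = dict(zip(df[cols[0]], df[cols[2]])) if len(cols) > 2 else {}
        return cls(sym, acc)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, provenance: str = "raw") -> TranscriptSet:
    """Read a (possibly wrapped) multi-FASTA into a TranscriptSet.

    Sequences are uppercased and U is mapped to T; any other character
    outside {A,C,G,T,N} is a hard error naming the record and character.
    """
    ts = TranscriptSet(provenance=provenance)
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"record {rec.id!r}: invalid character(s) {sorted(bad)!r}"
            )
        if not seq:
            raise ValueError(f"record {rec.id!r}: empty sequence")
        ts.add(Transcript(rec.id, seq))
    return ts


def write_fasta(ts: TranscriptSet, path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(t.seq), id=t.id, description="") for t in ts]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path, design: SampleDesign) -> CountMatrix:
    """Read a delimited counts table; columns are reordered to design order.

    Counts must parse as nonnegative integers; a fractional or negative value
    is a hard error citing the offending cell.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    extra = [c for c in df.columns if c not in design.groups]
    if extra:
        raise ValueError(f"sample(s) {extra} in counts header absent from design")
    missing = [s for s in design.samples if s not in df.columns]
    if missing:
        raise ValueError(f"design sample(s) {missing} absent from counts header")
    if df.isna().any().any():
        r, c = next(zip(*df.isna().values.nonzero()))
        raise ValueError(f"missing count at row {df.index[r]!r}, column {df.columns[c]!r}")
    for col in df.columns:
        vals = df[col]
        frac = vals != vals.astype("int64")
        if frac.any():
            row = vals.index[frac.argmax()]
            raise ValueError(
                f"non-integer count {vals[row]!r} at row {row!r}, column {col!r}")
        if (vals < 0).any():
            row = vals.index[(vals < 0).argmax()]
            raise ValueError(f"negative count at row {row!r}, column {col!r}")
    return CountMatrix(df[design.samples])


# ---------------------------------------------------------------------------
# AS event table
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = [
    "id_a", "id_b",
    "hsp1_a_start", "hsp1_a_end", "hsp1_b_start", "hsp1_b_end",
    "hsp2_a_start", "hsp2_a_end", "hsp2_b_start", "hsp2_b_end",
    "gap_len", "dist_5prime", "dist_3prime", "overlap",
]


def write_event_table(events, path: str | Path) -> None:
    """Write accepted AS events as TSV, coordinates 1-based inclusive."""
    rows = []
    for ev in events:
        h1, h2 = ev.hsps
        rows.append({
            "id_a": ev.id_a, "id_b": ev.id_b,
            "hsp1_a_start": h1.a_start + 1, "hsp1_a_end": h1.a_end,
            "hsp1_b_start": h1.b_start + 1, "hsp1_b_end": h1.b_end,
            "hsp2_a_start": h2.a_start + 1, "hsp2_a_end": h2.a_end,
            "hsp2_b_start": h2.b_start + 1, "hsp2_b_end": h2.b_end,
            "gap_len": ev.gap_len,
            "dist_5prime": ev.dist_5prime, "dist_3prime": ev.dist_3prime,
            "overlap": ev.overlap,
        })
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_event_table(path: str | Path):
    """Re-parse an event TSV into ASEvent objects (lossless round trip)."""
    from gonadiso.splicing import ASEvent, HSP

    df = pd.read_csv(path, sep="\t")
    events = []
    for _, r in df.iterrows():
        h1 = HSP(int(r.hsp1_a_start) - 1, int(r.hsp1_a_end),
                 int(r.hsp1_b_start) - 1, int(r.hsp1_b_end), score=1.0, identity=1.0)
        h2 = HSP(int(r.hsp2_a_start) - 1, int(r.hsp2_a_end),
                 int(r.hsp2_b_start) - 1, int(r.hsp2_b_end), score=1.0, identity=1.0)
        events.append(ASEvent(str(r.id_a), str(r.id_b), (h1, h2),
                              int(r.gap_len), int(r.dist_5prime),
                              int(r.dist_3prime), int(r.overlap)))
    return events
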