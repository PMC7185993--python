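"""Core-aligned GT-A domain sequences: I/O, trimming, filters and networks.

The GT-A common core is a fixed set of aligned match columns (231 in the
published alignment) shared across glycosyltransferase families with the
Rossmann-like GT-A fold.  Sequences are stored in an A2M-style aligned FASTA
dialect: uppercase letters and ``-`` are match states (residue or gap in a
core column), lowercase runs are insertions anchored between two consecutive
match columns, and ``.`` is an ignorable insert placeholder.  Lowercase runs
before the first or after the last match column are treated as N-/C-terminal
flanking regions rather than core insertions.

Column identifiers are 1-based throughout, so that e.g. the G-loop glycine
sits at aligned position 151 and the C-terminal histidine at 207 in the
published numbering.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

#: Ungapped Karlin-Altschul parameters for BLOSUM62 (lambda in nats, K).
KARLIN_ALTSCHUL_LAMBDA = 0.3176
KARLIN_ALTSCHUL_K = 0.134

MOTIF_TAGS = ("none", "DxD", "xED", "G-loop", "C-His", "hydrophobic-core")
HV_NAMES = ("HV1", "HV2", "HV3")


class AlignmentFormatError(ValueError):
    """Raised when a file violates the A2M match/insert convention."""


class AlignmentParseError(ValueError):
    """Raised on characters outside the amino-acid + gap alphabet."""


@dataclass
class SequenceRecord:
    """One core-aligned GT-A domain sequence.

    ``core_states`` has exactly one character (residue or ``-``) per core
    column.  ``inserts`` maps an anchor index *i* (1-based id of the match
    column preceding the insertion; 0 = before the first column) to the
    inserted residue string.  ``n_term``/``c_term`` hold flanking residues
    outside the aligned domain.
    """

    id: str
    core_states: str
    inserts: dict[int, str] = field(default_factory=dict)
    n_term: str = ""
    c_term: str = ""
    source_organism: str | None = None
    family_label: str | None = None

    def __post_init__(self) -> None:
        for ch in self.core_states:
            if ch != GAP and ch not in AMINO_ACIDS:
                raise AlignmentParseError(
                    f"record {self.id!r}: illegal core state {ch!r}"
                )
        for anchor, ins in self.inserts.items():
            if GAP in ins:
                raise AlignmentParseError(
                    f"record {self.id!r}: gap character inside insert at anchor {anchor}"
                )

    @property
    def n_term_flank(self) -> int:
        return len(self.n_term)

    @property
    def c_term_flank(self) -> int:
        return len(self.c_term)

    @property
    def n_aligned(self) -> int:
        """Number of non-gap match states (aligned positions covered)."""
        return len(self.core_states) - self.core_states.count(GAP)

    @property
    def total_insert_length(self) -> int:
        return sum(len(v) for v in self.inserts.values())


@dataclass
class AlignedSequenceSet:
    """An ordered collection of records over a fixed set of core columns."""

    records: list[SequenceRecord]
    n_core_columns: int

    def __post_init__(self) -> None:
        for rec in self.records:
            if len(rec.core_states) != self.n_core_columns:
                raise AlignmentFormatError(
                    f"record {rec.id!r} has {len(rec.core_states)} match states, "
                    f"expected {self.n_core_columns}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    @property
    def column_ids(self) -> list[int]:
        """1-based aligned-position identifiers."""
        return list(range(1, self.n_core_columns + 1))

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def column(self, column_id: int) -> str:
        """Residue states of one core column (1-based id), as a string."""
        if not 1 <= column_id <= self.n_core_columns:
            raise IndexError(f"column id {column_id} out of range")
        i = column_id - 1
        return "".join(r.core_states[i] for r in self.records)

    def core_matrix(self) -> np.ndarray:
        """(n_records, n_columns) array of single characters."""
        return np.array([list(r.core_states) for r in self.records], dtype="U1")

    def with_family_labels(self, labels: Mapping[str, str]) -> "AlignedSequenceSet":
        recs = [replace(r, family_label=labels.get(r.id, r.family_label)) for r in self.records]
        return AlignedSequenceSet(recs, self.n_core_columns)


@dataclass
class CoreAnnotation:
    """Per-core-column metadata: secondary structure, motif tag, HV anchor.

    Exactly three columns carry an HV anchor (HV1, HV2, HV3); an anchor
    column marks the core position after which the hypervariable insertion
    emerges.  A column carries at most one motif tag.
    """

    ss_element: list[str]
    motif_tag: list[str]
    hv_anchor: list[str]

    def __post_init__(self) -> None:
        n = len(self.ss_element)
        if not (len(self.motif_tag) == len(self.hv_anchor) == n):
            raise ValueError("annotation columns have inconsistent lengths")
        for tag in self.motif_tag:
            if tag not in MOTIF_TAGS:
                raise ValueError(f"unknown motif tag {tag!r}")
        anchors = [a for a in self.hv_anchor if a != "none"]
        if sorted(anchors) != sorted(HV_NAMES):
            raise ValueError("annotation must carry exactly one anchor for each of HV1-3")

    @property
    def n_columns(self) -> int:
        return len(self.ss_element)

    @property
    def hv_anchors(self) -> dict[str, int]:
        """Map HV name -> 1-based anchor column id."""
        return {a: i + 1 for i, a in enumerate(self.hv_anchor) if a != "none"}

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "column_id": range(1, self.n_columns + 1),
                "ss_element": self.ss_element,
                "motif_tag": self.motif_tag,
                "hv_anchor": self.hv_anchor,
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CoreAnnotation":
        df = pd.read_csv(path, sep="\t").sort_values("column_id")
        return cls(
            ss_element=df["ss_element"].astype(str).tolist(),
            motif_tag=df["motif_tag"].astype(str).tolist(),
            hv_anchor=df["hv_anchor"].astype(str).tolist(),
        )


# ---------------------------------------------------------------------------
# I/O


def _parse_a2m_states(rec_id: str, text: str) -> SequenceRecord:
    core: list[str] = []
    inserts: dict[int, list[str]] = {}
    for pos, ch in enumerate(text):
        if ch == GAP or (ch.isupper() and ch in AMINO_ACIDS):
            core.append(ch)
        elif ch == ".":
            continue
        elif ch.islower() and ch.upper() in AMINO_ACIDS:
            inserts.setdefault(len(core), []).append(ch.upper())
        else:
            raise AlignmentParseError(
                f"record {rec_id!r}: illegal character {ch!r} at position {pos + 1}"
            )
    n = len(core)
    n_term = "".join(inserts.pop(0, []))
    c_term = "".join(inserts.pop(n, [])) if n in inserts else ""
    return SequenceRecord(
        id=rec_id,
        core_states="".join(core),
        inserts={a: "".join(v) for a, v in inserts.items()},
        n_term=n_term,
        c_term=c_term,
    )


def read_core_alignment(path: str | Path) -> AlignedSequenceSet:
    """Read an A2M-style aligned FASTA file into an :class:`AlignedSequenceSet`.

    Every sequence must yield the same number of match states (uppercase or
    ``-``); a mismatch raises :class:`AlignmentFormatError` naming the
    offending record, an illegal character raises
    :class:`AlignmentParseError` with its position.
    """
    path = Path(path)
    records = []
    n_core: int | None = None
    for bio_rec in SeqIO.parse(str(path), "fasta"):
        rec = _parse_a2m_states(bio_rec.id, str(bio_rec.seq))
        if n_core is None:
            n_core = len(rec.core_states)
        elif len(rec.core_states) != n_core:
            raise AlignmentFormatError(
                f"record {rec.id!r} has {len(rec.core_states)} match columns, "
                f"but {n_core} were established by the first record"
            )
        records.append(rec)
    if n_core is None:
        raise AlignmentFormatError(f"no sequences found in {path}")
    return AlignedSequenceSet(records, n_core)


def _record_to_a2m(rec: SequenceRecord) -> str:
    parts = [rec.n_term.lower()]
    for i, state in enumerate(rec.core_states, start=1):
        parts.append(state)
        if i in rec.inserts and i != len(rec.core_states):
            parts.append(rec.inserts[i].lower())
    parts.append(rec.c_term.lower())
    return "".join(parts)


def write_core_alignment(aln: AlignedSequenceSet, path: str | Path) -> None:
    """Write the set back to A2M-style aligned FASTA (inverse of reading)."""
    bio_records = [
        BioSeqRecord(Seq(_record_to_a2m(r)), id=r.id, description="") for r in aln
    ]
    SeqIO.write(bio_records, str(path), "fasta-2line")


# ---------------------------------------------------------------------------
# Trimming and gap statistics


def trim_to_core(aln: AlignedSequenceSet) -> AlignedSequenceSet:
    """Discard all insert segments and flanks, keeping only core columns.

    Idempotent; column order is unchanged.  This is the projection used
    before phylogeny and feature encoding.
    """
    recs = [
        SequenceRecord(
            id=r.id,
            core_states=r.core_states,
            source_organism=r.source_organism,
            family_label=r.family_label,
        )
        for r in aln
    ]
    return AlignedSequenceSet(recs, aln.n_core_columns)


def column_gap_fractions(aln: AlignedSequenceSet) -> np.ndarray:
    """Fraction of records with a gap at each core column (length n array)."""
    if len(aln) == 0:
        raise ValueError("cannot compute gap fractions of an empty alignment")
    mat = aln.core_matrix()
    return (mat == GAP).mean(axis=0)


def filter_gapped_columns(
    aln: AlignedSequenceSet, threshold: float = 0.15
) -> tuple[AlignedSequenceSet, list[int]]:
    """Remove columns whose gap fraction strictly exceeds ``threshold``.

    Returns the reduced set and the kept original 1-based column ids;
    a column at exactly the threshold is kept.  Inserts are re-anchored to
    the nearest preceding kept column.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    fractions = column_gap_fractions(aln)
    kept = [cid for cid, f in zip(aln.column_ids, fractions) if f <= threshold]
    kept_idx = [c - 1 for c in kept]
    # old anchor (count of preceding original columns) -> count of preceding kept columns
    n_kept_before = np.cumsum(
        [1 if (c + 1) in kept else 0 for c in range(aln.n_core_columns)]
    )

    def remap(anchor: int) -> int:
        return 0 if anchor == 0 else int(n_kept_before[anchor - 1])

    recs = []
    for r in aln:
        new_inserts: dict[int, str] = {}
        for a, ins in r.inserts.items():
            na = remap(a)
            new_inserts[na] = new_inserts.get(na, "") + ins
        recs.append(
            SequenceRecord(
                id=r.id,
                core_states="".join(r.core_states[i] for i in kept_idx),
                inserts=new_inserts,
                n_term=r.n_term,
                c_term=r.c_term,
                source_organism=r.source_organism,
                family_label=r.family_label,
            )
        )
    return AlignedSequenceSet(recs, len(kept)), kept


# ---------------------------------------------------------------------------
# Consensus and prototype


@dataclass
class ConsensusResult:
    sequence: str
    tie_columns: list[int]
    all_gap_columns: list[int]


def consensus_sequence(aln: AlignedSequenceSet) -> ConsensusResult:
    """Per-column modal residue, gaps excluded from the vote.

    Ties are broken lexicographically by one-letter code and recorded in
    ``tie_columns``; all-gap columns yield ``-`` and are recorded in
    ``all_gap_columns``.
    """
    if len(aln) == 0:
        raise ValueError("cannot build a consensus of an empty alignment")
    out = []
    ties: list[int] = []
    all_gap: list[int] = []
    for cid in aln.column_ids:
        counts = Counter(ch for ch in aln.column(cid) if ch != GAP)
        if not counts:
            out.append(GAP)
            all_gap.append(cid)
            continue
        best = max(counts.values())
        winners = sorted(res for res, c in counts.items() if c == best)
        if len(winners) > 1:
            ties.append(cid)
        out.append(winners[0])
    return ConsensusResult("".join(out), ties, all_gap)


def prototype_select(
    aln: AlignedSequenceSet,
    consensus: str,
    matrix=None,
) -> tuple[SequenceRecord, float]:
    """Record closest to the consensus under a substitution matrix.

    The score is the summed substitution score over columns where both the
    record and the consensus carry a residue, normalized by the number of
    compared columns (BLOSUM62 by default).  Returns (record, score).
    """
    if len(aln) == 0:
        raise ValueError("cannot select a prototype from an empty set")
    if len(consensus) != aln.n_core_columns:
        raise ValueError("consensus length must match the core column count")
    if matrix is None:
        matrix = substitution_matrices.load("BLOSUM62")
    best_rec, best_score = None, -math.inf
    for rec in aln:
        total, n = 0.0, 0
        for res, cons in zip(rec.core_states, consensus):
            if res != GAP and cons != GAP:
                total += matrix[res, cons]
                n += 1
        score = total / n if n else -math.inf
        if score > best_score:
            best_rec, best_score = rec, score
    return best_rec, best_score


# ---------------------------------------------------------------------------
# Hypervariable regions


def detect_hypervariable(
    aln: AlignedSequenceSet,
    ann: CoreAnnotation,
    hv2_min_length: int = 28,
) -> pd.DataFrame:
    """Per-family insert-length report at the three HV anchor points.

    Returns a tidy frame with one row per (record, HV) pair that carries a
    non-empty insert: columns ``record_id, family, hv, anchor_column,
    insert_length, hv2_flag``.  HV2 is flagged when the insert between the
    beta6/beta7 anchors is strictly longer than ``hv2_min_length`` residues
    (the published definition uses 28).  A fully trimmed alignment yields an
    empty report.
    """
    if ann.n_columns != aln.n_core_columns:
        raise ValueError("annotation does not cover the alignment's columns")
    anchors = ann.hv_anchors
    rows = []
    for rec in aln:
        for hv in HV_NAMES:
            col = anchors[hv]
            length = len(rec.inserts.get(col, ""))
            if length == 0:
                continue
            rows.append(
                {
                    "record_id": rec.id,
                    "family": rec.family_label or "(unlabeled)",
                    "hv": hv,
                    "anchor_column": col,
                    "insert_length": length,
                    "hv2_flag": hv == "HV2" and length > hv2_min_length,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["record_id", "family", "hv", "anchor_column", "insert_length", "hv2_flag"],
    )


# ---------------------------------------------------------------------------
# Redundancy and ancient-sequence filters


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Matches over shared non-gap core columns; 0 if no column is shared."""
    shared = matches = 0
    for x, y in zip(a.core_states, b.core_states):
        if x != GAP and y != GAP:
            shared += 1
            if x == y:
                matches += 1
    return matches / shared if shared else 0.0


def redundancy_filter(
    aln: AlignedSequenceSet,
    max_identity: float = 0.70,
    per_family_overrides: Mapping[str, float] | None = None,
) -> AlignedSequenceSet:
    """Greedy family-wise redundancy reduction in input order.

    A record is kept iff its identity to every already-kept record of the
    same family is strictly below the family's threshold (default
    ``max_identity``; per-family overrides allow e.g. the stricter 50% bound
    used for the very large GT2 and GT8 families).
    """
    if not 0.0 < max_identity <= 1.0:
        raise ValueError("max_identity must be in (0, 1]")
    overrides = dict(per_family_overrides or {})
    kept_by_family: dict[str | None, list[SequenceRecord]] = {}
    kept: list[SequenceRecord] = []
    for rec in aln:
        fam = rec.family_label
        threshold = overrides.get(fam, max_identity)
        prior = kept_by_family.setdefault(fam, [])
        if all(pairwise_identity(rec, other) < threshold for other in prior):
            prior.append(rec)
            kept.append(rec)
    return AlignedSequenceSet(kept, aln.n_core_columns)


def ancient_filter(
    records: Iterable[SequenceRecord],
    min_aligned: int = 140,
    max_insert: int = 20,
    max_n_term: int = 100,
    max_c_term: int = 200,
) -> tuple[list[SequenceRecord], dict[str, str | None]]:
    """Select minimal ("ancient-like") GT-A domains by four printed bounds.

    Keeps records with more than ``min_aligned`` non-gap core positions
    (strict, removes fragments), fewer than ``max_insert`` total insert
    residues (strict), and flanks of at most ``max_n_term`` / ``max_c_term``
    residues.  Returns the kept records and a per-record reason map giving
    the first failing rule (``None`` when kept).  Aligned positions are
    counted as non-gap match states (the published criterion does not say
    whether gaps count; non-gap is the conservative reading).
    """
    kept = []
    reasons: dict[str, str | None] = {}
    for rec in records:
        if not rec.n_aligned > min_aligned:
            reasons[rec.id] = "aligned positions"
        elif not rec.total_insert_length < max_insert:
            reasons[rec.id] = "insert positions"
        elif not rec.n_term_flank <= max_n_term:
            reasons[rec.id] = "N-terminal region"
        elif not rec.c_term_flank <= max_c_term:
            reasons[rec.id] = "C-terminal region"
        else:
            reasons[rec.id] = None
            kept.append(rec)
    return kept, reasons


# ---------------------------------------------------------------------------
# Similarity network


def _pair_score(a: SequenceRecord, b: SequenceRecord, matrix) -> float:
    total = 0.0
    for x, y in zip(a.core_states, b.core_states):
        if x != GAP and y != GAP:
            total += matrix[x, y]
    return total


def similarity_network(
    aln: AlignedSequenceSet,
    evalue_cutoff: float = 0.05,
    matrix=None,
    ka_lambda: float = KARLIN_ALTSCHUL_LAMBDA,
    ka_k: float = KARLIN_ALTSCHUL_K,
) -> tuple[list[tuple[str, str, float]], list[str]]:
    """Sequence-similarity network over the core alignment.

    Edges connect pairs whose gapless core-alignment score yields a
    Karlin-Altschul E-value ``E = K m n exp(-lambda S)`` below
    ``evalue_cutoff`` (an approximation of an all-vs-all BLAST network on
    the same sequences).  Returns (edges, singletons); each edge is
    ``(id_a, id_b, evalue)``.
    """
    if len(aln) < 2:
        raise ValueError("similarity network requires at least two sequences")
    if matrix is None:
        matrix = substitution_matrices.load("BLOSUM62")
    edges = []
    connected: set[str] = set()
    recs = aln.records
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i], recs[j]
            s = _pair_score(a, b, matrix)
            m, n = a.n_aligned, b.n_aligned
            evalue = ka_k * m * n * math.exp(-ka_lambda * s)
            if evalue < evalue_cutoff:
                edges.append((a.id, b.id, evalue))
                connected.add(a.id)
                connected.add(b.id)
    singletons = [r.id for r in recs if r.id not in connected]
    return edges, singletons
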