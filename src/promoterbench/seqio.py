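"""Sequence containers, FASTA I/O, pairwise identity, and redundancy reduction.

Promoter windows are fixed-length DNA segments (default 81 nt) spanning
[TSS-60, TSS+20] with the mapped transcription start site at window
coordinate 60 (biological position 0).  Every record carries a class label
(promoter / non-promoter / unlabeled) and a provenance tag naming the
strategy that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO as _BioSeqIO
from Bio.Align import PairwiseAligner

DEFAULT_WINDOW = 81
ALPHABET = frozenset("ACGT")

#: provenance values a record may carry
SOURCES = (
    "experimental",
    "random",
    "coding",
    "convergent",
    "divergent",
    "copos",
    "coneg",
    "synthetic",
)

PROMOTER = 1
NONPROMOTER = 0


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending line/record."""


@dataclass(frozen=True)
class SequenceRecord:
    """One fixed-length DNA window with label and provenance.

    ``label`` is 1 (promoter), 0 (non-promoter) or None (unlabeled).
    """

    id: str
    residues: str
    label: Optional[int] = None
    source: str = "experimental"

    def __post_init__(self) -> None:
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-ACGT symbol(s) {sorted(bad)!r} rejected"
            )
        if self.label not in (None, 0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0, 1 or None")
        if self.source not in SOURCES:
            raise ValueError(
                f"record {self.id!r}: unknown source {self.source!r}; "
                f"expected one of {SOURCES}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceSet:
    """Ordered, id-unique collection of equal-length windows."""

    name: str
    records: list[SequenceRecord] = field(default_factory=list)
    window_length: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if len(rec) != self.window_length:
                raise ValueError(
                    f"record {rec.id!r} has length {len(rec)}, "
                    f"expected window length {self.window_length}"
                )
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r} in set {self.name!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    def sequences(self) -> list[str]:
        return [r.residues for r in self.records]

    def labels(self) -> list[Optional[int]]:
        return [r.label for r in self.records]

    def source_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.source] = counts.get(r.source, 0) + 1
        return counts

    def relabel(self, label: Optional[int]) -> "SequenceSet":
        return SequenceSet(
            name=self.name,
            records=[replace(r, label=label) for r in self.records],
            window_length=self.window_length,
        )


def read_fasta(
    path: str | Path,
    label: Optional[int] = None,
    source: str = "experimental",
    name: Optional[str] = None,
    window_length: Optional[int] = None,
) -> SequenceSet:
    """Read a multi-record FASTA file into a :class:`SequenceSet`.

    The header token before the first whitespace is used as the record id;
    input order is preserved.  Records with non-ACGT symbols or duplicate
    ids raise, they are never coerced.  ``window_length`` defaults to the
    length of the first record (all records must agree).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_fasta_text(path)
    records = []
    for entry in _BioSeqIO.parse(str(path), "fasta"):
        residues = str(entry.seq).upper()
        records.append(
            SequenceRecord(id=entry.id, residues=residues, label=label, source=source)
        )
    if window_length is None:
        window_length = len(records[0]) if records else DEFAULT_WINDOW
    return SequenceSet(
        name=name or path.stem, records=records, window_length=window_length
    )


def _validate_fasta_text(path: Path) -> None:
    # Biopython silently tolerates leading junk; fail loudly instead.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}:{lineno}: expected '>' header, got {line.strip()[:30]!r}"
                    )
                return


def write_fasta(sset: SequenceSet, path: str | Path, manifest: bool = True) -> Path:
    """Write a set as unwrapped FASTA plus a sidecar JSON provenance manifest."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in sset:
            fh.write(f">{rec.id}\n{rec.residues}\n")
    if manifest:
        digest = hashlib.md5(path.read_bytes()).hexdigest()
        meta = {
            "name": sset.name,
            "window_length": sset.window_length,
            "n_records": len(sset),
            "source_counts": sset.source_counts(),
            "md5": digest,
        }
        with open(path.with_suffix(path.suffix + ".manifest.json"), "w") as fh:
            json.dump(meta, fh, indent=2)
    return path


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: SequenceRecord | str, b: SequenceRecord | str) -> float:
    """Global-alignment identity in [0, 1]: matches / alignment length.

    Scoring: match +1, mismatch 0, linear gap penalty 1.  Symmetric, and
    1.0 exactly when the residues are identical.
    """
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    if not sa or not sb:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if sa == sb:
        return 1.0
    alignment = next(iter(_ALIGNER.align(sa, sb)))
    aln_a, aln_b = alignment[0], alignment[1]
    matches = sum(1 for x, y in zip(aln_a, aln_b) if x == y and x != "-")
    return matches / len(aln_a)


def reduce_redundancy(
    sset: SequenceSet,
    threshold: float = 0.45,
    reference: Optional[SequenceSet] = None,
) -> SequenceSet:
    """Greedy keep-first redundancy reduction at a pairwise-identity cutoff.

    A record survives iff its identity with every earlier survivor (and with
    every record of ``reference``, when given) is <= ``threshold``.  Order
    deterministic: first occurrence kept.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ref_seqs = list(reference.sequences()) if reference is not None else []
    survivors: list[SequenceRecord] = []
    for rec in sset:
        if any(pairwise_identity(rec.residues, s) > threshold for s in ref_seqs):
            continue
        if any(
            pairwise_identity(rec.residues, kept.residues) > threshold
            for kept in survivors
        ):
            continue
        survivors.append(rec)
    return SequenceSet(
        name=sset.name, records=survivors, window_length=sset.window_length
    )


def concat_sets(name: str, sets: Iterable[SequenceSet]) -> SequenceSet:
    """Concatenate sets sharing a window length; ids must stay unique."""
    sets = list(sets)
    if not sets:
        raise ValueError("need at least one set")
    wl = sets[0].window_length
    records = [r for s in sets for r in s]
    return SequenceSet(name=name, records=records, window_length=wl)
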