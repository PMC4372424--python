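"""The six non-promoter generation strategies and the mixed combiner.

Experimentally validated non-promoter data does not exist, so negatives are
manufactured.  Six strategies are implemented: windows sampled from (i) a
long random sequence with E. coli-like base composition, (ii) coding
regions, and (iii)-(vi) intergenic regions split by the orientation of the
flanking genes (convergent, divergent, codirectional on the forward or the
reverse strand).  A seventh "mixed" set draws equal shares from all six.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .seqio import NONPROMOTER, SequenceRecord, SequenceSet

#: background base frequencies of the random-sequence strategy (T, G, C, A)
ECOLI_BACKGROUND = {"T": 0.28, "G": 0.22, "C": 0.22, "A": 0.28}

INTERGENIC_CATEGORIES = (
    "convergent",
    "divergent",
    "codirectional_pos",
    "codirectional_neg",
)

_CATEGORY_TO_SOURCE = {
    "convergent": "convergent",
    "divergent": "divergent",
    "codirectional_pos": "copos",
    "codirectional_neg": "coneg",
}


@dataclass(frozen=True)
class BaseFrequencies:
    """Single-nucleotide background distribution over {A, C, G, T}."""

    freq: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.freq) != set("ACGT"):
            raise ValueError("frequencies must be given for exactly A, C, G, T")
        vals = list(self.freq.values())
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError("frequencies must lie in [0, 1]")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"frequencies must sum to 1, got {sum(vals)}")

    @classmethod
    def ecoli_like(cls) -> "BaseFrequencies":
        return cls(dict(ECOLI_BACKGROUND))

    def as_arrays(self) -> tuple[list[str], np.ndarray]:
        bases = sorted(self.freq)  # A C G T, fixed order
        return bases, np.array([self.freq[b] for b in bases])


@dataclass(frozen=True)
class Gene:
    id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.id!r}: strand must be '+' or '-'")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"gene {self.id!r}: need 1 <= start <= end")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAnnotation:
    """A genome sequence plus gene coordinates (1-based inclusive, GFF style)."""

    sequence: str
    genes: list[Gene]

    def __post_init__(self) -> None:
        n = len(self.sequence)
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        for g in self.genes:
            if g.end > n:
                raise ValueError(f"gene {g.id!r} extends past sequence end ({n})")
        # containment is disallowed; plain overlap is tolerated but flagged
        self.overlapping_pairs: list[tuple[str, str]] = []
        for a, b in zip(self.genes, self.genes[1:]):
            if b.end <= a.end:
                raise ValueError(f"gene {b.id!r} is contained inside {a.id!r}")
            if b.start <= a.end:
                self.overlapping_pairs.append((a.id, b.id))


def read_annotation_tsv(path: str | Path, sequence: str) -> GenomeAnnotation:
    """Read a 4-column TSV (id, start, end, strand) into a GenomeAnnotation."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gid, start, end, strand = line.split("\t")
            genes.append(Gene(gid, int(start), int(end), strand))
    return GenomeAnnotation(sequence=sequence, genes=genes)


def read_annotation_gff3(path: str | Path, sequence: str) -> GenomeAnnotation:
    """Read gene features from a GFF3 file (only ``gene`` rows are used)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8 or fields[2] != "gene":
                continue
            attrs = fields[8] if len(fields) > 8 else ""
            gid = None
            for part in attrs.split(";"):
                if part.startswith("ID="):
                    gid = part[3:]
                    break
            if gid is None:
                gid = f"gene_{len(genes) + 1}"
            genes.append(Gene(gid, int(fields[3]), int(fields[4]), fields[6]))
    return GenomeAnnotation(sequence=sequence, genes=genes)


def write_annotation_tsv(ann: GenomeAnnotation, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# id\tstart\tend\tstrand\n")
        for g in ann.genes:
            fh.write(f"{g.id}\t{g.start}\t{g.end}\t{g.strand}\n")
    return path


def random_dna(length: int, freqs: BaseFrequencies, rng: np.random.Generator) -> str:
    bases, p = freqs.as_arrays()
    return "".join(rng.choice(bases, size=length, p=p))


def generate_random_negatives(
    n: int,
    freqs: Optional[BaseFrequencies] = None,
    source_length: int = 1_000_000,
    window: int = 81,
    seed: int = 0,
    name: str = "random_negatives",
) -> SequenceSet:
    """Windows sampled from one long i.i.d. random sequence.

    A single source sequence of ``source_length`` is drawn from ``freqs``
    (default: the E. coli-like T/G/C/A = 0.28/0.22/0.22/0.28), then ``n``
    windows are cut at uniform random start positions (with replacement).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    freqs = freqs or BaseFrequencies.ecoli_like()
    rng = np.random.default_rng(seed)
    source = random_dna(source_length, freqs, rng)
    starts = rng.integers(0, source_length - window + 1, size=n)
    records = [
        SequenceRecord(
            id=f"rand_{i}_{s}",
            residues=source[s : s + window],
            label=NONPROMOTER,
            source="random",
        )
        for i, s in enumerate(starts)
    ]
    return SequenceSet(name=name, records=records, window_length=window)


def _sample_from_intervals(
    intervals: Sequence[tuple[int, int]],  # 0-based half-open
    sequence: str,
    n: int,
    window: int,
    rng: np.random.Generator,
    id_prefix: str,
    source: str,
) -> SequenceSet:
    """Sample windows uniformly over all valid start offsets across intervals."""
    valid = [(s, e) for s, e in intervals if e - s >= window]
    if not valid:
        raise ValueError(f"no interval of length >= {window} available for {source}")
    # choose interval proportional to its number of valid starts -> global uniform
    counts = np.array([e - s - window + 1 for s, e in valid], dtype=float)
    probs = counts / counts.sum()
    records = []
    for i in range(n):
        j = rng.choice(len(valid), p=probs)
        s0, e0 = valid[j]
        start = int(rng.integers(s0, e0 - window + 1))
        records.append(
            SequenceRecord(
                id=f"{id_prefix}_{i}_{start}",
                residues=sequence[start : start + window],
                label=NONPROMOTER,
                source=source,
            )
        )
    return SequenceSet(name=id_prefix, records=records, window_length=window)


def extract_coding_windows(
    ann: GenomeAnnotation,
    n: int,
    window: int = 81,
    seed: int = 0,
    name: str = "coding_negatives",
) -> SequenceSet:
    """Windows fully contained in gene bodies, uniform over valid placements."""
    rng = np.random.default_rng(seed)
    intervals = [(g.start - 1, g.end) for g in ann.genes]
    sset = _sample_from_intervals(
        intervals, ann.sequence, n, window, rng, "coding", "coding"
    )
    sset.name = name
    return sset


def classify_intergenic(
    ann: GenomeAnnotation,
) -> list[tuple[int, int, str]]:
    """Categorize gaps between adjacent genes by flanking-gene orientation.

    Returns 1-based inclusive (start, end, category) per adjacent pair with a
    positive gap.  (+,-) -> convergent, (-,+) -> divergent, (+,+) ->
    codirectional_pos, (-,-) -> codirectional_neg.
    """
    if len(ann.genes) < 2:
        raise ValueError("need at least two genes to define intergenic regions")
    table = {
        ("+", "-"): "convergent",
        ("-", "+"): "divergent",
        ("+", "+"): "codirectional_pos",
        ("-", "-"): "codirectional_neg",
    }
    regions = []
    for a, b in zip(ann.genes, ann.genes[1:]):
        gap_start, gap_end = a.end + 1, b.start - 1
        if gap_end < gap_start:
            continue  # abutting or overlapping pair: no region
        regions.append((gap_start, gap_end, table[(a.strand, b.strand)]))
    return regions


def extract_intergenic_windows(
    ann: GenomeAnnotation,
    category: str,
    n: int,
    window: int = 81,
    seed: int = 0,
    name: Optional[str] = None,
) -> SequenceSet:
    """Windows fully contained in intergenic regions of one category.

    Regions are used as written on the forward strand (no strand flipping).
    """
    if category not in INTERGENIC_CATEGORIES:
        raise ValueError(
            f"unknown category {category!r}; expected one of {INTERGENIC_CATEGORIES}"
        )
    rng = np.random.default_rng(seed)
    regions = [
        (s - 1, e) for s, e, cat in classify_intergenic(ann) if cat == category
    ]
    eligible = [(s, e) for s, e in regions if e - s >= window]
    if not eligible:
        raise ValueError(
            f"no {category} intergenic region of length >= {window} in annotation"
        )
    source = _CATEGORY_TO_SOURCE[category]
    sset = _sample_from_intervals(
        eligible, ann.sequence, n, window, rng, source, source
    )
    sset.name = name or f"{source}_negatives"
    return sset


def build_mixed(
    sets: Sequence[SequenceSet],
    n_total: int,
    seed: int = 0,
    name: str = "mixed_negatives",
) -> SequenceSet:
    """Draw ``n_total`` negatives in (near-)equal shares from six strategy sets.

    Share sizes differ by at most one; the larger shares go to the earlier
    sets in the given order (n_total = 579 over six sets gives
    97,97,97,96,96,96).  Sampling is without replacement within each set;
    per-record provenance is preserved.
    """
    k = len(sets)
    base, extra = divmod(n_total, k)
    shares = [base + (1 if i < extra else 0) for i in range(k)]
    for sset, share in zip(sets, shares):
        if len(sset) < share:
            raise ValueError(
                f"set {sset.name!r} has {len(sset)} records, needs {share}"
            )
    rng = np.random.default_rng(seed)
    records = []
    for sset, share in zip(sets, shares):
        idx = rng.choice(len(sset), size=share, replace=False)
        for j in sorted(idx):
            rec = sset[int(j)]
            records.append(
                SequenceRecord(
                    id=f"{sset.name}:{rec.id}",
                    residues=rec.residues,
                    label=NONPROMOTER,
                    source=rec.source,
                )
            )
    wl = sets[0].window_length
    return SequenceSet(name=name, records=records, window_length=wl)


def mixed_share_sizes(n_total: int, k: int = 6) -> list[int]:
    """The deterministic share allocation used by :func:`build_mixed`."""
    base, extra = divmod(n_total, k)
    return [base + (1 if i < extra else 0) for i in range(k)]
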