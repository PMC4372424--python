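"""Synthetic promoter windows and annotated genomes for fully offline studies.

Positives are background windows with degenerate sigma-70 box signals
planted at their canonical offsets: the -35 element TTGACA near window
offset 22 and the -10 element TATAAT near offset 49 (window coordinate 49
corresponds to TSS-11 in an 81-nt [TSS-60, TSS+20] window).  Each motif
copy is jittered by up to +/-2 nt and per-position mutated with probability
0.15 by default, giving a strong but imperfect discriminative signal
centred in positions ~45-55, where real sigma-70 promoter windows carry
their strongest structural footprint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .negatives import BaseFrequencies, Gene, GenomeAnnotation, random_dna
from .seqio import DEFAULT_WINDOW, PROMOTER, SequenceRecord, SequenceSet

MINUS35_BOX = "TTGACA"
MINUS10_BOX = "TATAAT"
MINUS35_OFFSET = 22
MINUS10_OFFSET = 49
DEFAULT_MUTATION_PROB = 0.15
DEFAULT_JITTER = 2

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class MotifSpec:
    """A degenerate motif planted at a (jittered) window offset."""

    consensus: str
    placement_position: int  # 0-based offset in the window
    per_position_mutation_prob: float = DEFAULT_MUTATION_PROB
    placement_jitter: int = DEFAULT_JITTER

    def __post_init__(self) -> None:
        if set(self.consensus) - set("ACGT"):
            raise ValueError("motif consensus must be over {A,C,G,T}")
        if not 0.0 <= self.per_position_mutation_prob <= 1.0:
            raise ValueError("mutation probability must be in [0, 1]")
        if self.placement_jitter < 0 or self.placement_position < 0:
            raise ValueError("placement and jitter must be non-negative")

    def max_extent(self) -> int:
        return self.placement_position + self.placement_jitter + len(self.consensus)

    def min_start(self) -> int:
        return self.placement_position - self.placement_jitter


def default_promoter_motifs() -> list[MotifSpec]:
    """The canonical sigma-70 -35 / -10 boxes at their window offsets."""
    return [
        MotifSpec(MINUS35_BOX, MINUS35_OFFSET),
        MotifSpec(MINUS10_BOX, MINUS10_OFFSET),
    ]


def _check_motifs(motifs: Sequence[MotifSpec], window: int) -> None:
    for m in motifs:
        if m.min_start() < 0 or m.max_extent() > window:
            raise ValueError(
                f"motif {m.consensus!r} at {m.placement_position} with jitter "
                f"{m.placement_jitter} does not fit window {window}"
            )
    spans = sorted((m.min_start(), m.max_extent()) for m in motifs)
    for (_, e1), (s2, _) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError("motif placements may overlap after jitter")


def make_synthetic_promoters(
    n: int,
    background: Optional[BaseFrequencies] = None,
    motifs: Optional[Sequence[MotifSpec]] = None,
    seed: int = 0,
    window: int = DEFAULT_WINDOW,
    name: str = "synthetic_promoters",
) -> SequenceSet:
    """Background windows with planted, jittered, degenerate motifs.

    Each record: (1) sample the window i.i.d. from ``background``; (2) write
    every motif at ``placement_position`` plus a uniform jitter in
    [-jitter, +jitter]; (3) mutate each written motif position to a uniform
    random base with the motif's mutation probability.  Labeled promoter;
    bit-reproducible for a given seed.
    """
    background = background or BaseFrequencies.ecoli_like()
    motifs = list(motifs) if motifs is not None else default_promoter_motifs()
    _check_motifs(motifs, window)
    rng = np.random.default_rng(seed)
    bases, p = background.as_arrays()
    records = []
    for i in range(n):
        seq = list(rng.choice(bases, size=window, p=p))
        for m in motifs:
            shift = int(rng.integers(-m.placement_jitter, m.placement_jitter + 1))
            start = m.placement_position + shift
            for j, base in enumerate(m.consensus):
                if rng.random() < m.per_position_mutation_prob:
                    seq[start + j] = str(_BASES[rng.integers(4)])
                else:
                    seq[start + j] = base
        records.append(
            SequenceRecord(
                id=f"synth_prom_{i}",
                residues="".join(seq),
                label=PROMOTER,
                source="synthetic",
            )
        )
    return SequenceSet(name=name, records=records, window_length=window)


def make_synthetic_genome(
    length: int = 50_000,
    n_genes: int = 40,
    strand_mix: float = 0.5,
    seed: int = 0,
    min_gene_length: int = 300,
    min_gap: int = 120,
    max_retries: int = 50,
) -> GenomeAnnotation:
    """A random annotated genome with all four intergenic categories present.

    Genes are packed left to right with random lengths and positive gaps;
    strands are i.i.d. Bernoulli(``strand_mix`` for '+').  The layout is
    re-drawn (bounded retries) until every category — convergent, divergent
    and both codirectional orientations — occurs at least once, so all six
    negative-set strategies are exercisable downstream.
    """
    need = length - n_genes * min_gene_length - (n_genes + 1) * min_gap
    if need < 0:
        raise ValueError(
            f"cannot pack {n_genes} genes of >= {min_gene_length} nt with "
            f"gaps >= {min_gap} into {length} nt"
        )
    rng = np.random.default_rng(seed)
    background = BaseFrequencies.ecoli_like()
    sequence = random_dna(length, background, rng)
    from .negatives import classify_intergenic  # local to avoid cycle at import

    for _ in range(max_retries):
        genes = _layout_genes(length, n_genes, strand_mix, min_gene_length, min_gap, rng)
        ann = GenomeAnnotation(sequence=sequence, genes=genes)
        cats = {cat for _, _, cat in classify_intergenic(ann)}
        if len(cats) == 4 or n_genes < 5:
            return ann
    raise RuntimeError(
        "could not realize all four intergenic categories; "
        "increase n_genes or retries"
    )


def _layout_genes(
    length: int,
    n_genes: int,
    strand_mix: float,
    min_gene_length: int,
    min_gap: int,
    rng: np.random.Generator,
) -> list[Gene]:
    # distribute the slack over genes and gaps with a Dirichlet draw
    slack = length - n_genes * min_gene_length - (n_genes + 1) * min_gap
    parts = rng.dirichlet(np.ones(2 * n_genes + 1)) * slack
    pos = 1
    genes = []
    for i in range(n_genes):
        pos += min_gap + int(parts[2 * i])
        glen = min_gene_length + int(parts[2 * i + 1])
        strand = "+" if rng.random() < strand_mix else "-"
        genes.append(Gene(f"g{i + 1}", pos, pos + glen - 1, strand))
        pos += glen
    assert genes[-1].end + min_gap <= length + 1
    return genes
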