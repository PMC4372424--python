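"""Loader for the published benchmark data sets (cross-validation and
independent test promoters with their seven matched negative versions).

The data are distributed as supplementary material of the study that
defined them and are not redistributed here.  To use them, download the
archive, extract the FASTA files and arrange them as::

    <root>/
      CV_promoters.fasta          579 positive windows
      TS_promoters.fasta          792 positive windows
      CV_Random_negatives.fasta   ... one file per negative version ...
      CV_Coding_negatives.fasta
      CV_Convergent_negatives.fasta
      CV_Divergent_negatives.fasta
      CV_CoPos_negatives.fasta
      CV_CoNeg_negatives.fasta
      CV_Mixed_negatives.fasta
      TS_Random_negatives.fasta   (same seven versions, TS_ prefix)
      ...

All windows must be 81 nt.  :func:`load_s1_dataset` returns the sets keyed
by their canonical names.
"""

from __future__ import annotations

from pathlib import Path

from .seqio import SequenceSet, read_fasta

VERSIONS = ("Random", "Coding", "Convergent", "Divergent", "CoPos", "CoNeg", "Mixed")

_SOURCE_OF = {
    "Random": "random",
    "Coding": "coding",
    "Convergent": "convergent",
    "Divergent": "divergent",
    "CoPos": "copos",
    "CoNeg": "coneg",
    "Mixed": "experimental",  # per-record provenance unknown in mixed files
}

EXPECTED_CV_POSITIVES = 579
EXPECTED_TS_POSITIVES = 792


def load_s1_dataset(root: str | Path, strict_counts: bool = True) -> dict[str, SequenceSet]:
    """Load the benchmark FASTA files from ``root``.

    Returns a dict with keys ``CV_promoters``, ``TS_promoters`` and
    ``{CV,TS}_{version}`` for the seven negative versions.  With
    ``strict_counts`` the canonical positive-set sizes (579 CV / 792 TS)
    are enforced.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(
            f"benchmark dataset directory not found: {root} "
            "(see module docstring for the expected layout)"
        )
    out: dict[str, SequenceSet] = {}
    for split, expected in (
        ("CV", EXPECTED_CV_POSITIVES),
        ("TS", EXPECTED_TS_POSITIVES),
    ):
        pos = read_fasta(root / f"{split}_promoters.fasta", label=1)
        if strict_counts and len(pos) != expected:
            raise ValueError(
                f"{split}_promoters.fasta has {len(pos)} records, expected {expected}"
            )
        out[f"{split}_promoters"] = pos
        for version in VERSIONS:
            neg = read_fasta(
                root / f"{split}_{version}_negatives.fasta",
                label=0,
                source=_SOURCE_OF[version],
            )
            out[f"{split}_{version}"] = neg
    return out
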