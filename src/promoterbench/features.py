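"""Feature encoders: k-mer composition, positional identity, one-hot, and
dinucleotide physicochemical structure profiles.

Sequence-based encodings
    * k-mer — 4^k numeric features, normalized overlapping counts.
    * NID — one nominal feature per position (L features, categories ACGT).
    * DNID — one nominal feature per adjacent pair (L-1 features, 16
      dinucleotide categories).
    * orthogonal codification — one-hot expansion of a nominal matrix for
      classifiers that require numeric input.

Structure-based encodings
    * struct:Mx — the sequence's dinucleotide-step profile under one of the
      twelve bundled physicochemical scales (M1..M12), smoothed with a
      centered moving average (window 3 by default, edges truncated), giving
      L-1 numeric features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from typing import Optional, Sequence

import numpy as np

from .seqio import SequenceSet

DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")
SCALE_IDS = tuple(f"M{i}" for i in range(1, 13))
DEFAULT_SMOOTHING = 3


@dataclass(frozen=True)
class DinucleotideScale:
    """A named map from the 16 dinucleotide steps to a physical value."""

    id: str
    name: str
    values: dict[str, float]
    units: str = ""
    citation: str = ""

    def __post_init__(self) -> None:
        if set(self.values) != set(DINUCLEOTIDES):
            missing = set(DINUCLEOTIDES) - set(self.values)
            raise ValueError(f"scale {self.id}: missing dinucleotides {sorted(missing)}")

    def __getitem__(self, dinuc: str) -> float:
        return self.values[dinuc]


@dataclass
class FeatureMatrix:
    """Design matrix (rows = sequences) with names, labels and encoding tag.

    ``values`` is float for numeric encodings and a string array for nominal
    ones; ``categories`` declares the per-column category set when nominal.
    """

    values: np.ndarray
    feature_names: list[str]
    encoding_tag: str
    labels: Optional[np.ndarray] = None
    categories: Optional[list[tuple[str, ...]]] = field(default=None)

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_sequences x d)")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must match number of columns")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.values.shape[0]:
                raise ValueError("labels length must match number of rows")
        if self.is_nominal:
            if self.categories is None or len(self.categories) != self.values.shape[1]:
                raise ValueError("nominal matrix needs one category set per column")
            for j, cats in enumerate(self.categories):
                observed = set(np.unique(self.values[:, j]))
                if not observed <= set(cats):
                    raise ValueError(
                        f"column {self.feature_names[j]!r} contains values "
                        f"outside its declared categories: {observed - set(cats)}"
                    )

    @property
    def is_nominal(self) -> bool:
        return not np.issubdtype(self.values.dtype, np.number)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def select_rows(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values[idx],
            feature_names=self.feature_names,
            encoding_tag=self.encoding_tag,
            labels=None if self.labels is None else self.labels[idx],
            categories=self.categories,
        )


def _labels_of(sset: SequenceSet) -> Optional[np.ndarray]:
    labs = sset.labels()
    if any(l is None for l in labs):
        return None
    return np.array(labs, dtype=int)


def kmer_names(k: int) -> list[str]:
    return ["".join(p) for p in product("ACGT", repeat=k)]


def encode_kmer(sset: SequenceSet, k: int) -> FeatureMatrix:
    """Normalized overlapping k-mer counts: 4^k columns in lexicographic
    order, each value count/(L-k+1), so every row sums to 1."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > sset.window_length:
        raise ValueError(f"k={k} exceeds window length {sset.window_length}")
    names = kmer_names(k)
    index = {kmer: j for j, kmer in enumerate(names)}
    L = sset.window_length
    denom = L - k + 1
    X = np.zeros((len(sset), len(names)))
    for i, rec in enumerate(sset):
        s = rec.residues
        for pos in range(denom):
            X[i, index[s[pos : pos + k]]] += 1.0
    X /= denom
    return FeatureMatrix(
        values=X,
        feature_names=names,
        encoding_tag=f"kmer:{k}",
        labels=_labels_of(sset),
    )


def encode_nid(sset: SequenceSet) -> FeatureMatrix:
    """Nucleotide identity: L nominal columns, column i = base at position i."""
    L = sset.window_length
    X = np.array([list(rec.residues) for rec in sset], dtype="<U1").reshape(
        len(sset), L
    )
    return FeatureMatrix(
        values=X,
        feature_names=[f"pos{i + 1}" for i in range(L)],
        encoding_tag="NID",
        labels=_labels_of(sset),
        categories=[tuple("ACGT")] * L,
    )


def encode_dnid(sset: SequenceSet) -> FeatureMatrix:
    """Dinucleotide identity: L-1 nominal columns over the 16 dinucleotides."""
    L = sset.window_length
    if L < 2:
        raise ValueError("DNID needs window length >= 2")
    rows = [
        [rec.residues[i : i + 2] for i in range(L - 1)] for rec in sset
    ]
    X = np.array(rows, dtype="<U2").reshape(len(sset), L - 1)
    return FeatureMatrix(
        values=X,
        feature_names=[f"step{i + 1}" for i in range(L - 1)],
        encoding_tag="DNID",
        labels=_labels_of(sset),
        categories=[DINUCLEOTIDES] * (L - 1),
    )


def decode_nid(m: FeatureMatrix) -> list[str]:
    """Inverse of :func:`encode_nid` (used to verify bijectivity)."""
    if m.encoding_tag != "NID":
        raise ValueError("decode_nid expects an NID matrix")
    return ["".join(row) for row in m.values]


def orthogonal_codify(m: FeatureMatrix) -> FeatureMatrix:
    """One-hot each nominal column: c categories become c binary indicators,
    exactly one hot per original column (NID(81) -> 324, DNID(80) -> 1280)."""
    if not m.is_nominal:
        raise ValueError("orthogonal codification applies to nominal matrices")
    blocks = []
    names = []
    for j, cats in enumerate(m.categories):
        col = m.values[:, j]
        block = np.zeros((m.n, len(cats)))
        cat_index = {c: t for t, c in enumerate(cats)}
        for i, v in enumerate(col):
            block[i, cat_index[v]] = 1.0  # values already validated vs categories
        blocks.append(block)
        names.extend(f"{m.feature_names[j]}={c}" for c in cats)
    return FeatureMatrix(
        values=np.hstack(blocks),
        feature_names=names,
        encoding_tag=f"{m.encoding_tag}:onehot",
        labels=m.labels,
    )


def load_scale(scale_id: str) -> DinucleotideScale:
    """Load one of the bundled dinucleotide physicochemical scales M1..M12."""
    if scale_id not in SCALE_IDS:
        raise ValueError(
            f"unknown scale {scale_id!r}; valid ids: {', '.join(SCALE_IDS)}"
        )
    ref = resources.files("promoterbench").joinpath(f"data/scales/{scale_id}.tsv")
    meta = {"name": "", "units": "", "citation": ""}
    values: dict[str, float] = {}
    for line in ref.read_text().splitlines():
        if line.startswith("#"):
            body = line[1:].strip()
            for key in meta:
                if body.startswith(f"{key}:"):
                    meta[key] = body[len(key) + 1 :].strip()
            continue
        if not line or line.startswith("dinucleotide"):
            continue
        dinuc, value = line.split("\t")
        values[dinuc] = float(value)
    return DinucleotideScale(id=scale_id, values=values, **meta)


def smooth_profile(profile: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with truncated (shrinking) edge windows."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    if window == 1:
        return profile.copy()
    half = window // 2
    n = profile.shape[-1]
    out = np.empty_like(profile, dtype=float)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[..., i] = profile[..., lo:hi].mean(axis=-1)
    return out


def encode_structure(
    sset: SequenceSet,
    scale: DinucleotideScale | str,
    smoothing_window: int = DEFAULT_SMOOTHING,
) -> FeatureMatrix:
    """Smoothed dinucleotide-step profile under a physicochemical scale.

    Raw profile p_i = scale(s[i:i+2]) for i = 1..L-1, then a centered moving
    average of width ``smoothing_window`` (edge windows shrink), keeping
    d = L-1 numeric features (80 for the 81-nt promoter window).
    """
    if isinstance(scale, str):
        scale = load_scale(scale)
    L = sset.window_length
    raw = np.empty((len(sset), L - 1))
    for i, rec in enumerate(sset):
        s = rec.residues
        raw[i] = [scale.values[s[j : j + 2]] for j in range(L - 1)]
    smoothed = smooth_profile(raw, smoothing_window)
    return FeatureMatrix(
        values=smoothed,
        feature_names=[f"step{i + 1}" for i in range(L - 1)],
        encoding_tag=f"struct:{scale.id}:w{smoothing_window}",
        labels=_labels_of(sset),
    )


def encode(sset: SequenceSet, tag: str) -> FeatureMatrix:
    """Dispatch on an encoding tag.

    Tags: ``kmer:<k>``, ``NID``, ``DNID``, ``NID:onehot``, ``DNID:onehot``,
    ``struct:<Mx>[:w<odd>]``.
    """
    parts = tag.split(":")
    if parts[0] == "kmer" and len(parts) == 2:
        return encode_kmer(sset, int(parts[1]))
    if tag == "NID":
        return encode_nid(sset)
    if tag == "DNID":
        return encode_dnid(sset)
    if tag == "NID:onehot":
        return orthogonal_codify(encode_nid(sset))
    if tag == "DNID:onehot":
        return orthogonal_codify(encode_dnid(sset))
    if parts[0] == "struct" and len(parts) in (2, 3):
        w = DEFAULT_SMOOTHING
        if len(parts) == 3:
            if not parts[2].startswith("w"):
                raise ValueError(f"bad smoothing spec in tag {tag!r}")
            w = int(parts[2][1:])
        return encode_structure(sset, parts[1], smoothing_window=w)
    raise ValueError(f"unknown encoding tag {tag!r}")


def write_matrix_tsv(m: FeatureMatrix, path) -> None:
    """Serialize a FeatureMatrix as TSV with a one-line encoding_tag header."""
    with open(path, "w") as fh:
        fh.write(f"# encoding_tag: {m.encoding_tag}\n")
        header = "\t".join(m.feature_names)
        if m.labels is not None:
            header += "\tlabel"
        fh.write(header + "\n")
        for i in range(m.n):
            row = "\t".join(str(v) for v in m.values[i])
            if m.labels is not None:
                row += f"\t{m.labels[i]}"
            fh.write(row + "\n")
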