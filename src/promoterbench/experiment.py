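"""Config-driven experiment runner: datasets -> encodings -> models ->
evaluation -> rank comparison, with reproducible seeded stages."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import evaluation as E
from . import negatives as N
from . import synthetic as S
from .seqio import SequenceSet, read_fasta, write_fasta
from .stats_compare import average_ranks, cd_diagram_text, nemenyi

STRATEGIES = ("random", "coding", "convergent", "divergent", "copos", "coneg")
_CATEGORY_OF = {
    "convergent": "convergent",
    "divergent": "divergent",
    "copos": "codirectional_pos",
    "coneg": "codirectional_neg",
}


def make_negative_suite(
    n: int,
    window: int = 81,
    seed: int = 0,
    genome: Optional[N.GenomeAnnotation] = None,
    genome_length: int = 120_000,
    n_genes: int = 80,
    include_mixed: bool = True,
) -> dict[str, SequenceSet]:
    """All six negative strategies (plus 'mixed') from one synthetic genome.

    One seeded annotated genome supplies coding and the four intergenic
    categories; the random strategy uses its own long background sequence.
    """
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731
    genome_seed = sub()
    if genome is None:
        genome = S.make_synthetic_genome(
            length=genome_length, n_genes=n_genes, seed=genome_seed
        )
    sets = {
        "random": N.generate_random_negatives(n, window=window, seed=sub()),
        "coding": N.extract_coding_windows(genome, n, window=window, seed=sub()),
    }
    for strat in ("convergent", "divergent", "copos", "coneg"):
        sets[strat] = N.extract_intergenic_windows(
            genome, _CATEGORY_OF[strat], n, window=window, seed=sub()
        )
    if include_mixed:
        sets["mixed"] = N.build_mixed(
            [sets[s] for s in STRATEGIES], n_total=n, seed=sub()
        )
    return sets


@dataclass
class ExperimentConfig:
    name: str
    seed: int = 0
    window_length: int = 81
    data: dict = field(default_factory=dict)
    models: list = field(default_factory=list)
    evaluation: dict = field(default_factory=dict)
    output: str = "out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for spec in self.models:
            if spec.get("algorithm") not in (
                "nb", "rf", "svm_linear", "svm_rbf", "hmm",
            ):
                raise ValueError(f"unknown algorithm in model spec {spec!r}")
            enc = spec.get("encoding", "DNID")
            if spec["algorithm"] != "hmm":
                from .features import SCALE_IDS

                ok = (
                    enc in ("NID", "DNID", "NID:onehot", "DNID:onehot")
                    or (enc.startswith("kmer:") and enc[5:].isdigit())
                    or (
                        enc.startswith("struct:")
                        and enc.split(":")[1] in SCALE_IDS
                    )
                )
                if not ok:
                    raise ValueError(f"undefined encoder tag {enc!r}")
        mode = self.evaluation.get("mode", "cv")
        if mode not in ("cv", "grid", "holdout"):
            raise ValueError(f"unknown evaluation mode {mode!r}")
        syn = self.data.get("synthetic")
        fasta = self.data.get("positives_fasta")
        if not syn and not fasta:
            raise ValueError("data must give either 'synthetic' or 'positives_fasta'")

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _build_positives(cfg: ExperimentConfig, seed: int) -> SequenceSet:
    if "positives_fasta" in cfg.data:
        return read_fasta(cfg.data["positives_fasta"], label=1)
    syn = cfg.data["synthetic"]
    return S.make_synthetic_promoters(
        n=int(syn.get("n_positives", 500)),
        seed=seed,
        window=cfg.window_length,
    )


def run_experiment(cfg: ExperimentConfig, seed_override: Optional[int] = None) -> dict:
    """Execute a full configured run and write its artifact bundle.

    Stages: build datasets, train/evaluate each model spec (CV, holdout or
    full train/test grid), rank models when the design produces a
    datasets x classifiers table.  Writes tidy TSV results, a JSON summary
    and a manifest (config hash + seeds) into the output directory.
    """
    seed = cfg.seed if seed_override is None else seed_override
    t0 = time.time()
    outdir = Path(cfg.output) / cfg.name
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731

    pos = _build_positives(cfg, sub())
    syn = cfg.data.get("synthetic", {})
    n_neg = int(syn.get("n_negatives", len(pos)))
    strategies = cfg.data.get("strategies", ["random"])
    suite = make_negative_suite(
        n=n_neg,
        window=cfg.window_length,
        seed=sub(),
        include_mixed="mixed" in strategies,
    )
    negs = {s: suite[s] for s in strategies}

    mode = cfg.evaluation.get("mode", "cv")
    records = []
    tidy = None
    if mode == "cv":
        k = int(cfg.evaluation.get("k", 10))
        runs = int(cfg.evaluation.get("runs", 10))
        for spec in cfg.models:
            trainer = E.make_trainer(
                spec["algorithm"], spec.get("encoding", "DNID"), seed=sub()
            )
            for strat, neg in negs.items():
                rec = E.repeated_cv(trainer, pos, neg, k=k, runs=runs, seed=sub())
                records.append(
                    {
                        "model": rec.model_id,
                        "train": f"CV_{strat}",
                        "test": "CV",
                        "auc": rec.metrics["AUC"],
                    }
                )
    else:
        trainers = {}
        for spec in cfg.models:
            trainer = E.make_trainer(
                spec["algorithm"], spec.get("encoding", "DNID"), seed=sub()
            )
            name = spec.get("id") or f"{spec['algorithm']}_{spec.get('encoding', '')}"
            trainers[name] = trainer
        test_suite = make_negative_suite(
            n=n_neg,
            window=cfg.window_length,
            seed=sub(),
            include_mixed="mixed" in strategies,
        )
        test_pos = S.make_synthetic_promoters(
            n=len(pos), seed=sub(), window=cfg.window_length
        )
        train_sets = {s: (pos, negs[s]) for s in strategies}
        test_sets = {s: (test_pos, test_suite[s]) for s in strategies}
        tidy = E.train_test_grid(trainers, train_sets, test_sets)
        records = tidy.to_dict("records")

    import pandas as pd

    frame = pd.DataFrame(records)
    frame.to_csv(outdir / "results.tsv", sep="\t", index=False)

    summary: dict = {
        "name": cfg.name,
        "seed": seed,
        "config_digest": cfg.digest(),
        "n_positives": len(pos),
        "n_negatives_per_strategy": n_neg,
        "results": records,
        "elapsed_s": round(time.time() - t0, 2),
    }
    # rank comparison whenever >= 2 models share >= 2 evaluation columns
    pivot = frame.pivot_table(index="train", columns="model", values="auc")
    if pivot.shape[0] >= 2 and pivot.shape[1] >= 2 and not pivot.isna().any().any():
        rm = average_ranks(pivot)
        cmp_result = nemenyi(rm, warn_not_rejected=False)
        summary["comparison"] = {
            "friedman_statistic": cmp_result.friedman_statistic,
            "p_value": cmp_result.p_value,
            "critical_difference": cmp_result.critical_difference,
            "avg_ranks": dict(
                zip(cmp_result.classifiers, cmp_result.avg_ranks.tolist())
            ),
        }
        (outdir / "cd_diagram.txt").write_text(cd_diagram_text(cmp_result) + "\n")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(
            {"config": cfg.__dict__, "seed": seed, "digest": cfg.digest()},
            fh,
            indent=2,
            default=str,
        )
    for strat, sset in negs.items():
        write_fasta(sset, outdir / f"neg_{strat}.fasta")
    write_fasta(pos, outdir / "positives.fasta")
    return summary
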