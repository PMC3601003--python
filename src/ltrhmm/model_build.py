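"""Family-model construction: train/test split, noise regularisation, selection.

The protocol: each LTR family is split 80/20 into training and held-out
sequences; for every candidate pair of model length M and noise level z a
profile HMM is trained by Baum-Welch on the training split augmented with
noisy copies, and evaluated by the mean held-out log-odds score. The best
cell wins, with ties broken toward smaller M (longer models merely pad the
profile with quasi-random match states).

Noise injection regularises the model: each sequence contributes one copy
with every residue independently substituted (to a uniformly chosen
different residue) with probability z, alongside the untouched original.
The held-out split is never perturbed and never seen by EM.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .hmm_core import ProfileHMM, init_profile, mean_test_score, train_baum_welch
from .io_formats import SequenceRecord

_OTHER = {
    "A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG",
}


@dataclass
class TrainingConfig:
    """Controls for the family-model build.

    ``split_fraction`` is the training share of the 80/20 split; ``z_grid``
    are candidate noise levels in [0, 1]; ``M_grid`` candidate match-state
    counts. ``seed`` drives the split, the noise and the model init.
    """

    split_fraction: float = 0.8
    z_grid: tuple[float, ...] = (0.0, 0.05)
    M_grid: tuple[int, ...] = (150,)
    seed: int = 0
    max_iter: int = 40
    tol: float = 1e-3
    min_family_size: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if not self.M_grid:
            raise ValueError("M_grid must be non-empty")
        for z in self.z_grid:
            if not 0 <= z <= 1:
                raise ValueError("z must be in [0, 1]")


@dataclass
class GridCell:
    M: int
    z: float
    mean_test_score: float
    em_iterations: int
    converged: bool
    failed: bool = False


@dataclass
class ModelSelectionReport:
    """Per-(M, z) held-out scores and the chosen grid cell."""

    cells: list[GridCell]
    chosen_M: int
    chosen_z: float
    n_train: int
    n_test: int
    seed: int
    train_hash: str = ""
    test_hash: str = ""

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "cells": [asdict(c) for c in self.cells],
                "chosen_M": self.chosen_M,
                "chosen_z": self.chosen_z,
                "n_train": self.n_train,
                "n_test": self.n_test,
                "seed": self.seed,
                "train_hash": self.train_hash,
                "test_hash": self.test_hash,
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("M\tz\tmean_test_score\tem_iterations\tconverged\tfailed\n")
            for c in self.cells:
                fh.write(
                    f"{c.M}\t{c.z:g}\t{c.mean_test_score:.4f}\t"
                    f"{c.em_iterations}\t{c.converged}\t{c.failed}\n"
                )


def _seq_set_hash(seqs: Sequence[SequenceRecord]) -> str:
    h = hashlib.sha256()
    for s in sorted(seqs, key=lambda r: r.id):
        h.update(s.id.encode())
        h.update(s.residues.encode())
    return h.hexdigest()


def split_train_test(
    seqs: Sequence[SequenceRecord], split_fraction: float = 0.8, seed: int = 0
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Random disjoint, exhaustive train/test partition.

    ``|train| = round(split_fraction * n)``, clamped so both parts are
    non-empty. Requires at least 5 sequences; below that the split
    degenerates.
    """
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must be in (0, 1)")
    n = len(seqs)
    if n < 5:
        raise ValueError(f"need at least 5 sequences to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(split_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    train = [seqs[i] for i in order[:n_train]]
    test = [seqs[i] for i in order[n_train:]]
    return train, test


def inject_noise(
    seqs: Sequence[SequenceRecord], z: float, seed: int = 0
) -> list[SequenceRecord]:
    """Augment a sequence set with per-sequence noisy copies.

    Every residue of the copy is independently substituted with probability
    z to a uniformly chosen *different* residue (N stays N). The originals
    are retained, so the result has twice the input size. z=0 yields copies
    identical to the originals; z=1 changes every ACGT residue.
    """
    if not 0 <= z <= 1:
        raise ValueError("z must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = list(seqs)
    for s in seqs:
        residues = list(s.residues)
        if z > 0:
            hit = rng.random(len(residues)) < z
            for i in np.nonzero(hit)[0]:
                c = residues[i]
                if c in _OTHER:
                    residues[i] = _OTHER[c][rng.integers(3)]
        out.append(SequenceRecord(f"{s.id}|noisy", "".join(residues), s.description))
    return out


def train_with_noise(
    seqs: Sequence[SequenceRecord],
    M: int,
    z: float,
    seed: int,
    max_iter: int = 40,
    tol: float = 1e-3,
    model_id: str = "profile",
) -> tuple[ProfileHMM, list[float]]:
    """Train a single profile of length M on a noise-augmented set."""
    augmented = inject_noise(seqs, z, seed=seed)
    model = init_profile(M, seed=seed, model_id=model_id)
    trained, trace = train_baum_welch(model, augmented, max_iter=max_iter, tol=tol, seed=seed)
    trained.metadata.update({"z": z, "n_train": len(seqs)})
    return trained, trace


def build_family_model(
    seqs: Sequence[SequenceRecord], config: TrainingConfig
) -> tuple[ProfileHMM, ModelSelectionReport]:
    """Grid-search (M, z) and return the best held-out-scoring model.

    Each candidate is trained on the noise-augmented training split and
    scored by :func:`ltrhmm.hmm_core.mean_test_score` on the untouched test
    split. Cells whose EM produces a non-finite score are marked failed and
    excluded; ties go to smaller M, then smaller z.
    """
    if len(seqs) < config.min_family_size:
        raise ValueError(
            f"family has {len(seqs)} sequences; minimum is {config.min_family_size}"
        )
    train, test = split_train_test(seqs, config.split_fraction, config.seed)
    train_hash, test_hash = _seq_set_hash(train), _seq_set_hash(test)

    cells: list[GridCell] = []
    best: tuple[float, int, float] | None = None  # (-score, M, z) minimised
    best_model: ProfileHMM | None = None
    for M in config.M_grid:
        for z in config.z_grid:
            try:
                model, trace = train_with_noise(
                    train, M, z, seed=config.seed,
                    max_iter=config.max_iter, tol=config.tol,
                )
                score = mean_test_score(model, test)
                failed = not math.isfinite(score)
            except Exception:
                score, failed, model, trace = float("nan"), True, None, []
            converged = (
                not failed
                and len(trace) >= 2
                and len(trace) < config.max_iter
            )
            cells.append(GridCell(M, z, score, len(trace), converged, failed))
            if not failed:
                key = (-score, M, z)
                if best is None or key < best:
                    best, best_model = key, model
    if best_model is None:
        raise RuntimeError("every (M, z) grid cell failed to train")
    assert _seq_set_hash(test) == test_hash, "test split was mutated"
    assert _seq_set_hash(train) == train_hash, "train split was mutated"
    chosen_M, chosen_z = best[1], best[2]
    best_model.metadata.update({"chosen_M": chosen_M, "chosen_z": chosen_z,
                               "seed": config.seed})
    report = ModelSelectionReport(
        cells=cells,
        chosen_M=chosen_M,
        chosen_z=chosen_z,
        n_train=len(train),
        n_test=len(test),
        seed=config.seed,
        train_hash=train_hash,
        test_hash=test_hash,
    )
    return best_model, report
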