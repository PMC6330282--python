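"""Subject-level k-fold splits.

Calibration (segmentation AC) and training (CNN AC) must never be performed
on the subject they are later applied to; both therefore share this split
machinery.  All examinations of a subject are assigned to the same fold.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np

__all__ = ["FoldSplit", "kfold_split"]


@dataclass(frozen=True)
class FoldSplit:
    """Mapping subject_id -> fold index, for k folds."""

    assignment: Dict[str, int]
    k: int

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("need at least 2 folds")
        bad = {s: f for s, f in self.assignment.items() if not 0 <= f < self.k}
        if bad:
            raise ValueError(f"fold indices out of range: {bad}")

    def fold_of(self, subject_id: str) -> int:
        return self.assignment[subject_id]

    def train_subjects(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignment.items() if f != fold)

    def test_subjects(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignment.items() if f == fold)


def kfold_split(cases: Sequence, k: int, seed: int) -> FoldSplit:
    """Shuffle subjects by seed and assign them round-robin to k folds.

    ``cases`` may be PhantomCase objects or bare subject-id strings; repeat
    exams collapse onto their subject, keeping every exam of a subject in
    one fold.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    subjects = sorted({getattr(c, "subject_id", c) for c in cases})
    if len(subjects) < k:
        raise ValueError(f"{len(subjects)} subjects cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    return FoldSplit({s: i % k for i, s in enumerate(order)}, k)
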