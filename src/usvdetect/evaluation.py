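"""Gold-standard construction, interval matching, and error-rate formulas.

Automatic detections are scored against manual annotations.  Because manual
segmentation is itself imperfect, the reference ("gold standard") keeps
only the elements found by *every* independent manual annotation of the
same recording.  Detections and references are then paired one-to-one by
temporal overlap, and three percentages summarize the outcome:

    correct         = 100 * Ncorr / Nauto
    false positives = 100 * (Nauto - Ncorr) / Nauto
    false negatives = 100 * (Nref - Ncorr) / Nref

where Nref is the reference count, Nauto the automatic count, and Ncorr the
number of matched pairs.  Correct and false-positive percentages always sum
to 100 when Nauto > 0.

Two optional filters mirror the standard validation workflow: reference
elements shorter than a duration floor can be excluded (detectors with a
minimum-duration setting cannot find them), and whole files with fewer than
a minimum number of reference elements can be skipped, since percentage
error rates on very few calls are unstable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IntervalSet",
    "ErrorRates",
    "build_gold_standard",
    "match_elements",
    "compute_error_rates",
    "evaluate_file",
]


@dataclass(frozen=True)
class IntervalSet:
    """A sorted, pairwise-disjoint list of (start_s, end_s) intervals."""

    intervals: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=np.float64).reshape(-1, 2)
        if arr.size:
            arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
            if not np.all(arr[:, 0] < arr[:, 1]):
                raise ValueError("every interval must satisfy start < end")
            if np.any(arr[1:, 0] < arr[:-1, 1]):
                raise ValueError("intervals must be pairwise disjoint")
        object.__setattr__(self, "intervals", arr)

    def __len__(self) -> int:
        return int(self.intervals.shape[0])

    def durations_s(self) -> np.ndarray:
        if len(self) == 0:
            return np.empty(0)
        return self.intervals[:, 1] - self.intervals[:, 0]

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[float, float]], source_label: str = ""
    ) -> "IntervalSet":
        return cls(intervals=np.asarray(list(pairs), dtype=np.float64).reshape(-1, 2),
                   source_label=source_label)

    @classmethod
    def from_elements(cls, elements: Sequence, source_label: str = "auto") -> "IntervalSet":
        """Build an interval set from detected elements (begin_s/length_s)."""
        pairs = [(e.begin_s, e.begin_s + e.length_s) for e in elements]
        return cls.from_pairs(pairs, source_label=source_label)

    @classmethod
    def from_csv(cls, path: str | Path, source_label: str | None = None) -> "IntervalSet":
        """Read a ``start_s,end_s,label`` CSV (one interval per row)."""
        path = Path(path)
        df = pd.read_csv(path)
        for col in ("start_s", "end_s"):
            if col not in df.columns:
                raise ValueError(f"{path}: annotation CSV must have a '{col}' column")
        return cls(
            intervals=df[["start_s", "end_s"]].to_numpy(dtype=np.float64),
            source_label=source_label if source_label is not None else path.stem,
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.intervals, columns=["start_s", "end_s"])
        df["label"] = self.source_label
        df.to_csv(path, index=False, float_format="%.6g")


@dataclass(frozen=True)
class ErrorRates:
    """Counts and the three percentage error rates for one file."""

    n_ref: int
    n_auto: int
    n_corr: int
    correct_pct: float
    false_positive_pct: float
    false_negative_pct: float


def _overlap(a: np.ndarray, b: np.ndarray) -> float:
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


def _has_match(interval: np.ndarray, others: IntervalSet, min_overlap_frac: float) -> bool:
    for other in others.intervals:
        ovl = _overlap(interval, other)
        if ovl <= 0.0:
            continue
        shorter = min(interval[1] - interval[0], other[1] - other[0])
        if ovl >= min_overlap_frac * shorter:
            return True
    return False


def build_gold_standard(
    annotation_sets: Sequence[IntervalSet],
    min_dur_ms: float | None = None,
    min_overlap_frac: float = 0.0,
) -> IntervalSet:
    """Intersect independent annotation sets into a consensus reference.

    An element of the first set is retained iff it temporally matches (any
    positive overlap by default; optionally a fraction of the shorter
    interval) at least one element of every other set.  Retained intervals
    keep the first set's boundaries.  If ``min_dur_ms`` is given, shorter
    reference elements are then dropped (strictly shorter; elements equal
    to the floor are kept).
    """
    if len(annotation_sets) == 0:
        raise ValueError("at least one annotation set is required")
    base = annotation_sets[0]
    kept = [
        iv
        for iv in base.intervals
        if all(_has_match(iv, other, min_overlap_frac) for other in annotation_sets[1:])
    ]
    if min_dur_ms is not None:
        floor_s = min_dur_ms / 1000.0
        kept = [iv for iv in kept if iv[1] - iv[0] >= floor_s]
    arr = np.asarray(kept, dtype=np.float64).reshape(-1, 2)
    return IntervalSet(intervals=arr, source_label="gold")


def match_elements(
    auto: IntervalSet,
    ref: IntervalSet,
    min_overlap_frac: float = 0.0,
) -> tuple[int, list[tuple[int, int]]]:
    """Pair automatic and reference intervals one-to-one by temporal overlap.

    Candidate pairs are all (auto, ref) pairs with positive overlap (and,
    if ``min_overlap_frac`` > 0, overlap at least that fraction of the
    shorter interval).  Pairs are assigned greedily by decreasing overlap,
    ties broken by earliest auto start then earliest ref start; each
    interval participates in at most one pair.  Returns the pair count
    (Ncorr) and the (auto_index, ref_index) pairing.
    """
    candidates: list[tuple[float, float, float, int, int]] = []
    for i, a in enumerate(auto.intervals):
        for j, r in enumerate(ref.intervals):
            ovl = _overlap(a, r)
            if ovl <= 0.0:
                continue
            shorter = min(a[1] - a[0], r[1] - r[0])
            if ovl < min_overlap_frac * shorter:
                continue
            candidates.append((-ovl, a[0], r[0], i, j))
    candidates.sort()
    used_auto: set[int] = set()
    used_ref: set[int] = set()
    pairing: list[tuple[int, int]] = []
    for _, _, _, i, j in candidates:
        if i in used_auto or j in used_ref:
            continue
        used_auto.add(i)
        used_ref.add(j)
        pairing.append((i, j))
    pairing.sort()
    return len(pairing), pairing


def compute_error_rates(n_ref: int, n_auto: int, n_corr: int) -> ErrorRates:
    """Apply the three error-rate formulas verbatim.

    With ``n_auto == 0`` the correct and false-positive percentages are
    undefined and reported as NaN; the false-negative rate is then 100 when
    references exist (every reference was missed) and NaN if there are
    none.
    """
    if n_corr > min(n_ref, n_auto):
        raise ValueError(
            f"n_corr={n_corr} cannot exceed min(n_ref={n_ref}, n_auto={n_auto})"
        )
    if min(n_ref, n_auto, n_corr) < 0:
        raise ValueError("counts must be non-negative")
    correct = 100.0 * n_corr / n_auto if n_auto > 0 else math.nan
    false_pos = 100.0 * (n_auto - n_corr) / n_auto if n_auto > 0 else math.nan
    false_neg = 100.0 * (n_ref - n_corr) / n_ref if n_ref > 0 else math.nan
    return ErrorRates(
        n_ref=int(n_ref),
        n_auto=int(n_auto),
        n_corr=int(n_corr),
        correct_pct=correct,
        false_positive_pct=false_pos,
        false_negative_pct=false_neg,
    )


def evaluate_file(
    auto: IntervalSet,
    annotation_sets: Sequence[IntervalSet],
    min_dur_ms: float | None = None,
    min_ref_count: int | None = None,
    min_overlap_frac: float = 0.0,
) -> ErrorRates | None:
    """Score one file's automatic detections against its manual annotations.

    Builds the gold standard (with the optional duration floor), skips the
    file -- returning ``None`` -- when the reference holds fewer than
    ``min_ref_count`` elements, and otherwise matches and computes the
    error rates.
    """
    gold = build_gold_standard(annotation_sets, min_dur_ms=min_dur_ms,
                               min_overlap_frac=min_overlap_frac)
    if min_ref_count is not None and len(gold) < min_ref_count:
        return None
    n_corr, _ = match_elements(auto, gold, min_overlap_frac=min_overlap_frac)
    return compute_error_rates(n_ref=len(gold), n_auto=len(auto), n_corr=n_corr)
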