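"""Detectability flooring, log2 fold changes, and the regulation filter.

The analysis gene set is defined operationally: after clamping intensities
at the array's empirical detectability floor, a transcript is retained when
it shows a two-fold-or-greater change (in either direction) versus the
untreated control at a minimum number of treatment stages.  No variance- or
test-based differential-expression screening is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "FoldChangeMatrix",
    "FilterRule",
    "apply_floor",
    "fold_change",
    "regulation_filter",
]

#: Intensity below which the platform does not reliably discriminate signal.
DEFAULT_FLOOR = 200.0


@dataclass(frozen=True)
class FoldChangeMatrix:
    """Transcript x stage matrix of log2 ratios versus the control column."""

    transcript_ids: tuple[str, ...]
    stage_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "transcript_ids", tuple(self.transcript_ids))
        object.__setattr__(self, "stage_labels", tuple(self.stage_labels))
        if vals.shape != (len(self.transcript_ids), len(self.stage_labels)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"{len(self.transcript_ids)} transcripts x {len(self.stage_labels)} stages"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("fold changes must be finite")

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    @property
    def n_stages(self) -> int:
        return len(self.stage_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.transcript_ids, name="transcript_id"),
            columns=list(self.stage_labels),
        )

    def subset(self, keep: np.ndarray) -> "FoldChangeMatrix":
        """Row subset by boolean mask or integer positions, order preserved."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return FoldChangeMatrix(
            transcript_ids=tuple(self.transcript_ids[i] for i in keep),
            stage_labels=self.stage_labels,
            values=self.values[keep],
        )


@dataclass(frozen=True)
class FilterRule:
    """Regulation-filter parameters.

    min_fold
        Linear fold-change threshold; a stage qualifies when
        ``|log2FC| >= log2(min_fold)`` (inclusive, either direction).
    min_stages
        Minimum number of qualifying treatment stages for a transcript
        to be retained.
    floor
        Detectability floor in linear intensity units, applied to control
        and treatment columns alike before ratios are formed.
    """

    min_fold: float = 2.0
    min_stages: int = 4
    floor: float = DEFAULT_FLOOR

    def __post_init__(self) -> None:
        if not self.min_fold > 1:
            raise ValueError(f"min_fold must be > 1, got {self.min_fold}")
        if self.min_stages < 1:
            raise ValueError(f"min_stages must be >= 1, got {self.min_stages}")
        if not self.floor > 0:
            raise ValueError(f"floor must be > 0, got {self.floor}")

    @property
    def log2_threshold(self) -> float:
        return float(np.log2(self.min_fold))


def apply_floor(matrix: ExpressionMatrix, floor: float = DEFAULT_FLOOR) -> ExpressionMatrix:
    """Clamp every intensity strictly below ``floor`` up to ``floor``.

    Values below the floor are technically undetectable, so they are
    replaced by the floor itself rather than dropped; ratios between two
    sub-floor values then become exactly zero on the log scale.  Applying
    the floor twice is an error (a silent no-op would mask misuse).
    """
    if matrix.floored:
        raise ValueError("matrix is already floored; apply_floor must run exactly once")
    if not floor > 0:
        raise ValueError(f"floor must be > 0, got {floor}")
    return replace(matrix, values=np.maximum(matrix.values, floor), floored=True)


def fold_change(matrix: ExpressionMatrix) -> FoldChangeMatrix:
    """log2(stage / control) per transcript and treatment stage.

    Requires a floored matrix so every ratio is finite and positive.
    """
    if not matrix.floored:
        raise ValueError("apply_floor must be called before fold_change")
    ctrl = matrix.values[:, matrix.control_index]
    stage_cols = [i for i, c in enumerate(matrix.condition_labels) if i != matrix.control_index]
    fc = np.log2(matrix.values[:, stage_cols] / ctrl[:, None])
    return FoldChangeMatrix(
        transcript_ids=matrix.transcript_ids,
        stage_labels=tuple(matrix.condition_labels[i] for i in stage_cols),
        values=fc,
    )


def regulation_filter(
    fc: FoldChangeMatrix, rule: FilterRule = FilterRule()
) -> tuple[FoldChangeMatrix, pd.DataFrame]:
    """Keep transcripts regulated >= ``rule.min_fold``-fold at >= ``rule.min_stages`` stages.

    Returns the kept row-subset (input order preserved) and a per-transcript
    report with columns ``transcript_id, qualifying_stages, kept``.
    """
    if rule.min_stages > fc.n_stages:
        raise ValueError(
            f"min_stages={rule.min_stages} exceeds the {fc.n_stages} available stages"
        )
    qualifying = (np.abs(fc.values) >= rule.log2_threshold).sum(axis=1)
    kept = qualifying >= rule.min_stages
    report = pd.DataFrame(
        {
            "transcript_id": list(fc.transcript_ids),
            "qualifying_stages": qualifying.astype(int),
            "kept": kept,
        }
    )
    return fc.subset(kept), report
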