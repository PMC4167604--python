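"""Tabular I/O: expression tables, GMT gene sets, and the result bundle.

All on-disk formats are plain tab-separated text so that runs are easy to
inspect and diff.  The expression table carries linear-scale intensities,
one row per transcript, one column per condition, with exactly one column
designated as the untreated control.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("edisom")

__all__ = [
    "ExpressionMatrix",
    "AnnotationSet",
    "ResultBundle",
    "read_expression_table",
    "write_expression_table",
    "read_gene_sets",
    "write_gene_sets",
    "read_clustered_matrix",
    "write_results",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Transcript x condition matrix of linear-scale expression intensities.

    Parameters
    ----------
    transcript_ids
        Ordered, unique transcript/probe identifiers (rows).
    condition_labels
        Ordered condition labels (columns); ``control_label`` must occur
        exactly once among them.
    control_label
        The label of the untreated-control column.
    values
        ``(n_transcripts, n_conditions)`` float array, linear scale.
    floored
        Whether the detectability floor has already been applied.  Once
        floored, all values are finite and strictly positive.
    """

    transcript_ids: tuple[str, ...]
    condition_labels: tuple[str, ...]
    control_label: str
    values: np.ndarray
    floored: bool = False

    def __post_init__(self) -> None:
        ids = tuple(str(t) for t in self.transcript_ids)
        labels = tuple(str(c) for c in self.condition_labels)
        object.__setattr__(self, "transcript_ids", ids)
        object.__setattr__(self, "condition_labels", labels)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(t for t in ids if t in seen or seen.add(t))
            raise ValueError(f"duplicate transcript ID: {dup!r}")
        if labels.count(self.control_label) != 1:
            raise ValueError(
                f"control label {self.control_label!r} must occur exactly once "
                f"among conditions {list(labels)}"
            )
        if vals.shape != (len(ids), len(labels)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"{len(ids)} transcripts x {len(labels)} conditions"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("expression values must be finite (missing values are not permitted)")
        if self.floored and not np.all(vals > 0):
            raise ValueError("floored matrix must be strictly positive")

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_labels)

    @property
    def control_index(self) -> int:
        return self.condition_labels.index(self.control_label)

    @property
    def stage_labels(self) -> tuple[str, ...]:
        """Condition labels with the control removed, order preserved."""
        return tuple(c for c in self.condition_labels if c != self.control_label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.transcript_ids, name="transcript_id"),
            columns=list(self.condition_labels),
        )


@dataclass(frozen=True)
class AnnotationSet:
    """A flat ontology namespace: term ID -> (description, member gene set).

    Terms are kept in file order; ontology graph structure is deliberately
    not modelled (terms are consumed as plain gene sets).
    """

    namespace: str
    terms: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for tid, (_, members) in self.terms.items():
            if not members:
                raise ValueError(f"term {tid!r} has an empty member set")

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def members(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]


def read_expression_table(
    path: str | Path,
    control_label: str,
    *,
    log2_input: bool = False,
) -> ExpressionMatrix:
    """Read a tab-separated expression table.

    Layout: header row, first column transcript IDs, remaining columns
    one condition each.  By default values are linear-scale intensities;
    pass ``log2_input=True`` for a table stored on the log2 scale, which
    is exponentiated on read so the detectability floor (declared in
    linear intensity units) applies uniformly.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    dup_mask = raw.index.duplicated()
    if dup_mask.any():
        raise ValueError(
            f"duplicate transcript ID: {raw.index[dup_mask][0]!r} in {path.name}"
        )
    if control_label not in raw.columns:
        raise ValueError(
            f"control label {control_label!r} not found among columns "
            f"{list(raw.columns)} in {path.name}"
        )
    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-numeric cell at transcript {raw.index[i]!r}, "
            f"column {raw.columns[j]!r}: {raw.iat[i, j]!r}"
        )
    values = numeric.to_numpy(dtype=float)
    if log2_input:
        values = np.exp2(values)
    return ExpressionMatrix(
        transcript_ids=tuple(raw.index),
        condition_labels=tuple(raw.columns),
        control_label=control_label,
        values=values,
        floored=False,
    )


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> Path:
    """Write an expression table (full float precision, round-trip safe)."""
    path = Path(path)
    frame = matrix.to_frame()
    frame.to_csv(path, sep="\t", float_format=None)
    return path


def read_gene_sets(path: str | Path, namespace: str) -> AnnotationSet:
    """Parse a GMT file: one term per line as ``ID<TAB>description<TAB>gene...``.

    Duplicate member genes within one term are de-duplicated; lines with
    fewer than three fields are skipped with a logged warning; a file that
    yields no terms at all is an error.
    """
    path = Path(path)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning(
                    "%s:%d: skipping GMT line with %d field(s) (need >= 3)",
                    path.name, lineno, len(fields),
                )
                continue
            term_id, description = fields[0], fields[1]
            members = frozenset(g for g in fields[2:] if g)
            if term_id in terms:
                raise ValueError(f"duplicate term ID {term_id!r} in {path.name}")
            terms[term_id] = (description, members)
    if not terms:
        raise ValueError(f"no gene-set terms parsed from {path.name}")
    return AnnotationSet(namespace=namespace, terms=terms)


def write_gene_sets(ann: AnnotationSet, path: str | Path) -> Path:
    """Serialize an AnnotationSet back to GMT (members sorted for stability)."""
    path = Path(path)
    with open(path, "w") as handle:
        for term_id, (description, members) in ann.terms.items():
            handle.write("\t".join([term_id, description, *sorted(members)]) + "\n")
    return path


def read_clustered_matrix(
    path: str | Path, cluster_column: str = "cluster"
) -> tuple[pd.DataFrame, pd.Series]:
    """Read a transcript x stage table that carries a cluster-label column.

    This is the layout of a deposited "regulated transcripts + SOM cluster"
    supplementary table: transcript IDs in the first column, one numeric
    column per treatment stage, plus an integer cluster assignment.
    Returns ``(stage_matrix, cluster_labels)``.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if cluster_column not in frame.columns:
        raise ValueError(f"cluster column {cluster_column!r} not found in {Path(path).name}")
    clusters = frame[cluster_column].astype(int)
    stages = frame.drop(columns=[cluster_column]).astype(float)
    return stages, clusters


@dataclass
class ResultBundle:
    """Everything one pipeline run produces, ready to be written out.

    ``planes`` maps a stage label to a ``unit, q, r, value`` frame.
    """

    cluster_table: pd.DataFrame | None = None
    seed_profiles: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    planes: dict[str, pd.DataFrame] = field(default_factory=dict)
    filter_report: pd.DataFrame | None = None


_REQUIRED_ARTIFACTS = ("cluster_table", "seed_profiles", "enrichment", "planes")


def write_results(bundle: ResultBundle, out_dir: str | Path) -> dict[str, str]:
    """Write every artifact of a run as TSV; return ``{filename: sha256}``.

    Writing is deterministic: row order is whatever the bundle frames carry
    (the pipeline sorts them stably), and floats are rendered with repr
    precision, so re-running on an identical bundle is byte-identical.
    """
    for name in _REQUIRED_ARTIFACTS:
        value = getattr(bundle, name)
        if value is None or (name == "planes" and not value):
            raise ValueError(f"result bundle is missing artifact: {name}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def _write(frame: pd.DataFrame, filename: str) -> None:
        target = out_dir / filename
        frame.to_csv(target, sep="\t", index=False)
        manifest[filename] = hashlib.sha256(target.read_bytes()).hexdigest()

    _write(bundle.cluster_table, "cluster_table.tsv")
    _write(bundle.seed_profiles, "seed_profiles.tsv")
    _write(bundle.enrichment, "enrichment.tsv")
    for stage in sorted(bundle.planes):
        _write(bundle.planes[stage], f"plane_{stage}.tsv")
    if bundle.filter_report is not None:
        _write(bundle.filter_report, "filter_report.tsv")
    return manifest
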