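"""Input/output: expression matrices, Cq tables, labels, results.

All tabular formats are plain TSV/CSV. Matrices are probes x samples with a
header row of sample ids and the probe id in the first column; "NA", "NaN",
"null" and empty cells are missing. Parsing is strict: ragged rows, duplicate
ids and non-numeric cells fail with the offending line number rather than
being coerced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError

__all__ = [
    "ExpressionMatrix",
    "CqTable",
    "GroundTruthLabels",
    "read_expression",
    "read_cq_table",
    "normalize_cq",
    "read_labels",
    "write_labels",
    "write_results",
    "read_results",
    "write_contributions",
]

_NA_STRINGS = {"", "na", "nan", "null", "n/a"}

ACTIVE = "active"
INACTIVE = "inactive"


@dataclass(frozen=True)
class ExpressionMatrix:
    """Continuous expression on a log2-like scale, probes x samples.

    platform_tag is "intensity" for microarray-style log2 intensities or
    "cq-normalized" for dCq-derived relative expression. Missing values are
    NaN. dropped_samples records samples excluded during dCq normalization
    (no valid reference gene).
    """

    values: pd.DataFrame
    platform_tag: str = "intensity"
    dropped_samples: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dupes = sorted(df.index[df.index.duplicated()].unique())
            raise ParseError(f"duplicate probe ids: {dupes}")
        if df.columns.has_duplicates:
            dupes = sorted(df.columns[df.columns.duplicated()].unique())
            raise ParseError(f"duplicate sample ids: {dupes}")
        vals = df.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ParseError("expression values must be finite or missing")

    @property
    def probes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample(self, sample_id: str) -> pd.Series:
        """One sample column (probe id -> value)."""
        return self.values[sample_id]


@dataclass(frozen=True)
class CqTable:
    """Raw qPCR quantification cycles, assays x samples.

    Lower Cq means more transcript. Values above cq_max (or missing) are the
    no-amplification convention; reference_gene_ids name the rows used for
    dCq normalization.
    """

    values: pd.DataFrame
    reference_gene_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "reference_gene_ids", tuple(self.reference_gene_ids)
        )
        if self.values.index.has_duplicates:
            raise ParseError("duplicate assay ids in Cq table")
        vals = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if (vals <= 0).any():
                raise ParseError("Cq values must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class GroundTruthLabels:
    """sample_id -> {"active", "inactive"} ground-truth pathway status."""

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        canon = {}
        for sid, lab in dict(self.labels).items():
            lab_c = str(lab).strip().lower()
            if lab_c not in (ACTIVE, INACTIVE):
                raise ParseError(
                    f"sample {sid!r}: label must be active/inactive, "
                    f"got {lab!r}"
                )
            canon[str(sid)] = lab_c
        object.__setattr__(self, "labels", canon)

    def __getitem__(self, sample_id: str) -> str:
        return self.labels[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.labels

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels)

    def samples_with(self, label: str) -> list[str]:
        return [s for s, l in self.labels.items() if l == label]


def _split_line(line: str, sep: str) -> list[str]:
    return line.rstrip("\r\n").split(sep)


def _infer_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def _parse_matrix(path: Path, sep: str) -> pd.DataFrame:
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = _split_line(lines[0], sep)
    if len(header) < 2:
        raise ParseError(f"{path}: line 1: header needs >=1 sample column")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{path}: line 1: duplicate sample ids")
    n_cols = len(header)
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = _split_line(line, sep)
        if len(fields) != n_cols:
            raise ParseError(
                f"{path}: line {lineno}: expected {n_cols} fields, "
                f"got {len(fields)}"
            )
        pid = fields[0]
        if pid in seen:
            raise ParseError(f"{path}: line {lineno}: duplicate probe {pid!r}")
        seen.add(pid)
        row = []
        for j, cell in enumerate(fields[1:], start=2):
            if cell.strip().lower() in _NA_STRINGS:
                row.append(np.nan)
                continue
            try:
                row.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}, column {j}: non-numeric "
                    f"cell {cell!r}"
                ) from None
        probe_ids.append(pid)
        rows.append(row)
    return pd.DataFrame(rows, index=probe_ids, columns=sample_ids, dtype=float)


def read_expression(
    path: str | Path, sep: str | None = None, platform_tag: str = "intensity"
) -> ExpressionMatrix:
    """Read a probes x samples TSV/CSV into an ExpressionMatrix.

    The delimiter is taken from the extension (.csv -> comma, otherwise tab)
    unless given explicitly.
    """
    path = Path(path)
    df = _parse_matrix(path, _infer_sep(path, sep))
    return ExpressionMatrix(values=df, platform_tag=platform_tag)


def read_cq_table(
    path: str | Path,
    reference_gene_ids: Sequence[str],
    sep: str | None = None,
) -> CqTable:
    """Read an assays x samples Cq TSV/CSV."""
    path = Path(path)
    df = _parse_matrix(path, _infer_sep(path, sep))
    return CqTable(values=df, reference_gene_ids=tuple(reference_gene_ids))


def normalize_cq(
    cq: CqTable,
    reference_gene_ids: Sequence[str] | None = None,
    cq_max: float = 40.0,
) -> ExpressionMatrix:
    """dCq normalization: expr(gene) = mean(reference Cq) - Cq(gene).

    Higher values mean more transcript, matching the intensity-scale
    orientation, so a single calibration code path serves both platforms.
    Cq above cq_max or missing becomes a missing expression value. Samples
    without any valid reference-gene Cq are dropped and recorded in
    ``dropped_samples``. Adding a constant to every Cq of a sample (a global
    efficiency shift) leaves the normalized values unchanged.
    """
    refs = tuple(
        reference_gene_ids
        if reference_gene_ids is not None
        else cq.reference_gene_ids
    )
    if not refs:
        raise ParseError("no reference genes given for Cq normalization")
    missing_refs = [r for r in refs if r not in cq.values.index]
    if missing_refs:
        raise ParseError(f"reference genes absent from Cq table: {missing_refs}")
    censored = cq.values.where(cq.values <= cq_max)
    ref_mean = censored.loc[list(refs)].mean(axis=0, skipna=True)
    keep = ref_mean.notna()
    dropped = tuple(s for s in cq.values.columns if not keep[s])
    targets = censored.drop(index=list(refs))
    expr = ref_mean[keep.index[keep]] - targets.loc[:, keep.index[keep]]
    return ExpressionMatrix(
        values=expr, platform_tag="cq-normalized", dropped_samples=dropped
    )


def read_labels(path: str | Path) -> GroundTruthLabels:
    """Read a two-column TSV (sample_id, label) with header.

    Labels are case-insensitive "active"/"inactive"; anything else is a
    parse error.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty labels file")
    labels: dict[str, str] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = _split_line(line, "\t")
        if len(fields) != 2:
            raise ParseError(
                f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
            )
        sid, lab = fields
        if sid in labels:
            raise ParseError(f"{path}: line {lineno}: duplicate sample {sid!r}")
        lab_c = lab.strip().lower()
        if lab_c not in (ACTIVE, INACTIVE):
            raise ParseError(
                f"{path}: line {lineno}: unknown label {lab!r} "
                "(expected active/inactive)"
            )
        labels[sid] = lab_c
    return GroundTruthLabels(labels)


def write_labels(labels: GroundTruthLabels, path: str | Path) -> None:
    lines = ["sample_id\tlabel"]
    lines += [f"{s}\t{l}" for s, l in labels.labels.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def write_results(results: Iterable, path: str | Path) -> None:
    """Write PathwayActivityResult records as a results TSV (6 decimals)."""
    lines = ["sample_id\tpathway\tlog2_odds\tscore\tn_missing_genes"]
    for r in results:
        lines.append(
            f"{r.sample_id}\t{r.pathway}\t{r.log2_odds:.6f}\t"
            f"{r.score:.6f}\t{r.n_missing_genes}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "pathway": str})
    expected = {"sample_id", "pathway", "log2_odds", "score", "n_missing_genes"}
    missing = expected - set(df.columns)
    if missing:
        raise ParseError(f"results file missing columns: {sorted(missing)}")
    return df


def write_contributions(results: Iterable, path: str | Path) -> None:
    """Optional long-format per-gene evidence contribution TSV."""
    lines = ["sample_id\tpathway\tgene\tlog2_lr"]
    for r in results:
        for gene, lr in r.contributions.items():
            lines.append(f"{r.sample_id}\t{r.pathway}\t{gene}\t{lr:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
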