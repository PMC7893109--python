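"""Healthy-tissue reference ranges and patient reports.

An activity score only becomes clinically interpretable against the score
distribution of the matching healthy tissue. The upper bound of normal is
the 95th percentile of the healthy-tissue scores (percentile by linear
interpolation between order statistics, the rank-h = 1 + (n-1)q/100 rule);
a sample scoring strictly above it is called potentially tumor driving and
targetable. Only the upper tail is thresholded: loss of activity of
tumor-suppressive pathways is pathway-dependent and reported descriptively,
not called.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ModelFormatError
from .inference import PathwayActivityResult

__all__ = [
    "ReferenceDistribution",
    "PathwayCall",
    "PatientReport",
    "build_reference",
    "classify",
    "build_report",
    "REPORT_FORMAT",
]

REPORT_FORMAT = "pathsig-report/1"

WITHIN_NORMAL = "within-normal"
ABOVE_THRESHOLD = "above-threshold"
TUMOR_DRIVING_NOTE = "potentially tumor driving and targetable"

_MIN_REFERENCE_N = 5


@dataclass(frozen=True)
class ReferenceDistribution:
    """Healthy-tissue score set for one pathway with its upper threshold."""

    tissue: str
    pathway: str
    scores: tuple[float, ...]
    q: float = 95.0
    threshold: float = field(init=False)

    def __post_init__(self) -> None:
        scores = tuple(float(s) for s in self.scores)
        object.__setattr__(self, "scores", scores)
        if len(scores) < _MIN_REFERENCE_N:
            raise ConfigurationError(
                f"reference set too small to threshold: n={len(scores)} "
                f"(need >= {_MIN_REFERENCE_N})"
            )
        if not all(np.isfinite(scores)):
            raise ConfigurationError("reference scores must be finite")
        if not (0.0 < self.q < 100.0):
            raise ConfigurationError("percentile q must be in (0, 100)")
        # Linear interpolation between order statistics at rank
        # h = 1 + (n-1)q/100 (the classical inclusive definition, same as
        # numpy's "linear" method up to floating-point rounding; computing
        # (n-1)*q before dividing keeps round-number thresholds exact).
        s = np.sort(np.asarray(scores, dtype=float))
        pos = (len(s) - 1) * self.q / 100.0
        lo = int(np.floor(pos))
        hi = min(lo + 1, len(s) - 1)
        frac = pos - lo
        object.__setattr__(
            self, "threshold", float(s[lo] + frac * (s[hi] - s[lo]))
        )


def build_reference(
    scores: Sequence[float],
    q: float = 95.0,
    tissue: str = "",
    pathway: str = "",
) -> ReferenceDistribution:
    """Build a reference distribution and its q-th percentile threshold."""
    return ReferenceDistribution(
        tissue=tissue, pathway=pathway, scores=tuple(scores), q=q
    )


@dataclass(frozen=True)
class PathwayCall:
    """Per-pathway outcome of comparing a score against normal."""

    pathway: str
    score: float
    threshold: float
    call: str
    interpretation: str = ""

    @property
    def is_above_threshold(self) -> bool:
        return self.call == ABOVE_THRESHOLD


def classify(
    result: PathwayActivityResult, ref: ReferenceDistribution
) -> PathwayCall:
    """Compare one activity score against its healthy reference.

    Strictly above the threshold is abnormal; a score exactly at the
    threshold is still within normal.
    """
    if result.pathway != ref.pathway:
        raise ConfigurationError(
            f"pathway mismatch: result is {result.pathway!r}, reference is "
            f"{ref.pathway!r}"
        )
    above = result.score > ref.threshold
    return PathwayCall(
        pathway=result.pathway,
        score=result.score,
        threshold=ref.threshold,
        call=ABOVE_THRESHOLD if above else WITHIN_NORMAL,
        interpretation=TUMOR_DRIVING_NOTE if above else "",
    )


@dataclass(frozen=True)
class PatientReport:
    """Multi-pathway report for one sample against one tissue's normals."""

    sample_id: str
    tissue: str
    calls: tuple[PathwayCall, ...]
    cancer_context: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "calls", tuple(sorted(self.calls, key=lambda c: c.pathway))
        )
        object.__setattr__(self, "cancer_context", dict(self.cancer_context))

    def to_dict(self) -> dict:
        return {
            "format": REPORT_FORMAT,
            "sample_id": self.sample_id,
            "tissue": self.tissue,
            "calls": [
                {
                    "pathway": c.pathway,
                    "score": c.score,
                    "threshold": c.threshold,
                    "call": c.call,
                    "interpretation": c.interpretation,
                }
                for c in self.calls
            ],
            "cancer_context": {
                k: dict(v) for k, v in self.cancer_context.items()
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "PatientReport":
        if data.get("format") != REPORT_FORMAT:
            raise ModelFormatError(
                f"unsupported report format {data.get('format')!r}"
            )
        try:
            calls = tuple(
                PathwayCall(
                    pathway=str(c["pathway"]),
                    score=float(c["score"]),
                    threshold=float(c["threshold"]),
                    call=str(c["call"]),
                    interpretation=str(c.get("interpretation", "")),
                )
                for c in data["calls"]
            )
            return cls(
                sample_id=str(data["sample_id"]),
                tissue=str(data["tissue"]),
                calls=calls,
                cancer_context=data.get("cancer_context", {}),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ModelFormatError(f"malformed report: {exc}") from exc

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load_json(cls, path: str | Path) -> "PatientReport":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_tsv(self, path: str | Path) -> None:
        lines = ["sample_id\ttissue\tpathway\tscore\tthreshold\tcall"]
        for c in self.calls:
            lines.append(
                f"{self.sample_id}\t{self.tissue}\t{c.pathway}\t"
                f"{c.score:.6f}\t{c.threshold:.6f}\t{c.call}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def build_report(
    sample_id: str,
    results: Iterable[PathwayActivityResult],
    refs: Iterable[ReferenceDistribution],
    cancer_refs: Mapping[str, Mapping[str, float]] | None = None,
    tissue: str = "",
) -> PatientReport:
    """Assemble one patient's multi-pathway report.

    Every result must have a reference for its pathway; calls are ordered
    by pathway name. ``cancer_refs`` optionally carries per-pathway summary
    statistics of a matching cancer-type score distribution for context
    (descriptive only, never used in the call).
    """
    ref_by_pathway = {r.pathway: r for r in refs}
    calls = []
    missing = []
    for result in results:
        ref = ref_by_pathway.get(result.pathway)
        if ref is None:
            missing.append(result.pathway)
            continue
        calls.append(classify(result, ref))
    if missing:
        raise ConfigurationError(
            f"no reference distribution for pathways: {sorted(missing)}"
        )
    if not tissue:
        tissues = {r.tissue for r in ref_by_pathway.values() if r.tissue}
        tissue = tissues.pop() if len(tissues) == 1 else ""
    return PatientReport(
        sample_id=sample_id,
        tissue=tissue,
        calls=tuple(calls),
        cancer_context=dict(cancer_refs or {}),
    )
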