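"""Second-layer calibration on ground-truth samples.

The first layer (TF -> gene) carries fixed literature-style priors; the
second layer (gene -> measurement) is fitted on samples whose pathway status
is known from etiology, mutation or controlled stimulation. Calibration is a
deterministic hard-assignment scheme:

1. Per probe, the dichotomization threshold is the midpoint of the
   class-conditional medians (robust to outliers; ties at the threshold
   read "high").
2. Each calibration sample's latent gene state is deduced from its label
   and the gene's direction: an active-labeled sample implies "up" for
   induced genes and "down" for repressed genes, and vice versa.
3. Emission probabilities are Laplace-smoothed frequencies of "high" reads
   within each deduced state, so no probability is ever exactly 0 or 1.

Porting a panel to another measurement platform (microarray -> qPCR)
re-runs steps 1-3 on the very same calibration samples re-measured on the
new platform; the first-layer priors and gene directions are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, ConfigurationError
from .io import ACTIVE, INACTIVE, ExpressionMatrix, GroundTruthLabels
from .model import (
    EmissionParameters,
    PathwayModel,
    PriorParameters,
    ProbeEmission,
    build_model,
)
from .panel import GenePanel

__all__ = [
    "CalibrationConfig",
    "derive_thresholds",
    "fit_emissions",
    "calibrate",
    "port_platform",
]


@dataclass(frozen=True)
class CalibrationConfig:
    """Knobs of the calibration procedure.

    smoothing_alpha is the Laplace pseudo-count (must be > 0 so fitted
    probabilities stay strictly inside (0,1)); min_samples_per_class guards
    against degenerate calibrations.
    """

    smoothing_alpha: float = 1.0
    threshold_rule: str = "class-median-midpoint"
    min_samples_per_class: int = 2

    def __post_init__(self) -> None:
        if self.smoothing_alpha <= 0:
            raise ConfigurationError("smoothing_alpha must be > 0")
        if self.threshold_rule != "class-median-midpoint":
            raise ConfigurationError(
                f"unknown threshold rule {self.threshold_rule!r}"
            )
        if self.min_samples_per_class < 1:
            raise ConfigurationError("min_samples_per_class must be >= 1")


def _class_columns(
    matrix: ExpressionMatrix, labels: GroundTruthLabels
) -> tuple[list[str], list[str]]:
    present = [s for s in matrix.samples if s in labels]
    act = [s for s in present if labels[s] == ACTIVE]
    inact = [s for s in present if labels[s] == INACTIVE]
    return act, inact


def derive_thresholds(
    matrix: ExpressionMatrix,
    labels: GroundTruthLabels,
    panel: GenePanel,
) -> dict[str, float]:
    """Per-probe dichotomization threshold: midpoint of the two
    class-conditional medians of that probe's values.

    The threshold itself is direction-agnostic (a midpoint is symmetric in
    the two classes); direction matters downstream when deducing which
    labeled class corresponds to the "up" transcription state.
    """
    act, inact = _class_columns(matrix, labels)
    if not act or not inact:
        raise CalibrationError(
            "both an active and an inactive class are required to derive "
            f"thresholds (got {len(act)} active, {len(inact)} inactive)"
        )
    thresholds: dict[str, float] = {}
    for gene in panel.target_genes:
        for probe in gene.probe_ids:
            if probe not in matrix.values.index:
                raise ConfigurationError(
                    f"gene {gene.gene_id!r}: probe {probe!r} absent from "
                    "the calibration matrix"
                )
            row = matrix.values.loc[probe]
            m_act = row[act].median(skipna=True)
            m_inact = row[inact].median(skipna=True)
            if np.isnan(m_act) or np.isnan(m_inact):
                raise CalibrationError(
                    f"probe {probe!r}: a class has no observed values"
                )
            thresholds[probe] = float((m_act + m_inact) / 2.0)
    return thresholds


def fit_emissions(
    matrix: ExpressionMatrix,
    labels: GroundTruthLabels,
    panel: GenePanel,
    thresholds: dict[str, float],
    config: CalibrationConfig | None = None,
) -> EmissionParameters:
    """Laplace-smoothed emission probabilities under hard state assignment.

    For each probe, samples are split into the deduced "up" and "down"
    transcription states (active label implies up for +1 genes, down for -1
    genes), and

        p_high_given_up = (n_high_in_up + alpha) / (n_up + 2 alpha)

    counting value >= threshold as high, NaN values excluded from both
    counts.
    """
    config = config or CalibrationConfig()
    alpha = config.smoothing_alpha
    act, inact = _class_columns(matrix, labels)
    if (
        len(act) < config.min_samples_per_class
        or len(inact) < config.min_samples_per_class
    ):
        raise CalibrationError(
            f"need >= {config.min_samples_per_class} samples per class, got "
            f"{len(act)} active / {len(inact)} inactive"
        )
    emissions: dict[str, ProbeEmission] = {}
    for gene in panel.target_genes:
        up_cols, down_cols = (act, inact) if gene.direction == +1 else (inact, act)
        for probe in gene.probe_ids:
            if probe not in thresholds:
                raise ConfigurationError(
                    f"gene {gene.gene_id!r}: no threshold for probe {probe!r}"
                )
            t = thresholds[probe]
            row = matrix.values.loc[probe]
            up_vals = row[up_cols].dropna()
            down_vals = row[down_cols].dropna()
            p_high_up = (float((up_vals >= t).sum()) + alpha) / (
                len(up_vals) + 2.0 * alpha
            )
            p_high_down = (float((down_vals >= t).sum()) + alpha) / (
                len(down_vals) + 2.0 * alpha
            )
            emissions[probe] = ProbeEmission(
                threshold=t,
                p_high_given_up=p_high_up,
                p_high_given_down=p_high_down,
            )
    return EmissionParameters(probe_emissions=emissions)


def calibrate(
    panel: GenePanel,
    matrix: ExpressionMatrix,
    labels: GroundTruthLabels,
    priors: PriorParameters | None = None,
    config: CalibrationConfig | None = None,
    platform_tag: str | None = None,
) -> PathwayModel:
    """Full calibration pipeline: thresholds -> emissions -> model.

    Calibration provenance (class sizes, smoothing, threshold rule) is
    recorded in the model metadata for traceability.
    """
    config = config or CalibrationConfig()
    priors = priors if priors is not None else PriorParameters.defaults(panel)
    thresholds = derive_thresholds(matrix, labels, panel)
    emissions = fit_emissions(matrix, labels, panel, thresholds, config)
    act, inact = _class_columns(matrix, labels)
    tag = platform_tag if platform_tag is not None else matrix.platform_tag
    metadata = {
        "calibration": {
            "n_active": len(act),
            "n_inactive": len(inact),
            "smoothing_alpha": config.smoothing_alpha,
            "threshold_rule": config.threshold_rule,
            "min_samples_per_class": config.min_samples_per_class,
            "platform_tag": tag,
        }
    }
    return build_model(
        panel, priors, emissions, platform_tag=tag, metadata=metadata
    )


def port_platform(
    model: PathwayModel,
    new_matrix: ExpressionMatrix,
    labels: GroundTruthLabels,
    config: CalibrationConfig | None = None,
    panel: GenePanel | None = None,
) -> PathwayModel:
    """Re-calibrate an existing model on the same samples re-measured on a
    new platform (e.g. qPCR after dCq normalization).

    First-layer priors and gene directions carry over unchanged; thresholds
    and emissions are re-derived on the new measurements. ``panel`` may name
    a reduced subset of the original panel (the usual ~12-gene qPCR
    reduction); its genes must all exist in the original panel, and each
    probe must be present in the new matrix.
    """
    if new_matrix.n_samples == 0:
        raise CalibrationError("platform port: new matrix has no samples")
    target_panel = panel if panel is not None else model.panel
    original = set(model.panel.gene_ids)
    unknown = [g for g in target_panel.gene_ids if g not in original]
    if unknown:
        raise ConfigurationError(
            f"platform port: genes not in the original panel: {unknown}"
        )
    for gene in target_panel.target_genes:
        for probe in gene.probe_ids:
            if probe not in new_matrix.values.index:
                raise ConfigurationError(
                    f"platform port: gene {gene.gene_id!r} probe {probe!r} "
                    "absent from the new matrix"
                )
    priors = PriorParameters(
        p_tf_active=model.priors.p_tf_active,
        gene_priors={
            g: model.priors.gene_priors[g] for g in target_panel.gene_ids
        },
    )
    ported = calibrate(
        target_panel,
        new_matrix,
        labels,
        priors=priors,
        config=config,
        platform_tag=new_matrix.platform_tag,
    )
    meta = dict(ported.metadata)
    meta["ported_from_platform"] = model.platform_tag
    return build_model(
        ported.panel,
        ported.priors,
        ported.emissions,
        platform_tag=ported.platform_tag,
        metadata=meta,
    )
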