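"""Synthetic cohorts with the statistical structure the assay assumes.

The generator mirrors the model's own causal story: each sample has a known
pathway status (the ground-truth label); given the status, each target
gene's transcription state is drawn from the first-layer conditionals
(honoring direction); given the state, each probe measurement is Gaussian
on the log2 scale around a class-conditional mean. "Conflicting" genes —
target genes whose state contradicts the pathway status, e.g. because of
tissue-specific regulation — are emulated by flipping the drawn state for a
fixed fraction of genes per sample.

Low-input material (FFPE scraps, circulating tumor cells, dilution series)
is emulated statistically: independent per-measurement dropout, extra
Gaussian noise, and — on the Cq scale — a global upward Cq shift that pushes
weak assays past the no-amplification cap.

All randomness flows from explicit integer seeds; identical spec + seed
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import ACTIVE, INACTIVE, CqTable, ExpressionMatrix, GroundTruthLabels
from .model import PathwayModel, PriorParameters
from .panel import GenePanel

__all__ = [
    "CohortSpec",
    "LowInputSpec",
    "simulate_cohort",
    "simulate_cq",
    "simulate_from_model",
    "degrade_low_input",
]


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a calibration/test cohort.

    mean_up / mean_down are the class-conditional measurement means on the
    log2 scale (defaults 8 vs 5: a three-fold-log2 separation typical of a
    clearly responsive direct target gene); sd is the within-state standard
    deviation. frac_conflicting is the fraction of genes per sample whose
    transcription state is flipped.
    """

    panel: GenePanel
    n_active: int
    n_inactive: int
    mean_up: float = 8.0
    mean_down: float = 5.0
    sd: float = 1.0
    frac_conflicting: float = 0.0
    seed: int = 0
    priors: PriorParameters | None = None

    def __post_init__(self) -> None:
        if self.n_active < 0 or self.n_inactive < 0:
            raise ConfigurationError("cohort sizes must be >= 0")
        if not (0.0 <= self.frac_conflicting <= 1.0):
            raise ConfigurationError("frac_conflicting must be in [0,1]")
        if self.sd <= 0:
            raise ConfigurationError("sd must be > 0")

    def effective_priors(self) -> PriorParameters:
        return (
            self.priors
            if self.priors is not None
            else PriorParameters.defaults(self.panel)
        )


@dataclass(frozen=True)
class LowInputSpec:
    """Statistical low-input degradation, applied independently per
    measurement: dropout (missing at random), extra Gaussian noise, and a
    global Cq shift (dilution raises Cq; meaningful only on CqTable input,
    where it interacts with the no-amplification cap)."""

    dropout_rate: float = 0.0
    extra_sd: float = 0.0
    cq_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ConfigurationError("dropout_rate must be in [0,1]")
        if self.extra_sd < 0 or self.cq_shift < 0:
            raise ConfigurationError("extra_sd and cq_shift must be >= 0")


def _simulate_states_and_expression(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, GroundTruthLabels, pd.DataFrame]:
    """Shared generator core.

    Returns (expression probes x samples, labels, gene-state matrix
    genes x samples with 1 = up). Driven entirely by a generator seeded
    with spec.seed so any re-measurement of the same spec sees the same
    underlying samples.
    """
    rng = np.random.default_rng(spec.seed)
    panel = spec.panel
    priors = spec.effective_priors()
    genes = panel.target_genes
    n_genes = len(genes)
    sample_ids = [f"A{i + 1}" for i in range(spec.n_active)] + [
        f"I{i + 1}" for i in range(spec.n_inactive)
    ]
    labels = GroundTruthLabels(
        {
            sid: (ACTIVE if i < spec.n_active else INACTIVE)
            for i, sid in enumerate(sample_ids)
        }
    )
    n_conflict = int(round(spec.frac_conflicting * n_genes))
    states = np.zeros((n_genes, len(sample_ids)), dtype=int)
    expr_rows: dict[str, list[float]] = {p: [] for p in panel.probe_ids}
    for j, sid in enumerate(sample_ids):
        is_active = labels[sid] == ACTIVE
        for gi, gene in enumerate(genes):
            gp = priors.gene_priors[gene.gene_id]
            p_up = gp.p_up_given_active if is_active else gp.p_up_given_inactive
            states[gi, j] = int(rng.random() < p_up)
        if n_conflict:
            flip = rng.choice(n_genes, size=n_conflict, replace=False)
            states[flip, j] = 1 - states[flip, j]
        for gi, gene in enumerate(genes):
            mean = spec.mean_up if states[gi, j] else spec.mean_down
            for probe in gene.probe_ids:
                expr_rows[probe].append(mean + rng.normal(0.0, spec.sd))
    expr = pd.DataFrame(expr_rows, index=sample_ids).T
    state_df = pd.DataFrame(
        states, index=[g.gene_id for g in genes], columns=sample_ids
    )
    return expr, labels, state_df


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[ExpressionMatrix, GroundTruthLabels]:
    """Simulate an intensity-platform cohort with known ground truth."""
    expr, labels, _ = _simulate_states_and_expression(spec)
    return ExpressionMatrix(values=expr, platform_tag="intensity"), labels


def simulate_cq(
    spec: CohortSpec,
    ref_base_cq: float = 28.0,
    target_base_cq: float = 28.0,
    sd_cq: float = 0.2,
    n_reference_genes: int = 2,
) -> tuple[CqTable, GroundTruthLabels]:
    """Re-measure the cohort of ``spec`` on a qPCR platform.

    The latent samples (states and true expression) are regenerated from
    spec.seed — exactly the samples :func:`simulate_cohort` produces for the
    same spec — then converted to cycles as

        Cq(probe) = target_base_cq - expression + Normal(0, sd_cq)

    (one extra doubling of transcript lowers Cq by one cycle). Reference
    genes sit at ref_base_cq + Normal(0, sd_cq). Measurement noise uses an
    independent child stream so it is uncorrelated with the intensity
    platform's noise. dCq normalization of the result recovers the
    expression up to noise plus the constant ref_base_cq - target_base_cq
    offset, which recalibration absorbs.
    """
    if not (0 < ref_base_cq < 40) or not (0 < target_base_cq < 40):
        raise ConfigurationError("base Cq values must be in (0, 40)")
    expr, labels, _ = _simulate_states_and_expression(spec)
    noise_rng = np.random.default_rng([int(spec.seed), 77])
    cq_targets = (
        target_base_cq
        - expr
        + noise_rng.normal(0.0, sd_cq, size=expr.shape)
    )
    ref_ids = (
        list(spec.panel.reference_gene_ids)
        if spec.panel.reference_gene_ids
        else [f"REF{i + 1}" for i in range(n_reference_genes)]
    )
    refs = pd.DataFrame(
        ref_base_cq + noise_rng.normal(0.0, sd_cq, size=(len(ref_ids), expr.shape[1])),
        index=ref_ids,
        columns=expr.columns,
    )
    table = pd.concat([cq_targets, refs])
    return CqTable(values=table, reference_gene_ids=tuple(ref_ids)), labels


def simulate_from_model(
    model: PathwayModel,
    n_active: int,
    n_inactive: int,
    seed: int = 0,
    spread: float = 1.0,
    gap: float = 0.3,
    hard_states: bool = True,
) -> tuple[ExpressionMatrix, GroundTruthLabels]:
    """Generate measurements from a model's *own* parameters.

    Per probe a high/low read is drawn from the emission probabilities given
    the gene's transcription state, and the continuous value is placed at
    threshold + gap + |Normal(0, spread)| for high reads (mirrored below the
    threshold for low reads; ties-at-threshold read high). The gap keeps the
    two measurement modes separated from the threshold, as dichotomizable
    data must be.

    With ``hard_states=True`` (default) the transcription state is deduced
    deterministically from the sample label and gene direction — exactly the
    assumption the hard-assignment calibration makes — so recalibrating on
    the output recovers the emission probabilities without bias. With
    ``hard_states=False`` states are drawn stochastically from the
    first-layer conditionals (the full generative model); the plug-in
    calibration estimates are then biased toward the other state's emission
    probability by up to (1 - p_up_given_active) * (p_hi|up - p_hi|down).
    """
    rng = np.random.default_rng(seed)
    sample_ids = [f"A{i + 1}" for i in range(n_active)] + [
        f"I{i + 1}" for i in range(n_inactive)
    ]
    labels = GroundTruthLabels(
        {
            sid: (ACTIVE if i < n_active else INACTIVE)
            for i, sid in enumerate(sample_ids)
        }
    )
    rows: dict[str, list[float]] = {p: [] for p in model.panel.probe_ids}
    for sid in sample_ids:
        is_active = labels[sid] == ACTIVE
        for gene in model.panel.target_genes:
            gp = model.priors.gene_priors[gene.gene_id]
            if hard_states:
                p_up = gp.p_up_given_active > gp.p_up_given_inactive
                up = p_up if is_active else not p_up
            else:
                p_up = gp.p_up_given_active if is_active else gp.p_up_given_inactive
                up = rng.random() < p_up
            for probe in gene.probe_ids:
                em = model.emissions[probe]
                p_high = em.p_high_given_up if up else em.p_high_given_down
                high = rng.random() < p_high
                mag = gap + abs(rng.normal(0.0, spread))
                value = em.threshold + mag if high else em.threshold - mag
                rows[probe].append(value)
    expr = pd.DataFrame(rows, index=sample_ids).T
    return ExpressionMatrix(values=expr, platform_tag=model.platform_tag), labels


def degrade_low_input(
    data: ExpressionMatrix | CqTable,
    spec: LowInputSpec,
    cq_max: float = 40.0,
) -> ExpressionMatrix | CqTable:
    """Apply low-input degradation to a matrix or Cq table.

    ExpressionMatrix: each value independently set missing with probability
    dropout_rate; survivors perturbed by Normal(0, extra_sd). CqTable: the
    same, plus cq_shift added to every value (dilution raises Cq), with
    values pushed past cq_max censored to missing.
    """
    rng = np.random.default_rng(spec.seed)
    if isinstance(data, ExpressionMatrix):
        vals = data.values.to_numpy(dtype=float).copy()
        drop = rng.random(vals.shape) < spec.dropout_rate
        if spec.extra_sd > 0:
            vals = vals + rng.normal(0.0, spec.extra_sd, size=vals.shape)
        vals[drop] = np.nan
        df = pd.DataFrame(
            vals, index=data.values.index, columns=data.values.columns
        )
        return ExpressionMatrix(
            values=df,
            platform_tag=data.platform_tag,
            dropped_samples=data.dropped_samples,
        )
    vals = data.values.to_numpy(dtype=float).copy()
    drop = rng.random(vals.shape) < spec.dropout_rate
    if spec.extra_sd > 0:
        vals = vals + rng.normal(0.0, spec.extra_sd, size=vals.shape)
    vals = vals + spec.cq_shift
    vals[drop] = np.nan
    with np.errstate(invalid="ignore"):
        vals[vals > cq_max] = np.nan
    df = pd.DataFrame(vals, index=data.values.index, columns=data.values.columns)
    return CqTable(values=df, reference_gene_ids=data.reference_gene_ids)
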