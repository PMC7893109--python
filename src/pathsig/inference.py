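"""Bayesian inference of transcription-factor activation from measurements.

Given a calibrated PathwayModel and one sample's measurements, the posterior
log2 odds that the TF is active is

    L = log2 O(TF) + sum_g log2 LR_g

where O(TF) is the prior odds and LR_g marginalizes gene g's latent
transcription state over its probes' dichotomized evidence. Missing
measurements contribute a likelihood factor of 1 — absence of evidence is
not evidence of low expression, which is what makes the assay robust to
unexpressed or conflicting target genes.

L is mapped to the 0-100 activity score by a linear rescaling between the
model's achievable extremes (l_min, l_max), clamped to [0, 100].

``brute_force_infer`` recomputes L by summing the full joint over all 2^n
latent gene-state configurations; it exists purely as a verification oracle
for the factorized path and refuses panels beyond 16 genes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import NoEvidenceError, PanelTooLargeError
from .io import ExpressionMatrix
from .model import (
    HIGH,
    LOW,
    MISSING,
    PathwayModel,
    gene_log2_lr_from_states,
)
from .panel import TargetGeneSpec

__all__ = [
    "EvidenceVector",
    "PathwayActivityResult",
    "ScoredCohort",
    "dichotomize",
    "gene_log2_lr",
    "infer",
    "brute_force_infer",
    "score_cohort",
]

_BRUTE_FORCE_MAX_GENES = 16

#: Reporting convention for FOXO-based models: the measured transcriptional
#: program is the FOXO one, and PI3K growth-factor pathway activity is read
#: as its inverse. This is an annotation only; the score is never inverted
#: numerically.
FOXO_PI3K_NOTE = (
    "PI3K pathway activity is interpreted as the inverse of the measured "
    "FOXO activity"
)


@dataclass(frozen=True)
class EvidenceVector:
    """Dichotomized per-probe evidence: probe id -> high/low/missing."""

    states: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", dict(self.states))

    def __getitem__(self, probe_id: str) -> str:
        return self.states[probe_id]

    @property
    def n_observed(self) -> int:
        return sum(1 for s in self.states.values() if s != MISSING)


@dataclass(frozen=True)
class PathwayActivityResult:
    """Per-sample inference output.

    contributions maps gene id to its log2 likelihood-ratio term, so the
    evidence behind a call stays auditable. n_missing_genes counts genes
    with no observed probe at all.
    """

    sample_id: str
    pathway: str
    log2_odds: float
    score: float
    contributions: Mapping[str, float]
    n_missing_genes: int
    annotations: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "contributions", dict(self.contributions))
        object.__setattr__(self, "annotations", tuple(self.annotations))


@dataclass(frozen=True)
class ScoredCohort:
    """Batch scoring output: per-sample results plus collected failures."""

    results: tuple[PathwayActivityResult, ...]
    errors: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def scores(self) -> pd.Series:
        return pd.Series(
            {r.sample_id: r.score for r in self.results}, dtype=float
        )

    def log2_odds(self) -> pd.Series:
        return pd.Series(
            {r.sample_id: r.log2_odds for r in self.results}, dtype=float
        )


def dichotomize(sample: pd.Series, model: PathwayModel) -> EvidenceVector:
    """Turn a sample column into per-probe evidence using model thresholds.

    Convention: value >= threshold reads "high" (ties count as high). Probes
    absent from the sample, or with NaN values, are "missing".
    """
    states: dict[str, str] = {}
    for probe_id, em in model.emissions.probe_emissions.items():
        if probe_id not in sample.index:
            states[probe_id] = MISSING
            continue
        v = sample[probe_id]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            states[probe_id] = MISSING
        elif float(v) >= em.threshold:
            states[probe_id] = HIGH
        else:
            states[probe_id] = LOW
    return EvidenceVector(states)


def gene_log2_lr(
    gene: TargetGeneSpec, evidence: EvidenceVector, model: PathwayModel
) -> float:
    """log2 likelihood ratio contributed by one gene's evidence.

    Marginalizes the latent transcription state; missing probes contribute
    factor 1, so a fully missing gene contributes exactly 0.
    """
    prior = model.priors.gene_priors[gene.gene_id]
    ems = [model.emissions[p] for p in gene.probe_ids]
    states = [evidence.states.get(p, MISSING) for p in gene.probe_ids]
    return gene_log2_lr_from_states(prior, ems, states)


def _score_from_log2_odds(L: float, l_min: float, l_max: float) -> float:
    if l_max - l_min <= 0:
        return 50.0  # fully uninformative model: neutral midpoint
    # ratio first: keeps S exact (50, 100) at the symmetric anchor points
    s = 100.0 * ((L - l_min) / (l_max - l_min))
    return min(100.0, max(0.0, s))


def _annotations(model: PathwayModel) -> tuple[str, ...]:
    if "foxo" in model.pathway_name.lower():
        return (FOXO_PI3K_NOTE,)
    return ()


def infer(
    model: PathwayModel,
    sample: pd.Series,
    sample_id: str | None = None,
) -> PathwayActivityResult:
    """Score one sample: dichotomize, sum gene contributions, normalize.

    Raises
    ------
    NoEvidenceError
        If no panel probe has an observed value in this sample. A sample
        with zero evidence has no defensible score; refusing beats silently
        reporting the prior.
    """
    sid = sample_id if sample_id is not None else str(sample.name)
    evidence = dichotomize(sample, model)
    if evidence.n_observed == 0:
        raise NoEvidenceError(
            f"sample {sid!r}: no evidence — no panel probe has an observed "
            "value"
        )
    contributions: dict[str, float] = {}
    n_missing_genes = 0
    for gene in model.panel.target_genes:
        lr = gene_log2_lr(gene, evidence, model)
        contributions[gene.gene_id] = lr
        if all(
            evidence.states.get(p, MISSING) == MISSING for p in gene.probe_ids
        ):
            n_missing_genes += 1
    L = model.priors.log2_prior_odds + sum(contributions.values())
    return PathwayActivityResult(
        sample_id=sid,
        pathway=model.pathway_name,
        log2_odds=L,
        score=_score_from_log2_odds(L, model.l_min, model.l_max),
        contributions=contributions,
        n_missing_genes=n_missing_genes,
        annotations=_annotations(model),
    )


def brute_force_infer(
    model: PathwayModel,
    sample: pd.Series,
    sample_id: str | None = None,
) -> PathwayActivityResult:
    """Oracle: posterior odds by explicit summation of the full joint
    P(TF, TG_1..TG_n, evidence) over all 2^n gene-state configurations.

    Unlike :func:`infer`, an all-missing sample is legal here and yields
    L = log2(prior odds) exactly (the degenerate posterior); the oracle
    reports what the model says, the user-facing path refuses to.

    Raises
    ------
    PanelTooLargeError
        For panels beyond 16 genes (enumeration would be 2^n).
    """
    genes = model.panel.target_genes
    if len(genes) > _BRUTE_FORCE_MAX_GENES:
        raise PanelTooLargeError(
            f"brute-force enumeration refused: {len(genes)} genes "
            f"(cap {_BRUTE_FORCE_MAX_GENES})"
        )
    sid = sample_id if sample_id is not None else str(sample.name)
    evidence = dichotomize(sample, model)

    # Per gene and per latent state, the probe-evidence likelihood. Genes
    # with no observed probe contribute a factor of exactly 1 and are left
    # out of the enumeration (this also makes the empty-evidence case exact:
    # L is then the prior log2 odds to the last bit).
    observed_genes = []
    lik_given_state: list[tuple[float, float]] = []  # (P(e|up), P(e|down))
    for gene in genes:
        up = 1.0
        down = 1.0
        seen = False
        for p in gene.probe_ids:
            st = evidence.states.get(p, MISSING)
            if st == MISSING:
                continue
            seen = True
            em = model.emissions[p]
            if st == HIGH:
                up *= em.p_high_given_up
                down *= em.p_high_given_down
            else:
                up *= 1.0 - em.p_high_given_up
                down *= 1.0 - em.p_high_given_down
        if seen:
            observed_genes.append(gene)
            lik_given_state.append((up, down))

    joint = {True: 0.0, False: 0.0}
    p_act = model.priors.p_tf_active
    for tf_active in (True, False):
        p_tf = p_act if tf_active else 1.0 - p_act
        total = 0.0
        for states in itertools.product(
            (True, False), repeat=len(observed_genes)
        ):
            p = 1.0
            for gene, up_state, (lik_up, lik_down) in zip(
                observed_genes, states, lik_given_state
            ):
                gp = model.priors.gene_priors[gene.gene_id]
                p_up = gp.p_up_given_active if tf_active else gp.p_up_given_inactive
                p *= (p_up * lik_up) if up_state else ((1.0 - p_up) * lik_down)
            total += p
        joint[tf_active] = p_tf * total
    L = math.log2(joint[True] / joint[False])

    contributions = {
        g.gene_id: gene_log2_lr(g, evidence, model) for g in genes
    }
    n_missing_genes = sum(
        1
        for g in genes
        if all(evidence.states.get(p, MISSING) == MISSING for p in g.probe_ids)
    )
    return PathwayActivityResult(
        sample_id=sid,
        pathway=model.pathway_name,
        log2_odds=L,
        score=_score_from_log2_odds(L, model.l_min, model.l_max),
        contributions=contributions,
        n_missing_genes=n_missing_genes,
        annotations=_annotations(model),
    )


def score_cohort(
    model: PathwayModel, matrix: ExpressionMatrix
) -> ScoredCohort:
    """Score every sample column of a matrix.

    Per-sample failures (e.g. no evidence) are collected into
    ``ScoredCohort.errors`` rather than aborting the batch; successful
    results keep column order. Results are independent of column order.
    """
    results: list[PathwayActivityResult] = []
    errors: list[tuple[str, str]] = []
    for sid in matrix.samples:
        try:
            results.append(infer(model, matrix.sample(sid), sample_id=sid))
        except NoEvidenceError as exc:
            errors.append((sid, str(exc)))
    return ScoredCohort(results=tuple(results), errors=tuple(errors))
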