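"""The two-layer Bayesian pathway model.

Structure (a tree): one latent binary root node TF (transcription factor
complex active / inactive); per target gene a latent binary TG node
(transcription up / down); per probe an observed binary measurement node
(high / low after dichotomization at a calibrated threshold).

Layer (a), TF -> TG, carries literature-style conditional probabilities
P(TG=up | TF). Layer (b), TG -> probe, carries emission probabilities
P(measurement=high | TG) calibrated on ground-truth samples. Inference
marginalizes the TG nodes analytically, so the posterior log2 odds of TF
activation factorizes into a sum of per-gene log2 likelihood ratios.

The model also stores the extreme achievable log2 odds (l_min, l_max) over
all complete evidence assignments; these anchor the linear mapping of the
log2 odds onto the 0-100 activity score.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ConfigurationError, ModelFormatError
from .panel import GenePanel, TargetGeneSpec

__all__ = [
    "GenePrior",
    "PriorParameters",
    "ProbeEmission",
    "EmissionParameters",
    "PathwayModel",
    "build_model",
    "compute_bounds",
    "save_model",
    "load_model",
    "MODEL_FORMAT",
]

MODEL_FORMAT = "pathsig-model/1"

#: Default first-layer coupling for an induced (+1) gene: strong but
#: non-degenerate. Swapped for repressed (-1) genes.
DEFAULT_P_UP_GIVEN_ACTIVE = 0.95
DEFAULT_P_UP_GIVEN_INACTIVE = 0.05
DEFAULT_P_TF_ACTIVE = 0.5

HIGH = "high"
LOW = "low"
MISSING = "missing"

# Per-gene enumeration cap for the bounds computation (2^k probe states).
_MAX_PROBES_PER_GENE = 12


def _check_prob(p: float, what: str) -> float:
    p = float(p)
    if not (0.0 < p < 1.0):
        raise ConfigurationError(f"{what} must be strictly inside (0,1), got {p}")
    return p


@dataclass(frozen=True)
class GenePrior:
    """First-layer conditionals P(TG=up | TF) for one gene."""

    p_up_given_active: float
    p_up_given_inactive: float

    def __post_init__(self) -> None:
        _check_prob(self.p_up_given_active, "p_up_given_active")
        _check_prob(self.p_up_given_inactive, "p_up_given_inactive")


@dataclass(frozen=True)
class PriorParameters:
    """TF prior and per-gene first-layer conditionals.

    The direction convention is enforced at model build time: for +1 genes
    p_up_given_active > p_up_given_inactive, reversed for -1 genes.
    """

    p_tf_active: float = DEFAULT_P_TF_ACTIVE
    gene_priors: Mapping[str, GenePrior] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_prob(self.p_tf_active, "p_tf_active")
        object.__setattr__(self, "gene_priors", dict(self.gene_priors))

    @property
    def log2_prior_odds(self) -> float:
        return math.log2(self.p_tf_active / (1.0 - self.p_tf_active))

    @classmethod
    def defaults(cls, panel: GenePanel, p_tf_active: float = DEFAULT_P_TF_ACTIVE,
                 p_up: float = DEFAULT_P_UP_GIVEN_ACTIVE,
                 p_down: float = DEFAULT_P_UP_GIVEN_INACTIVE) -> "PriorParameters":
        """Default literature-style priors, honoring gene direction.

        Repressed genes get the swapped conditionals rather than negated
        measurements, keeping the emission layer purely about measurement
        behavior.
        """
        priors = {}
        for g in panel.target_genes:
            if g.direction == +1:
                priors[g.gene_id] = GenePrior(p_up, p_down)
            else:
                priors[g.gene_id] = GenePrior(p_down, p_up)
        return cls(p_tf_active=p_tf_active, gene_priors=priors)


@dataclass(frozen=True)
class ProbeEmission:
    """Second-layer parameters for one probe: dichotomization threshold and
    P(measurement=high | TG state)."""

    threshold: float
    p_high_given_up: float
    p_high_given_down: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold):
            raise ConfigurationError("probe threshold must be finite")
        _check_prob(self.p_high_given_up, "p_high_given_up")
        _check_prob(self.p_high_given_down, "p_high_given_down")


@dataclass(frozen=True)
class EmissionParameters:
    """Per-probe emission records, keyed by probe id."""

    probe_emissions: Mapping[str, ProbeEmission] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "probe_emissions", dict(self.probe_emissions))

    def __getitem__(self, probe_id: str) -> ProbeEmission:
        return self.probe_emissions[probe_id]


@dataclass(frozen=True)
class PathwayModel:
    """A calibrated pathway model, immutable once built.

    l_min / l_max are the extreme log2 odds achievable over complete
    (no-missing) evidence assignments; under the symmetric default
    parameterization l_min == -l_max.
    """

    panel: GenePanel
    priors: PriorParameters
    emissions: EmissionParameters
    l_min: float
    l_max: float
    platform_tag: str = "intensity"
    metadata: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "metadata", dict(self.metadata))

    @property
    def pathway_name(self) -> str:
        return self.panel.pathway_name


def gene_log2_lr_from_states(
    prior: GenePrior,
    emissions: Iterable[ProbeEmission],
    states: Iterable[str],
) -> float:
    """log2 likelihood ratio P(evidence|TF=active)/P(evidence|TF=inactive)
    for one gene, marginalizing its latent TG state.

    Probes in the MISSING state contribute a likelihood factor of 1 (evidence
    absent is not evidence of low expression). With no observed probe the
    ratio is exactly 1, i.e. log2 LR = 0.
    """
    lik_up = 1.0
    lik_down = 1.0
    observed = False
    for em, st in zip(emissions, states):
        if st == MISSING:
            continue
        observed = True
        if st == HIGH:
            lik_up *= em.p_high_given_up
            lik_down *= em.p_high_given_down
        elif st == LOW:
            lik_up *= 1.0 - em.p_high_given_up
            lik_down *= 1.0 - em.p_high_given_down
        else:
            raise ValueError(f"unknown evidence state {st!r}")
    if not observed:
        return 0.0
    a = prior.p_up_given_active
    b = prior.p_up_given_inactive
    num = a * lik_up + (1.0 - a) * lik_down
    den = b * lik_up + (1.0 - b) * lik_down
    return math.log2(num / den)


def _gene_lr_extremes(
    gene: TargetGeneSpec, prior: GenePrior, emissions: EmissionParameters
) -> tuple[float, float]:
    """(min, max) of the gene's log2 LR over complete probe assignments."""
    ems = [emissions[p] for p in gene.probe_ids]
    if len(ems) > _MAX_PROBES_PER_GENE:
        raise ConfigurationError(
            f"gene {gene.gene_id!r}: {len(ems)} probes exceeds the "
            f"enumeration cap of {_MAX_PROBES_PER_GENE}"
        )
    lo = math.inf
    hi = -math.inf
    for states in itertools.product((HIGH, LOW), repeat=len(ems)):
        lr = gene_log2_lr_from_states(prior, ems, states)
        lo = min(lo, lr)
        hi = max(hi, lr)
    return lo, hi


def compute_bounds(
    panel: GenePanel, priors: PriorParameters, emissions: EmissionParameters
) -> tuple[float, float]:
    """Extreme achievable log2 odds over all complete evidence assignments.

    The tree structure factorizes the log2 odds into the prior log2 odds plus
    independent per-gene log2 likelihood ratios, so the extremes are the
    prior log2 odds plus the sum of per-gene extremes (each found by
    enumerating that gene's probe states).
    """
    base = priors.log2_prior_odds
    l_min = base
    l_max = base
    for g in panel.target_genes:
        lo, hi = _gene_lr_extremes(g, priors.gene_priors[g.gene_id], emissions)
        l_min += lo
        l_max += hi
    return l_min, l_max


def _validate_coverage(
    panel: GenePanel, priors: PriorParameters, emissions: EmissionParameters
) -> None:
    for g in panel.target_genes:
        if g.gene_id not in priors.gene_priors:
            raise ConfigurationError(
                f"gene {g.gene_id!r} has no first-layer prior parameters"
            )
        gp = priors.gene_priors[g.gene_id]
        if g.direction == +1 and not (
            gp.p_up_given_active > gp.p_up_given_inactive
        ):
            raise ConfigurationError(
                f"gene {g.gene_id!r} (direction +1): requires "
                "p_up_given_active > p_up_given_inactive"
            )
        if g.direction == -1 and not (
            gp.p_up_given_active < gp.p_up_given_inactive
        ):
            raise ConfigurationError(
                f"gene {g.gene_id!r} (direction -1): requires "
                "p_up_given_active < p_up_given_inactive"
            )
        for p in g.probe_ids:
            if p not in emissions.probe_emissions:
                raise ConfigurationError(
                    f"gene {g.gene_id!r}: probe {p!r} has no emission "
                    "parameters"
                )


def build_model(
    panel: GenePanel,
    priors: PriorParameters,
    emissions: EmissionParameters,
    platform_tag: str = "intensity",
    metadata: Mapping | None = None,
) -> PathwayModel:
    """Assemble a PathwayModel, validating parameter coverage and computing
    the score-normalization bounds.

    Raises
    ------
    ConfigurationError
        If any panel gene lacks prior or emission parameters, or a prior
        violates the direction convention.
    """
    _validate_coverage(panel, priors, emissions)
    l_min, l_max = compute_bounds(panel, priors, emissions)
    return PathwayModel(
        panel=panel,
        priors=priors,
        emissions=emissions,
        l_min=l_min,
        l_max=l_max,
        platform_tag=platform_tag,
        metadata=dict(metadata or {}),
    )


# ---------------------------------------------------------------------------
# Serialization: a single self-describing, versioned JSON document.
# Probabilities are stored as plain decimals (auditable), never log-space.

def _model_to_dict(model: PathwayModel) -> dict:
    return {
        "format": MODEL_FORMAT,
        "platform_tag": model.platform_tag,
        "panel": model.panel.to_dict(),
        "priors": {
            "p_tf_active": model.priors.p_tf_active,
            "genes": {
                gid: {
                    "p_up_given_active": gp.p_up_given_active,
                    "p_up_given_inactive": gp.p_up_given_inactive,
                }
                for gid, gp in model.priors.gene_priors.items()
            },
        },
        "emissions": {
            pid: {
                "threshold": em.threshold,
                "p_high_given_up": em.p_high_given_up,
                "p_high_given_down": em.p_high_given_down,
            }
            for pid, em in model.emissions.probe_emissions.items()
        },
        "bounds": {"l_min": model.l_min, "l_max": model.l_max},
        "metadata": dict(model.metadata),
    }


def save_model(model: PathwayModel, path: str | Path) -> None:
    """Write the model as a versioned JSON document."""
    Path(path).write_text(json.dumps(_model_to_dict(model), indent=2) + "\n")


_REQUIRED_KEYS = ("format", "platform_tag", "panel", "priors", "emissions")


def load_model(path: str | Path) -> PathwayModel:
    """Load a model JSON, checking schema and format version.

    Bounds are recomputed from the parameters and cross-checked against the
    stored values, so a hand-edited file cannot silently carry stale bounds.
    """
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"model file is not valid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise ModelFormatError("model file must be a JSON object")
    for key in _REQUIRED_KEYS:
        if key not in data:
            raise ModelFormatError(f"model file missing required key {key!r}")
    fmt = str(data["format"])
    prefix, _, major = fmt.rpartition("/")
    if prefix != "pathsig-model" or major != MODEL_FORMAT.rpartition("/")[2]:
        raise ModelFormatError(
            f"unsupported model format {fmt!r}; this build reads "
            f"{MODEL_FORMAT!r}"
        )
    try:
        panel = GenePanel.from_dict(data["panel"])
        priors = PriorParameters(
            p_tf_active=float(data["priors"]["p_tf_active"]),
            gene_priors={
                gid: GenePrior(
                    float(gp["p_up_given_active"]),
                    float(gp["p_up_given_inactive"]),
                )
                for gid, gp in data["priors"]["genes"].items()
            },
        )
        emissions = EmissionParameters(
            probe_emissions={
                pid: ProbeEmission(
                    float(em["threshold"]),
                    float(em["p_high_given_up"]),
                    float(em["p_high_given_down"]),
                )
                for pid, em in data["emissions"].items()
            }
        )
    except (KeyError, TypeError, ValueError, ConfigurationError) as exc:
        raise ModelFormatError(f"malformed model file: {exc}") from exc
    model = build_model(
        panel,
        priors,
        emissions,
        platform_tag=str(data["platform_tag"]),
        metadata=data.get("metadata", {}),
    )
    stored = data.get("bounds")
    if stored is not None:
        if (
            abs(float(stored["l_min"]) - model.l_min) > 1e-9
            or abs(float(stored["l_max"]) - model.l_max) > 1e-9
        ):
            raise ModelFormatError(
                "stored score bounds disagree with the model parameters"
            )
    return model
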