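"""Shared fixtures: small default models and random-model factories."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pathsig import (
    EmissionParameters,
    GenePanel,
    GenePrior,
    PathwayModel,
    PriorParameters,
    ProbeEmission,
    TargetGeneSpec,
    build_model,
    uniform_panel,
)

DEFAULT_THRESHOLD = 6.5


def default_emissions(panel: GenePanel, t: float = DEFAULT_THRESHOLD,
                      p_up: float = 0.9, p_down: float = 0.1) -> EmissionParameters:
    return EmissionParameters(
        {p: ProbeEmission(t, p_up, p_down) for p in panel.probe_ids}
    )


def default_model(panel: GenePanel, **kwargs) -> PathwayModel:
    return build_model(
        panel, PriorParameters.defaults(panel), default_emissions(panel), **kwargs
    )


@pytest.fixture
def two_gene_panel() -> GenePanel:
    return uniform_panel("Wnt", 2)


@pytest.fixture
def two_gene_model(two_gene_panel) -> PathwayModel:
    return default_model(two_gene_panel)


@pytest.fixture
def panel12() -> GenePanel:
    return uniform_panel("Wnt", 12)


def random_model(
    rng: np.random.Generator,
    n_genes: int | None = None,
    max_probes_per_gene: int = 2,
    oriented_emissions: bool = True,
) -> PathwayModel:
    """A random but valid pathway model.

    Emission probabilities are drawn oriented (p_high|up > p_high|down) by
    default, matching any sane calibration outcome.
    """
    n = int(n_genes if n_genes is not None else rng.integers(2, 13))
    genes = []
    for i in range(n):
        k = int(rng.integers(1, max_probes_per_gene + 1))
        genes.append(
            TargetGeneSpec(
                gene_id=f"G{i + 1}",
                direction=int(rng.choice([1, -1])),
                probe_ids=tuple(f"G{i + 1}_p{j + 1}" for j in range(k)),
            )
        )
    panel = GenePanel(pathway_name="random", target_genes=tuple(genes))
    gene_priors = {}
    for g in genes:
        a = float(rng.uniform(0.55, 0.99))
        b = float(rng.uniform(0.01, 0.45))
        if g.direction == +1:
            gene_priors[g.gene_id] = GenePrior(a, b)
        else:
            gene_priors[g.gene_id] = GenePrior(b, a)
    priors = PriorParameters(
        p_tf_active=float(rng.uniform(0.2, 0.8)), gene_priors=gene_priors
    )
    ems = {}
    for p in panel.probe_ids:
        hi = float(rng.uniform(0.55, 0.99))
        lo = float(rng.uniform(0.01, 0.45))
        if not oriented_emissions and rng.random() < 0.5:
            hi, lo = lo, hi
        ems[p] = ProbeEmission(float(rng.uniform(4.0, 9.0)), hi, lo)
    return build_model(panel, priors, EmissionParameters(ems))


def random_sample(
    rng: np.random.Generator, model: PathwayModel, p_missing: float = 0.2
) -> pd.Series:
    """Random measurement vector for a model, with missing values."""
    vals = {}
    for p, em in model.emissions.probe_emissions.items():
        if rng.random() < p_missing:
            vals[p] = np.nan
        else:
            vals[p] = em.threshold + rng.normal(0.0, 2.0)
    return pd.Series(vals)
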