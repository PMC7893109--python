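"""Gene-panel definitions.

A pathway assay is defined by a panel of high-evidence direct target genes of
the pathway's transcription factor, each with a regulation direction (+1 for
genes induced when the TF is active, -1 for repressed genes) and one or more
measurement probes/assays. qPCR panels additionally list the stably expressed
reference genes used for dCq normalization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import ConfigurationError

__all__ = ["TargetGeneSpec", "GenePanel", "load_panel", "save_panel"]


@dataclass(frozen=True)
class TargetGeneSpec:
    """One direct target gene of the pathway's transcription factor.

    Parameters
    ----------
    gene_id : str
        Gene symbol.
    direction : int
        +1 if the gene is induced by the active TF complex, -1 if repressed.
    probe_ids : tuple of str
        Identifiers of the measurement nodes (microarray probesets or qPCR
        assays) reading out this gene. At least one.
    """

    gene_id: str
    direction: int
    probe_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ConfigurationError(
                f"gene {self.gene_id!r}: direction must be +1 or -1, "
                f"got {self.direction!r}"
            )
        object.__setattr__(self, "probe_ids", tuple(self.probe_ids))
        if not self.probe_ids:
            raise ConfigurationError(f"gene {self.gene_id!r}: no probes")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ConfigurationError(
                f"gene {self.gene_id!r}: duplicate probe ids"
            )


@dataclass(frozen=True)
class GenePanel:
    """A named pathway panel: target genes plus optional reference genes.

    Invariants enforced here: at least two target genes, unique gene ids,
    probe ids unique across the whole panel, reference genes disjoint from
    target genes.
    """

    pathway_name: str
    target_genes: tuple[TargetGeneSpec, ...]
    reference_gene_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_genes", tuple(self.target_genes))
        object.__setattr__(
            self, "reference_gene_ids", tuple(self.reference_gene_ids)
        )
        if len(self.target_genes) < 2:
            raise ConfigurationError(
                f"panel {self.pathway_name!r}: needs >=2 target genes, "
                f"got {len(self.target_genes)}"
            )
        gene_ids = [g.gene_id for g in self.target_genes]
        if len(set(gene_ids)) != len(gene_ids):
            dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
            raise ConfigurationError(
                f"panel {self.pathway_name!r}: duplicate gene ids {dupes}"
            )
        probes = self.probe_ids
        if len(set(probes)) != len(probes):
            raise ConfigurationError(
                f"panel {self.pathway_name!r}: probe ids not unique "
                "across genes"
            )
        overlap = set(gene_ids) & set(self.reference_gene_ids)
        if overlap:
            raise ConfigurationError(
                f"panel {self.pathway_name!r}: reference genes overlap "
                f"target genes: {sorted(overlap)}"
            )

    @property
    def probe_ids(self) -> tuple[str, ...]:
        """All probe ids in panel (gene) order."""
        return tuple(p for g in self.target_genes for p in g.probe_ids)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.target_genes)

    def gene(self, gene_id: str) -> TargetGeneSpec:
        for g in self.target_genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def to_dict(self) -> dict:
        return {
            "pathway": self.pathway_name,
            "target_genes": [
                {
                    "gene": g.gene_id,
                    "direction": g.direction,
                    "probes": list(g.probe_ids),
                }
                for g in self.target_genes
            ],
            "reference_genes": list(self.reference_gene_ids),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "GenePanel":
        try:
            genes = tuple(
                TargetGeneSpec(
                    gene_id=str(g["gene"]),
                    direction=int(g["direction"]),
                    probe_ids=tuple(str(p) for p in g["probes"]),
                )
                for g in data["target_genes"]
            )
            return cls(
                pathway_name=str(data["pathway"]),
                target_genes=genes,
                reference_gene_ids=tuple(
                    str(r) for r in data.get("reference_genes", [])
                ),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"malformed panel config: {exc}") from exc


def load_panel(path: str | Path) -> GenePanel:
    """Read a panel config (YAML or JSON, by extension) into a GenePanel."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"panel config {path} is not a mapping")
    return GenePanel.from_dict(data)


def save_panel(panel: GenePanel, path: str | Path) -> None:
    path = Path(path)
    data = panel.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def uniform_panel(
    pathway_name: str,
    n_genes: int,
    directions: Sequence[int] | None = None,
    probes_per_gene: int = 1,
    reference_gene_ids: Sequence[str] = (),
) -> GenePanel:
    """Convenience constructor for synthetic panels G1..Gn.

    Probe ids are ``<gene>_p<k>``. Used heavily by the cohort simulator and
    tests; not intended for real assay definitions.
    """
    if directions is None:
        directions = [+1] * n_genes
    genes = tuple(
        TargetGeneSpec(
            gene_id=f"G{i + 1}",
            direction=directions[i],
            probe_ids=tuple(
                f"G{i + 1}_p{k + 1}" for k in range(probes_per_gene)
            ),
        )
        for i in range(n_genes)
    )
    return GenePanel(
        pathway_name=pathway_name,
        target_genes=genes,
        reference_gene_ids=tuple(reference_gene_ids),
    )
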