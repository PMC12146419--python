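"""Dataset bundle: the full set of aligned inputs for one prediction run."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .datamodel import (
    AssociationNetwork,
    DataModelError,
    DiseaseDAG,
    LocalizationMatrix,
    MirnaSet,
    read_dag,
    read_edge_list,
    read_fasta,
    read_localization,
)

#: Conventional file names inside a dataset directory.
FILES = {
    "fasta": "mirna.fasta",
    "disease": "mirna_disease.tsv",
    "drug": "mirna_drug.tsv",
    "mrna": "mirna_mrna.tsv",
    "dag": "disease_dag.tsv",
    "mrna_loc": "mrna_localization.tsv",
    "labels": "mirna_localization.tsv",
}


@dataclass(frozen=True)
class LocalizationDataset:
    """All inputs aligned to the canonical miRNA order (FASTA file order)."""

    mirnas: MirnaSet
    disease_net: AssociationNetwork
    drug_net: AssociationNetwork
    mrna_net: AssociationNetwork
    dag: DiseaseDAG
    mrna_loc: LocalizationMatrix
    labels: LocalizationMatrix  # miRNA x 7

    def __post_init__(self) -> None:
        order = self.mirnas.ids
        for net in (self.disease_net, self.drug_net, self.mrna_net):
            if net.mirna_ids != order:
                raise DataModelError(
                    f"{net.entity_kind} network row order does not match the miRNA universe"
                )
        if self.labels.entity_ids != order:
            raise DataModelError("label matrix row order does not match the miRNA universe")

    @property
    def n_mirna(self) -> int:
        return len(self.mirnas.ids)

    @classmethod
    def from_directory(cls, path: str | Path) -> "LocalizationDataset":
        """Load a dataset from a directory using the conventional file names."""
        path = Path(path)
        mirnas = read_fasta(path / FILES["fasta"])
        order = mirnas.ids
        return cls(
            mirnas=mirnas,
            disease_net=read_edge_list(path / FILES["disease"], "disease", order),
            drug_net=read_edge_list(path / FILES["drug"], "drug", order),
            mrna_net=read_edge_list(path / FILES["mrna"], "mrna", order),
            dag=read_dag(path / FILES["dag"]),
            mrna_loc=read_localization(path / FILES["mrna_loc"]),
            labels=read_localization(path / FILES["labels"]).align_to(order),
        )
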