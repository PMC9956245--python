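"""Shared record types for strain panels and proteomes."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its locus id and strain of origin."""

    strain_id: str
    locus_id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class StrainInfo:
    """Strain metadata: phylogenetic cluster label and sporulation phenotype.

    ``phenotype`` is ``"Sp+"`` for strains sporulating inside host nodules,
    ``"Sp-"`` for strains that do not, and ``"none"`` where the phenotype is
    not applicable (e.g. outgroup clusters).
    """

    strain_id: str
    cluster_label: str
    phenotype: str = "none"


@dataclass
class StrainPanel:
    """A set of proteomes plus per-strain metadata.

    proteomes maps strain_id -> list of ProteinRecord (insertion order kept);
    metadata maps strain_id -> StrainInfo.  Every proteome strain must have
    metadata; metadata-only strains (empty proteomes) are allowed.
    """

    proteomes: dict[str, list[ProteinRecord]] = field(default_factory=dict)
    metadata: dict[str, StrainInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.proteomes) - set(self.metadata)
        if missing:
            raise ValueError(f"strains without metadata: {sorted(missing)}")

    @property
    def strain_ids(self) -> list[str]:
        return sorted(self.metadata)

    def all_records(self) -> list[ProteinRecord]:
        return [r for s in sorted(self.proteomes) for r in self.proteomes[s]]

    def record_by_locus(self) -> dict[str, ProteinRecord]:
        out: dict[str, ProteinRecord] = {}
        for rec in self.all_records():
            if rec.locus_id in out:
                raise ValueError(f"duplicate locus id across panel: {rec.locus_id}")
            out[rec.locus_id] = rec
        return out

    def n_proteins(self, strain_id: str) -> int:
        return len(self.proteomes.get(strain_id, []))
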