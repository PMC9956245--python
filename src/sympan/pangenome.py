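"""Core / pan / specific-core set algebra over a presence matrix.

Presence means member count >= 1; copy number is ignored here (it is the
subject of the paralog analysis).  The specific core of a focal group is
its core minus the pan-genome of all other groups — the families every
focal strain carries and no outside strain does.  Lost families between a
retained and a reduced group are those present in every retained-group
strain and absent from every reduced-group strain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .records import StrainInfo


@dataclass
class PresenceMatrix:
    """Family-by-strain member-count table with strain metadata attached."""

    counts: pd.DataFrame  # index: family ids; columns: strain ids; int counts
    metadata: dict[str, StrainInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("member counts must be non-negative")
        if len(self.counts) and (self.counts.sum(axis=1) == 0).any():
            empty = self.counts.index[self.counts.sum(axis=1) == 0]
            raise ValueError(f"all-zero rows not allowed: {list(empty)[:5]}")
        missing = set(self.counts.columns) - set(self.metadata)
        if missing:
            raise ValueError(f"strains without metadata: {sorted(missing)}")

    @property
    def strain_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def family_ids(self) -> list[str]:
        return list(self.counts.index)

    def strains_in_cluster(self, cluster_label: str) -> set[str]:
        return {s for s in self.strain_ids
                if self.metadata[s].cluster_label == cluster_label}

    def strains_with_phenotype(self, phenotype: str) -> set[str]:
        return {s for s in self.strain_ids
                if self.metadata[s].phenotype == phenotype}

    def genes_per_strain(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class GroupDefinition:
    """A named strain group, e.g. one cluster label or one phenotype."""

    group_id: str
    strain_ids: frozenset[str]
    basis: str = ""  # free text: which label defined the group

    def __post_init__(self) -> None:
        if not self.strain_ids:
            raise ValueError(f"group {self.group_id!r} has no strains")

    @classmethod
    def from_cluster(cls, matrix: PresenceMatrix, label: str) -> "GroupDefinition":
        return cls(label, frozenset(matrix.strains_in_cluster(label)),
                   basis=f"cluster_label={label}")

    @classmethod
    def from_phenotype(cls, matrix: PresenceMatrix, phenotype: str) -> "GroupDefinition":
        return cls(phenotype, frozenset(matrix.strains_with_phenotype(phenotype)),
                   basis=f"phenotype={phenotype}")


def _check_group(matrix: PresenceMatrix, group: GroupDefinition) -> list[str]:
    unknown = group.strain_ids - set(matrix.strain_ids)
    if unknown:
        raise ValueError(
            f"group {group.group_id!r} names strains absent from the matrix: "
            f"{sorted(unknown)}")
    return sorted(group.strain_ids)

def core_families(matrix: PresenceMatrix, group: GroupDefinition) -> list[str]:
    """Families present (count >= 1) in every strain of the group."""
    cols = _check_group(matrix, group)
    mask = (matrix.counts[cols] >= 1).all(axis=1)
    return sorted(matrix.counts.index[mask])


def pan_families(matrix: PresenceMatrix, group: GroupDefinition) -> list[str]:
    """Families present in at least one strain of the group."""
    cols = _check_group(matrix, group)
    mask = (matrix.counts[cols] >= 1).any(axis=1)
    return sorted(matrix.counts.index[mask])


def specific_core(matrix: PresenceMatrix, focal_group: GroupDefinition,
                  other_groups: list[GroupDefinition]) -> list[str]:
    """Core of the focal group minus the pan-genome of all other groups."""
    for other in other_groups:
        overlap = focal_group.strain_ids & other.strain_ids
        if overlap:
            raise ValueError(
                f"groups {focal_group.group_id!r} and {other.group_id!r} "
                f"overlap on {sorted(overlap)}")
    core = set(core_families(matrix, focal_group))
    for other in other_groups:
        core -= set(pan_families(matrix, other))
    return sorted(core)


def strain_unique_counts(matrix: PresenceMatrix) -> pd.Series:
    """Flower-plot petals: per strain, families found in it and nowhere else."""
    present = matrix.counts >= 1
    singleton = present.sum(axis=1) == 1
    return present[singleton].sum(axis=0).astype(int)


def lost_families(matrix: PresenceMatrix, retained_group: GroupDefinition,
                  lost_group: GroupDefinition,
                  min_retained_strains: int | None = None) -> list[str]:
    """Families kept by the retained group but absent from the lost group.

    By default a family must be present in every retained-group strain and
    in no lost-group strain; min_retained_strains relaxes the first
    condition to "present in at least that many retained strains".
    """
    overlap = retained_group.strain_ids & lost_group.strain_ids
    if overlap:
        raise ValueError(f"groups overlap on {sorted(overlap)}")
    retained_cols = _check_group(matrix, retained_group)
    lost_cols = _check_group(matrix, lost_group)
    need = len(retained_cols) if min_retained_strains is None else min_retained_strains
    present = matrix.counts >= 1
    mask = (present[retained_cols].sum(axis=1) >= need) & \
        (~present[lost_cols]).all(axis=1)
    return sorted(matrix.counts.index[mask])


@dataclass(frozen=True)
class VennSummary:
    core_size: int
    pan_size: int
    specific_core_size: int


def venn_summary(matrix: PresenceMatrix, focal_group: GroupDefinition,
                 other_groups: list[GroupDefinition]) -> VennSummary:
    return VennSummary(
        core_size=len(core_families(matrix, focal_group)),
        pan_size=len(pan_families(matrix, focal_group)),
        specific_core_size=len(specific_core(matrix, focal_group, other_groups)))
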