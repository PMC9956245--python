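"""Synthetic multi-strain pangenomes with planted ground truth.

The generator emulates the kind of strain panel used in symbiont
comparative genomics: a focal cluster of strains split into Sp+ / Sp-
sporulation phenotypes plus outgroup clusters.  Families are planted with
known roles so every downstream stage (family clustering, core/pan algebra,
lost-family detection, paralog calls, ANI) can be checked against exact
truth:

* ``universal``            — one member in every strain of the panel;
* ``groupA_core_specific`` — one member in every focal-cluster strain, none
  elsewhere (the "specific core" of the focal cluster);
* ``lost_in_spplus``       — one member in every Sp- strain, absent from all
  Sp+ strains (families lost during Sp+ genome reduction);
* ``strain_specific``      — a fresh random protein in a single strain.

Each family descends from one ancestral sequence; every member is the
ancestor with a fixed fraction of positions substituted, so within-family
identity is analytically controlled without any alignment.  Mutations are
substitutions only; decoy (strain-specific) proteins are i.i.d. uniform
random sequences whose expected identity to anything else is ~5%, far below
every clustering threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records import ProteinRecord, StrainInfo

AA20 = "ACDEFGHIKLMNPQRSTVWY"
DNA4 = "ACGT"

ROLES = ("universal", "groupA_core_specific", "lost_in_spplus", "strain_specific")


@dataclass(frozen=True)
class GroupSpec:
    """One strain group: shared cluster label and sporulation phenotype."""

    group_id: str
    cluster_label: str
    phenotype: str  # "Sp+", "Sp-", or "none"
    n_strains: int

    def __post_init__(self) -> None:
        if self.phenotype not in ("Sp+", "Sp-", "none"):
            raise ValueError(
                f"group {self.group_id}: phenotype must be Sp+/Sp-/none, "
                f"got {self.phenotype!r}")
        if self.n_strains < 0:
            raise ValueError(f"group {self.group_id}: n_strains must be >= 0")


def default_groups() -> tuple[GroupSpec, ...]:
    """The default panel: a 12-strain focal cluster (6 Sp+ / 6 Sp-) plus two
    2-strain outgroup clusters."""
    return (
        GroupSpec("Ia-Spp", "Ia", "Sp+", 6),
        GroupSpec("Ia-Spm", "Ia", "Sp-", 6),
        GroupSpec("Ic", "Ic", "none", 2),
        GroupSpec("III", "III", "none", 2),
    )


@dataclass(frozen=True)
class PangenomeConfig:
    """Panel layout and planted-structure counts.

    The first group's cluster label defines the focal cluster ("group A")
    that receives the group-specific core families; lost_in_spplus families
    are planted in every Sp- strain and no Sp+ strain.  paralog_fraction is
    the fraction of families (per role class) that carry a duplicated,
    independently mutated copy in their first member strain.
    """

    groups: tuple[GroupSpec, ...] = field(default_factory=default_groups)
    n_universal_families: int = 40
    n_groupA_specific_core: int = 9
    n_lost_in_spplus: int = 88
    n_strain_specific_per_strain: int = 7
    protein_length_range: tuple[int, int] = (120, 300)
    within_family_divergence: float = 0.05
    paralog_fraction: float = 24 / 88
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_universal_families", "n_groupA_specific_core",
                     "n_lost_in_spplus", "n_strain_specific_per_strain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.protein_length_range
        if not (0 < lo <= hi):
            raise ValueError("protein_length_range must satisfy 0 < min <= max")
        if not (0.0 <= self.within_family_divergence < 0.5):
            raise ValueError("within_family_divergence must be in [0, 0.5)")
        if not (0.0 <= self.paralog_fraction <= 1.0):
            raise ValueError("paralog_fraction must be in [0, 1]")
        if self.n_lost_in_spplus > 0:
            phenos = {g.phenotype for g in self.groups}
            if "Sp-" not in phenos:
                raise ValueError(
                    "n_lost_in_spplus > 0 requires at least one Sp- group")

    @property
    def focal_cluster(self) -> str | None:
        return self.groups[0].cluster_label if self.groups else None

    def strain_infos(self) -> list[StrainInfo]:
        out = []
        for g in self.groups:
            for i in range(g.n_strains):
                out.append(StrainInfo(f"{g.group_id}-{i + 1:02d}",
                                      g.cluster_label, g.phenotype))
        return out


@dataclass
class PangenomeTruth:
    """Exact planted structure of a generated panel."""

    families: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)
    paralog_pairs: set[tuple[str, str]] = field(default_factory=set)

    def family_ids_with_role(self, role: str) -> list[str]:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return sorted(f for f, r in self.roles.items() if r == role)

    def locus_to_family(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for fid, members in self.families.items():
            for _, locus in members:
                out[locus] = fid
        return out

    def as_member_sets(self) -> set[frozenset[str]]:
        """Families as frozensets of locus ids (id-agnostic comparison)."""
        return {frozenset(l for _, l in m) for m in self.families.values()}


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def mutate_protein(seq: str, divergence: float, seed: int) -> str:
    """Substitute round(divergence * len) positions, chosen uniformly without
    replacement, each to a uniformly drawn different residue."""
    if not (0.0 <= divergence < 1.0):
        raise ValueError(f"divergence must be in [0, 1), got {divergence}")
    if not seq:
        raise ValueError("sequence must be non-empty")
    bad = set(seq) - set(AA20)
    if bad:
        raise ValueError(f"sequence contains non-standard residues: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    n_mut = int(round(divergence * len(seq)))
    if n_mut == 0:
        return seq
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [aa for aa in AA20 if aa != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def _mutate_with_rng(seq: str, divergence: float, rng: np.random.Generator) -> str:
    return mutate_protein(seq, divergence, int(rng.integers(2**31 - 1)))


def generate_pangenome(
    config: PangenomeConfig,
) -> tuple[dict[str, list[ProteinRecord]], PangenomeTruth]:
    """Generate per-strain proteomes and the matching planted truth.

    Deterministic in config.seed: the same config yields byte-identical
    sequences, locus ids and truth tables.
    """
    rng = np.random.default_rng(config.seed)
    infos = config.strain_infos()
    proteomes: dict[str, list[ProteinRecord]] = {s.strain_id: [] for s in infos}
    truth = PangenomeTruth()

    focal = config.focal_cluster
    all_ids = [s.strain_id for s in infos]
    focal_ids = [s.strain_id for s in infos if s.cluster_label == focal]
    spm_ids = [s.strain_id for s in infos if s.phenotype == "Sp-"]

    lo, hi = config.protein_length_range
    div = config.within_family_divergence
    counters = {s: 0 for s in all_ids}

    def new_locus(strain: str) -> str:
        counters[strain] += 1
        return f"{strain}_p{counters[strain]:04d}"

    ancestors: dict[str, str] = {}

    def plant_family(fid: str, role: str, member_strains: list[str]) -> None:
        length = int(rng.integers(lo, hi + 1))
        ancestor = random_protein(length, rng)
        ancestors[fid] = ancestor
        members: set[tuple[str, str]] = set()
        for strain in member_strains:
            locus = new_locus(strain)
            proteomes[strain].append(
                ProteinRecord(strain, locus, _mutate_with_rng(ancestor, div, rng)))
            members.add((strain, locus))
        truth.families[fid] = members
        truth.roles[fid] = role

    fam_counter = 0

    def next_fid() -> str:
        nonlocal fam_counter
        fam_counter += 1
        return f"FAM{fam_counter:05d}"

    role_plans: list[tuple[str, list[str], int]] = [
        ("universal", all_ids, config.n_universal_families),
        ("groupA_core_specific", focal_ids, config.n_groupA_specific_core),
        ("lost_in_spplus", spm_ids, config.n_lost_in_spplus),
    ]
    for role, member_strains, n_fam in role_plans:
        fids = []
        for _ in range(n_fam):
            fid = next_fid()
            plant_family(fid, role, member_strains)
            fids.append(fid)
        # duplicate a fraction of this class in their first member strain
        n_dup = int(round(config.paralog_fraction * len(fids)))
        if n_dup and member_strains:
            dup_fids = sorted(rng.choice(fids, size=n_dup, replace=False))
            for fid in dup_fids:
                strain = min(s for s, _ in truth.families[fid])
                orig_locus = min(l for s, l in truth.families[fid] if s == strain)
                dup_locus = new_locus(strain)
                proteomes[strain].append(
                    ProteinRecord(strain, dup_locus,
                                  _mutate_with_rng(ancestors[fid], div, rng)))
                truth.families[fid].add((strain, dup_locus))
                truth.paralog_pairs.add(tuple(sorted((orig_locus, dup_locus))))

    for strain in all_ids:
        for _ in range(config.n_strain_specific_per_strain):
            fid = next_fid()
            length = int(rng.integers(lo, hi + 1))
            locus = new_locus(strain)
            proteomes[strain].append(
                ProteinRecord(strain, locus, random_protein(length, rng)))
            truth.families[fid] = {(strain, locus)}
            truth.roles[fid] = "strain_specific"

    return proteomes, truth


def generate_genome_pair(length: int, substitution_rate: float,
                         seed: int) -> tuple[str, str]:
    """A random genome and a copy with an exact fraction of substitutions.

    Requires length >= 2040 (two ANI fragments) and rate in [0, 0.3).
    Exactly round(rate * length) positions differ between the two sequences.
    """
    if length < 2040:
        raise ValueError(f"genome length must be >= 2040, got {length}")
    if not (0.0 <= substitution_rate < 0.3):
        raise ValueError(
            f"substitution_rate must be in [0, 0.3), got {substitution_rate}")
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 4, size=length)
    b = a.copy()
    n_sub = int(round(substitution_rate * length))
    if n_sub:
        positions = rng.choice(length, size=n_sub, replace=False)
        shift = rng.integers(1, 4, size=n_sub)
        b[positions] = (b[positions] + shift) % 4
    lut = np.array(list(DNA4))
    return "".join(lut[a]), "".join(lut[b])


# ---------------------------------------------------------------------------
# writers


def write_proteomes(proteomes: dict[str, list[ProteinRecord]],
                    out_dir: str | Path) -> list[Path]:
    """One protein FASTA per strain, headers ``>{strain_id}|{locus_id}``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for strain in sorted(proteomes):
        path = out_dir / f"{strain}.faa"
        with open(path, "w") as fh:
            for rec in proteomes[strain]:
                fh.write(f">{rec.strain_id}|{rec.locus_id}\n{rec.seq}\n")
        paths.append(path)
    return paths


def write_metadata(infos: list[StrainInfo], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("strain_id\tcluster_label\tphenotype\n")
        for s in infos:
            fh.write(f"{s.strain_id}\t{s.cluster_label}\t{s.phenotype}\n")
    return path


def write_truth(truth: PangenomeTruth, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("family_id\trole\tstrain_id\tlocus_id\n")
        for fid in sorted(truth.families):
            for strain, locus in sorted(truth.families[fid]):
                fh.write(f"{fid}\t{truth.roles[fid]}\t{strain}\t{locus}\n")
    return path


def write_genome_fasta(seq: str, genome_id: str, path: str | Path,
                       width: int = 80) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{genome_id}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")
    return path
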