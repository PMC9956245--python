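"""End-to-end analysis: all-vs-all alignment -> families -> presence matrix
-> core / pan / specific core -> lost families -> paralog classification.

The pipeline is deterministic under a fixed configuration; when an output
directory is given every artifact is written as TSV together with a JSON
manifest recording thresholds, seeds and stage record counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .align import SubstitutionMatrix
from .config import PipelineConfig
from .families import (ProteinFamily, all_vs_all_edges, build_families,
                       presence_matrix, write_edges_tsv, write_families_tsv)
from .io import write_family_list, write_presence_matrix
from .pangenome import (GroupDefinition, PresenceMatrix, core_families,
                        lost_families, pan_families, specific_core,
                        strain_unique_counts)
from .paralogs import classify_copy_number, detect_paralogs
from .records import StrainPanel

log = logging.getLogger("sympan")


@dataclass
class PipelineResult:
    families: list[ProteinFamily]
    matrix: PresenceMatrix
    core: list[str]
    pan: list[str]
    specific_core: list[str]
    strain_unique: pd.Series
    lost: list[str]
    paralog_calls: dict[str, list[str]]
    copy_classes: dict[str, str]
    manifest: dict = field(default_factory=dict)


def run_pipeline(panel: StrainPanel, config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full comparative analysis on a strain panel.

    The focal cluster (config.focal_cluster) defines the specific-core
    contrast against all other clusters; the retained/lost phenotypes
    (default Sp- / Sp+) define the lost-family contrast inside the focal
    cluster.  Stages with nothing to compare (e.g. no Sp+ strains) yield
    empty results rather than errors.
    """
    config = config or PipelineConfig()
    if not panel.proteomes:
        raise ValueError("empty strain panel: no proteomes to analyse")
    matrix62 = SubstitutionMatrix.blosum62()
    params = config.alignment_params()

    log.info("stage align: all-vs-all local search")
    edges = all_vs_all_edges(
        panel, matrix62, params,
        min_coverage=config.family_coverage,
        min_similarity=config.family_similarity,
        prefilter_k=config.prefilter_k)

    log.info("stage families: clustering %d edges", len(edges))
    all_loci = [(r.strain_id, r.locus_id) for r in panel.all_records()]
    families = build_families(edges, all_loci)
    pm = presence_matrix(families, panel.metadata)

    focal = GroupDefinition.from_cluster(pm, config.focal_cluster)
    other_labels = sorted({i.cluster_label for i in pm.metadata.values()}
                          - {config.focal_cluster})
    others = [GroupDefinition.from_cluster(pm, lab) for lab in other_labels]

    core = core_families(pm, focal)
    pan = pan_families(pm, focal)
    spec = specific_core(pm, focal, others)
    petals = strain_unique_counts(pm)

    retained_ids = pm.strains_with_phenotype(config.retained_phenotype)
    lost_ids = pm.strains_with_phenotype(config.lost_phenotype)
    lost: list[str] = []
    paralog_calls: dict[str, list[str]] = {}
    copy_classes: dict[str, str] = {}
    if retained_ids and lost_ids:
        retained = GroupDefinition.from_phenotype(pm, config.retained_phenotype)
        lost_grp = GroupDefinition.from_phenotype(pm, config.lost_phenotype)
        lost = lost_families(pm, retained, lost_grp,
                             min_retained_strains=config.min_retained_strains)
        log.info("stage paralogs: %d lost families", len(lost))
        by_locus = panel.record_by_locus()
        fam_by_id = {f.family_id: f for f in families}
        members_by_family: dict[str, list[str]] = {}
        for fid in lost:
            members = [l for s, l in sorted(fam_by_id[fid].members)
                       if s in retained_ids]
            members_by_family[fid] = members
            for locus in members:
                rec = by_locus[locus]
                paralog_calls[locus] = detect_paralogs(
                    rec, panel.proteomes[rec.strain_id], matrix62, params,
                    min_coverage=config.paralog_coverage,
                    min_identity=config.paralog_identity,
                    prefilter_k=config.prefilter_k)
        copy_classes = classify_copy_number(members_by_family, paralog_calls)

    manifest = {
        "config": {k: v for k, v in config.to_dict().items() if k != "paths"},
        "n_strains": len(panel.proteomes),
        "n_proteins": len(all_loci),
        "n_edges": len(edges),
        "n_families": len(families),
        "core_size": len(core),
        "pan_size": len(pan),
        "specific_core_size": len(spec),
        "n_lost_families": len(lost),
        "n_lost_several_copies": sum(
            1 for v in copy_classes.values() if v == "several_copies"),
    }
    result = PipelineResult(
        families=families, matrix=pm, core=core, pan=pan, specific_core=spec,
        strain_unique=petals, lost=lost, paralog_calls=paralog_calls,
        copy_classes=copy_classes, manifest=manifest)
    if out_dir is not None:
        _write_bundle(result, edges, Path(out_dir))
    return result


def _write_bundle(result: PipelineResult, edges, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_edges_tsv(edges, out_dir / "edges.tsv")
    write_families_tsv(result.families, out_dir / "families.tsv")
    write_presence_matrix(result.matrix, out_dir / "presence_matrix.tsv")
    write_family_list(result.core, out_dir / "core_families.tsv")
    write_family_list(result.specific_core, out_dir / "specific_core.tsv")
    write_family_list(result.lost, out_dir / "lost_families.tsv")
    petals = result.strain_unique.rename("n_strain_specific")
    petals.index.name = "strain_id"
    petals.to_csv(out_dir / "flower_counts.tsv", sep="\t")
    with open(out_dir / "copy_classes.tsv", "w") as fh:
        fh.write("family_id\tcopy_class\n")
        for fid in sorted(result.copy_classes):
            fh.write(f"{fid}\t{result.copy_classes[fid]}\n")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
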