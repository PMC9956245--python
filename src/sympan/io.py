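"""Readers and writers for strain panels, plus the GC read filter.

Protein FASTA headers are ``>{strain_id}|{locus_id}``; strain metadata is a
TSV with columns strain_id, cluster_label, phenotype.  The GC filter
removes sequencing reads whose G+C fraction is at or below a cutoff
(default 54%), the signature of plant contamination in a high-GC
actinobacterial assembly; N bases are excluded from the denominator.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .records import ProteinRecord, StrainInfo, StrainPanel

log = logging.getLogger("sympan")


def gc_fraction(seq: str) -> float | None:
    """(G+C) / (A+C+G+T); None when no unambiguous base is present."""
    s = seq.upper()
    denom = sum(s.count(b) for b in "ACGT")
    if denom == 0:
        return None
    return (s.count("G") + s.count("C")) / denom


def gc_read_filter(reads: list[tuple[str, str]],
                   max_gc: float = 0.54) -> tuple[list[tuple[str, str]],
                                                  list[tuple[str, str]]]:
    """Split (id, sequence) reads into (kept, removed).

    A read is removed when its GC fraction is <= max_gc (the boundary is
    removed); empty or all-N reads are removed with a warning.
    """
    kept, removed = [], []
    for read_id, seq in reads:
        gc = gc_fraction(seq)
        if gc is None:
            log.warning("read %s has no unambiguous bases; removed", read_id)
            removed.append((read_id, seq))
        elif gc <= max_gc:
            removed.append((read_id, seq))
        else:
            kept.append((read_id, seq))
    log.info("GC filter (<= %.0f%%): kept %d, removed %d reads",
             100 * max_gc, len(kept), len(removed))
    return kept, removed


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def read_metadata(path: str | Path) -> dict[str, StrainInfo]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("none")
    required = {"strain_id", "cluster_label", "phenotype"}
    if not required <= set(df.columns):
        raise ValueError(
            f"{path}: metadata needs columns {sorted(required)}")
    out = {}
    for row in df.itertuples(index=False):
        if row.strain_id in out:
            raise ValueError(f"{path}: duplicate strain {row.strain_id!r}")
        out[row.strain_id] = StrainInfo(row.strain_id, row.cluster_label,
                                        row.phenotype)
    return out


def read_proteomes(paths: list[str | Path],
                   metadata_path: str | Path) -> StrainPanel:
    """Load per-strain protein FASTAs into a validated panel.

    Headers must be ``strain|locus``; each strain must appear in the
    metadata; locus ids must be unique within a strain.
    """
    metadata = read_metadata(metadata_path)
    proteomes: dict[str, list[ProteinRecord]] = {}
    for path in paths:
        records = read_fasta(path)
        if not records:
            raise ValueError(f"{path}: empty FASTA file")
        for header, seq in records:
            if "|" not in header:
                raise ValueError(
                    f"{path}: header {header!r} is not strain|locus")
            strain, locus = header.split("|", 1)
            if strain not in metadata:
                raise ValueError(
                    f"{path}: strain {strain!r} absent from metadata")
            bucket = proteomes.setdefault(strain, [])
            if any(r.locus_id == locus for r in bucket):
                raise ValueError(f"{path}: duplicate header {header!r}")
            proteomes[strain].append(ProteinRecord(strain, locus, seq))
    return StrainPanel(proteomes=proteomes, metadata=metadata)


def write_reads_fasta(reads: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f">{read_id}\n{seq}\n")


def write_presence_matrix(matrix, path: str | Path) -> None:
    df = matrix.counts.copy()
    df.index.name = "family_id"
    df.to_csv(path, sep="\t")


def write_family_list(family_ids: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\n")
        for fid in family_ids:
            fh.write(fid + "\n")
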