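"""Within-genome paralog detection and lost-family characterization.

A paralog call between two proteins of the same genome requires the best
local alignment to cover more than half of the query's full length with
more than 30% identity over its aligned columns (both strict).  Lost
families are classified "several copies" when at least one retained-genome
member has a detected paralog, else "single copy"; annotation tables
(COG letter, SP/TM localization, curated paralog lists) are consumed as
given labels and summarized.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .align import AlignmentParams, SubstitutionMatrix, local_align
from .records import ProteinRecord

LOCALIZATIONS = ("SP", "TM", "none")

# Single-letter COG functional categories; NI = not in COGs.
COG_LETTERS = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ") | {"NI"}


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated locus of a lost family (labels consumed as given)."""

    locus_id: str
    cog_letter: str  # first letter if several were assigned; "NI" = not in COGs
    product: str = ""
    localization: str = "none"  # SP (secreted) | TM (transmembrane) | none
    listed_paralogs: tuple[str, ...] = ()
    gene_name: str = ""
    cog_category: str = ""

    def __post_init__(self) -> None:
        if self.localization not in LOCALIZATIONS:
            raise ValueError(
                f"{self.locus_id}: localization must be one of {LOCALIZATIONS}")
        if self.cog_letter not in COG_LETTERS:
            raise ValueError(f"{self.locus_id}: unknown COG letter {self.cog_letter!r}")


@dataclass(frozen=True)
class LostFamilySummary:
    total: int
    per_cog: dict[str, int]
    per_cog_percent: dict[str, float]  # one decimal, as reported
    tm_or_sp: int
    tm_or_sp_percent: int  # nearest integer
    with_paralogs: int
    with_paralogs_percent: int  # nearest integer


def detect_paralogs(locus: ProteinRecord, proteome: list[ProteinRecord],
                    matrix: SubstitutionMatrix, params: AlignmentParams,
                    min_coverage: float = 0.50,
                    min_identity: float = 0.30,
                    prefilter_k: int | None = None) -> list[str]:
    """Loci of the same strain paralogous to the query, sorted by id.

    Uses the best (lowest-E-value) local hit per candidate; coverage is the
    best hit's query-span length over the query's full length.  Both
    thresholds are strict, so coverage exactly 50% or identity exactly 30%
    is rejected.  With prefilter_k set, candidates sharing no k-mer with
    the query are skipped before the DP (None = exact, the default).
    """
    if all(r.locus_id != locus.locus_id for r in proteome):
        raise ValueError(f"locus {locus.locus_id!r} not found in the proteome")
    query_words: set[str] | None = None
    if prefilter_k is not None:
        k = prefilter_k
        query_words = {locus.seq[p:p + k] for p in range(len(locus.seq) - k + 1)}
    out = []
    for other in proteome:
        if other.locus_id == locus.locus_id:
            continue
        if other.strain_id != locus.strain_id:
            raise ValueError(
                f"proteome mixes strains: {other.strain_id} vs {locus.strain_id}")
        if query_words is not None:
            k = prefilter_k
            if not any(other.seq[p:p + k] in query_words
                       for p in range(len(other.seq) - k + 1)):
                continue
        hits = local_align(locus, other, matrix, params)
        if not hits:
            continue
        best = hits[0]
        coverage = (best.query_span[1] - best.query_span[0]) / len(locus)
        if coverage > min_coverage and best.identity_fraction > min_identity:
            out.append(other.locus_id)
    return sorted(out)


def classify_copy_number(
    lost_family_members: dict[str, list[str]],
    paralog_calls: dict[str, list[str]],
) -> dict[str, str]:
    """Assign each lost family to "several_copies" or "single_copy".

    lost_family_members maps family id -> retained-genome member loci;
    paralog_calls maps each of those loci -> its detected paralogs.  A
    family has several copies when any member has at least one paralog.
    """
    out = {}
    for fid, members in lost_family_members.items():
        missing = [l for l in members if l not in paralog_calls]
        if missing:
            raise ValueError(
                f"family {fid}: paralog calls missing for {missing[:3]}")
        has = any(paralog_calls[l] for l in members)
        out[fid] = "several_copies" if has else "single_copy"
    return out


def summarize_lost_families(records: list[AnnotationRecord]) -> LostFamilySummary:
    """Counts and percentages over an annotated lost-family table.

    COG percentages are reported to one decimal; the TM-or-SP and
    with-paralog shares to the nearest integer percent, matching the
    precision these statistics are conventionally quoted at.
    """
    if not records:
        raise ValueError("cannot summarize an empty annotation table")
    total = len(records)
    per_cog = Counter(r.cog_letter for r in records)
    tm_or_sp = sum(1 for r in records if r.localization in ("SP", "TM"))
    with_paralogs = sum(1 for r in records if r.listed_paralogs)
    return LostFamilySummary(
        total=total,
        per_cog=dict(sorted(per_cog.items())),
        per_cog_percent={k: round(100.0 * v / total, 1)
                         for k, v in sorted(per_cog.items())},
        tm_or_sp=tm_or_sp,
        tm_or_sp_percent=round(100.0 * tm_or_sp / total),
        with_paralogs=with_paralogs,
        with_paralogs_percent=round(100.0 * with_paralogs / total),
    )


# ---------------------------------------------------------------------------
# annotation table I/O

_COLUMNS = ["cog_letter", "cog_category", "locus_id", "gene_name", "product",
            "paralogs", "localization", "copy_class"]


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read an annotation TSV (columns as written by write_annotations)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for row in df.itertuples(index=False):
        paralogs = tuple(p for p in str(row.paralogs).split(",") if p)
        records.append(AnnotationRecord(
            locus_id=row.locus_id,
            cog_letter=row.cog_letter or "NI",
            product=row.product,
            localization=row.localization or "none",
            listed_paralogs=paralogs,
            gene_name=row.gene_name,
            cog_category=row.cog_category))
    seen = Counter(r.locus_id for r in records)
    dups = [l for l, c in seen.items() if c > 1]
    if dups:
        raise ValueError(f"duplicate locus ids in annotation table: {dups[:5]}")
    return records


def write_annotations(records: list[AnnotationRecord], path: str | Path) -> None:
    rows = [{
        "cog_letter": r.cog_letter, "cog_category": r.cog_category,
        "locus_id": r.locus_id, "gene_name": r.gene_name, "product": r.product,
        "paralogs": ",".join(r.listed_paralogs),
        "localization": r.localization,
        "copy_class": "several_copies" if r.listed_paralogs else "single_copy",
    } for r in records]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def load_lost_family_annotations() -> list[AnnotationRecord]:
    """The packaged 88-family annotation table: protein families carried by
    all six Sp- *Frankia* genomes of cluster Ia but absent from every Sp+
    genome, with COG letter, curated paralog loci and SP/TM localization."""
    ref = resources.files("sympan.data") / "lost_families_annotation.tsv"
    with resources.as_file(ref) as path:
        return read_annotations(path)
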