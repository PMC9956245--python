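"""Homologous protein family construction from all-vs-all local alignment.

Two proteins join the same family when their HSPs (all passing the E-value
threshold) cover at least 80% of the protein length on BOTH sides and their
length-weighted mean similarity fraction exceeds 50%.  Families are the
connected components of the resulting homology graph (single linkage);
proteins with no qualifying partner form singleton families.  Within-strain
edges are allowed, so paralogs can share a family; self-hits never form
edges.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx

from .align import AlignmentParams, LocalHit, SubstitutionMatrix, coverage_fraction, local_align
from .records import ProteinRecord, StrainInfo, StrainPanel


@dataclass(frozen=True)
class HomologyEdge:
    """A qualifying homology relation between two loci."""

    locus_a: str
    locus_b: str
    coverage_a: float
    coverage_b: float
    similarity: float
    best_evalue: float


@dataclass(frozen=True)
class ProteinFamily:
    family_id: str
    members: frozenset[tuple[str, str]]  # (strain_id, locus_id)

    def loci(self) -> frozenset[str]:
        return frozenset(l for _, l in self.members)


def weighted_similarity(hits: list[LocalHit]) -> float:
    """Mean similarity fraction across HSPs, weighted by gap-free columns."""
    total = sum(h.n_columns for h in hits)
    if total == 0:
        return 0.0
    return sum(h.similarity_fraction * h.n_columns for h in hits) / total


def edge_test(hits: list[LocalHit], len_a: int, len_b: int,
              min_coverage: float = 0.80,
              min_similarity: float = 0.50) -> HomologyEdge | None:
    """Apply the coverage / similarity family rule to one protein pair.

    Coverage must reach min_coverage on both proteins (inclusive: "at
    least"); the weighted similarity must exceed min_similarity (strict:
    "over").  Returns None when the pair does not qualify.
    """
    if not hits:
        return None
    cov_a = coverage_fraction(hits, len_a, "query")
    cov_b = coverage_fraction(hits, len_b, "subject")
    if cov_a < min_coverage or cov_b < min_coverage:
        return None
    sim = weighted_similarity(hits)
    if not sim > min_similarity:
        return None
    return HomologyEdge(
        locus_a=hits[0].query_locus, locus_b=hits[0].subject_locus,
        coverage_a=cov_a, coverage_b=cov_b, similarity=sim,
        best_evalue=min(h.evalue for h in hits))


def _kmer_candidate_pairs(records: list[ProteinRecord], k: int = 5,
                          stride: int = 3) -> set[tuple[int, int]]:
    """Index pairs of records sharing at least one k-mer (sampled with a
    stride on both sides).  Used only as a prescreen before the exact DP."""
    buckets: dict[str, list[int]] = {}
    for idx, rec in enumerate(records):
        seen = set()
        for p in range(0, len(rec.seq) - k + 1, stride):
            seen.add(rec.seq[p:p + k])
        for word in seen:
            buckets.setdefault(word, []).append(idx)
    pairs: set[tuple[int, int]] = set()
    for members in buckets.values():
        if len(members) < 2:
            continue
        for i, j in itertools.combinations(members, 2):
            pairs.add((i, j))
    return pairs


def all_vs_all_edges(panel: StrainPanel, matrix: SubstitutionMatrix,
                     params: AlignmentParams,
                     min_coverage: float = 0.80,
                     min_similarity: float = 0.50,
                     prefilter_k: int | None = 5) -> list[HomologyEdge]:
    """Run the all-vs-all local search and return qualifying edges.

    With prefilter_k set (default 5), pairs sharing no sampled k-mer are
    skipped before the DP; pass None for the exhaustive quadratic search.
    Edges are emitted in deterministic (locus_a, locus_b) order.
    """
    records = panel.all_records()
    n = len(records)
    if prefilter_k is None:
        candidates = {(i, j) for i in range(n) for j in range(i + 1, n)}
    else:
        candidates = _kmer_candidate_pairs(records, k=prefilter_k)
    edges = []
    for i, j in sorted(candidates):
        a, b = records[i], records[j]
        hits = local_align(a, b, matrix, params)
        edge = edge_test(hits, len(a), len(b), min_coverage, min_similarity)
        if edge is not None:
            edges.append(edge)
    return edges


def build_families(edges: list[HomologyEdge],
                   all_loci: list[tuple[str, str]]) -> list[ProteinFamily]:
    """Connected components of the homology graph over the locus universe.

    all_loci lists every (strain_id, locus_id); loci with no edges become
    singleton families.  Family ids are the lexicographically smallest
    member locus, so ids are stable across runs.
    """
    strain_of = {locus: strain for strain, locus in all_loci}
    if len(strain_of) != len(all_loci):
        raise ValueError("duplicate locus ids in the locus universe")
    g = nx.Graph()
    g.add_nodes_from(strain_of)
    for e in edges:
        for locus in (e.locus_a, e.locus_b):
            if locus not in strain_of:
                raise ValueError(f"edge references unknown locus {locus!r}")
        if e.locus_a != e.locus_b:
            g.add_edge(e.locus_a, e.locus_b)
    families = []
    for component in nx.connected_components(g):
        fid = min(component)
        families.append(ProteinFamily(
            family_id=fid,
            members=frozenset((strain_of[l], l) for l in component)))
    families.sort(key=lambda f: f.family_id)
    return families


def presence_matrix(families: list[ProteinFamily],
                    metadata: dict[str, StrainInfo]):
    """Family-by-strain member-count matrix with attached metadata."""
    from .pangenome import PresenceMatrix  # local import avoids a cycle
    import pandas as pd

    strains = sorted(metadata)
    counts = pd.DataFrame(0, index=[f.family_id for f in families],
                          columns=strains, dtype=int)
    for fam in families:
        for strain, _ in fam.members:
            if strain not in metadata:
                raise ValueError(f"strain {strain!r} missing from metadata")
            counts.loc[fam.family_id, strain] += 1
    counts.sort_index(inplace=True)
    return PresenceMatrix(counts=counts, metadata=dict(metadata))


def write_families_tsv(families: list[ProteinFamily], path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tstrain_id\tlocus_id\n")
        for fam in sorted(families, key=lambda f: f.family_id):
            for strain, locus in sorted(fam.members):
                fh.write(f"{fam.family_id}\t{strain}\t{locus}\n")


def write_edges_tsv(edges: list[HomologyEdge], path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_a\tlocus_b\tcoverage_a\tcoverage_b\tsimilarity\tbest_evalue\n")
        for e in edges:
            fh.write(f"{e.locus_a}\t{e.locus_b}\t{e.coverage_a:.4f}\t"
                     f"{e.coverage_b:.4f}\t{e.similarity:.4f}\t{e.best_evalue:.3g}\n")
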