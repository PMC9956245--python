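"""Fragment-based average nucleotide identity and species delineation.

Each genome is cut into consecutive non-overlapping 1020-bp fragments
(trailing remainder discarded).  Per direction, every fragment of the
source genome is placed on the target by shared-16-mer diagonal voting and
locally aligned (match +2 / mismatch -3 / gap open 5 / extend 2) to a
window around the candidate position; a fragment is retained when the best
alignment shows >= 30% identity over >= 70% of the fragment length.  The
direction's ANI is the mean percent identity of retained fragments.  Two
genomes belong to the same species when the mean of their two directional
ANI values reaches the 95% threshold; species are the connected components
of that graph.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np

from . import _kernels
from .align import SubstitutionMatrix


@dataclass(frozen=True)
class ANIParams:
    fragment_len: int = 1020
    min_identity: float = 0.30
    min_coverage: float = 0.70
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    seed_k: int = 16
    seed_stride: int = 8
    window_margin: int = 64


@dataclass(frozen=True)
class ANIResult:
    """Direction-specific ANI between two genomes (percent scale).

    ani_ab aligns fragments of genome_a onto genome_b; None marks an
    undefined direction (no fragment passed the retention rule).
    """

    genome_a: str
    genome_b: str
    ani_ab: float | None
    ani_ba: float | None
    n_fragments_ab: int
    n_fragments_ba: int

    def mean(self) -> float | None:
        if self.ani_ab is None or self.ani_ba is None:
            return None
        return (self.ani_ab + self.ani_ba) / 2.0

    def pair(self) -> frozenset[str]:
        return frozenset((self.genome_a, self.genome_b))


def fragment_genome(seq: str, fragment_len: int = 1020) -> list[str]:
    """Consecutive non-overlapping windows; the short tail is discarded."""
    if len(seq) < fragment_len:
        raise ValueError(
            f"sequence of {len(seq)} bp is shorter than one "
            f"{fragment_len}-bp fragment")
    n = len(seq) // fragment_len
    return [seq[i * fragment_len:(i + 1) * fragment_len] for i in range(n)]


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for p in range(len(seq) - k + 1):
        index.setdefault(seq[p:p + k], []).append(p)
    return index


def _best_fragment_alignment(fragment: str, target: str,
                             index: dict[str, list[int]],
                             matrix: SubstitutionMatrix,
                             params: ANIParams) -> tuple[float, float] | None:
    """(identity_fraction, coverage) of the fragment's best local placement."""
    votes: Counter[int] = Counter()
    k = params.seed_k
    for p in range(0, len(fragment) - k + 1, params.seed_stride):
        for tpos in index.get(fragment[p:p + k], ()):
            votes[tpos - p] += 1
    if not votes:
        return None
    diag = max(votes, key=lambda d: (votes[d], -d))
    lo = max(0, diag - params.window_margin)
    hi = min(len(target), diag + len(fragment) + params.window_margin)
    window = target[lo:hi]
    enc_f = matrix.encode(fragment)
    enc_w = matrix.encode(window)
    H, E, F, best, bi, bj = _kernels.sw_affine(
        enc_f, enc_w, matrix.scores, params.gap_open, params.gap_extend,
        np.zeros(len(enc_f), np.bool_), np.zeros(len(enc_w), np.bool_))
    if best <= 0:
        return None
    ai, bjx, ncols = _kernels.sw_traceback(
        H, E, F, enc_f, enc_w, matrix.scores, params.gap_open,
        params.gap_extend, bi, bj,
        np.zeros(len(enc_f), np.bool_), np.zeros(len(enc_w), np.bool_))
    cols_a = ai[:ncols]
    cols_b = bjx[:ncols]
    pair = (cols_a >= 0) & (cols_b >= 0)
    n_pairs = int(pair.sum())
    if n_pairs == 0:
        return None
    ident = int((enc_f[cols_a[pair]] == enc_w[cols_b[pair]]).sum())
    a_used = cols_a[cols_a >= 0]
    coverage = (int(a_used.max()) + 1 - int(a_used.min())) / len(fragment)
    return ident / n_pairs, coverage


def _one_direction(source: str, target: str, matrix: SubstitutionMatrix,
                   params: ANIParams) -> tuple[float | None, int]:
    index = _kmer_index(target, params.seed_k)
    identities = []
    for fragment in fragment_genome(source, params.fragment_len):
        res = _best_fragment_alignment(fragment, target, index, matrix, params)
        if res is None:
            continue
        identity, coverage = res
        if identity >= params.min_identity and coverage >= params.min_coverage:
            identities.append(identity)
    if not identities:
        return None, 0
    return 100.0 * float(np.mean(identities)), len(identities)


def ani_pair(genome_a: tuple[str, str], genome_b: tuple[str, str],
             params: ANIParams | None = None) -> ANIResult:
    """Directional ANI between two (id, sequence) genomes."""
    params = params or ANIParams()
    matrix = SubstitutionMatrix.dna(params.match, params.mismatch)
    id_a, seq_a = genome_a
    id_b, seq_b = genome_b
    ab, n_ab = _one_direction(seq_a.upper(), seq_b.upper(), matrix, params)
    ba, n_ba = _one_direction(seq_b.upper(), seq_a.upper(), matrix, params)
    return ANIResult(id_a, id_b, ab, ba, n_ab, n_ba)


@dataclass(frozen=True)
class SpeciesPartition:
    labels: dict[str, str]  # genome id -> species label

    def species_of(self, genome_id: str) -> str:
        return self.labels[genome_id]

    def groups(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gid, label in self.labels.items():
            out.setdefault(label, set()).add(gid)
        return out


def species_components(results: list[ANIResult],
                       threshold: float = 95.0) -> SpeciesPartition:
    """Species as connected components of the >= threshold mean-ANI graph.

    Each species is labelled by its lexicographically smallest member.
    Duplicate pair entries are rejected.
    """
    seen: set[frozenset[str]] = set()
    g = nx.Graph()
    for r in results:
        key = r.pair()
        if len(key) == 1:
            continue  # self comparisons carry no grouping information
        if key in seen:
            raise ValueError(f"duplicate pair entry: {sorted(key)}")
        seen.add(key)
        g.add_nodes_from(key)
        m = r.mean()
        if m is not None and m >= threshold:
            g.add_edge(r.genome_a, r.genome_b)
    labels: dict[str, str] = {}
    for comp in nx.connected_components(g):
        label = min(comp)
        for gid in comp:
            labels[gid] = label
    return SpeciesPartition(labels=labels)


def ani_matrix(results: list[ANIResult]):
    """Full asymmetric ANI matrix (rows = source, columns = target)."""
    import pandas as pd

    ids = sorted({g for r in results for g in (r.genome_a, r.genome_b)})
    m = pd.DataFrame(np.nan, index=ids, columns=ids)
    for gid in ids:
        m.loc[gid, gid] = 100.0
    for r in results:
        if r.ani_ab is not None:
            m.loc[r.genome_a, r.genome_b] = round(r.ani_ab, 2)
        if r.ani_ba is not None:
            m.loc[r.genome_b, r.genome_a] = round(r.ani_ba, 2)
    return m
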