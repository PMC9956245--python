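"""Pairwise protein alignment: affine-gap Smith-Waterman local search with
Karlin-Altschul E-values, multi-HSP extraction by greedy path masking, and
Needleman-Wunsch global percent identity.

Scoring uses BLOSUM62 by default.  A residue pair is "similar" when its
matrix score is positive; identity and similarity fractions are computed
over gap-free aligned columns only.  E = K*m*n*exp(-lambda*score) with m, n
the full sequence lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from . import _kernels
from .records import ProteinRecord

PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
NUCLEOTIDE_ALPHABET = "ACGTN"


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric residue substitution score matrix over an ordered alphabet."""

    alphabet: str
    scores: np.ndarray  # int16, shape (len(alphabet), len(alphabet))
    name: str = "BLOSUM62"

    def __post_init__(self) -> None:
        n = len(self.alphabet)
        if self.scores.shape != (n, n):
            raise ValueError("score matrix shape does not match alphabet")
        if not np.array_equal(self.scores, self.scores.T):
            raise ValueError("substitution matrix must be symmetric")

    def encoder(self) -> np.ndarray:
        """Maps ASCII byte -> alphabet index, -1 for letters outside it."""
        table = np.full(128, -1, np.int8)
        for i, ch in enumerate(self.alphabet):
            table[ord(ch)] = i
        return table

    def encode(self, seq: str, locus: str = "<seq>") -> np.ndarray:
        table = self.encoder()
        raw = np.frombuffer(seq.encode("ascii"), np.uint8)
        enc = table[raw]
        if (enc < 0).any():
            pos = int(np.nonzero(enc < 0)[0][0])
            raise ValueError(
                f"residue {seq[pos]!r} at position {pos} of {locus} "
                f"is outside the {self.name} alphabet"
            )
        return enc.astype(np.int8)

    def score(self, a: str, b: str) -> int:
        return int(self.scores[self.alphabet.index(a), self.alphabet.index(b)])

    @classmethod
    def blosum62(cls, x_scores_zero: bool = True) -> "SubstitutionMatrix":
        """The standard BLOSUM62 matrix.

        With ``x_scores_zero`` (the package default) the ambiguity code X is
        rescored to 0 against every letter, so unknown residues neither help
        nor hurt an alignment.
        """
        m = substitution_matrices.load("BLOSUM62")
        alphabet = str(m.alphabet)
        arr = np.array(m, dtype=np.int16)
        if x_scores_zero and "X" in alphabet:
            xi = alphabet.index("X")
            arr[xi, :] = 0
            arr[:, xi] = 0
        return cls(alphabet=alphabet, scores=arr, name="BLOSUM62")

    @classmethod
    def from_ncbi_text(cls, path) -> "SubstitutionMatrix":
        """Read a matrix in the standard NCBI text layout."""
        with open(path) as fh:
            m = substitution_matrices.read(fh)
        return cls(alphabet=str(m.alphabet), scores=np.array(m, dtype=np.int16),
                   name=str(getattr(m, "name", "") or "custom"))

    @classmethod
    def dna(cls, match: int = 2, mismatch: int = -3) -> "SubstitutionMatrix":
        """Simple nucleotide matrix; N scores 0 against everything."""
        n = len(NUCLEOTIDE_ALPHABET)
        arr = np.full((n, n), mismatch, np.int16)
        np.fill_diagonal(arr, match)
        ni = NUCLEOTIDE_ALPHABET.index("N")
        arr[ni, :] = 0
        arr[:, ni] = 0
        return cls(alphabet=NUCLEOTIDE_ALPHABET, scores=arr, name="DNA")


@dataclass(frozen=True)
class AlignmentParams:
    """Gap penalties and Karlin-Altschul statistics for the local search.

    Defaults pair BLOSUM62 with gap open 11 / extend 1 and the published
    gapped constants lambda = 0.267, K = 0.041.  A gap of length k costs
    open + k*extend.
    """

    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_K: float = 0.041
    evalue_threshold: float = 1e-4
    max_hsps: int = 8

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.karlin_lambda <= 0 or self.karlin_K <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be positive")


@dataclass(frozen=True)
class LocalHit:
    """One HSP: a maximal-scoring local alignment segment.

    Spans are 0-based half-open on each sequence.  identity_fraction and
    similarity_fraction are computed over gap-free aligned columns; a column
    counts as similar when its substitution score is positive, so every
    identical pair is also similar.
    """

    query_locus: str
    subject_locus: str
    score: int
    evalue: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    identity_fraction: float
    similarity_fraction: float
    n_columns: int  # gap-free aligned columns
    n_gap_opens: int = 0
    alignment_length: int = 0  # columns including gaps


def evalue(score: int, query_len: int, subject_len: int,
           params: AlignmentParams) -> float:
    """Karlin-Altschul expectation K*m*n*exp(-lambda*score)."""
    if query_len <= 0 or subject_len <= 0:
        raise ValueError("sequence lengths must be positive")
    return params.karlin_K * query_len * subject_len * float(
        np.exp(-params.karlin_lambda * score)
    )


def _columns_to_hit(ai: np.ndarray, bj: np.ndarray, k: int,
                    enc_a: np.ndarray, enc_b: np.ndarray,
                    scores: np.ndarray) -> dict:
    """Summarize traceback columns (reverse order) into hit statistics."""
    cols_a = ai[:k][::-1]
    cols_b = bj[:k][::-1]
    pair = (cols_a >= 0) & (cols_b >= 0)
    n_cols = int(pair.sum())
    if n_cols:
        ra = enc_a[cols_a[pair]]
        rb = enc_b[cols_b[pair]]
        ident = int((ra == rb).sum())
        simil = int((scores[ra, rb] > 0).sum())
    else:
        ident = simil = 0
    gap_flags = ~pair
    n_gap_opens = int(((gap_flags) & ~np.concatenate(([False], gap_flags[:-1]))).sum())
    a_used = cols_a[cols_a >= 0]
    b_used = cols_b[cols_b >= 0]
    return {
        "query_span": (int(a_used.min()), int(a_used.max()) + 1),
        "subject_span": (int(b_used.min()), int(b_used.max()) + 1),
        "identity": ident,
        "similarity": simil,
        "n_columns": n_cols,
        "n_gap_opens": n_gap_opens,
        "alignment_length": k,
        "a_positions": a_used,
        "b_positions": b_used,
    }


def local_align(a: ProteinRecord, b: ProteinRecord, matrix: SubstitutionMatrix,
                params: AlignmentParams) -> list[LocalHit]:
    """All HSPs between two sequences passing the E-value threshold.

    The optimal local alignment is found first; its path positions are then
    masked on both sequences and the DP re-run, yielding non-overlapping
    suboptimal HSPs, until the next HSP fails the threshold or max_hsps is
    reached.  Hits are returned sorted by ascending E-value (score as the
    tie-break).
    """
    if not a.seq or not b.seq:
        raise ValueError("cannot align empty sequences")
    enc_a = matrix.encode(a.seq, a.locus_id)
    enc_b = matrix.encode(b.seq, b.locus_id)
    mask_a = np.zeros(len(enc_a), np.bool_)
    mask_b = np.zeros(len(enc_b), np.bool_)
    hits: list[LocalHit] = []
    for _ in range(params.max_hsps):
        H, E, F, best, bi, bj = _kernels.sw_affine(
            enc_a, enc_b, matrix.scores, params.gap_open, params.gap_extend,
            mask_a, mask_b)
        if best <= 0:
            break
        ev = evalue(best, len(enc_a), len(enc_b), params)
        if ev > params.evalue_threshold:
            break
        ai, bjx, k = _kernels.sw_traceback(
            H, E, F, enc_a, enc_b, matrix.scores, params.gap_open,
            params.gap_extend, bi, bj, mask_a, mask_b)
        info = _columns_to_hit(ai, bjx, k, enc_a, enc_b, matrix.scores)
        hits.append(LocalHit(
            query_locus=a.locus_id, subject_locus=b.locus_id,
            score=int(best), evalue=ev,
            query_span=info["query_span"], subject_span=info["subject_span"],
            identity_fraction=info["identity"] / max(info["n_columns"], 1),
            similarity_fraction=info["similarity"] / max(info["n_columns"], 1),
            n_columns=info["n_columns"], n_gap_opens=info["n_gap_opens"],
            alignment_length=info["alignment_length"]))
        mask_a[info["a_positions"]] = True
        mask_b[info["b_positions"]] = True
    hits.sort(key=lambda h: (h.evalue, -h.score))
    return hits


def local_best_score(a_seq: str, b_seq: str, matrix: SubstitutionMatrix,
                     params: AlignmentParams) -> int:
    """Optimal local alignment score only (no threshold, no traceback)."""
    enc_a = matrix.encode(a_seq)
    enc_b = matrix.encode(b_seq)
    mask = np.zeros(0, np.bool_)
    _, _, _, best, _, _ = _kernels.sw_affine(
        enc_a, enc_b, matrix.scores, params.gap_open, params.gap_extend,
        np.zeros(len(enc_a), np.bool_), np.zeros(len(enc_b), np.bool_))
    del mask
    return int(best)


def coverage_fraction(hits: list[LocalHit], protein_len: int,
                      side: str = "query") -> float:
    """Fraction of the protein covered by the union of HSP spans on one side."""
    if side not in ("query", "subject"):
        raise ValueError(f"side must be 'query' or 'subject', got {side!r}")
    if not hits:
        return 0.0
    spans = sorted(h.query_span if side == "query" else h.subject_span
                   for h in hits)
    for lo, hi in spans:
        if lo < 0 or hi > protein_len:
            raise ValueError(f"span ({lo}, {hi}) outside [0, {protein_len})")
    covered = 0
    cur_lo, cur_hi = spans[0]
    for lo, hi in spans[1:]:
        if lo > cur_hi:
            covered += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    covered += cur_hi - cur_lo
    return covered / protein_len


@dataclass(frozen=True)
class GlobalAlignment:
    score: int
    n_identical: int
    n_pair_columns: int  # gap-free aligned columns
    alignment_length: int

    @property
    def percent_identity(self) -> float:
        if self.n_pair_columns == 0:
            return 0.0
        return round(100.0 * self.n_identical / self.n_pair_columns, 2)

    @property
    def percent_identity_full_length(self) -> float:
        """Alternative denominator: all alignment columns including gaps."""
        if self.alignment_length == 0:
            return 0.0
        return round(100.0 * self.n_identical / self.alignment_length, 2)


def global_align(a_seq: str, b_seq: str, matrix: SubstitutionMatrix,
                 params: AlignmentParams) -> GlobalAlignment:
    if not a_seq or not b_seq:
        raise ValueError("cannot globally align an empty sequence")
    enc_a = matrix.encode(a_seq)
    enc_b = matrix.encode(b_seq)
    score, ai, bjx, k = _kernels.nw_affine(
        enc_a, enc_b, matrix.scores, params.gap_open, params.gap_extend)
    cols_a = ai[:k]
    cols_b = bjx[:k]
    pair = (cols_a >= 0) & (cols_b >= 0)
    ra = enc_a[cols_a[pair]]
    rb = enc_b[cols_b[pair]]
    return GlobalAlignment(score=int(score), n_identical=int((ra == rb).sum()),
                           n_pair_columns=int(pair.sum()), alignment_length=k)


def global_percent_identity(a: ProteinRecord | str, b: ProteinRecord | str,
                            matrix: SubstitutionMatrix,
                            params: AlignmentParams,
                            include_gaps: bool = False) -> float:
    """Percent identity of the optimal global alignment, two decimals.

    By default identities are divided by gap-free aligned columns; with
    ``include_gaps`` the denominator is the full alignment length.
    """
    a_seq = a.seq if isinstance(a, ProteinRecord) else a
    b_seq = b.seq if isinstance(b, ProteinRecord) else b
    aln = global_align(a_seq, b_seq, matrix, params)
    return aln.percent_identity_full_length if include_gaps else aln.percent_identity


def hits_to_table(hits: list[LocalHit]):
    """Hits as a 12-column tabular DataFrame (1-based inclusive coordinates)."""
    import pandas as pd

    rows = []
    for h in hits:
        rows.append({
            "query": h.query_locus, "subject": h.subject_locus,
            "pident": round(100.0 * h.identity_fraction, 2),
            "length": h.alignment_length,
            "mismatches": h.n_columns - round(h.identity_fraction * h.n_columns),
            "gapopens": h.n_gap_opens,
            "qstart": h.query_span[0] + 1, "qend": h.query_span[1],
            "sstart": h.subject_span[0] + 1, "send": h.subject_span[1],
            "evalue": h.evalue, "score": h.score,
        })
    cols = ["query", "subject", "pident", "length", "mismatches", "gapopens",
            "qstart", "qend", "sstart", "send", "evalue", "score"]
    return pd.DataFrame(rows, columns=cols)
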