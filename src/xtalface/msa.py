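"""Multiple sequence alignments: reading, weighting, diversity, polishing.

Alignments live on the 21-state alphabet (20 amino acids + gap).  Sequence
weights follow the usual redundancy-downweighting scheme: a sequence's weight
is the reciprocal of the number of alignment members within the identity
threshold, and the sum of weights is the number of effective non-redundant
clusters.  Coupling analysis is only meaningful when that cluster count
reaches the query length (the diversity criterion); when it fails, the
clustering threshold is escalated in 1% steps up to 80%.

Alignment polishing removes the sequences most distant from the query, one at
a time in ascending identity order, stopping before the diversity criterion
would break.  This suppresses noise from distant homologs whose oligomeric
state differs from the query's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import AlignIO

__all__ = [
    "ALPHABET",
    "Alignment",
    "DiversityReport",
    "read_alignment",
    "write_fasta",
    "sequence_weights",
    "pairwise_identity_matrix",
    "check_diversity",
    "polish_alignment",
]

# 21-state alphabet: canonical amino-acid order then gap
ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"
GAP = 20
_CODE = {c: i for i, c in enumerate(ALPHABET)}


def encode(seq: str) -> np.ndarray:
    """Encode one sequence row; non-standard residues map to gap."""
    return np.array([_CODE.get(c, GAP) for c in seq.upper()], dtype=np.int8)


def decode(row: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in row)


@dataclass
class Alignment:
    ids: list
    matrix: np.ndarray                 # (n_seq, L) int8 codes into ALPHABET
    query_index: int = 0
    weights: Optional[np.ndarray] = None
    # column indices where a new chain block starts (for concatenated
    # hetero-oligomer alignments); empty for monomers/homomers
    chain_boundaries: list = field(default_factory=list)

    @property
    def n_seq(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def query(self) -> np.ndarray:
        return self.matrix[self.query_index]

    def query_sequence(self) -> str:
        return decode(self.query)

    def subset(self, rows) -> "Alignment":
        rows = np.asarray(rows)
        new_q = int(np.where(rows == self.query_index)[0][0])
        return Alignment(
            [self.ids[i] for i in rows], self.matrix[rows].copy(),
            new_q, None, list(self.chain_boundaries))


def _normalize(ids: list, seqs: list, query_index: int,
               chain_boundaries: list) -> Alignment:
    lens = {len(s) for s in seqs}
    if len(lens) != 1:
        raise ValueError(f"ragged alignment after normalization: "
                         f"row lengths {sorted(lens)}")
    mat = np.stack([encode(s) for s in seqs])
    # columns are defined by the query's match states: drop query-gap columns
    keep = mat[query_index] != GAP
    mat = mat[:, keep]
    return Alignment(ids, mat, query_index,
                     chain_boundaries=list(chain_boundaries))


def read_alignment(path, format: str = "auto", query_index: int = 0,
                   chain_boundaries: Optional[list] = None) -> Alignment:
    """Read an aligned FASTA, A3M or Stockholm file.

    A3M lowercase insertion states (and '.') are removed so that columns are
    the query's match states; for the other formats any column gapped in the
    query is dropped for the same reason.  Non-standard residue letters map
    to the gap state.
    """
    path = Path(path)
    if format == "auto":
        suffix = path.suffix.lower()
        format = {".a3m": "a3m", ".sto": "stockholm",
                  ".stk": "stockholm", ".stockholm": "stockholm"}.get(
            suffix, "fasta")
    if format == "a3m":
        ids, seqs = [], []
        cur = None
        for line in path.read_text().splitlines():
            if line.startswith(">"):
                ids.append(line[1:].split()[0] if line[1:].strip() else "")
                seqs.append([])
                cur = seqs[-1]
            elif line.strip():
                if cur is None:
                    raise ValueError(f"{path}: sequence before header")
                cur.append("".join(c for c in line.strip()
                                   if not c.islower() and c != "."))
        seqs = ["".join(s) for s in seqs]
    elif format in ("fasta", "stockholm"):
        aln = AlignIO.read(str(path), format)
        ids = [rec.id for rec in aln]
        seqs = [str(rec.seq).replace(".", "-") for rec in aln]
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return _normalize(ids, seqs, query_index, chain_boundaries or [])


def write_fasta(a: Alignment, path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(a.ids, a.matrix):
            fh.write(f">{name}\n{decode(row)}\n")


# ---------------------------------------------------------------------------
# Weighting and diversity


def pairwise_identity_matrix(a: Alignment) -> np.ndarray:
    """Fractional pairwise identity over columns where both rows are
    non-gap; pairs with no comparable column have identity 0."""
    mat = a.matrix
    n, L = mat.shape
    onehot = np.zeros((n, L * 20), dtype=np.float32)
    nongap = (mat != GAP)
    rows, cols = np.nonzero(nongap)
    onehot[rows, cols * 20 + mat[rows, cols]] = 1.0
    matches = onehot @ onehot.T
    comparable = nongap.astype(np.float32) @ nongap.astype(np.float32).T
    with np.errstate(divide="ignore", invalid="ignore"):
        ident = np.where(comparable > 0, matches / comparable, 0.0)
    return ident


@dataclass
class DiversityReport:
    n_sequences: int
    n_clusters: float
    threshold_used: float       # percent identity
    passes: bool


def sequence_weights(a: Alignment, identity_threshold: float = 62.0,
                     identity: Optional[np.ndarray] = None
                     ) -> tuple:
    """Set redundancy weights at the given clustering threshold.

    ``weight(s) = 1 / |{t : identity(s, t) >= threshold}|`` (s counts
    itself), and the effective cluster count is the weight sum.  Returns the
    alignment (weights set in place) and a :class:`DiversityReport`.
    """
    if not 0.0 < identity_threshold < 100.0:
        raise ValueError("identity threshold must be in (0, 100)")
    if identity is None:
        identity = pairwise_identity_matrix(a)
    counts = (identity >= identity_threshold / 100.0 - 1e-12).sum(axis=1)
    a.weights = 1.0 / counts
    n_clusters = float(a.weights.sum())
    return a, DiversityReport(a.n_seq, n_clusters, identity_threshold,
                              n_clusters >= a.length)


def check_diversity(a: Alignment, start_threshold: float = 62.0,
                    max_threshold: float = 80.0, step: float = 1.0,
                    identity: Optional[np.ndarray] = None
                    ) -> DiversityReport:
    """Diversity criterion with threshold escalation.

    The criterion requires at least as many non-redundant sequence clusters
    as alignment columns.  On failure the clustering threshold rises by
    ``step`` percent up to ``max_threshold``; the report carries the last
    threshold tried.  ``passes=False`` is a valid outcome.
    """
    if start_threshold > max_threshold:
        raise ValueError("start_threshold must not exceed max_threshold")
    if identity is None:
        identity = pairwise_identity_matrix(a)
    thr = start_threshold
    while True:
        _, report = sequence_weights(a, thr, identity=identity)
        if report.passes or thr >= max_threshold:
            return report
        thr = min(thr + step, max_threshold)


def polish_alignment(a: Alignment, identity_floor: float,
                     start_threshold: float = 62.0,
                     max_threshold: float = 80.0) -> Alignment:
    """Remove the sequences most distant from the query while the diversity
    criterion holds.

    Candidates are the non-query sequences with identity-to-query below
    ``identity_floor`` (percent), removed one at a time in ascending
    identity order; removal stops before the first deletion that would break
    the criterion.  If even the first removal breaks it, the input is
    returned unchanged with a warning.
    """
    ident_to_query = pairwise_identity_matrix(a)[a.query_index]
    order = np.argsort(ident_to_query, kind="stable")
    candidates = [int(i) for i in order
                  if i != a.query_index
                  and ident_to_query[i] < identity_floor / 100.0]
    keep = np.ones(a.n_seq, dtype=bool)
    current = a
    removed = 0
    for i in candidates:
        keep[i] = False
        trial = a.subset(np.nonzero(keep)[0])
        if check_diversity(trial, start_threshold, max_threshold).passes:
            current = trial
            removed += 1
        else:
            keep[i] = True
            break
    if removed == 0:
        if candidates:
            warnings.warn("polishing would break the diversity criterion; "
                          "alignment returned unchanged")
        return a
    return current
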