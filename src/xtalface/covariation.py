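"""Covariation scores between alignment columns.

The built-in scorer is of the shrinkage inverse-covariance family: weighted,
pseudocounted single and pair frequencies build the 21L x 21L covariance
matrix ``C_ij(a,b) = f_ij(a,b) - f_i(a) f_j(b)``, which is shrunk toward its
diagonal just enough to become positive definite and then inverted.  The
off-diagonal 21x21 blocks of the precision matrix are the raw couplings;
each block is reduced to one score per column pair by the L2,1 norm (sum of
row Euclidean norms) or the Frobenius norm over the 20x20 non-gap sub-block,
and the score matrix is corrected by the Average Product Correction (APC) to
remove background from phylogeny and column entropy.  For concatenated
hetero-oligomer alignments the APC is applied block-wise: separately within
each chain block and on each inter-chain rectangle, so the inter-chain
background is not polluted by the (much stronger) intra-chain statistics.

External PSICOV (sparse ``i j 0 8 score`` lines) and CCMpred (dense L x L
matrix) score files can be ingested in place of the built-in scorer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import linalg

from .msa import GAP, Alignment

__all__ = [
    "ColumnStats",
    "CouplingMatrix",
    "column_stats",
    "invcov_couplings",
    "pair_score",
    "apc",
    "compute_couplings",
    "read_psicov_scores",
    "read_ccmpred_scores",
    "write_coupling_tsv",
    "read_coupling_tsv",
    "rank_of_pair",
]

N_STATES = 21


@dataclass
class ColumnStats:
    """Weighted, pseudocounted column statistics of an alignment."""

    singles: np.ndarray        # (L, 21), rows sum to 1
    pair: np.ndarray           # (21L, 21L) pair frequencies (off-diag blocks)
    n_eff: float               # sum of sequence weights
    length: int


@dataclass
class CouplingMatrix:
    """Symmetric L x L coupling scores; NaN marks unscored pairs."""

    scores: np.ndarray
    method: str                              # builtin_invcov | psicov_file | ccmpred_file
    apc_applied: bool = False
    block_structure: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def score(self, i: int, j: int) -> float:
        return float(self.scores[i, j])


def column_stats(a: Alignment, pseudocount_weight: float = 0.2
                 ) -> ColumnStats:
    """Weighted single/pair frequencies mixed with a uniform pseudocount.

    ``f = (1 - lam) * empirical + lam / 21`` for singles and ``lam / 441``
    for pairs, which keeps pair marginals consistent with singles.
    """
    if a.length == 0:
        raise ValueError("empty alignment")
    if a.weights is None:
        raise ValueError("alignment weights not set; run sequence_weights "
                         "first")
    lam = pseudocount_weight
    n, L = a.matrix.shape
    w = np.asarray(a.weights, dtype=np.float64)
    n_eff = float(w.sum())

    onehot = np.zeros((n, L * N_STATES), dtype=np.float64)
    rows = np.repeat(np.arange(n), L)
    cols = (np.tile(np.arange(L), n) * N_STATES
            + a.matrix.reshape(-1).astype(np.int64))
    onehot[rows, cols] = 1.0

    singles = (w[:, None] * onehot).sum(axis=0).reshape(L, N_STATES) / n_eff
    pair = (onehot.T * w) @ onehot / n_eff

    singles = (1.0 - lam) * singles + lam / N_STATES
    pair = (1.0 - lam) * pair + lam / (N_STATES * N_STATES)
    return ColumnStats(singles, pair, n_eff, L)


def invcov_couplings(stats: ColumnStats, shrinkage_start: float = 0.005,
                     shrinkage_factor: float = 2.0,
                     normalize: str = "pcorr") -> np.ndarray:
    """Coupling blocks from the shrunk inverse covariance matrix.

    Returns the precision matrix reshaped to ``(L, 21, L, 21)``; the
    ``[i, :, j, :]`` blocks for i != j are the couplings.  Shrinkage
    ``C <- (1 - rho) C + rho diag(C)`` escalates geometrically from
    ``shrinkage_start`` until the matrix is positive definite.

    With ``normalize="pcorr"`` (default) precision entries are scaled to
    partial correlations, ``theta_ij(a,b) / sqrt(theta_ii(a,a)
    theta_jj(b,b))``, which pins coupling norms to a bounded scale on which
    strong couplings score O(1) and noise stays well below 0.1 - the scale
    the covariation-count thresholds assume.  ``normalize="none"`` returns
    the raw precision entries.
    """
    if normalize not in ("pcorr", "none"):
        raise ValueError(f"unknown normalization {normalize!r}")
    L, q = stats.length, N_STATES
    f = stats.singles.reshape(L * q)
    C = stats.pair - np.outer(f, f)
    # diagonal blocks are the single-column covariances, not pair counts
    for i in range(L):
        sl = slice(i * q, (i + 1) * q)
        fi = stats.singles[i]
        C[sl, sl] = np.diag(fi) - np.outer(fi, fi)

    d = np.diag(C).copy()
    rho = shrinkage_start
    while rho <= 1.0:
        S = (1.0 - rho) * C
        S[np.diag_indices_from(S)] = d  # (1-rho) d + rho d
        try:
            cho = linalg.cho_factor(S, check_finite=False)
            theta = linalg.cho_solve(cho, np.eye(L * q), check_finite=False)
            blocks = theta.reshape(L, q, L, q)
            if normalize == "pcorr":
                d_th = np.sqrt(np.einsum("iaia->ia", blocks))
                blocks = blocks / (d_th[:, :, None, None]
                                   * d_th[None, None, :, :])
            return blocks
        except np.linalg.LinAlgError:
            rho *= shrinkage_factor
    raise np.linalg.LinAlgError(
        "covariance matrix not positive definite even at full shrinkage; "
        "alignment is degenerate")


def pair_score(blocks: np.ndarray, norm: str = "l21") -> np.ndarray:
    """Reduce 21x21 coupling blocks to a symmetric L x L score matrix.

    The norm runs over the 20x20 non-gap sub-block.  The L2,1 norm (sum of
    row norms) is not transpose-invariant, so the symmetrized mean of the
    (i, j) and (j, i) block scores is reported; the Frobenius norm is
    transpose-invariant and unaffected.
    """
    if norm not in ("l21", "frobenius"):
        raise ValueError(f"unknown norm {norm!r}")
    L = blocks.shape[0]
    sub = blocks[:, :GAP, :, :GAP]  # drop the gap state
    if norm == "frobenius":
        raw = np.sqrt((sub ** 2).sum(axis=(1, 3)))
    else:
        raw = np.sqrt((sub ** 2).sum(axis=3)).sum(axis=1)
    raw = 0.5 * (raw + raw.T)
    np.fill_diagonal(raw, 0.0)
    return raw


def _apc_region(m: np.ndarray) -> np.ndarray:
    """APC on a square symmetric region.

    Full-matrix means (diagonal included) so that any exact product
    structure ``m = a a^T`` is annihilated identically; score matrices from
    :func:`pair_score` carry a zero diagonal, which simply enters the means.
    """
    L = m.shape[0]
    if L < 2:
        return np.zeros_like(m)
    row_mean = m.mean(axis=1)
    grand = m.mean()
    if grand == 0.0:
        return m.copy()
    out = m - np.outer(row_mean, row_mean) / grand
    np.fill_diagonal(out, 0.0)
    return out


def _apc_rect(m: np.ndarray) -> np.ndarray:
    """APC on a rectangular inter-chain region."""
    row_mean = m.mean(axis=1)
    col_mean = m.mean(axis=0)
    grand = m.mean()
    if grand == 0.0:
        return m.copy()
    return m - np.outer(row_mean, col_mean) / grand


def apc(raw: np.ndarray, block_structure: Optional[list] = None
        ) -> CouplingMatrix:
    """Average Product Correction, block-wise for hetero-oligomer MSAs.

    ``corrected(i, j) = raw(i, j) - mean_i * mean_j / mean_all``.  With chain
    boundaries present, the correction is computed separately within each
    intra-chain square and on each inter-chain rectangle; a single global
    region is used otherwise.  A region with zero mean is passed through
    uncorrected (nothing to remove; flagged by ``apc_applied`` staying True
    with the region untouched).
    """
    if not np.allclose(raw, raw.T, equal_nan=True):
        raise ValueError("raw score matrix must be symmetric")
    L = raw.shape[0]
    bounds = sorted(b for b in (block_structure or []) if 0 < b < L)
    edges = [0] + bounds + [L]
    out = np.zeros_like(raw, dtype=float)
    for bi in range(len(edges) - 1):
        ri = slice(edges[bi], edges[bi + 1])
        for bj in range(bi, len(edges) - 1):
            rj = slice(edges[bj], edges[bj + 1])
            if bi == bj:
                out[ri, rj] = _apc_region(raw[ri, rj])
            else:
                corrected = _apc_rect(raw[ri, rj])
                out[ri, rj] = corrected
                out[rj, ri] = corrected.T
    return CouplingMatrix(out, "builtin_invcov", apc_applied=True,
                          block_structure=bounds)


def compute_couplings(a: Alignment, pseudocount_weight: float = 0.2,
                      norm: str = "l21") -> CouplingMatrix:
    """Full built-in pipeline: statistics -> inverse covariance -> norm ->
    block-wise APC (blocks from the alignment's chain boundaries)."""
    stats = column_stats(a, pseudocount_weight)
    blocks = invcov_couplings(stats)
    raw = pair_score(blocks, norm)
    return apc(raw, a.chain_boundaries)


# ---------------------------------------------------------------------------
# External score files


def read_psicov_scores(path, length: int) -> CouplingMatrix:
    """PSICOV output: whitespace-separated ``i j 0 8 score`` lines, 1-based
    column indices.  Unlisted pairs carry NaN ("no score")."""
    scores = np.full((length, length), np.nan)
    np.fill_diagonal(scores, 0.0)
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) < 5:
            raise ValueError(f"{path}:{ln}: expected 'i j _ _ score'")
        i, j = int(parts[0]), int(parts[1])
        v = float(parts[4])
        if i == j:
            raise ValueError(f"{path}:{ln}: self-pair {i}")
        if not (1 <= i <= length and 1 <= j <= length):
            raise ValueError(f"{path}:{ln}: index out of range for L={length}")
        scores[i - 1, j - 1] = v
        scores[j - 1, i - 1] = v
    return CouplingMatrix(scores, "psicov_file", apc_applied=True)


def read_ccmpred_scores(path) -> CouplingMatrix:
    """CCMpred output: dense whitespace-separated L x L matrix."""
    m = np.loadtxt(path)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: not a square matrix")
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    return CouplingMatrix(m, "ccmpred_file", apc_applied=True)


def write_coupling_tsv(cm: CouplingMatrix, path) -> None:
    """Native TSV dump: 1-based ``i j score apc_flag`` for scored i < j."""
    with open(path, "w") as fh:
        fh.write(f"# method={cm.method} L={cm.length} "
                 f"blocks={','.join(map(str, cm.block_structure)) or '-'}\n")
        fh.write("i\tj\tscore\tapc\n")
        flag = int(cm.apc_applied)
        L = cm.length
        for i in range(L):
            for j in range(i + 1, L):
                v = cm.scores[i, j]
                if np.isnan(v):
                    continue
                fh.write(f"{i + 1}\t{j + 1}\t{v:.8g}\t{flag}\n")


def read_coupling_tsv(path) -> CouplingMatrix:
    lines = Path(path).read_text().splitlines()
    header = lines[0]
    meta = dict(part.split("=", 1) for part in header[1:].split())
    L = int(meta["L"])
    blocks = ([] if meta.get("blocks", "-") == "-"
              else [int(x) for x in meta["blocks"].split(",")])
    scores = np.full((L, L), np.nan)
    np.fill_diagonal(scores, 0.0)
    apc_flag = False
    for line in lines[2:]:
        i, j, v, fl = line.split("\t")
        scores[int(i) - 1, int(j) - 1] = float(v)
        scores[int(j) - 1, int(i) - 1] = float(v)
        apc_flag = bool(int(fl))
    return CouplingMatrix(scores, meta.get("method", "builtin_invcov"),
                          apc_flag, blocks)


NO_RANK = -1


def rank_of_pair(cm: CouplingMatrix, i: int, j: int) -> tuple:
    """Descending 1-based rank of pair (i, j) among all scored pairs and the
    rank normalized by alignment length.

    Ties break lexicographically by (i, j).  Unscored pairs return
    ``(NO_RANK, NO_RANK)``.
    """
    if i == j:
        raise ValueError("rank of a diagonal entry is undefined")
    a, b = (i, j) if i < j else (j, i)
    if np.isnan(cm.scores[a, b]):
        return NO_RANK, NO_RANK
    iu, ju = np.triu_indices(cm.length, k=1)
    vals = cm.scores[iu, ju]
    scored = ~np.isnan(vals)
    order = sorted(
        ((-vals[k], int(iu[k]), int(ju[k])) for k in np.nonzero(scored)[0]))
    pos = order.index((-cm.scores[a, b], a, b)) + 1
    return pos, pos / cm.length
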