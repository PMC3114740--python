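"""Character-by-character comparison of two topologies.

The Templeton test is a two-tailed Wilcoxon signed-rank test on the per-
character weighted length differences between the trees; the winning-sites
test is an exact two-tailed binomial sign test on the same differences.
Characters of equal length on both trees are excluded.  For small samples
(n <= 20 nonzero differences) the Templeton null distribution is enumerated
exactly over all sign assignments (midranks for tied magnitudes); beyond that
a normal approximation with tie-corrected variance and continuity correction
is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .matrix_io import CharacterMatrix, MatrixError
from .parsimony import PackedMatrix, WeightScheme
from .tree import PhyloTree

__all__ = [
    "PairwiseDiff",
    "per_character_diffs",
    "templeton_test",
    "winning_sites_test",
]

EXACT_LIMIT = 20


@dataclass
class PairwiseDiff:
    per_char_delta: np.ndarray  # weighted length on tree B - tree A
    n_nonzero: int


def per_character_diffs(
    matrix: CharacterMatrix,
    weights: WeightScheme,
    tree_a: PhyloTree,
    tree_b: PhyloTree,
) -> PairwiseDiff:
    if set(tree_a.tip_labels()) != set(tree_b.tip_labels()):
        raise MatrixError("trees must share an identical tip set")
    packed = PackedMatrix(matrix)
    w = weights.weights_for(matrix)
    delta = (packed.per_char_lengths(tree_b) - packed.per_char_lengths(tree_a)) * w
    return PairwiseDiff(
        per_char_delta=delta, n_nonzero=int(np.sum(np.abs(delta) > 1e-12))
    )


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """PMF of W+ over all 2^n sign assignments; ranks doubled to integers.

    Returns an array p where p[s] = P(W+ = s) on the doubled-rank scale.
    """
    total = int(ranks2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in ranks2:
        r = int(r)
        nxt = pmf.copy()
        nxt[r:] += pmf[: total + 1 - r]
        pmf = nxt / 2.0
    return pmf


def templeton_test(diffs: PairwiseDiff) -> tuple[float, float]:
    """Two-tailed Wilcoxon signed-rank test on nonzero per-character deltas.

    Returns (W+, p).  With no nonzero differences the trees are
    indistinguishable and p = 1.
    """
    delta = diffs.per_char_delta
    nz = delta[np.abs(delta) > 1e-12]
    n = len(nz)
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(nz))  # midranks for ties
    w_plus = float(ranks[nz > 0].sum())
    expect = n * (n + 1) / 4.0
    if n <= EXACT_LIMIT:
        ranks2 = np.round(ranks * 2).astype(int)
        pmf = _signed_rank_distribution(ranks2)
        obs2 = int(round(w_plus * 2))
        dev = abs(obs2 - 2 * expect)
        hi = 2 * expect + dev
        lo = 2 * expect - dev
        scale = np.arange(len(pmf))
        p = float(pmf[scale >= hi - 1e-9].sum() + pmf[scale <= lo + 1e-9].sum())
        return w_plus, min(p, 1.0)
    # normal approximation with tie correction and continuity correction
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        ((counts**3 - counts) / 48.0).sum()
    )
    dev = abs(w_plus - expect)
    z = max(dev - 0.5, 0.0) / np.sqrt(var)
    return w_plus, float(2 * stats.norm.sf(z))


def winning_sites_test(diffs: PairwiseDiff) -> float:
    """Exact two-tailed binomial sign test on nonzero per-character deltas."""
    delta = diffs.per_char_delta
    nz = delta[np.abs(delta) > 1e-12]
    n = len(nz)
    if n == 0:
        return 1.0
    k = int(np.sum(nz > 0))
    return float(stats.binomtest(k, n, p=0.5, alternative="two-sided").pvalue)
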