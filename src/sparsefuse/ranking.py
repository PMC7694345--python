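"""Nonparametric ranking of fusion methods across datasets and metrics.

Given a table of quality scores (methods x blocks, where each block is one
dataset-metric combination and higher scores are better), this module
computes within-block average ranks, the tie-corrected Friedman chi-square
omnibus test, and the post-hoc Nemenyi critical difference (CD): two
methods whose mean ranks differ by more than

    CD = q_alpha(k) * sqrt(k (k + 1) / (6 N))

are declared significantly different, where ``q_alpha(k)`` is the
infinite-degrees-of-freedom Studentized-range critical value divided by
sqrt(2).

A published benchmark score table for ten fusion methods over six CT/MRI
dataset pairs and the five quality metrics ships with the package (see
:func:`benchmark_scores`).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import rankdata

__all__ = [
    "ScoreTable",
    "RankResult",
    "mean_ranks",
    "friedman_test",
    "nemenyi_cd",
    "significance_matrix",
    "rank_analysis",
    "benchmark_scores",
    "NEMENYI_Q",
]

# infinite-df Studentized range / sqrt(2) critical values, k = 2..20
NEMENYI_Q: dict[float, dict[int, float]] = {
    0.05: dict(zip(range(2, 21), [
        1.960, 2.344, 2.569, 2.728, 2.850, 2.948, 3.031, 3.102, 3.164,
        3.219, 3.268, 3.313, 3.354, 3.391, 3.426, 3.458, 3.489, 3.517, 3.544,
    ])),
    0.10: dict(zip(range(2, 21), [
        1.645, 2.052, 2.291, 2.460, 2.589, 2.693, 2.780, 2.855, 2.920,
        2.978, 3.030, 3.077, 3.120, 3.159, 3.196, 3.230, 3.261, 3.291, 3.319,
    ])),
}


@dataclass
class ScoreTable:
    """Methods x blocks score grid; higher scores are better."""

    methods: list[str]
    blocks: list[str]
    values: np.ndarray  # (k, N)

    def validate(self) -> "ScoreTable":
        k, n = self.values.shape
        if k != len(self.methods) or n != len(self.blocks):
            raise ValueError("values shape does not match labels")
        if k < 2 or n < 2:
            raise ValueError("need at least 2 methods and 2 blocks")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score table has missing/non-finite cells")
        return self

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScoreTable":
        """CSV layout: first column method names, one column per block."""
        df = pd.read_csv(path, index_col=0)
        return cls(
            methods=[str(m) for m in df.index],
            blocks=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=np.float64),
        ).validate()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.methods, columns=self.blocks)


@dataclass
class RankResult:
    """Mean ranks, omnibus test, and critical difference for one table."""

    methods: list[str]
    mean_ranks: np.ndarray
    friedman_chi2: float
    p_value: float
    critical_difference: float
    alpha: float


def _block_ranks(t: ScoreTable) -> np.ndarray:
    """(k, N) within-block ranks; rank 1 = highest score, ties averaged."""
    return np.column_stack(
        [rankdata(-t.values[:, j], method="average") for j in range(t.values.shape[1])]
    )


def mean_ranks(t: ScoreTable) -> np.ndarray:
    """Per-method mean rank over blocks (sums to k(k+1)/2 across methods)."""
    t.validate()
    return _block_ranks(t).mean(axis=1)


def friedman_test(t: ScoreTable) -> tuple[float, float]:
    """Tie-corrected Friedman chi-square and upper-tail p (k-1 df).

    A table with no discrimination at all (every block fully tied) returns
    (0, 1).
    """
    t.validate()
    k, n = t.values.shape
    ranks = _block_ranks(t)
    rank_sums = ranks.sum(axis=1)
    # general tie-corrected form: the denominator is the total squared
    # deviation of the ranks, which shrinks under ties
    num = n * (k - 1) * float(((rank_sums - n * (k + 1) / 2.0) ** 2).sum())
    den = float((ranks**2).sum()) * n - n * n * k * (k + 1) ** 2 / 4.0
    if den <= 0:
        return 0.0, 1.0
    chi2 = num / den
    return chi2, float(chi2_dist.sf(chi2, k - 1))


def nemenyi_cd(k: int, n_blocks: int, alpha: float = 0.05) -> float:
    """Nemenyi critical difference for k methods over n_blocks blocks."""
    if k < 2 or n_blocks < 1:
        raise ValueError("need k >= 2 and n_blocks >= 1")
    table = NEMENYI_Q.get(round(alpha, 2))
    if table is None or k not in table:
        raise ValueError(
            f"no critical value embedded for alpha={alpha}, k={k} "
            f"(supported: alpha in {sorted(NEMENYI_Q)}, k in 2..20)"
        )
    return table[k] * np.sqrt(k * (k + 1) / (6.0 * n_blocks))


def significance_matrix(t: ScoreTable, alpha: float = 0.05) -> np.ndarray:
    """Pairwise boolean matrix: True where |mean rank difference| > CD."""
    ranks = mean_ranks(t)
    cd = nemenyi_cd(len(t.methods), len(t.blocks), alpha)
    diff = np.abs(ranks[:, None] - ranks[None, :])
    out = diff > cd
    np.fill_diagonal(out, False)
    return out


def rank_analysis(t: ScoreTable, alpha: float = 0.05) -> RankResult:
    """Mean ranks + Friedman omnibus + Nemenyi CD in one result."""
    t.validate()
    chi2, p = friedman_test(t)
    return RankResult(
        methods=list(t.methods),
        mean_ranks=mean_ranks(t),
        friedman_chi2=chi2,
        p_value=p,
        critical_difference=nemenyi_cd(len(t.methods), len(t.blocks), alpha),
        alpha=alpha,
    )


def benchmark_scores() -> ScoreTable:
    """The packaged benchmark table: ten fusion methods scored with the
    five quality metrics on six CT/MRI dataset pairs (30 blocks)."""
    path = resources.files("sparsefuse.data") / "fusion_benchmark_scores.csv"
    with resources.as_file(path) as p:
        return ScoreTable.from_csv(p)
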