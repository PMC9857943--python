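"""Rank-based multi-classifier comparison: Friedman test and Nemenyi post hoc.

Given a table of scores (datasets × algorithms), each row is converted to
ranks 1..k (best = 1, ties receive the mean of the spanned ranks). The
Friedman chi-square statistic

    Γ = 12 n / (k (k+1)) · (Σ r̄_j² − k (k+1)² / 4)

tests the null that all algorithms perform equally; the F-distributed variant
τ_F = (n−1) Γ / (n (k−1) − Γ) with ((k−1), (k−1)(n−1)) degrees of freedom is
less conservative and is the one reported. When the null is rejected, the
Nemenyi critical difference CD = q_α √(k (k+1) / (6 n)) declares a pair of
algorithms different when their average ranks differ by more than CD.

The packaged fixture is a transcription of a published benchmark comparison
of eight fuzzy-SVM-family classifiers over twenty imbalanced datasets, one
table per metric (G-mean, F-measure, AUC).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import rankdata

__all__ = [
    "ScoreTable",
    "FriedmanResult",
    "NemenyiResult",
    "rank_table",
    "friedman_test",
    "nemenyi_cd",
    "compare_report",
    "load_benchmark_table",
    "load_synthetic_table",
]

# Two-tailed Nemenyi critical values q_alpha for k = 2..10, from the
# studentized range statistic divided by sqrt(2) (Demsar 2006, Table 5).
Q_ALPHA = {
    0.05: {2: 1.960, 3: 2.343, 4: 2.569, 5: 2.728, 6: 2.850, 7: 2.949, 8: 3.031, 9: 3.102, 10: 3.164},
    0.10: {2: 1.645, 3: 2.052, 4: 2.291, 5: 2.459, 6: 2.589, 7: 2.693, 8: 2.780, 9: 2.855, 10: 2.920},
}


@dataclass(frozen=True)
class ScoreTable:
    """n datasets × k algorithms score matrix for a single metric."""

    scores: pd.DataFrame
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        df = self.scores
        if df.isna().any().any():
            raise ValueError("score table has missing cells")
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise ValueError("need at least 2 datasets and 2 algorithms")

    @classmethod
    def from_csv(cls, path, index_col: int = 0, higher_is_better: bool = True) -> "ScoreTable":
        return cls(pd.read_csv(path, index_col=index_col), higher_is_better)

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def k(self) -> int:
        return self.scores.shape[1]


@dataclass(frozen=True)
class FriedmanResult:
    average_ranks: pd.Series
    chi2: float
    tau_f: float
    df_between: int
    df_error: int
    alpha: float
    critical_value: float
    reject: bool


@dataclass(frozen=True)
class NemenyiResult:
    cd: float
    alpha: float
    q_alpha: float
    significant: pd.DataFrame | None = None


def rank_table(table: ScoreTable) -> pd.DataFrame:
    """Per-row ranks, best = 1; ties share the mean of the spanned ranks."""
    sign = -1.0 if table.higher_is_better else 1.0
    ranks = np.vstack([rankdata(sign * row) for row in table.scores.to_numpy(dtype=float)])
    return pd.DataFrame(ranks, index=table.scores.index, columns=table.scores.columns)


def friedman_test(ranks: pd.DataFrame, alpha: float = 0.05) -> FriedmanResult:
    """Friedman chi-square and its F-distributed variant from a rank matrix."""
    n, k = ranks.shape
    avg = ranks.mean(axis=0)
    chi2 = 12.0 * n / (k * (k + 1)) * (float(np.sum(avg.to_numpy() ** 2)) - k * (k + 1) ** 2 / 4.0)
    denom = n * (k - 1) - chi2
    if denom <= 0:
        raise ValueError("degenerate rank configuration: n(k-1) - chi2 <= 0")
    tau_f = (n - 1) * chi2 / denom
    df1, df2 = k - 1, (k - 1) * (n - 1)
    crit = float(f_dist.ppf(1.0 - alpha, df1, df2))
    return FriedmanResult(avg, float(chi2), float(tau_f), df1, df2, alpha, crit, bool(tau_f > crit))


def nemenyi_cd(
    k: int,
    n: int,
    alpha: float = 0.05,
    average_ranks: pd.Series | None = None,
    q: float | None = None,
) -> NemenyiResult:
    """Critical difference CD = q_α √(k(k+1)/(6n)) with optional pairwise flags.

    ``q`` overrides the tabulated critical value (e.g. for untabulated α).
    """
    if k < 2 or n < 1:
        raise ValueError("need k >= 2 algorithms and n >= 1 datasets")
    if q is None:
        try:
            q = Q_ALPHA[alpha][k]
        except KeyError as exc:
            raise ValueError(f"no tabulated q for alpha={alpha}, k={k}") from exc
    cd = q * np.sqrt(k * (k + 1) / (6.0 * n))
    significant = None
    if average_ranks is not None:
        diffs = np.abs(average_ranks.to_numpy()[:, None] - average_ranks.to_numpy()[None, :])
        significant = pd.DataFrame(diffs > cd, index=average_ranks.index, columns=average_ranks.index)
    return NemenyiResult(float(cd), alpha, q, significant)


def compare_report(tables: dict[str, ScoreTable], alpha: float = 0.05) -> dict:
    """Full comparison per metric: ranks, Friedman decision, Nemenyi CD."""
    report = {}
    for metric, table in tables.items():
        ranks = rank_table(table)
        fr = friedman_test(ranks, alpha)
        nem = nemenyi_cd(table.k, table.n, alpha, fr.average_ranks)
        report[metric] = {
            "n_datasets": table.n,
            "n_algorithms": table.k,
            "average_ranks": {str(a): float(r) for a, r in fr.average_ranks.items()},
            "friedman_chi2": fr.chi2,
            "tau_F": fr.tau_f,
            "df": [fr.df_between, fr.df_error],
            "critical_value": fr.critical_value,
            "reject_equal_performance": fr.reject,
            "nemenyi_cd": nem.cd,
            "q_alpha": nem.q_alpha,
            "significant_pairs": {
                str(a): [str(b) for b in nem.significant.columns[nem.significant.loc[a]]]
                for a in nem.significant.index
            },
            "alpha": alpha,
        }
    return report


_TABLE_FILES = {
    "gmean": "table3_gmean.csv",
    "fmeasure": "table3_fmeasure.csv",
    "auc": "table3_auc.csv",
}


def load_benchmark_table(metric: str) -> ScoreTable:
    """Packaged 20-dataset × 8-algorithm benchmark fixture for one metric."""
    try:
        fname = _TABLE_FILES[metric.lower()]
    except KeyError as exc:
        raise ValueError(f"metric must be one of {sorted(_TABLE_FILES)}") from exc
    with resources.files("rifsvm.data").joinpath(fname).open() as fh:
        return ScoreTable.from_csv(fh)


def load_synthetic_table() -> pd.DataFrame:
    """Packaged reference metrics of IFSVM/RIFSVM on the two synthetic presets."""
    with resources.files("rifsvm.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)
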