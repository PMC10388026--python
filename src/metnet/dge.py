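"""Differential expression from a normalized log2 expression matrix.

The pipeline ingests an already-normalized (RMA/quantile-style) log2 matrix with
two conditions measured in replicate, and calls differential expression the way
classic microarray studies do: a per-gene two-sample Student t-test (pooled
variance), Benjamini-Hochberg FDR control, and a fold-change filter on the
ratio scale (``|FC| > 1.5`` meaning ratio > 1.5 or < 1/1.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CONTROL = "control"
RESTRICTED = "restricted"

#: Pooled-variance floor: replicate-identical probes otherwise yield 0/0 t-statistics.
DEFAULT_VAR_FLOOR = 1e-8


@dataclass
class ExpressionMatrix:
    """log2 expression values, genes x samples, with a condition label per sample.

    Exactly two condition labels are expected (:data:`CONTROL` and
    :data:`RESTRICTED`); each must cover at least two replicate columns before
    any statistic can be computed.
    """

    genes: list[str]
    samples: list[str]
    conditions: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(self.conditions) != len(self.samples):
            raise ValueError("one condition label per sample is required")

    def columns_for(self, condition: str) -> np.ndarray:
        idx = [i for i, c in enumerate(self.conditions) if c == condition]
        return self.values[:, idx]

    def n_replicates(self, condition: str) -> int:
        return sum(c == condition for c in self.conditions)


def t_test_per_gene(
    matrix: ExpressionMatrix,
    var_floor: float = DEFAULT_VAR_FLOOR,
) -> pd.DataFrame:
    """Per-gene two-sided Student (equal-variance) t-test, restricted vs control.

    Returns a DataFrame with columns ``gene, mean_control, mean_restricted,
    log2fc, fold_change, t_stat, p_raw``.  ``log2fc`` is
    ``mean_restricted - mean_control`` and ``fold_change`` its ratio
    ``2**log2fc``.  Genes whose replicates are identical in both groups with
    equal means get ``t = 0, p = 1``; otherwise the pooled variance is floored
    at ``var_floor`` so the statistic stays defined.
    """
    for cond in (CONTROL, RESTRICTED):
        if matrix.n_replicates(cond) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 replicates")
    x = matrix.columns_for(CONTROL)
    y = matrix.columns_for(RESTRICTED)
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    ss1 = ((x - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((y - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    pooled = (ss1 + ss2) / df
    degenerate = (pooled == 0) & (m1 == m2)
    pooled = np.maximum(pooled, var_floor)
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    t = np.where(degenerate, 0.0, (m2 - m1) / se)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, 1.0, np.minimum(p, 1.0))
    log2fc = m2 - m1
    return pd.DataFrame(
        {
            "gene": matrix.genes,
            "mean_control": m1,
            "mean_restricted": m2,
            "log2fc": log2fc,
            "fold_change": np.exp2(log2fc),
            "t_stat": t,
            "p_raw": p,
        }
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, aligned to input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significant(
    table: pd.DataFrame,
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
) -> tuple[list[str], list[str]]:
    """Apply the FDR + fold-change filter; returns (up, down) gene lists.

    Adds ``p_adj``, ``direction`` and ``is_significant`` columns in place.
    Both cuts are strict: ``p_adj < alpha`` and ratio ``> fc_threshold`` (up)
    or ``< 1/fc_threshold`` (down); a fold change of exactly the threshold is
    not called.
    """
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    fc = table["fold_change"].to_numpy()
    sig = table["p_adj"].to_numpy() < alpha
    up = sig & (fc > fc_threshold)
    down = sig & (fc < 1.0 / fc_threshold)
    table["is_significant"] = up | down
    table["direction"] = np.select([up, down], ["up", "down"], default="ns")
    genes = table["gene"].to_numpy()
    return list(genes[up]), list(genes[down])


def differential_expression(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
    var_floor: float = DEFAULT_VAR_FLOOR,
) -> pd.DataFrame:
    """Full DGE table: t-test, BH adjustment and significance calls."""
    table = t_test_per_gene(matrix, var_floor=var_floor)
    call_significant(table, alpha=alpha, fc_threshold=fc_threshold)
    return table
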