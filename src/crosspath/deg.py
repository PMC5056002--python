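"""Two-group differential-expression screen.

Genes are flagged as differentially expressed (DEG) when they pass both
an absolute log2 fold-change cut-off and a P-value cut-off, applied
inclusively (|logFC| ≥ 1.5 and P ≤ 0.01 by default). The P value comes
from a moderated two-group t-test: gene-wise pooled variances are shrunk
toward the mean variance of all genes with a fixed prior weight
(``prior_df`` pseudo-degrees of freedom), and the statistic is referred
to a t distribution with residual + prior degrees of freedom. This
captures the variance-moderation behaviour of empirical-Bayes microarray
tests with a single transparent tuning constant; a plain Welch t-test is
available via ``method="welch"``.

The fold change is mean(test group) − mean(reference group) on the log2
scale, where the reference group is ``study.group_order[0]``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError
from .io import ExpressionStudy


def screen_degs(
    study: ExpressionStudy,
    lfc_threshold: float = 1.5,
    p_threshold: float = 0.01,
    method: str = "moderated",
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Screen DEGs between the study's two groups.

    Returns a DataFrame indexed by gene id with columns ``log_fc``
    (test − reference, log2 units), ``p_value`` (two-sided) and
    ``is_deg`` (both thresholds passed, inclusively).
    """
    ref, test = study.require_two_groups()
    a = study.group_matrix(ref)
    b = study.group_matrix(test)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ContractError("each group needs ≥ 2 samples for the DEG screen")

    log_fc = b.mean(axis=1) - a.mean(axis=1)

    if method == "moderated":
        t, p = _moderated_t(a, b, prior_df)
    elif method == "welch":
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    else:
        raise ContractError(f"unknown DEG test method {method!r}")

    is_deg = (np.abs(log_fc) >= lfc_threshold) & (p <= p_threshold)
    return pd.DataFrame(
        {"log_fc": log_fc, "p_value": p, "is_deg": is_deg},
        index=pd.Index(study.gene_ids, name="gene_id"),
    )


def _moderated_t(a: np.ndarray, b: np.ndarray, prior_df: float) -> tuple[np.ndarray, np.ndarray]:
    n1, n2 = a.shape[1], b.shape[1]
    df = n1 + n2 - 2
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    prior_var = pooled.mean()
    shrunk = (prior_df * prior_var + df * pooled) / (prior_df + df)

    diff = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(shrunk * (1.0 / n1 + 1.0 / n2))
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0),
                     np.sign(diff) * np.inf)
    # se == 0 (all variances zero): |t| = inf when means differ, 0 otherwise
    t = np.where((se == 0) & (diff == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df + prior_df)
    return t, p


def deg_ids(result: pd.DataFrame) -> set[str]:
    """Gene ids flagged as DEGs, for the cross-talk edge filter."""
    return set(result.index[result["is_deg"]])


def write_deg_table(result: pd.DataFrame, path) -> None:
    result.to_csv(path, sep="\t", float_format="%.10g")
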