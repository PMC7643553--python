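"""FPKM computation, expression binning and Pearson coexpression screening.

The coexpression screen follows the convention that a pair is called
positively coexpressed when its Pearson correlation reaches the critical
value of the exact t-based test at the chosen alpha: r_crit = t / sqrt(t^2
+ df) with df = n_samples - 2, which gives 0.468 at df = 16 and alpha =
0.05.  Pairs where either member never reaches 1 FPKM in any sample are
excluded as low-abundance before any correlation is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

LOW_ABUNDANCE_FPKM_MAX = 1.0

#: expression bins (FPKM): low [0,1), medium [1,15], high (15,100], very high >100
BIN_EDGES = (1.0, 15.0, 100.0)


def fpkm_from_counts(fragments: float, length_nt: float, total_fragments: float) -> float:
    """FPKM = fragments x 1e9 / (transcript length x total mapped fragments)."""
    if length_nt <= 0 or total_fragments <= 0:
        raise ValueError("length and total fragments must be positive")
    if fragments < 0:
        raise ValueError("fragment count must be non-negative")
    return fragments * 1e9 / (length_nt * total_fragments)


def gene_fpkm(isoform_fpkms: list[float] | np.ndarray) -> float:
    """Gene-level FPKM: the sum over all isoforms."""
    if len(isoform_fpkms) == 0:
        raise ValueError("at least one isoform required")
    return float(np.sum(isoform_fpkms))


def bin_expression(fpkm: float) -> str:
    if fpkm < 0:
        raise ValueError("FPKM must be non-negative")
    if fpkm < BIN_EDGES[0]:
        return "low"
    if fpkm <= BIN_EDGES[1]:
        return "medium"
    if fpkm <= BIN_EDGES[2]:
        return "high"
    return "very_high"


def bin_summary(matrix: ExpressionMatrix) -> pd.Series:
    """Fraction of features per bin, judged on each feature's FPKM_max."""
    bins = matrix.fpkm_max().map(bin_expression)
    return bins.value_counts(normalize=True).reindex(
        ["low", "medium", "high", "very_high"], fill_value=0.0
    )


def critical_pearson_r(df: int, alpha: float) -> float:
    """Two-tailed critical Pearson r: r = t / sqrt(t^2 + df).

    t is the two-tailed alpha critical value of Student's t with ``df``
    degrees of freedom (df = n - 2 for a correlation over n samples).
    """
    if df < 1:
        raise ValueError("df must be at least 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    t = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t / np.sqrt(t * t + df))


@dataclass
class CoexpressionResult:
    lnc_id: str
    target_id: str
    r: float | None
    n_samples: int
    df: int
    p_value: float | None
    verdict: str  # excluded_low_abundance | positive | negative | not_significant
    zero_variance: bool = False


def coexpression_screen(
    pairs: list[tuple[str, str]],
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
) -> list[CoexpressionResult]:
    """Screen (lncRNA, target) pairs for coexpression across samples.

    Pairs with FPKM_max < 1 on either member are excluded before
    correlation; the rest are tested against the symmetric critical r at
    df = n_samples - 2.  Constant expression vectors leave r undefined;
    such pairs are reported not_significant with the zero-variance flag.
    """
    n = len(matrix.samples)
    if n < 4:
        raise ValueError("at least 4 samples are required for the screen")
    df = n - 2
    r_crit = critical_pearson_r(df, alpha)
    fpkm_max = matrix.fpkm_max()
    results: list[CoexpressionResult] = []
    for lnc_id, target_id in pairs:
        for fid in (lnc_id, target_id):
            if fid not in matrix:
                raise KeyError(f"feature {fid!r} not in expression matrix")
        if (
            fpkm_max[lnc_id] < LOW_ABUNDANCE_FPKM_MAX
            or fpkm_max[target_id] < LOW_ABUNDANCE_FPKM_MAX
        ):
            results.append(
                CoexpressionResult(
                    lnc_id, target_id, None, n, df, None, "excluded_low_abundance"
                )
            )
            continue
        x = matrix.row(lnc_id)
        y = matrix.row(target_id)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning(
                "zero-variance expression for pair (%s, %s); r undefined", lnc_id, target_id
            )
            results.append(
                CoexpressionResult(
                    lnc_id, target_id, 0.0, n, df, 1.0, "not_significant", zero_variance=True
                )
            )
            continue
        r, p = stats.pearsonr(x, y)
        r = float(np.clip(r, -1.0, 1.0))
        if r >= r_crit:
            verdict = "positive"
        elif r <= -r_crit:
            verdict = "negative"
        else:
            verdict = "not_significant"
        results.append(CoexpressionResult(lnc_id, target_id, r, n, df, float(p), verdict))
    return results


def screen_frame(results: list[CoexpressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lnc_id": r.lnc_id,
                "target_id": r.target_id,
                "r": r.r,
                "n_samples": r.n_samples,
                "df": r.df,
                "p_value": r.p_value,
                "verdict": r.verdict,
                "zero_variance": r.zero_variance,
            }
            for r in results
        ],
        columns=[
            "lnc_id",
            "target_id",
            "r",
            "n_samples",
            "df",
            "p_value",
            "verdict",
            "zero_variance",
        ],
    )
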