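"""Expression-level analyses: differential expression decision rule,
NAT-ST co-expression, qPCR delta-Ct normalization, and FDR control.

The differential-expression caller is a Welch t-test on log2(FPKM + 1)
replicate values, combined with the decision thresholds |log2 fold change|
>= 1 and q <= 0.05 (it does not model count overdispersion).  Co-expression
uses the sample Pearson correlation over all replicate samples (nine in the
reference three-tissue, three-replicate design), with Benjamini-Hochberg
FDR across pairs; r >= 0.9 is called a high positive correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_model import ExpressionMatrix
from .nat_discovery import SATPair

logger = logging.getLogger(__name__)

R_HIGH = 0.9
DE_LOG2FC = 1.0
DE_Q = 0.05
PSEUDOCOUNT = 1.0  # FPKM


@dataclass
class CoexpressionRecord:
    pair_id: str
    st_id: str
    nat_id: str
    r: float
    p: float
    q: float
    klass: str  # positive_high | positive | negative


@dataclass
class DEResult:
    transcript_id: str
    contrast: tuple[str, str]
    log2fc: float
    p: float
    q: float
    is_de: bool


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; NaN (with a warning) on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("pearson_r: zero variance, correlation undefined")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def pearson_r_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """(r, two-sided p) via the t-distribution test on r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("pearson_r: zero variance, correlation undefined")
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, original order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    expr: ExpressionMatrix,
    contrast: tuple[str, str],
    pseudocount: float = PSEUDOCOUNT,
    lfc_cutoff: float = DE_LOG2FC,
    q_cutoff: float = DE_Q,
) -> list[DEResult]:
    """Per-transcript DE call between two tissues.

    log2fc = log2((meanA + eps) / (meanB + eps)) on FPKM tissue means;
    p from a Welch t-test on log2(FPKM + 1) replicate values; q by BH.
    """
    tissue_a, tissue_b = contrast
    samples_a = expr.samples_of(tissue_a)
    samples_b = expr.samples_of(tissue_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each tissue needs at least 2 replicates")
    a = expr.values[samples_a].to_numpy()
    b = expr.values[samples_b].to_numpy()
    log2fc = np.log2((a.mean(axis=1) + pseudocount) / (b.mean(axis=1) + pseudocount))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant rows -> nan p
        pvals = stats.ttest_ind(
            np.log2(a + 1.0), np.log2(b + 1.0), axis=1, equal_var=False
        ).pvalue
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    qvals = bh_fdr(pvals)
    out = []
    for tid, lfc, p, q in zip(expr.transcripts, log2fc, pvals, qvals):
        out.append(
            DEResult(
                transcript_id=tid,
                contrast=contrast,
                log2fc=float(lfc),
                p=float(p),
                q=float(q),
                is_de=bool(abs(lfc) >= lfc_cutoff and q <= q_cutoff),
            )
        )
    return out


def coexpress(
    pairs: Sequence[SATPair],
    expr: ExpressionMatrix,
    r_high: float = R_HIGH,
) -> list[CoexpressionRecord]:
    """Pearson correlation of NAT and ST profiles over all replicate samples.

    Pairs with a transcript missing from the matrix are excluded (logged).
    q-values are BH-adjusted across all tested pairs; classes: positive_high
    (r >= r_high), positive (0 <= r < r_high), negative (r < 0).
    """
    rows = []
    n_missing = 0
    for pair in pairs:
        if pair.st_id not in expr.values.index or pair.nat_id not in expr.values.index:
            n_missing += 1
            continue
        r, p = pearson_r_p(expr.row(pair.st_id), expr.row(pair.nat_id))
        rows.append((pair, r, p))
    if n_missing:
        logger.warning("coexpress: %d pairs excluded (transcript missing from matrix)", n_missing)
    qvals = bh_fdr([np.nan_to_num(p, nan=1.0) for _, _, p in rows])
    records = []
    for (pair, r, p), q in zip(rows, qvals):
        if np.isnan(r):
            klass = "undefined"
        elif r >= r_high:
            klass = "positive_high"
        elif r >= 0:
            klass = "positive"
        else:
            klass = "negative"
        pair.coexpression_r = r
        records.append(
            CoexpressionRecord(
                pair_id=f"{pair.st_id}|{pair.nat_id}",
                st_id=pair.st_id,
                nat_id=pair.nat_id,
                r=r,
                p=p,
                q=float(q),
                klass=klass,
            )
        )
    return records


@dataclass
class DeltaCtResult:
    delta_ct: pd.DataFrame   # Ct[X] - Ct[reference], per transcript x sample
    relative: pd.DataFrame   # 2 ** (-delta_ct)


def delta_ct(ct: pd.DataFrame, reference_id: str) -> DeltaCtResult:
    """qPCR delta-Ct normalization against a reference gene.

    Correlation analyses downstream use the delta-Ct values directly; the
    relative expression 2^(-dCt) is reported alongside.
    """
    if reference_id not in ct.index:
        raise ValueError(f"reference {reference_id!r} missing from Ct table")
    ref = ct.loc[reference_id]
    if ref.isna().any():
        raise ValueError("reference must be present (non-NaN) in every sample")
    d = ct.sub(ref, axis=1)
    return DeltaCtResult(delta_ct=d, relative=2.0 ** (-d))


def coexpression_table(records: Sequence[CoexpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair_id": r.pair_id,
                "st_id": r.st_id,
                "nat_id": r.nat_id,
                "r": r.r,
                "p": r.p,
                "q": r.q,
                "class": r.klass,
            }
            for r in records
        ]
    )


def de_table(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "contrast": f"{r.contrast[0]}_vs_{r.contrast[1]}",
                "log2fc": r.log2fc,
                "p": r.p,
                "q": r.q,
                "is_de": r.is_de,
            }
            for r in results
        ]
    )
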