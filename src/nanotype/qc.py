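"""Quality-control metrics: Shannon–Wiener expression entropy and linear
regressions of QC metrics against prediction probability.

Entropy is computed on the unfiltered transcript-level TPM vector — it is a
measure of transcriptome diversity per sample, not of the filtered feature
matrix the classifier sees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import ExpressionProfile


def shannon_entropy(tpm: Mapping[str, float], base: Union[float, str] = 2) -> float:
    """Shannon–Wiener diversity index H = −Σ p_i log p_i of the expression
    proportion vector, in bits by default (base 2; pass "e" for nats).

    Zero entries contribute nothing; an all-zero profile is a failed QC state
    and raises.
    """
    values = np.asarray(list(tpm.values()), dtype=float)
    if (values < 0).any():
        raise ValueError("TPM values must be non-negative")
    total = values.sum()
    if total <= 0:
        raise ValueError("all-zero profile: entropy undefined (failed QC)")
    p = values[values > 0] / total
    log_base = math.e if base == "e" else float(base)
    return float(-(p * (np.log(p) / np.log(log_base))).sum())


@dataclass
class QCRegression:
    """Ordinary-least-squares fit of a QC metric against prediction probability
    (slope/intercept, Pearson r, R², two-sided p from the t statistic)."""

    x_name: str
    y_name: str
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "x": self.x_name,
            "y": self.y_name,
            "slope": self.slope,
            "intercept": self.intercept,
            "pearson_r": self.pearson_r,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
        }


def regress_qc(
    x: Sequence[float],
    y: Sequence[float],
    x_name: str = "x",
    y_name: str = "y",
) -> QCRegression:
    """OLS regression of y on x with Pearson r and Wald-test p-value
    (t = r·sqrt((n−2)/(1−r²)), two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    fit = stats.linregress(x, y)
    return QCRegression(
        x_name=x_name,
        y_name=y_name,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        r_squared=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
    )


def qc_table(profiles: Iterable[ExpressionProfile], entropy_base: Union[float, str] = 2) -> pd.DataFrame:
    """Per-sample QC summary (fills the entropy field of each profile)."""
    rows = []
    for p in profiles:
        if p.entropy is None and p.transcript_tpm and sum(p.transcript_tpm.values()) > 0:
            p.entropy = shannon_entropy(p.transcript_tpm, base=entropy_base)
        rows.append(
            {
                "sample_id": p.sample_id,
                "n_reads": p.n_reads,
                "n_aligned": p.n_aligned,
                "alignment_rate": p.alignment_rate,
                "mean_length": p.mean_read_length,
                "read_n50": p.read_n50,
                "entropy_bits": p.entropy,
            }
        )
    return pd.DataFrame(rows)
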