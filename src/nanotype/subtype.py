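"""Genomic-subtype calling within one tumor type.

Two routes: (1) the same composite PLS→SVM architecture fitted on binary
subtype labels (FOXO1 fusion status in rhabdomyosarcoma, MYCN amplification
in neuroblastoma), and (2) a deliberately simple expression heuristic that
calls MYCN amplification when the MYCN/NAGK TPM ratio reaches a threshold
(default ≥ 5; NAGK serves as a housekeeping normalizer). The ratio cancels
the TPM unit, so the heuristic is invariant to global rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple, Union

import pandas as pd

from .config import RunConfig
from .evaluate import EvaluationReport, grouped_loocv
from .io import strip_version
from .matrix import ExpressionMatrix

# symbol and ENSEMBL gene id aliases; matrices may be keyed by either
GENE_ALIASES: Dict[str, Tuple[str, ...]] = {
    "MYCN": ("MYCN", "ENSG00000134323"),
    "NAGK": ("NAGK", "ENSG00000124357"),
}


@dataclass
class SubtypeCall:
    """One subtype decision for one sample; the heuristic path carries a
    ratio, the composite-model path a probability."""

    sample_id: str
    scheme: str
    call: str
    method: str  # "heuristic" | "composite"
    ratio: Optional[float] = None
    probability: Optional[float] = None
    reason: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "scheme": self.scheme,
            "call": self.call,
            "method": self.method,
            "ratio": self.ratio,
            "probability": self.probability,
            "reason": self.reason,
        }


def lookup_gene(tpm: Union[Mapping[str, float], pd.Series], symbol: str) -> Optional[float]:
    """Find a gene's TPM by symbol or ENSEMBL id, tolerating version suffixes."""
    aliases = GENE_ALIASES.get(symbol, (symbol,))
    getter = tpm.get if hasattr(tpm, "get") else None
    for alias in aliases:
        if getter is not None:
            v = getter(alias)
            if v is not None:
                return float(v)
    for key in tpm.keys() if hasattr(tpm, "keys") else tpm.index:
        if strip_version(str(key)) in aliases:
            return float(tpm[key])
    return None


def mycn_ratio_call(
    gene_tpm: Union[Mapping[str, float], pd.Series],
    threshold: float = 5.0,
    sample_id: str = "sample",
) -> SubtypeCall:
    """Call MYCN amplification from the MYCN/NAGK expression ratio.

    amplified iff TPM(MYCN)/TPM(NAGK) >= threshold (boundary inclusive).
    NAGK absent or zero leaves the ratio undefined; the call is flagged rather
    than guessed.
    """
    nagk = lookup_gene(gene_tpm, "NAGK")
    if nagk is None or nagk <= 0:
        return SubtypeCall(
            sample_id=sample_id,
            scheme="MYCN_amplification",
            call="undefined",
            method="heuristic",
            reason="NAGK expression absent or zero; ratio undefined",
        )
    mycn = lookup_gene(gene_tpm, "MYCN") or 0.0
    ratio = mycn / nagk
    return SubtypeCall(
        sample_id=sample_id,
        scheme="MYCN_amplification",
        call="amplified" if ratio >= threshold else "not_amplified",
        method="heuristic",
        ratio=ratio,
    )


def subtype_matrix(m: ExpressionMatrix, scheme: str) -> ExpressionMatrix:
    """Restrict a cohort to samples labeled under a subtype scheme and promote
    those labels to the primary labels."""
    if scheme not in m.subtype_labels:
        raise ValueError(f"matrix has no subtype scheme {scheme!r}")
    labels = m.subtype_labels[scheme]
    keep = list(labels.index[labels.notna()])
    if not keep:
        raise ValueError(f"no samples labeled under scheme {scheme!r}")
    sub = m.subset_samples(keep).with_labels(labels[keep])
    if len(sub.classes) < 2:
        raise ValueError(
            f"scheme {scheme!r}: only one observed subtype {sub.classes}; cannot evaluate"
        )
    return sub


def subtype_loocv(
    m: ExpressionMatrix, scheme: str, config: Optional[RunConfig] = None
) -> EvaluationReport:
    """Replicate-aware LOOCV of the binary composite subtype model."""
    return grouped_loocv(subtype_matrix(m, scheme), config=config)
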