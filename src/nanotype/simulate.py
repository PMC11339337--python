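"""Synthetic cohorts and toy alignments.

The generator emulates the statistical structure the classifier must tolerate
in low-coverage nanopore cDNA data: compositional TPM profiles, sparsity
driven by finite library size (multinomial read sampling), class-specific
signature genes on a shared log-normal abundance baseline, per-sample
biological noise, and technical replicate twins resampled from the same
underlying abundance vector (which grouped cross-validation must exclude).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


@dataclass
class CohortSpec:
    """Parameters of a synthetic class-structured expression cohort.

    Defaults describe a well-separated multi-class study: four tumor-like
    classes of 15 samples, 2000 genes of which 40 per class form a signature
    shifted by ``effect_size`` log2-fold, and 50k reads per sample (so the
    mean gene gets ~25 reads and the sparse tail is substantial).
    """

    n_classes: int = 4
    samples_per_class: int = 15
    n_genes: int = 2000
    n_signature_genes: int = 40
    effect_size: float = 4.0  # log2-fold shift of signature genes
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    sample_log_sd: float = 0.5  # per-sample biological noise
    library_size: int = 50_000
    replicate_rate: float = 0.0  # fraction of samples given a same-group twin
    signature_classes: Optional[Tuple[int, ...]] = None  # default: every class
    seed: int = 1

    def __post_init__(self) -> None:
        if min(self.n_classes, self.samples_per_class, self.n_genes, self.library_size) <= 0:
            raise ValueError("counts must be positive")
        if self.n_signature_genes * self.n_classes > self.n_genes:
            raise ValueError(
                f"{self.n_classes} classes x {self.n_signature_genes} signature genes "
                f"exceed {self.n_genes} genes"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0.0 <= self.replicate_rate <= 1.0):
            raise ValueError("replicate_rate must lie in [0, 1]")
        if self.signature_classes is not None:
            self.signature_classes = tuple(int(i) for i in self.signature_classes)
            if any(not 0 <= i < self.n_classes for i in self.signature_classes):
                raise ValueError("signature_classes indices out of range")


def _class_names(n: int) -> List[str]:
    return [f"type{chr(65 + i)}" for i in range(n)]


def simulate_cohort(spec: CohortSpec) -> ExpressionMatrix:
    """Draw a labeled, grouped TPM matrix from the spec; deterministic per seed.

    Per sample: abundance = shared log-normal gene baseline × class signature
    (signature block multiplied by 2^effect_size) × per-sample log-normal
    noise; observed counts ~ multinomial(library_size, abundance); TPM =
    counts/library × 1e6. Replicate twins resample counts from the *same*
    abundance vector and share the original sample's group id.
    """
    rng = np.random.default_rng(spec.seed)
    classes = _class_names(spec.n_classes)
    genes = [f"G{j:05d}" for j in range(spec.n_genes)]
    baseline = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_genes)

    sample_ids: List[str] = []
    labels: List[str] = []
    groups: List[str] = []
    rows: List[np.ndarray] = []

    def _observe(abund: np.ndarray) -> np.ndarray:
        counts = rng.multinomial(spec.library_size, abund / abund.sum())
        return counts / counts.sum() * 1e6

    for ci, cls in enumerate(classes):
        class_abund = baseline.copy()
        if spec.signature_classes is None or ci in spec.signature_classes:
            signature = slice(ci * spec.n_signature_genes, (ci + 1) * spec.n_signature_genes)
            class_abund[signature] *= 2.0 ** spec.effect_size
        for si in range(spec.samples_per_class):
            noise = rng.lognormal(0.0, spec.sample_log_sd, spec.n_genes)
            abund = class_abund * noise
            base_id = f"{cls}_s{si:03d}"
            sample_ids.append(base_id)
            labels.append(cls)
            groups.append(base_id)
            rows.append(_observe(abund))
            if rng.random() < spec.replicate_rate:
                sample_ids.append(f"{base_id}_rep")
                labels.append(cls)
                groups.append(base_id)  # twin shares the group
                rows.append(_observe(abund))

    values = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=genes)
    return ExpressionMatrix(
        values=values,
        labels=pd.Series(labels, index=sample_ids),
        groups=pd.Series(groups, index=sample_ids),
    )


def simulate_paf(
    n_reads: int,
    transcripts: Mapping[str, int],
    multimap_fraction: float = 0.0,
    seed: int = 0,
    mean_read_length: float = 250.0,
    sd_read_length: float = 60.0,
    decoy_fraction: float = 0.3,
) -> Tuple[str, Dict[str, float]]:
    """Emit toy PAF text plus the ground-truth fractional counts.

    Each read originates from one transcript (uniformly). A ``multimap_fraction``
    of reads additionally aligns, score-tied, to a second transcript — truth
    splits such reads 0.5/0.5. A ``decoy_fraction`` of reads also carry one
    strictly lower-scoring alignment, which must not affect counting. Read
    lengths are drawn around 250 nt, the regime of fragmented FFPE cDNA.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if not transcripts:
        raise ValueError("need at least one transcript")
    rng = np.random.default_rng(seed)
    tids = list(transcripts)
    lines: List[str] = []
    truth: Dict[str, float] = {t: 0.0 for t in tids}

    def _paf_line(rid: str, rlen: int, tid: str, score: int) -> str:
        tlen = int(transcripts[tid])
        span = max(1, min(rlen, tlen) - 1)
        tstart = int(rng.integers(0, max(1, tlen - span)))
        nmatch = max(1, int(0.9 * span))
        return "\t".join(
            str(x)
            for x in (
                rid, rlen, 0, span, "+", tid, tlen, tstart, tstart + span,
                nmatch, span, 60, f"AS:i:{score}",
            )
        )

    for i in range(n_reads):
        rid = f"r{i:06d}"
        rlen = int(np.clip(rng.normal(mean_read_length, sd_read_length), 50, None))
        source = tids[int(rng.integers(len(tids)))]
        score = 2 * rlen
        targets = [source]
        if len(tids) > 1 and rng.random() < multimap_fraction:
            other = source
            while other == source:
                other = tids[int(rng.integers(len(tids)))]
            targets.append(other)
        share = 1.0 / len(targets)
        for t in targets:
            truth[t] += share
            lines.append(_paf_line(rid, rlen, t, score))
        if len(tids) > 1 and rng.random() < decoy_fraction:
            decoy = tids[int(rng.integers(len(tids)))]
            lines.append(_paf_line(rid, rlen, decoy, max(1, score // 2)))
    return "".join(line + "\n" for line in lines), {t: c for t, c in truth.items() if c > 0}


def simulate_subtype_cohort(
    spec: Optional[CohortSpec] = None,
    amplified_ratio: Tuple[float, float] = (8.0, 20.0),
    normal_ratio: Tuple[float, float] = (0.0, 1.0),
    nagk_tpm: float = 200.0,
    scheme: str = "MYCN",
    tumor_type: str = "neuroblastoma_like",
) -> ExpressionMatrix:
    """A single-tumor-type cohort with a binary subtype structure.

    The two internal classes of ``simulate_cohort`` become the amplified /
    not-amplified subtypes (so a composite subtype model has signal to learn),
    and two designated marker genes are appended: NAGK at a fixed housekeeping
    level and MYCN at NAGK × ratio, with the ratio drawn uniformly from a
    subtype-specific interval. Rows are renormalized to sum to 1e6; the
    MYCN/NAGK ratio is unaffected by that rescaling.
    """
    if spec is None:
        spec = CohortSpec(
            n_classes=2, samples_per_class=15, n_genes=1000, n_signature_genes=30,
            library_size=30_000,
        )
    else:
        spec = replace(spec, n_classes=2)
    m = simulate_cohort(spec)
    rng = np.random.default_rng(spec.seed + 1)

    amplified = m.labels == _class_names(2)[1]  # second class = amplified
    ratios = np.where(
        amplified.to_numpy(),
        rng.uniform(*amplified_ratio, m.n_samples),
        rng.uniform(*normal_ratio, m.n_samples),
    )
    values = m.values.copy()
    values["NAGK"] = nagk_tpm
    values["MYCN"] = nagk_tpm * ratios
    values = values.div(values.sum(axis=1), axis=0) * 1e6

    subtype = pd.Series(
        np.where(amplified.to_numpy(), "amplified", "not_amplified"), index=m.values.index
    )
    return ExpressionMatrix(
        values=values,
        labels=pd.Series(tumor_type, index=m.values.index),
        groups=m.groups,
        subtype_labels={scheme: subtype},
    )
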