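"""Transcript and gene quantification from per-read alignments.

Multi-mapping reads receive partial (fractional) counts: each read contributes
total weight exactly 1, split among the transcripts tied at its best alignment
score (or, optionally, proportionally to score). Counts are normalized to
transcripts-per-million and collapsed to the gene level.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

from .io import AlignmentRecord, TranscriptGeneMap

UNMAPPED_GENE = "__unmapped__"


@dataclass
class ExpressionProfile:
    """Per-sample expression vector plus sequencing QC metrics.

    ``transcript_tpm`` and ``gene_tpm`` each sum to 1e6 whenever at least one
    read aligned; ``entropy`` is filled by the qc module.
    """

    sample_id: str
    transcript_tpm: Dict[str, float] = field(default_factory=dict)
    gene_tpm: Dict[str, float] = field(default_factory=dict)
    n_reads: int = 0
    n_aligned: int = 0
    read_n50: int = 0
    mean_read_length: float = 0.0
    entropy: Optional[float] = None

    @property
    def alignment_rate(self) -> float:
        return self.n_aligned / self.n_reads if self.n_reads else 0.0


def fractional_counts(
    alignments: Iterable[AlignmentRecord], weighted: bool = False
) -> Dict[str, float]:
    """Assign each read a total weight of 1 across its aligned transcripts.

    Default policy: the weight is split equally among the unique transcripts
    whose alignment score ties the read's maximum. With ``weighted=True`` the
    split is proportional to alignment score across all of the read's
    alignments instead.
    """
    by_read: Dict[str, List[AlignmentRecord]] = defaultdict(list)
    for rec in alignments:
        by_read[rec.read_id].append(rec)

    counts: Dict[str, float] = defaultdict(float)
    for recs in by_read.values():
        if weighted:
            # best score per unique target, then proportional split
            best_per_target: Dict[str, int] = {}
            for r in recs:
                if r.align_score > best_per_target.get(r.target_id, -1):
                    best_per_target[r.target_id] = r.align_score
            total = sum(best_per_target.values())
            if total <= 0:
                share = 1.0 / len(best_per_target)
                for t in best_per_target:
                    counts[t] += share
            else:
                for t, s in best_per_target.items():
                    counts[t] += s / total
        else:
            best = max(r.align_score for r in recs)
            tied = sorted({r.target_id for r in recs if r.align_score == best})
            share = 1.0 / len(tied)
            for t in tied:
                counts[t] += share
    return dict(counts)


def tpm_normalize(
    counts: Dict[str, float],
    lengths: Optional[Dict[str, int]] = None,
    length_normalize: bool = False,
) -> Dict[str, float]:
    """Normalize counts to transcripts-per-million (sums to 1e6).

    With ``length_normalize`` the classic TPM definition is used: counts are
    first divided by transcript length, then rescaled. All-zero input yields
    an all-zero result rather than dividing by zero.
    """
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    if length_normalize:
        if lengths is None:
            raise ValueError("length_normalize requires transcript lengths")
        rates = {}
        for t, c in counts.items():
            length = lengths.get(t)
            if length is None or length <= 0:
                raise ValueError(f"missing/invalid length for transcript {t}")
            rates[t] = c / length
    else:
        rates = dict(counts)
    total = sum(rates.values())
    if total <= 0:
        return {t: 0.0 for t in counts}
    return {t: r / total * 1e6 for t, r in rates.items()}


def collapse_genes(
    transcript_tpm: Dict[str, float], t2g: TranscriptGeneMap
) -> Dict[str, float]:
    """Sum transcript-level TPM to the gene level; the grand total is conserved.

    Transcripts absent from the map are routed to the ``__unmapped__`` bucket
    with a warning so that the compositional total stays intact.
    """
    gene_tpm: Dict[str, float] = defaultdict(float)
    unmapped = []
    for tid, tpm in transcript_tpm.items():
        gene = t2g.gene_of(tid)
        if gene is None:
            if tpm > 0:
                unmapped.append(tid)
            gene = UNMAPPED_GENE
        gene_tpm[gene] += tpm
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} expressed transcripts not in t2g map, "
            f"routed to {UNMAPPED_GENE!r} (e.g. {unmapped[:3]})",
            stacklevel=2,
        )
    if not gene_tpm.get(UNMAPPED_GENE, 1.0):
        del gene_tpm[UNMAPPED_GENE]
    return dict(gene_tpm)


def read_n50(lengths: Sequence[int]) -> int:
    """N50: the largest length L such that reads of length >= L together cover
    at least half of all sequenced bases."""
    if not lengths:
        raise ValueError("read_n50 requires at least one read length")
    if any(l <= 0 for l in lengths):
        raise ValueError("read lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2.0
    acc = 0
    for l in ordered:
        acc += l
        if acc >= half:
            return l
    return ordered[-1]  # unreachable; keeps the function total


def quantify_sample(
    alignments: Iterable[AlignmentRecord],
    t2g: TranscriptGeneMap,
    sample_id: str = "sample",
    weighted_split: bool = False,
    length_normalize: bool = False,
    total_reads: Optional[int] = None,
) -> ExpressionProfile:
    """Full per-sample quantification: fractional counts → TPM → gene collapse,
    plus read-level QC (N50, mean length).

    ``total_reads`` (e.g. from a sequencing summary) lets the alignment rate
    account for unmapped reads that never appear in a PAF; otherwise the
    distinct read ids seen are used.
    """
    recs = list(alignments)
    read_lengths: Dict[str, int] = {}
    for r in recs:
        read_lengths[r.read_id] = max(read_lengths.get(r.read_id, 0), r.read_length)

    counts = fractional_counts(recs, weighted=weighted_split)
    n_aligned = len(read_lengths)
    total = sum(counts.values())
    if recs and not math.isclose(total, n_aligned, rel_tol=0, abs_tol=1e-9 * max(1, n_aligned)):
        raise AssertionError(f"count conservation violated: {total} != {n_aligned}")

    lengths = None
    if length_normalize:
        lengths = {t: t2g.length_of(t) or 0 for t in counts}
    transcript_tpm = tpm_normalize(counts, lengths=lengths, length_normalize=length_normalize)
    gene_tpm = collapse_genes(transcript_tpm, t2g) if transcript_tpm else {}

    lens = list(read_lengths.values())
    return ExpressionProfile(
        sample_id=sample_id,
        transcript_tpm=transcript_tpm,
        gene_tpm=gene_tpm,
        n_reads=total_reads if total_reads is not None else n_aligned,
        n_aligned=n_aligned,
        read_n50=read_n50(lens) if lens else 0,
        mean_read_length=float(sum(lens)) / len(lens) if lens else 0.0,
    )
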