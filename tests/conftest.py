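from collections import defaultdict

import numpy as np
import pandas as pd
import pytest

from nanotype.io import AlignmentRecord, TranscriptGeneMap
from nanotype.matrix import ExpressionMatrix


@pytest.fixture
def t2g_two_genes() -> TranscriptGeneMap:
    """Four transcripts over two genes, for collapse tests."""
    return TranscriptGeneMap(
        {
            "T1a": ("G1", "GENE1", 500),
            "T1b": ("G1", "GENE1", 700),
            "T2a": ("G2", "GENE2", 900),
            "T2b": ("G2", "GENE2", 300),
        }
    )


def make_matrix(values: np.ndarray, labels=None, groups=None) -> ExpressionMatrix:
    """Wrap a raw array into an ExpressionMatrix with default metadata."""
    n, g = values.shape
    samples = [f"s{i}" for i in range(n)]
    genes = [f"g{j}" for j in range(g)]
    labels = labels or ["A" if i < n // 2 else "B" for i in range(n)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=samples, columns=genes),
        labels=pd.Series(labels, index=samples),
        groups=pd.Series(groups or samples, index=samples),
    )


def brute_force_fractional_counts(records) -> dict:
    """Independent per-read enumeration: for each read, find its maximum score
    by pairwise comparison, collect the unique score-tied targets, and split a
    unit weight among them."""
    reads = sorted({r.read_id for r in records})
    counts: dict = defaultdict(float)
    for rid in reads:
        mine = [r for r in records if r.read_id == rid]
        best = mine[0].align_score
        for r in mine:
            if r.align_score > best:
                best = r.align_score
        winners = sorted({r.target_id for r in mine if r.align_score == best})
        for t in winners:
            counts[t] += 1.0 / len(winners)
    return dict(counts)


def brute_force_n50(lengths) -> int:
    """Try every observed length as the threshold; keep the largest one whose
    covered bases reach half the total."""
    total = sum(lengths)
    best = 0
    for candidate in sorted(set(lengths)):
        covered = sum(l for l in lengths if l >= candidate)
        if covered >= total / 2 and candidate > best:
            best = candidate
    return best
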