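"""Cohort expression matrix assembly and the zero-fraction gene filter.

Low-coverage cDNA sequencing samples the transcriptome sparsely; genes that
are unobserved in more than a small fraction of samples destabilize downstream
models, so the cohort matrix is aggressively filtered before classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd

from .io import SampleSheet
from .quantify import ExpressionProfile

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Samples × genes TPM matrix with per-sample labels and replicate groups.

    ``values`` is indexed by sample id (rows) and gene id (columns); ``labels``
    and ``groups`` are Series over the same sample index. ``subtype_labels``
    maps a scheme name (e.g. "FOXO1", "MYCN") to a per-sample label Series
    which may contain missing values for uncharacterized samples.
    """

    values: pd.DataFrame
    labels: pd.Series
    groups: pd.Series
    subtype_labels: Dict[str, pd.Series] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("duplicate sample ids in matrix")
        if v.columns.has_duplicates:
            raise ValueError("duplicate gene ids in matrix")
        arr = v.to_numpy(dtype=float)
        if arr.size and (not np.isfinite(arr).all() or (arr < 0).any()):
            raise ValueError("matrix values must be finite and non-negative")
        self.labels = self.labels.reindex(v.index)
        self.groups = self.groups.reindex(v.index)
        if self.labels.isna().any():
            raise ValueError(f"missing labels for samples: {list(v.index[self.labels.isna()])}")
        if self.groups.isna().any():
            raise ValueError(f"missing groups for samples: {list(v.index[self.groups.isna()])}")
        self.subtype_labels = {
            scheme: s.reindex(v.index) for scheme, s in self.subtype_labels.items()
        }

    @property
    def samples(self) -> List[str]:
        return list(self.values.index)

    @property
    def genes(self) -> List[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> List[str]:
        return sorted(self.labels.unique())

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(
            values=self.values.loc[ids],
            labels=self.labels.loc[ids],
            groups=self.groups.loc[ids],
            subtype_labels={k: s.loc[ids] for k, s in self.subtype_labels.items()},
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[:, list(gene_ids)],
            labels=self.labels,
            groups=self.groups,
            subtype_labels=dict(self.subtype_labels),
        )

    def with_labels(self, labels: pd.Series) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values,
            labels=labels,
            groups=self.groups,
            subtype_labels=dict(self.subtype_labels),
        )


def assemble(profiles: Sequence[ExpressionProfile], sheet: SampleSheet) -> ExpressionMatrix:
    """Stack per-sample gene TPM vectors into a labeled cohort matrix.

    The gene set is the union over profiles (absent gene → 0). Every profile
    must have a row in the sample sheet.
    """
    if not profiles:
        raise ValueError("no profiles to assemble")
    missing = [p.sample_id for p in profiles if p.sample_id not in sheet.frame.index]
    if missing:
        raise ValueError(f"profiles without sample-sheet metadata: {missing}")
    genes = sorted(set().union(*(p.gene_tpm.keys() for p in profiles)))
    sample_ids = [p.sample_id for p in profiles]
    data = np.zeros((len(profiles), len(genes)))
    gene_pos = {g: j for j, g in enumerate(genes)}
    for i, p in enumerate(profiles):
        for g, tpm in p.gene_tpm.items():
            data[i, gene_pos[g]] = tpm
    values = pd.DataFrame(data, index=sample_ids, columns=genes)
    subtypes = {
        scheme: sheet.subtype_labels(scheme).reindex(sample_ids)
        for scheme in sheet.subtype_schemes
    }
    return ExpressionMatrix(
        values=values,
        labels=sheet.labels.reindex(sample_ids),
        groups=sheet.groups.reindex(sample_ids),
        subtype_labels=subtypes,
    )


def filter_genes(m: ExpressionMatrix, max_zero_fraction: float = 0.01) -> ExpressionMatrix:
    """Drop genes with zero expression in strictly more than ``max_zero_fraction``
    of samples (default: > 1%).

    Sample set and the order of surviving genes are unchanged. Removing every
    gene is an error — relax the threshold or check the input coverage.
    """
    if m.n_samples == 0 or m.n_genes == 0:
        raise ValueError("cannot filter an empty matrix")
    zero_fraction = (m.values.to_numpy() == 0).mean(axis=0)
    keep = zero_fraction <= max_zero_fraction
    if not keep.any():
        raise ValueError(
            f"zero-fraction filter at {max_zero_fraction} removed all {m.n_genes} genes; "
            "relax max_zero_fraction or check input coverage"
        )
    kept_genes = [g for g, k in zip(m.genes, keep) if k]
    logger.info("gene filter: %d -> %d genes", m.n_genes, len(kept_genes))
    return m.subset_genes(kept_genes)
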