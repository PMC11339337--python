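"""Readers and writers: PAF/SAM alignments, transcript→gene maps, sample sheets,
expression matrices.

Alignment input is the output of minimap2 run against a transcriptome reference
(the documented invocation for short fragmented cDNA reads is
``minimap2 -x map-ont -k12 -w1 -n2 -m20 ref_mRNA_ncRNA.fa reads.fq``); this
module consumes that output, it never runs the aligner.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Tuple, Union

import pandas as pd
import pysam


class PafParseError(ValueError):
    """Raised for a malformed PAF line; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"PAF line {line_number}: {message}")


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-transcript alignment, the unit of evidence for quantification."""

    read_id: str
    read_length: int
    target_id: str
    align_score: int
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError(f"read_length must be positive, got {self.read_length}")
        if self.align_score < 0:
            raise ValueError(f"align_score must be >= 0, got {self.align_score}")
        if not self.target_id:
            raise ValueError("target_id must be non-empty")


def strip_version(transcript_id: str) -> str:
    """Drop an ENSEMBL-style version suffix ("ENST...3" -> "ENST...")."""
    head, dot, tail = transcript_id.rpartition(".")
    if dot and tail.isdigit():
        return head
    return transcript_id


def _iter_lines(source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            yield from fh
    else:
        yield from source


def read_paf(source) -> List[AlignmentRecord]:
    """Parse PAF (minimap2 default output) into alignment records.

    ``source`` may be a path, an open text stream, or an iterable of lines.
    The alignment score is the ``AS:i`` tag when present, otherwise column 10
    (number of residue matches). Unmapped reads never appear in PAF, so they
    are simply absent from the result.
    """
    records: List[AlignmentRecord] = []
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise PafParseError(lineno, f"expected >= 12 tab-separated columns, got {len(fields)}")
        try:
            read_id = fields[0]
            read_length = int(fields[1])
            target_id = fields[5]
            n_match = int(fields[9])
        except ValueError as exc:
            raise PafParseError(lineno, f"non-integer numeric column: {exc}") from None
        score = n_match
        is_primary = True
        for tag in fields[12:]:
            if tag.startswith("AS:i:"):
                score = int(tag[5:])
            elif tag.startswith("tp:A:"):
                is_primary = tag[5:] == "P"
        try:
            records.append(
                AlignmentRecord(
                    read_id=read_id,
                    read_length=read_length,
                    target_id=target_id,
                    align_score=max(score, 0),
                    is_primary=is_primary,
                )
            )
        except ValueError as exc:
            raise PafParseError(lineno, str(exc)) from None
    return records


def read_sam(path: Union[str, Path]) -> List[AlignmentRecord]:
    """Read SAM/BAM alignments against a transcriptome into alignment records.

    Unmapped records are skipped. A record without an AS tag falls back to the
    number of aligned query bases from its CIGAR. Secondary/supplementary
    status is preserved in ``is_primary``.
    """
    records: List[AlignmentRecord] = []
    with pysam.AlignmentFile(os.fspath(path), "r") as fh:
        if not fh.header.references:
            raise ValueError(f"{path}: SAM header has no reference sequences")
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            if aln.has_tag("AS"):
                score = int(aln.get_tag("AS"))
            else:
                score = aln.query_alignment_length
            read_length = aln.query_length or aln.infer_read_length() or aln.query_alignment_length
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    read_length=int(read_length),
                    target_id=aln.reference_name,
                    align_score=max(int(score), 0),
                    is_primary=not (aln.is_secondary or aln.is_supplementary),
                )
            )
    return records


class TranscriptGeneMap:
    """Function-valued transcript → (gene_id, gene_symbol, length) mapping.

    Lookups tolerate ENSEMBL version suffixes on the query id; keys are stored
    version-stripped.
    """

    def __init__(self, entries: Dict[str, Tuple[str, str, int]]):
        self._entries: Dict[str, Tuple[str, str, int]] = {}
        for tid, (gene_id, symbol, length) in entries.items():
            if int(length) <= 0:
                raise ValueError(f"transcript {tid}: non-positive length {length}")
            self._entries[strip_version(tid)] = (gene_id, symbol, int(length))

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, transcript_id: str) -> bool:
        return strip_version(transcript_id) in self._entries

    def gene_of(self, transcript_id: str) -> Optional[str]:
        entry = self._entries.get(strip_version(transcript_id))
        return entry[0] if entry else None

    def symbol_of(self, transcript_id: str) -> Optional[str]:
        entry = self._entries.get(strip_version(transcript_id))
        return entry[1] if entry else None

    def length_of(self, transcript_id: str) -> Optional[int]:
        entry = self._entries.get(strip_version(transcript_id))
        return entry[2] if entry else None

    @property
    def transcript_ids(self) -> List[str]:
        return list(self._entries)


def read_t2g(source) -> TranscriptGeneMap:
    """Read a TSV transcript→gene table (columns: transcript_id, gene_id,
    gene_symbol, length).

    Duplicate transcript rows pointing at the same gene are deduplicated;
    duplicates pointing at different genes are an error (the map must be a
    function).
    """
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, sep="\t", dtype=str)
    else:
        df = pd.read_csv(_io.StringIO("".join(_iter_lines(source))), sep="\t", dtype=str)
    required = {"transcript_id", "gene_id", "gene_symbol", "length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"t2g table missing columns: {sorted(missing)}")
    entries: Dict[str, Tuple[str, str, int]] = {}
    for row in df.itertuples(index=False):
        tid = strip_version(str(row.transcript_id))
        entry = (str(row.gene_id), str(row.gene_symbol), int(row.length))
        if entry[2] <= 0:
            raise ValueError(f"transcript {tid}: non-positive length {entry[2]}")
        if tid in entries:
            if entries[tid][0] != entry[0]:
                raise ValueError(
                    f"transcript {tid} maps to conflicting genes "
                    f"{entries[tid][0]!r} and {entry[0]!r}"
                )
            continue
        entries[tid] = entry
    return TranscriptGeneMap(entries)


class SampleSheet:
    """Per-sample metadata: diagnosis label, replicate group, optional subtype
    labels / purity / therapy status.

    ``group_id`` defaults to the sample's own id, so singleton samples form
    their own replicate groups.
    """

    _RESERVED = {"sample_id", "group_id", "label", "purity", "therapy_status"}

    def __init__(self, frame: pd.DataFrame):
        df = frame.copy()
        if "sample_id" not in df.columns or "label" not in df.columns:
            raise ValueError("sample sheet requires 'sample_id' and 'label' columns")
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if "group_id" not in df.columns:
            df["group_id"] = df["sample_id"]
        else:
            df["group_id"] = df["group_id"].fillna(df["sample_id"])
        self.frame = df.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.frame.index)

    @property
    def labels(self) -> pd.Series:
        return self.frame["label"]

    @property
    def groups(self) -> pd.Series:
        return self.frame["group_id"]

    @property
    def subtype_schemes(self) -> List[str]:
        return [c for c in self.frame.columns if c not in self._RESERVED]

    def subtype_labels(self, scheme: str) -> pd.Series:
        if scheme not in self.subtype_schemes:
            raise KeyError(f"no subtype scheme {scheme!r} in sample sheet")
        return self.frame[scheme]


def read_sample_sheet(source) -> SampleSheet:
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, sep="\t")
    else:
        df = pd.read_csv(_io.StringIO("".join(_iter_lines(source))), sep="\t")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: Union[str, Path]) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


def write_matrix(matrix, path: Union[str, Path], float_format: str = "%.12g") -> None:
    """Write an expression matrix as TSV: rows are genes, one column per sample."""
    df = matrix.values.T  # genes x samples
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=float_format)


def read_matrix(path: Union[str, Path], sheet: Optional[SampleSheet] = None):
    """Read a gene (rows) × sample (columns) TSV back into an ExpressionMatrix.

    When ``sheet`` is given, labels/groups/subtype labels are attached from it;
    otherwise placeholder labels are used and every sample is its own group.
    """
    from .matrix import ExpressionMatrix  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged or non-numeric matrix rows")
    values = df.T  # samples x genes
    values.index = values.index.astype(str)
    samples = list(values.index)
    if sheet is not None:
        missing = [s for s in samples if s not in sheet.frame.index]
        if missing:
            raise ValueError(f"samples absent from sample sheet: {missing}")
        labels = sheet.labels.reindex(samples)
        groups = sheet.groups.reindex(samples)
        subtypes = {
            scheme: sheet.subtype_labels(scheme).reindex(samples)
            for scheme in sheet.subtype_schemes
        }
    else:
        labels = pd.Series("NA", index=samples)
        groups = pd.Series(samples, index=samples)
        subtypes = {}
    return ExpressionMatrix(values=values, labels=labels, groups=groups, subtype_labels=subtypes)


def read_profile(path: Union[str, Path]) -> pd.Series:
    """Read a two-column TSV (id, tpm) into a Series keyed by id."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (id, tpm)")
    return pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str))


def write_profile(tpm: Dict[str, float], path: Union[str, Path], id_name: str = "gene_id") -> None:
    df = pd.DataFrame({id_name: list(tpm.keys()), "tpm": list(tpm.values())})
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
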