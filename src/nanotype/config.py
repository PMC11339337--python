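"""Run configuration shared across the pipeline.

Every tunable that the pipeline exposes lives here so that a single resolved
config can be embedded in outputs (models, reports) for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

import yaml

_TRANSFORMS = ("log2p1", "none")
_KERNELS = ("rbf", "linear")
_FILTER_SCOPES = ("train_only", "cohort")


@dataclass
class RunConfig:
    """Resolved pipeline configuration with documented defaults.

    Parameters
    ----------
    transform:
        Expression transform applied before PLS ("log2p1" = log2(TPM+1), or
        "none" for raw TPM).
    length_normalize:
        If True, classic TPM with a per-transcript length term; default is
        counts-per-million semantics (short fragmented cDNA reads do not tile
        transcripts uniformly, so the length term is off by default).
    weighted_split:
        If True, multi-mapping reads are split proportionally to alignment
        score instead of equally among best-score ties.
    component_range:
        Inclusive range of PLS component counts fitted per contrast.
    svm_kernel:
        Kernel of the stacking SVM ("rbf" or "linear").
    entropy_base:
        Logarithm base for Shannon entropy; 2 (bits) or "e" (nats).
    filter_scope:
        Whether the zero-fraction gene filter is refit on each training fold
        ("train_only", leakage-free) or once on the whole cohort ("cohort").
    max_zero_fraction:
        A gene is dropped when the fraction of samples with zero expression
        strictly exceeds this value.
    thresholds:
        Prediction-probability tiers reported by the evaluator (strict >).
    mycn_threshold:
        MYCN/NAGK expression ratio at or above which a sample is called
        MYCN-amplified.
    seed:
        Seed for every stochastic sub-step (SVM probability calibration).
    """

    transform: str = "log2p1"
    length_normalize: bool = False
    weighted_split: bool = False
    component_range: tuple = (5, 11)
    svm_kernel: str = "rbf"
    entropy_base: Union[float, str] = 2
    filter_scope: str = "train_only"
    max_zero_fraction: float = 0.01
    thresholds: tuple = (0.5, 0.6, 0.8)
    mycn_threshold: float = 5.0
    seed: int = 17

    def __post_init__(self) -> None:
        if self.transform not in _TRANSFORMS:
            raise ValueError(f"transform must be one of {_TRANSFORMS}, got {self.transform!r}")
        if self.svm_kernel not in _KERNELS:
            raise ValueError(f"svm_kernel must be one of {_KERNELS}, got {self.svm_kernel!r}")
        if self.filter_scope not in _FILTER_SCOPES:
            raise ValueError(f"filter_scope must be one of {_FILTER_SCOPES}")
        lo, hi = (int(x) for x in self.component_range)
        if not (1 <= lo <= hi):
            raise ValueError(f"component_range must satisfy 1 <= lo <= hi, got {self.component_range}")
        self.component_range = (lo, hi)
        if not (0.0 <= self.max_zero_fraction <= 1.0):
            raise ValueError("max_zero_fraction must lie in [0, 1]")
        if self.entropy_base != "e" and not float(self.entropy_base) > 0:
            raise ValueError("entropy_base must be 'e' or a positive number")
        self.thresholds = tuple(float(t) for t in self.thresholds)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a YAML mapping")
        return cls.from_dict(data)
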