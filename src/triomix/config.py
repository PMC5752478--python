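"""Run configuration: the thresholds that drive every stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .io import TriomixError


@dataclass
class RunConfig:
    """Pipeline thresholds and knobs.

    Attributes
    ----------
    p_de
        Significance cutoff for differential calls (applied to p or, in
        ``bh`` mode, to q).
    lfc_min
        Minimum |log2 fold change| for the miRNA layer (difference on the
        log2 scale). The protein layer uses ``protein_lfc_min``; set it to
        0 for the p-value-only call some iTRAQ workflows use (expect a
        false-positive rate of about p_de times the feature count).
    vip_min
        VIP threshold for metabolite selection. 8.0 reflects dominant-peak
        LC-MS intensity tables; on variance-homogeneous data the
        field-standard cutoff is 1.0.
    r_min, p_edge_max
        Cross-layer edge filter: keep |r| >= r_min and p <= p_edge_max.
    n_orthogonal
        Orthogonal components removed by OPLS-DA before the predictive fit.
    cv_folds
        Cross-validation folds for Q2 (capped at the smallest class size).
    multiple_testing
        ``raw`` (per-feature p, mirrors the source analyses) or ``bh``.
    impact_min
        Topology-impact threshold flagging a "potential pathway".
    """

    p_de: float = 0.05
    lfc_min: float = 1.0
    protein_lfc_min: float = 1.0
    vip_min: float = 8.0
    r_min: float = 0.9
    p_edge_max: float = 0.05
    n_orthogonal: int = 1
    cv_folds: int = 7
    seed: int = 0
    multiple_testing: str = "raw"
    impact_min: float = 0.1

    def __post_init__(self) -> None:
        for name in ("p_de", "p_edge_max"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise TriomixError(f"{name} must be in (0, 1], got {v}")
        if not 0 <= self.r_min <= 1:
            raise TriomixError(f"r_min must be in [0, 1], got {self.r_min}")
        if self.vip_min <= 0:
            raise TriomixError(f"vip_min must be > 0, got {self.vip_min}")
        if self.cv_folds < 2:
            raise TriomixError(f"cv_folds must be >= 2, got {self.cv_folds}")
        if self.n_orthogonal < 0:
            raise TriomixError("n_orthogonal must be >= 0")
        if self.multiple_testing not in ("raw", "bh"):
            raise TriomixError("multiple_testing must be 'raw' or 'bh'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
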