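"""Pipeline configuration.

A single dataclass carries every tunable of the scoring pipeline, from
normalization through curve fitting to BPS normalization.  All stages take a
``Config`` (or individual keyword arguments mirroring it); the CLI loads the
same keys from a YAML file.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Optional

logger = logging.getLogger("lpcbps")


@dataclass
class Config:
    # --- preprocessing ---
    #: divide by reference "variance" (literal method description) or "sd"
    scale: str = "variance"
    #: genes with variance strictly below this quantile are removed
    variance_filter_quantile: float = 0.25
    #: keep leading PCs whose tumor variance exceeds (1+fraction)*normal variance
    pc_excess_fraction: float = 0.10
    #: "contiguous" scan stopping at the first failing PC, or "count_all"
    component_rule: str = "contiguous"
    #: "total": tumor PC variance vs fraction of the normals' total variance;
    #: "per_component": vs (1+fraction) times the normal variance on that PC
    component_compare: str = "total"
    #: without reference samples: smallest k explaining this variance fraction
    explained_variance_fallback: float = 0.80
    #: cap on mapping-space dimension; trailing PCs are noise and destabilize
    #: the kernel-weighted curve search
    max_components: int = 4
    #: gene sets with fewer matched genes are skipped
    min_genes_per_set: int = 2

    # --- local principal curve ---
    #: per-dimension kernel bandwidth as a fraction of the data range
    bandwidth_fraction: float = 0.10
    #: step size t0; None -> mean of the per-dimension bandwidths
    step_size: Optional[float] = None
    #: convergence threshold on center-of-mass movement; None -> 1e-3*mean(h)
    tol: Optional[float] = None
    #: per-direction iteration cap; None -> 10*n
    max_iter: Optional[int] = None
    #: 1.0 = pure sign-flip continuity; <1 blends with the previous direction
    angle_penalty: float = 1.0
    #: stop when kernel mass falls below this fraction of the densest point seen
    boundary_frac: float = 0.01
    #: None -> one-sided from a reference start, two-sided from a mean-shift start
    two_sided: Optional[bool] = None

    # --- curve parameterization / projection ---
    grid_per_interval: int = 50
    projection_refine: bool = True
    #: tangent-ray extension beyond each curve end, as a fraction of arc length
    extension_fraction: float = 0.25

    # --- scoring ---
    #: "minmax" or "clamp_minmax" projection-index normalization
    normalization: str = "minmax"
    #: case-insensitive gene-symbol matching between GMT and expression
    case_insensitive: bool = False

    def __post_init__(self) -> None:
        if self.scale not in ("variance", "sd"):
            raise ValueError(f"scale must be 'variance' or 'sd', got {self.scale!r}")
        if self.component_rule not in ("contiguous", "count_all"):
            raise ValueError(f"unknown component_rule {self.component_rule!r}")
        if self.component_compare not in ("total", "per_component"):
            raise ValueError(f"unknown component_compare {self.component_compare!r}")
        if self.normalization not in ("minmax", "clamp_minmax"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if not 0.0 <= self.variance_filter_quantile < 1.0:
            raise ValueError("variance_filter_quantile must be in [0, 1)")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "Config":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path) -> "Config":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config YAML must contain a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
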