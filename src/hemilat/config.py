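"""Pipeline configuration.

One :class:`PipelineConfig` object carries every tunable of the analysis:
the graph-threshold grid, the train/test split, the repetition count, the
feature-selection and random-forest settings, and the switches that resolve
deliberately-exposed methodological choices (weight-normalizer scope,
self-correlation handling, inter-network reading, leakage guard).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml


@dataclass
class PipelineConfig:
    #: graph thresholds applied to each hemispheric network before nodal
    #: metrics; metric curves are integrated (trapezoid) over this grid.
    threshold_grid: tuple[float, ...] = tuple(np.round(np.arange(0.60, 0.951, 0.05), 2))
    train_fraction: float = 0.7
    n_repetitions: int = 100
    segmentation_k: int = 1
    rng_seed: int = 0
    #: weighting coefficients on/off (off reproduces the unweighted ablation)
    weighting_enabled: bool = True
    #: scope of the weight normalizer mean for the connectivity index:
    #: "all_rois" (mean over all seeds) or "per_hemisphere".
    weight_normalizer_scope: str = "all_rois"
    #: include the seed's self-correlation (always 1) in its own-hemisphere
    #: mean; off by default (the unbiased reading).
    include_self: bool = False
    #: "cross_only": the inter-hemispheric network keeps only cross edges;
    #: "full": the whole connectome unmodified.
    inter_network: str = "cross_only"
    #: betweenness on the binarized graph ("binary") or with inverse-weight
    #: distances ("weighted").
    betweenness_mode: str = "binary"
    #: cap on features retained by the decision-tree selector (None = no cap)
    max_features: int | None = None
    #: class weighting: "balanced" or "logistic" (one-pass multinomial
    #: logistic recalibration, weight proportional to inverse class recall)
    class_weighting: str = "balanced"
    rf_n_estimators: tuple[int, ...] = (100, 200, 500)
    rf_max_depth: tuple[int | None, ...] = (None, 5, 10)
    rf_cv_folds: int = 3
    #: keep all segments of one original subject on one side of the split
    leakage_guard: bool = True

    def __post_init__(self) -> None:
        grid = tuple(float(t) for t in self.threshold_grid)
        if any(not 0 < t < 1 for t in grid):
            raise ValueError("threshold grid must lie strictly inside (0, 1)")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("threshold grid must be strictly increasing")
        self.threshold_grid = grid
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.segmentation_k < 1:
            raise ValueError("segmentation_k must be >= 1")
        if self.weight_normalizer_scope not in ("all_rois", "per_hemisphere"):
            raise ValueError("weight_normalizer_scope must be all_rois|per_hemisphere")
        if self.inter_network not in ("cross_only", "full"):
            raise ValueError("inter_network must be cross_only|full")
        if self.betweenness_mode not in ("binary", "weighted"):
            raise ValueError("betweenness_mode must be binary|weighted")
        if self.class_weighting not in ("balanced", "logistic"):
            raise ValueError("class_weighting must be balanced|logistic")
        self.rf_n_estimators = tuple(int(n) for n in self.rf_n_estimators)
        self.rf_max_depth = tuple(
            None if d in (None, "none", "None") else int(d) for d in self.rf_max_depth
        )

    @property
    def rf_grid(self) -> list[dict]:
        """Grid-search candidates in deterministic order (ties -> first)."""
        return [
            {"n_estimators": n, "max_depth": d}
            for n in self.rf_n_estimators
            for d in self.rf_max_depth
        ]

    def as_dict(self) -> dict:
        d = asdict(self)
        d["threshold_grid"] = list(self.threshold_grid)
        d["rf_n_estimators"] = list(self.rf_n_estimators)
        d["rf_max_depth"] = list(self.rf_max_depth)
        return d


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config file, apply keyword overrides, and validate."""
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**values)
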