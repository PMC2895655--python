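"""Configuration objects for the simulation and the analysis pipeline.

All randomness in the package flows from a single integer seed through
:class:`numpy.random.SeedSequence` spawn keys, so each simulation stage
(ChIP, expression, reporters) draws from an independent, reproducible
stream and can be re-simulated on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

__all__ = ["SimulationConfig", "PipelineConfig"]

# spawn keys for the per-stage random streams
_STREAM_CHIP = 0
_STREAM_EXPR = 1
_STREAM_REPORTER = 2
_STREAM_LAYOUT = 3


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


def _check_mixture(name: str, mixture: Mapping[str, float]) -> None:
    for key, p in mixture.items():
        _check_fraction(f"{name}[{key!r}]", p)
    total = float(sum(mixture.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1, got {total}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic two-colour array study.

    Defaults encode the experimental design being emulated: overlapping
    3 kb tiles, two antibodies with four IP replicates plus four matched
    mock precipitations per timepoint, six one-hour expression timepoints
    with four replicate mutant-vs-wild-type hybridisations, and
    dual-titration (1 ng / 10 ng) luciferase reporter assays.
    """

    genome_length: int = 2_000_000
    tile_length: int = 3_000
    tile_step: int = 1_500

    n_genes: int = 1_000
    n_bound_A: int = 40
    n_bound_B: int = 40
    #: fraction of A-bound regions that are also bound by B
    cobind_fraction: float = 0.69
    #: length of a planted bound site (an enhancer-sized interval)
    site_length: int = 1_000
    #: antibody-specific spurious sites, removed by the dual-antibody rule
    n_offtarget_per_antibody: int = 10

    n_antibodies: int = 2
    n_ip_replicates_per_antibody: int = 4
    n_mock: int = 4
    chip_effect_log2: float = 1.2
    chip_noise_sd: float = 0.25
    #: per-antibody multiplier on the planted effect
    antibody_efficiency: tuple[float, ...] = (1.0, 0.8)

    n_timepoints_expr: int = 6
    n_expr_replicates: int = 4
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "down_both": 0.10,
            "up_in_A_mut": 0.05,
            "divergent": 0.05,
            "down_A_only": 0.05,
            "null": 0.75,
        }
    )
    expr_effect_log2: float = 1.5
    expr_noise_sd: float = 0.5

    n_enhancers: int = 24
    reporter_modes: dict[str, float] = field(
        default_factory=lambda: {
            "additive": 1 / 3,
            "cooperative": 1 / 3,
            "repressive": 1 / 3,
        }
    )
    synergy_gamma: float = 1.0
    repression_kappa: float = 0.3
    reporter_cv: float = 0.1
    n_reporter_replicates: int = 9

    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "genome_length": self.genome_length,
            "tile_length": self.tile_length,
            "tile_step": self.tile_step,
            "n_genes": self.n_genes,
            "n_antibodies": self.n_antibodies,
            "n_ip_replicates_per_antibody": self.n_ip_replicates_per_antibody,
            "n_mock": self.n_mock,
            "n_timepoints_expr": self.n_timepoints_expr,
            "n_expr_replicates": self.n_expr_replicates,
            "n_enhancers": self.n_enhancers,
            "n_reporter_replicates": self.n_reporter_replicates,
            "site_length": self.site_length,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        for name, value in (
            ("n_bound_A", self.n_bound_A),
            ("n_bound_B", self.n_bound_B),
            ("n_offtarget_per_antibody", self.n_offtarget_per_antibody),
        ):
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if self.tile_step > self.tile_length:
            raise ValueError(
                "tile_step must not exceed tile_length "
                f"({self.tile_step} > {self.tile_length})"
            )
        if self.tile_length > self.genome_length:
            raise ValueError("tile grid does not cover the genome")
        _check_fraction("cobind_fraction", self.cobind_fraction)
        _check_mixture("class_proportions", self.class_proportions)
        _check_mixture("reporter_modes", self.reporter_modes)
        if len(self.antibody_efficiency) != self.n_antibodies:
            raise ValueError(
                "antibody_efficiency must have one entry per antibody"
            )
        if self.n_ip_replicates_per_antibody < 2:
            raise ValueError("need at least 2 IP replicates per antibody")
        if self.n_reporter_replicates < 3:
            raise ValueError("need at least 3 reporter replicates")

    # ------------------------------------------------------------------
    # random streams
    def _rng(self, stream: int) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed, spawn_key=(stream,))
        return np.random.default_rng(ss)

    def rng_chip(self) -> np.random.Generator:
        return self._rng(_STREAM_CHIP)

    def rng_expression(self) -> np.random.Generator:
        return self._rng(_STREAM_EXPR)

    def rng_reporter(self) -> np.random.Generator:
        return self._rng(_STREAM_REPORTER)

    def rng_layout(self) -> np.random.Generator:
        """Stream for the genome layout (sites, genes) shared by stages."""
        return self._rng(_STREAM_LAYOUT)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["antibody_efficiency"] = list(self.antibody_efficiency)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "antibody_efficiency" in d:
            d["antibody_efficiency"] = tuple(d["antibody_efficiency"])
        return cls(**d)


@dataclass
class PipelineConfig:
    """Thresholds and paths for a full pipeline run.

    The statistical thresholds default to the published analysis values:
    ChIP enrichment at FDR < 2% with fold > 1.5, differential expression
    at q < 1% with fold > 1.6 (|log2| > 0.7).
    """

    fixture_dir: str = "."
    out_dir: str = "run"

    fdr_max: float = 0.02
    min_fold: float = 1.5
    q_max: float = 0.01
    log2fc_min: float = 0.7
    window_bp: int = 10_000
    k: int = 4
    alpha: float = 0.05
    n_perm: int = 1_000
    seed: int = 0
    #: run the reporter-mode classification stage
    modes_stage: bool = True

    def __post_init__(self) -> None:
        _check_fraction("fdr_max", self.fdr_max)
        _check_fraction("q_max", self.q_max)
        _check_fraction("alpha", self.alpha)
        if self.min_fold <= 0:
            raise ValueError("min_fold must be positive")
        if self.log2fc_min < 0:
            raise ValueError("log2fc_min must be non-negative")
        if self.window_bp < 0:
            raise ValueError("window_bp must be non-negative")
        if self.k < 1:
            raise ValueError("k must be at least 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        return cls(**d)
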