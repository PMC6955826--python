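"""Pipeline configuration: one YAML file drives simulation and analysis.

Unknown keys are rejected so a typo in a configuration cannot silently
fall back to a default.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .exceptions import InvalidArgumentError
from .groupstats import DEFAULT_PAIRS
from .network import FixedEdgeRule, SurrogateEdgeRule
from .synthetic import (
    CohortSpec,
    CouplingGraph,
    GroupDegradation,
    generate_coupling_graph,
)

__all__ = ["PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GraphConfig(_Strict):
    """Base coupling graph of the healthy-control population."""

    n_nodes: int = 10
    density: float = 0.4
    weight_range: tuple[float, float] = (0.5, 0.9)
    max_lag: int = 3
    seed: int = 0
    nonlinearity_choices: tuple[str, ...] = (
        "linear",
        "linear",
        "quadratic",
        "monotone",
    )

    def build(self) -> CouplingGraph:
        return generate_coupling_graph(
            n_nodes=self.n_nodes,
            density=self.density,
            weight_range=self.weight_range,
            max_lag=self.max_lag,
            seed=self.seed,
            nonlinearity_choices=self.nonlinearity_choices,
        )


class DegradationConfig(_Strict):
    edge_deletion_prob: float = 0.0
    weight_attenuation: float = 0.0
    noise_inflation: float = 1.0

    def build(self) -> GroupDegradation:
        return GroupDegradation(
            self.edge_deletion_prob, self.weight_attenuation, self.noise_inflation
        )


class CohortConfig(_Strict):
    """Synthetic-cohort description (group sizes and degradations)."""

    n_subjects: dict[str, int] = Field(
        default_factory=lambda: {"HC": 27, "MCS": 24, "UWS": 24}
    )
    n_timepoints: int = 297
    sampling_interval: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0
    graph: GraphConfig = Field(default_factory=GraphConfig)
    degradation: dict[str, DegradationConfig] = Field(
        default_factory=lambda: {
            "HC": DegradationConfig(),
            "MCS": DegradationConfig(
                edge_deletion_prob=0.25, weight_attenuation=0.25, noise_inflation=1.25
            ),
            "UWS": DegradationConfig(
                edge_deletion_prob=0.5, weight_attenuation=0.5, noise_inflation=1.5
            ),
        }
    )

    def build(self) -> CohortSpec:
        return CohortSpec(
            n_subjects=dict(self.n_subjects),
            n_timepoints=self.n_timepoints,
            sampling_interval=self.sampling_interval,
            base_graph=self.graph.build(),
            degradation={g: d.build() for g, d in self.degradation.items()},
            noise_sd=self.noise_sd,
            seed=self.seed,
        )


class EdgeRuleConfig(_Strict):
    kind: Literal["surrogate", "fixed"] = "surrogate"
    alpha: float = 0.05
    n_surrogates: int = 100
    seed: int = 0
    threshold: float | None = None

    def build(self) -> SurrogateEdgeRule | FixedEdgeRule:
        if self.kind == "surrogate":
            return SurrogateEdgeRule(
                alpha=self.alpha, n_surrogates=self.n_surrogates, seed=self.seed
            )
        if self.threshold is None:
            raise InvalidArgumentError("fixed edge rule requires a threshold")
        return FixedEdgeRule(threshold=self.threshold)


class AnalysisConfig(_Strict):
    max_lag: int = 3
    edge_rule: EdgeRuleConfig = Field(default_factory=EdgeRuleConfig)
    alpha: float = 0.05
    bonferroni_family: int = 10
    pairs: list[tuple[str, str]] = Field(default_factory=lambda: list(DEFAULT_PAIRS))

    @field_validator("pairs", mode="before")
    @classmethod
    def _tuplify(cls, v):
        return [tuple(p) for p in v]


class PipelineConfig(_Strict):
    """Everything one end-to-end run needs.

    Exactly one data source: a synthetic ``cohort`` description, or an
    ``input_dir`` of per-subject time-course TSVs with JSON sidecars
    naming each subject's group.
    """

    cohort: CohortConfig | None = Field(default_factory=CohortConfig)
    input_dir: str | None = None
    output_dir: str = "fnconn-output"
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    return PipelineConfig.model_validate(raw)
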