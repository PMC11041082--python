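"""Scenario configuration files, output serialization and provenance.

A scenario file (YAML or JSON) describes a design (either explicit
allocation probabilities or a named allocation rule), the arm means and
standard deviations, the analysis, an optional time trend and the
simulation settings.  Unknown keys are rejected so typos fail loudly.
Every emitted artifact carries the package version, the seed and a hash of
the effective configuration, making reruns byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .designs import PlatformDesign
from .optimize import SQRT_K_CONTROL_SHARE, optimize_case3_cc
from .simulate import SimScenario, TimeTrendSpec

__all__ = ["ScenarioConfig", "load_scenario", "emit_report"]

_TOL = 1e-9


class DesignBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    N: float = Field(gt=0)
    r: list[float] = Field(min_length=3, max_length=3)
    p: Optional[list[list[float]]] = None
    rule: Optional[Literal["one", "sqrt", "opt"]] = None

    @field_validator("r")
    @classmethod
    def _r_simplex(cls, v):
        if any(x < 0 for x in v) or abs(sum(v) - 1.0) > _TOL:
            raise ValueError(f"period fractions must be >= 0 and sum to 1, got {v}")
        return v

    @field_validator("p")
    @classmethod
    def _p_rows(cls, v):
        if v is None:
            return v
        if len(v) != 3 or any(len(row) != 3 for row in v):
            raise ValueError("p must have 3 rows (periods) of 3 entries (control first)")
        for s, row in enumerate(v, start=1):
            if any(x < 0 for x in row):
                raise ValueError(f"allocation probabilities in period {s} must be >= 0")
            if abs(sum(row) - 1.0) > _TOL:
                raise ValueError(
                    f"allocation probabilities in period {s} sum to {sum(row)}, not 1"
                )
        return v


class ArmsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    means: list[float] = Field(default=[0.0, 0.0, 0.0], min_length=3, max_length=3)
    sds: list[float] = Field(default=[1.0, 1.0, 1.0], min_length=3, max_length=3)

    @field_validator("sds")
    @classmethod
    def _positive(cls, v):
        if any(x <= 0 for x in v):
            raise ValueError("standard deviations must be positive")
        return v


class AnalysisBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mode: Literal["cc", "ncc"] = "cc"
    test: Literal["t", "z"] = "t"
    alpha: float = Field(default=0.025, gt=0, lt=1)


class TrendBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    shape: Literal["none", "linear", "stepwise"] = "none"
    magnitude: float = 0.0
    equal_across_arms: bool = True


class SimulationBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    nsim: int = Field(default=10_000, gt=0)
    seed: int = 0


class ScenarioConfig(BaseModel):
    """Validated scenario: design, arms, analysis, trend and simulation."""

    model_config = ConfigDict(extra="forbid")

    design: DesignBlock
    arms: ArmsBlock = ArmsBlock()
    analysis: AnalysisBlock = AnalysisBlock()
    trend: TrendBlock = TrendBlock()
    simulation: SimulationBlock = SimulationBlock()

    def allocation_matrix(self) -> tuple[tuple[float, float, float], ...]:
        """Resolve the period-2 allocation rule to explicit probabilities."""
        if self.design.p is not None:
            return tuple(tuple(row) for row in self.design.p)
        if self.design.rule is None:
            raise ValueError("design needs either explicit p or an allocation rule")
        r1, r2 = self.design.r[0], self.design.r[1]
        if self.design.rule == "one":
            p2 = (1 / 3, 1 / 3, 1 / 3)
        elif self.design.rule == "sqrt":
            c = SQRT_K_CONTROL_SHARE
            p2 = (c, (1 - c) / 2, (1 - c) / 2)
        else:
            p2 = optimize_case3_cc(min(max(r1, 1e-9), 1 - 1e-9), r2).design.p[1]
        return ((0.5, 0.5, 0.0), p2, (0.5, 0.0, 0.5))

    def platform_design(self) -> PlatformDesign:
        return PlatformDesign(
            N=self.design.N,
            r=tuple(self.design.r),
            p=self.allocation_matrix(),
            sigma=tuple(self.arms.sds),
        )

    def sim_scenario(self) -> SimScenario:
        from .simulate import round_sample_sizes

        return SimScenario(
            counts=round_sample_sizes(self.platform_design()),
            means=tuple(self.arms.means),
            sigma=tuple(self.arms.sds),
            trend=TimeTrendSpec(**self.trend.model_dump()),
            analysis=self.analysis.mode,
            test=self.analysis.test,
            alpha=self.analysis.alpha,
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_scenario(path) -> ScenarioConfig:
    """Load and validate a YAML/JSON scenario file.

    Validation errors enumerate every offending key; defaults are
    materialized so the effective configuration can be echoed into outputs.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path} does not contain a mapping")
    return ScenarioConfig.model_validate(raw)


def _provenance(seed=None, config: ScenarioConfig | None = None) -> dict:
    prov = {"package": "platalloc", "version": __version__}
    if seed is not None:
        prov["seed"] = seed
    if config is not None:
        prov["config_hash"] = config.config_hash()
        prov["config"] = config.model_dump()
    return prov


def _to_jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def emit_report(results, path, fmt: str = "json", seed=None,
                config: ScenarioConfig | None = None) -> Path:
    """Write results as JSON (dict/records) or TSV (tabular) with provenance.

    ``results`` may be a pandas DataFrame, a dict, or a list of records.
    Rerunning with identical inputs produces byte-identical files.
    """
    import pandas as pd

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    prov = _provenance(seed=seed, config=config)
    if fmt == "tsv":
        if not isinstance(results, pd.DataFrame):
            results = pd.DataFrame(results)
        header = "".join(
            f"# {k}: {json.dumps(_to_jsonable(v), sort_keys=True)}\n"
            for k, v in prov.items()
        )
        body = results.to_csv(sep="\t", index=False, float_format="%.6g")
        path.write_text(header + body)
    elif fmt == "json":
        if isinstance(results, pd.DataFrame):
            results = results.to_dict(orient="records")
        payload = {"provenance": prov, "results": _to_jsonable(results)}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path
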