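"""End-to-end orchestration: simulate/load -> filter -> predict ->
classify -> validate -> report, with a reproducibility log."""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort import InclusionCriteria, apply_inclusion_filters
from .engine import CoefficientSet, default_coefficients
from .io import read_cohort_csv, write_cohort_csv, write_report
from .synthetic import CovariateMarginals, default_true_model, make_benchmark_cohort
from .validation import run_validation


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    out_dir: str = "crval_out"
    seed: int = 0
    cohort_path: Optional[str] = None    # simulate a benchmark cohort when None
    coeffs_path: Optional[str] = None    # illustrative defaults when None
    n_simulate: int = 20_000
    horizon_cap: float = 15.0
    n_groups: int = 5
    comparators: tuple[str, ...] = ("capra", "eau", "nccn")
    missing_m_as_m0: bool = False
    include_as_subgroup: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.horizon_cap <= 15:
            raise ValueError("horizon_cap must lie in (0, 15]")
        if self.n_groups < 2:
            raise ValueError("n_groups must be >= 2")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "comparators" in d:
            d["comparators"] = tuple(d["comparators"])
        return cls(**d)


def run_pipeline(config: PipelineConfig):
    """Execute every stage; on failure remove partial outputs and raise a
    stage-tagged :class:`PipelineError`."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        # --- configuration stage -----------------------------------------
        if config.coeffs_path is not None:
            try:
                coefs = CoefficientSet.from_json(config.coeffs_path)
            except (OSError, ValueError, KeyError) as exc:
                raise PipelineError("config", f"cannot load coefficients: {exc}")
        else:
            coefs = default_coefficients()

        # --- cohort stage ------------------------------------------------
        if config.cohort_path is not None:
            try:
                records = read_cohort_csv(config.cohort_path)
            except (OSError, ValueError) as exc:
                raise PipelineError("cohort", str(exc))
        else:
            records, _truth = make_benchmark_cohort(config.n_simulate, config.seed)
            p = out_dir / "cohort.csv"
            write_cohort_csv(records, p)
            written.append(p)

        # --- filter stage ------------------------------------------------
        criteria = InclusionCriteria(missing_m_as_m0=config.missing_m_as_m0)
        cohort, log = apply_inclusion_filters(records, criteria)
        if not cohort:
            raise PipelineError("filter", "no records pass the inclusion criteria")
        p = out_dir / "exclusion_log.json"
        with open(p, "w") as fh:
            json.dump(log.as_dict(), fh, indent=2)
        written.append(p)

        # --- validate stage (predict + classify + validate) ---------------
        try:
            report = run_validation(
                cohort,
                coefs,
                comparator_systems=config.comparators,
                n_groups=config.n_groups,
                horizon_cap=config.horizon_cap,
                include_as_subgroup=config.include_as_subgroup,
            )
        except ValueError as exc:
            raise PipelineError("validate", str(exc))

        written.extend(write_report(report, out_dir))

        # --- run log -----------------------------------------------------
        p = out_dir / "run_log.json"
        with open(p, "w") as fh:
            json.dump(
                {
                    "crval_version": __version__,
                    "python": platform.python_version(),
                    "numpy": np.__version__,
                    "pandas": pd.__version__,
                    "seed": config.seed,
                    "config": {
                        k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in dataclasses.asdict(config).items()
                    },
                },
                fh,
                indent=2,
            )
        written.append(p)
        return report
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
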