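"""Result tables, manifests, and file outputs for pipeline runs."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .engine import CohortTrace
from .outcomes import ScenarioOutcome
from .psa import PSAResult, ScenarioComparison

__all__ = [
    "RunManifest",
    "write_outcome",
    "write_trace",
    "write_psa_summary",
    "psa_summary_frame",
]


@dataclass
class RunManifest:
    """Record of one pipeline invocation, sufficient to reproduce it."""

    command: str
    config_paths: list[str]
    seeds: list[int]
    n_iterations: int | None
    tool_version: str
    timestamp: str

    @classmethod
    def create(
        cls,
        command: str,
        config_paths: list[str],
        seeds: list[int],
        n_iterations: int | None = None,
    ) -> "RunManifest":
        return cls(
            command=command,
            config_paths=[str(p) for p in config_paths],
            seeds=seeds,
            n_iterations=n_iterations,
            tool_version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, out_dir: str | Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(asdict(self), indent=2))
        return path


def write_outcome(outcome: ScenarioOutcome, out_dir: str | Path, stem: str) -> None:
    """Write one deterministic outcome as JSON plus a cost-composition CSV."""
    out_dir = Path(out_dir)
    record = outcome.as_dict() | {"horizon_cycles": outcome.horizon}
    (out_dir / f"{stem}.json").write_text(json.dumps(record, indent=2))
    outcome.to_table().round(2).to_csv(out_dir / f"{stem}_costs.csv", index=False)


def write_trace(trace: CohortTrace, out_dir: str | Path, stem: str) -> None:
    trace.to_dataframe().to_csv(Path(out_dir) / f"{stem}_trace.csv", index=False)


def psa_summary_frame(results: dict[str, PSAResult]) -> pd.DataFrame:
    """Estimate + 95% credible interval per stratum, one row per outcome."""
    rows = []
    for stratum, res in results.items():
        for outcome, (mean, lo, hi) in res.summaries.items():
            rows.append(
                {
                    "stratum": stratum,
                    "outcome": outcome,
                    "estimate": mean,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    return pd.DataFrame(rows)


def write_psa_summary(
    results: dict[str, PSAResult],
    out_dir: str | Path,
    comparison: ScenarioComparison | None = None,
) -> None:
    out_dir = Path(out_dir)
    frame = psa_summary_frame(results)
    frame.to_csv(out_dir / "psa_summary.csv", index=False)
    payload = {
        stratum: {
            "n_iterations": res.n_iterations,
            "seed": res.seed,
            "summaries": {k: list(v) for k, v in res.summaries.items()},
            "redraws": res.redraws,
        }
        for stratum, res in results.items()
    }
    if comparison is not None:
        payload["comparison"] = {
            "delta_cost": comparison.delta_cost,
            "delta_qaly": comparison.delta_qaly,
            "ci_overlap": comparison.ci_overlap,
            "icer": comparison.icer,
        }
    (out_dir / "psa_summary.json").write_text(json.dumps(payload, indent=2))
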