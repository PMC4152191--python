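"""Probabilistic sensitivity analysis: outcome distributions and contrasts.

Runs the 1000-iteration Monte Carlo PSA per stratum over the 1-year
horizon, summarizes each outcome with its mean and equal-tailed 95%
credible interval, contrasts absenteeism vs presenteeism within each
occupation, and writes results/psa_summary.{csv,json}.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from depmark import compare_scenarios, load_scenario, run_psa  # noqa: E402
from depmark.reporting import RunManifest, psa_summary_frame, write_psa_summary  # noqa: E402

ROOT = Path(__file__).resolve().parents[1]
CONFIGS = ROOT / "results" / "configs"
OUT = ROOT / "results"
N_ITERATIONS = 1000
SEED = 0


def main() -> None:
    results = {}
    for i, path in enumerate(sorted(CONFIGS.glob("*_*.json"))):
        cfg = load_scenario(path)
        key = f"{cfg.scenario}_{cfg.occupation}"
        results[key] = run_psa(cfg, N_ITERATIONS, seed=SEED + i)
    frame = psa_summary_frame(results)
    cost = frame[frame.outcome == "cost_total"].set_index("stratum")
    qaly = frame[frame.outcome == "qalys"].set_index("stratum")
    print("1-year per-worker outcomes (mean [95% credible interval]):\n")
    for key in sorted(results):
        c, q = cost.loc[key], qaly.loc[key]
        print(
            f"  {key:20s} cost {c.estimate:8.0f} [{c.ci_low:8.0f}, {c.ci_high:8.0f}] AUD"
            f"   QALYs {q.estimate:.3f} [{q.ci_low:.3f}, {q.ci_high:.3f}]"
        )
    write_psa_summary(results, OUT)
    for occ in ("blue", "white"):
        comp = compare_scenarios(
            results[f"absenteeism_{occ}"], results[f"presenteeism_{occ}"]
        )
        verdict = "overlap" if comp.ci_overlap["cost_total"] else "are disjoint"
        print(
            f"\n{occ}-collar: absenteeism - presenteeism = {comp.delta_cost:+.0f} AUD, "
            f"{comp.delta_qaly:+.3f} QALYs; total-cost intervals {verdict}"
        )
    RunManifest.create(
        "analysis/03_psa",
        [str(p) for p in sorted(CONFIGS.glob('*_*.json'))],
        [SEED + i for i in range(len(results))],
        N_ITERATIONS,
    ).write(OUT)


if __name__ == "__main__":
    main()
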