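"""Materialize the study's scenario configurations.

Writes the four stratum configs (absenteeism/presenteeism x blue/white
collar) used by the downstream analyses to results/configs/. These are the
packaged frozen draw (generator seed 5): synthetic inputs anchored to the
published wages, salaries, turnover probability and run settings, with the
remaining clinical parameters drawn from literature-plausible ranges.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from depmark import packaged_fixture, save_scenario, validate_scenario  # noqa: E402
from depmark.reporting import RunManifest  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "results" / "configs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    configs, refs = packaged_fixture()
    paths = []
    for key, cfg in configs.items():
        assert validate_scenario(cfg) == []
        path = OUT / f"{key}.json"
        save_scenario(cfg, path)
        paths.append(str(path))
        c = cfg.costs
        print(
            f"{key:20s} wage {c.daily_wage:7.2f} AUD/day  salary {c.annual_salary:9.0f} "
            f"AUD/yr  days/cycle {max(c.absenteeism_days_per_cycle, c.presenteeism_days_per_cycle):5.2f}"
        )
    RunManifest.create("analysis/01_generate_configs", paths, [refs["generator_seed"]]).write(OUT)
    print(f"\n4 configs written to {OUT} (generator seed {refs['generator_seed']})")


if __name__ == "__main__":
    main()
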