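"""Regenerate the shipped JSON schema for scenario configuration files.

    python scripts/make_schema.py
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from depmark.config import ScenarioConfig  # noqa: E402

out = Path(__file__).resolve().parents[1] / "src" / "depmark" / "data"
out.mkdir(parents=True, exist_ok=True)
schema = ScenarioConfig.model_json_schema()
(out / "scenario_config.schema.json").write_text(json.dumps(schema, indent=2))
print(f"schema written to {out / 'scenario_config.schema.json'}")
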