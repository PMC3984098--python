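"""End-to-end report from a single configuration.

Runs simulate -> segment -> measure -> statistics (+ AFM map) and writes
CSVs, plots, a provenance record and a markdown summary into out/. Equivalent
to `fibrilcyte report --out out/`.
"""

from pathlib import Path

import yaml

from fibrilcyte import load_config, run_report

cfg_yaml = {
    "fibril": {"field_width": 400.0, "field_height": 400.0},
    "doses_um": [0.0, 2.5, 25.0],
    "conditions": ["fibril", "flat"],
    "afm": {"grid": [8, 8]},
    "seed": 11,
}
cfg_path = Path("out_report_cfg.yaml")
cfg_path.write_text(yaml.safe_dump(cfg_yaml))

out = run_report(load_config(cfg_path), "out_report")
print((out / "report.md").read_text())
print(f"artifacts in {out}/")
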