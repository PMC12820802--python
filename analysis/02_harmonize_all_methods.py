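#!/usr/bin/env python
"""Harmonize the simulated consortium table with every method.

Applies ComBat, GAM-ComBat, GAM-CovBat at 90/95/100% retained variance, and
RELIEF to the full recording set (harmonization runs before any
per-subject deduplication), writing one TSV per method under results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from megharm.pipeline import RunConfig, run_harmonize

config = RunConfig(band="delta", seed=7, out_dir="results")
outputs = run_harmonize(config)
for label, path in outputs.items():
    print(f"{label:12s} -> {path}")
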