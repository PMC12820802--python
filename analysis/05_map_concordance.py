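#!/usr/bin/env python
"""Concordance of age-binned study power maps before and after harmonization.

Builds per-study parcel-mean maps for the 20-30-year age bin (studies with
at least 30 qualifying recordings), then compares maps across studies via
median pairwise Pearson r, median Lin concordance, ICC(3,k), and the median
across-study coefficient of variation — for the raw table and the
GAM-ComBat harmonized one.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from megharm.core_data import read_feature_table, select_one_recording_per_subject
from megharm.evaluation import age_bin_site_maps, concordance_report
from megharm.pipeline import RunConfig

config = RunConfig(band="delta", seed=7, out_dir="results")
out = Path(config.out_dir)

results = {}
for label in ("raw", "gamcombat"):
    suffix = "" if label == "raw" else f"_{label}"
    table = read_feature_table(out / f"power_{config.band}{suffix}.tsv",
                               band=config.band)
    table = select_one_recording_per_subject(table)
    maps = age_bin_site_maps(table, config.age_bin, config.min_n)
    results[label] = concordance_report(maps)
    rep = results[label]
    print(f"{label:10s} ({rep['n_studies']} studies): "
          f"Pearson {rep['median_pearson']:.3f}  CCC {rep['median_ccc']:.3f}  "
          f"ICC(3,k) {rep['icc_3k']:.3f}  CV {rep['median_cv']:.3f}")

with open(out / f"concordance_{config.band}.json", "w") as fh:
    json.dump(results, fh, indent=1)
print(f"\nwrote {out / f'concordance_{config.band}.json'}")
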