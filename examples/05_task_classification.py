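"""Task/effort discrimination from map features on a simulated cohort.

Six subjects perform four isometric elbow tasks at three effort levels;
five muscle arrays are processed end to end (QC, map, replacement,
segmentation) and the per-condition features feed Friedman tests and
leave-one-out LDA classification, comparing HD-map intensity (RMS_av-HD)
with a single bipolar channel (RMS_av-bip).
"""

import pandas as pd

from hdemgmap import (
    DetectorConfig,
    PipelineConfig,
    dataset_statistics,
    extract_condition_features,
    iter_task_dataset,
)

config = PipelineConfig(detector=DetectorConfig(k1=11.2, k2=0.002), seed=1)
rows = []
for record in iter_task_dataset(6, seed=1):
    rows.extend(extract_condition_features(record, config))
table = pd.DataFrame(rows)
stats = dataset_statistics(table)

print(f"{len(table)} feature rows "
      f"({table.subject.nunique()} subjects x 4 tasks x 3 efforts x 5 muscles)")
for key in ("rms_av_hd_task", "rms_av_bip_task",
            "rms_av_hd_task_effort", "rms_av_bip_task_effort"):
    c = stats["classification"][key]
    print(f"{key:28s} accuracy = {100 * c['accuracy']:.1f}%  "
          f"({c['n_classes']} classes)")
fr = stats["friedman_electrode_type"]
print(f"Friedman (HD vs bipolar, blocked by muscle): "
      f"chi2 = {fr['chi2']:.2f}, p = {fr['p']:.3f}")
# Both feature sets classify far above the 25% / 8.3% chance levels.  At
# this small cohort size either feature can edge ahead; at the full
# 12-subject design (scripts/acceptance.py) the segmented-area mean is at
# least as accurate as the single bipolar pair, which is what its
# robustness to electrode-placement differences predicts.
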