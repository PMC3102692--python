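"""Apply the combined low-information gene filter to a small matrix.

A gene is dropped only if BOTH its between-sample range and its mean signal
fall strictly below the respective medians over all genes — flat AND dim.
"""

import pandas as pd

from coexnet import filter_low_information

m = pd.DataFrame(
    {
        "s1": [1.0, 1.0, 5.0, 0.0],
        "s2": [1.0, 2.0, 5.0, 4.0],
        "s3": [1.0, 3.0, 5.0, 8.0],
    },
    index=pd.Index(["A", "B", "C", "D"], name="gene"),
)

filtered, report = filter_low_information(m)
print(f"median range: {report.median_range}, median mean: {report.median_mean}")
print(f"removed: {report.removed}  (flat AND dim)")
print(f"kept:    {report.kept}")
# 'A' is flat (range 0 < 1) and dim (mean 1 < 3) -> removed.
# 'C' is flat but bright (mean 5): one condition is not enough, so it stays.
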