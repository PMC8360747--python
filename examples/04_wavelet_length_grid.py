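"""Compare wavelets x segment lengths on a common synthetic cohort.

A miniature version of the accuracy-grid experiment: each cell builds its
own scalogram dataset from the same records, trains an identically seeded
CNN, and reports validation accuracy.  The 'none' row is the no-CWT
baseline (raw segment tiled into a grayscale image).
"""

import tempfile

from ppgbp import TrainConfig, grid_search, make_spec
from ppgbp.experiments import make_two_class_records

records = make_two_class_records(12, base_seed=0, n_samples=3000)
cfg = TrainConfig(learning_rate=1e-3, batch_size=16, epochs=8, seed=0,
                  input_size=32)

result = grid_search(
    records,
    wavelets=[make_spec("cgau1"), make_spec("mexh"), None],
    lengths=[250, 300],
    cfg=cfg,
    out_dir=tempfile.mkdtemp(),
)

print("validation accuracy per (wavelet, segment length):")
print(result.accuracies.round(3).to_string())
if result.errors:
    print("failed cells:", result.errors)
# Rows are wavelets ('none' = raw-signal baseline), columns segment lengths
# in samples at 125 Hz (250 = 2.0 s, 300 = 2.4 s).  With the BP-coupled
# synthetic morphology the CWT rows should match or beat the baseline row.
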