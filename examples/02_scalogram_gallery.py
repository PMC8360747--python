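"""Transform one PPG segment with all six wavelets and save the scalograms.

Each 2.4-s (300-sample) segment becomes a 224x224x3 PNG; dark blue pixels
are small |W(a,b)| coefficients, bright yellow the largest.
"""

import warnings
from pathlib import Path

from ppgbp import (
    SubjectProfile, WAVELET_NAMES, cwt, default_scales, generate_record,
    make_spec, preprocess_ppg, render_cwt, save_image,
)

warnings.filterwarnings("ignore", message="shan parameters")

out = Path("scalogram_gallery")
out.mkdir(exist_ok=True)

profile = SubjectProfile(sbp_target=110.0, dbp_target=72.0, seed=1)
record = generate_record(profile, n_samples=600, fs=125.0)
segment = preprocess_ppg(record.ppg, record.fs)[150:450]  # one 2.4 s window

for name in WAVELET_NAMES:
    spec = make_spec(name)
    scales = default_scales(len(segment), record.fs, spec)  # 0.5-20 Hz band
    result = cwt(segment, scales, spec, record.fs)
    image = render_cwt(result)
    save_image(image, out / f"{name}.png")
    print(f"{name:6s} -> {out / (name + '.png')}  "
          f"(64 scales, pseudo-freq {result.pseudo_frequencies[-1]:.2f}-"
          f"{result.pseudo_frequencies[0]:.1f} Hz)")
# The complex wavelets (fbsp, shan, cgau1) render |W|; the real ones
# (morl, mexh, gaus1) render the signed real part before color mapping.
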