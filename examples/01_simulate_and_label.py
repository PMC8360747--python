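"""Generate a synthetic paired PPG/ABP record and recover its BP label.

The generator plants exact systolic/diastolic targets in the ABP channel;
the labeler should read them back via peak/trough averaging and assign the
matching ACC/AHA category.
"""

import numpy as np

from ppgbp import SubjectProfile, generate_record, label_segment, quality_check

profile = SubjectProfile(sbp_target=128.0, dbp_target=78.0, heart_rate=72.0,
                         wander_amplitude=0.1, noise_sd=0.01, seed=42)
record = generate_record(profile, n_samples=2500, fs=125.0)  # 20 s

qc = quality_check(record)
label = label_segment(record.abp, record.fs)

print(f"QC passed: {qc.passed}")
print(f"recovered SBP/DBP: {label.sbp:.1f}/{label.dbp:.1f} mmHg "
      f"(target {profile.sbp_target:.0f}/{profile.dbp_target:.0f})")
print(f"category: {label.category.name}, binary label: {label.binary}")
# SBP/DBP should sit within ~1 mmHg of the targets despite the mild noise;
# 128/78 lands in the ELEVATED band (SBP 120-129, DBP < 80) -> abnormal (1).
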