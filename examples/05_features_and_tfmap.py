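"""ERD/ERS band-power features and the relative time-frequency map.

The classifier's input is Welch power at 8, 12, 16, 20, 24 Hz computed
separately for the movement window (0-3 s, ERD) and the post-movement
window (3.5-6 s, ERS): 9 channels x 5 frequencies x 2 windows = 90
features.  The time-frequency map shows the effect directly at C3: mu
power drops below 1 during the cue and rebounds above 1 afterwards.
"""

import numpy as np

from erdswitch import (
    MOTOR_CHANNELS,
    SyntheticConfig,
    build_session_plan,
    extract_epochs,
    extract_features,
    generate_recording,
    linear_detrend,
    spherical_spline_laplacian,
    tf_map,
)

plan = build_session_plan(2, seed=11, sample_rate_hz=500.0)
rec = generate_recording(plan, SyntheticConfig(sample_rate_hz=500.0, seed=11))
epochs = spherical_spline_laplacian(linear_detrend(extract_epochs(rec, plan)))

features = extract_features(epochs, channels=MOTOR_CHANNELS)
print(f"feature matrix: {features.values.shape[0]} trials x "
      f"{features.values.shape[1]} features")
print("first columns:", features.column_names()[:4])

tm = tf_map(epochs, "attempted")
c3 = tm.channel_labels.index("C3")
mu = (tm.freqs >= 8) & (tm.freqs <= 12)
erd = tm.values[c3][mu][:, (tm.times >= 0) & (tm.times <= 3)].mean()
ers = tm.values[c3][mu][:, (tm.times >= 3.5) & (tm.times <= 6)].mean()
print(f"C3 mu power, relative units: during cue {erd:.2f} (ERD, < 1), "
      f"after cue {ers:.2f} (ERS, > 1)")
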