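"""Ten-fold cross-validated attempted-vs-rest classification.

One synthetic phase-2 subject with the default strong-ERD profile; the
rLLR classifier on the 9-channel motor set, regularization grid-searched
inside each training fold.  The binomial CI says whether the subject
beats the 50% chance level; the group CI aggregates several subjects the
way the study's summary rows do.
"""

from erdswitch import (
    MOTOR_CHANNELS,
    SyntheticConfig,
    binomial_ci,
    build_session_plan,
    crossval_accuracy,
    extract_epochs,
    extract_features,
    format_ci,
    generate_recording,
    group_mean_ci,
    linear_detrend,
    spherical_spline_laplacian,
)

accs = []
for seed in range(4):
    plan = build_session_plan(2, seed=seed, sample_rate_hz=500.0)
    rec = generate_recording(plan, SyntheticConfig(sample_rate_hz=500.0, seed=seed))
    epochs = spherical_spline_laplacian(linear_detrend(extract_epochs(rec, plan)))
    feats = extract_features(epochs, channels=MOTOR_CHANNELS)
    cv = crossval_accuracy(feats, k=10, seed=seed)
    ci = binomial_ci(round(cv.overall_accuracy * cv.n_trials), cv.n_trials)
    accs.append(100 * cv.overall_accuracy)
    print(f"subject {seed + 1}: accuracy "
          f"{format_ci(ci.accuracy, ci.lower, ci.upper)} % "
          f"({cv.n_trials} trials)")

g = group_mean_ci(accs)
print(f"group mean (95% CI): {format_ci(g.mean, g.lower, g.upper)} %")
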