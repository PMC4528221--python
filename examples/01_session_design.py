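"""Build the cued-movement session plans and inspect their design.

Phase 1 (before neuromuscular block): 4 conditions x 81 trials over 3
blocks; phase 2 (during block): attempted movement vs. no movement, 54
trials each.  Every sequence is nine 3-second cues with 4-second gaps.
"""

from erdswitch import build_session_plan

for phase in (1, 2):
    plan = build_session_plan(phase, seed=42, sample_rate_hz=500.0)
    counts = plan.trial_counts()
    first_seq = [e for e in plan.events if e.sequence_index == 0]
    print(f"phase {phase}: {plan.n_trials} trials, per condition {counts}")
    print(f"  first sequence: condition={first_seq[0].condition.name}, "
          f"onsets {[e.onset_s for e in first_seq]}")

plan.to_tsv("/tmp/phase2_events.tsv")
print("wrote /tmp/phase2_events.tsv (onset, duration, condition, sequence, block)")
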