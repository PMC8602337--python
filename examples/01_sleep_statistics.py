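"""Global sleep statistics from a hypnogram.

Builds a synthetic 8 h hypnogram and computes sleep period time (SPT),
total sleep time (TST), wake after sleep onset (WASO) and per-stage
minutes.
"""

from sleeposc import compute_sleep_stats, generate_hypnogram

hyp = generate_hypnogram(480, seed=1)
stats = compute_sleep_stats(hyp)

print(f"epochs: {hyp.n_epochs} x {hyp.epoch_length:.0f} s")
print(f"SPT  = {stats.spt_min:6.1f} min   (sleep onset to final awakening)")
print(f"TST  = {stats.tst_min:6.1f} min   (SPT minus wake after sleep onset)")
print(f"WASO = {stats.waso_min:6.1f} min")
for stage, minutes in stats.stage_minutes.items():
    print(f"  {stage:<4} {minutes:6.1f} min")
# TST + WASO equals SPT exactly; the stage minutes sum to TST.
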