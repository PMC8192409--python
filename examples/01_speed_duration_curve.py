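"""The two-parameter speed-duration model of a single runner.

Given a runner's critical speed CS and distance-above-CS d', predict how
long any supra-CS speed can be sustained, the distance covered, and the
best sustainable speed for a target duration.
"""

from critspeed import (
    CSParameters,
    IncrementalTestResult,
    kmh_to_mps,
    mps_to_kmh,
    peak_speed,
    predict_distance_from_speed,
    predict_speed,
    predict_time,
)

# A trained runner: CS 4.39 m/s (~15.8 km/h), 226 m runnable above CS.
runner = CSParameters(cs=4.39, d_prime=226.0)

# Peak speed from an incremental test: last full stage 18 km/h, 60% of
# the next 1 km/h stage completed.
ps_kmh = peak_speed(IncrementalTestResult(s_vo2max=18.0, alpha=0.6, delta_s=1.0))
print(f"peak speed: {ps_kmh:.1f} km/h = {kmh_to_mps(ps_kmh):.2f} m/s")

for pct in (0.9, 1.0, 1.1, 1.2):
    s = pct * kmh_to_mps(ps_kmh)
    t = predict_time(runner, s)
    d = predict_distance_from_speed(runner, s)
    print(
        f"{pct:4.0%} PS = {s:.2f} m/s -> exhaustion after {t / 60:6.1f} min "
        f"({d:7.0f} m)"
    )

# Inverse question: fastest sustainable pace for a 20-minute effort.
s20 = predict_speed(runner, 20 * 60)
print(f"best 20-min pace: {s20:.2f} m/s ({mps_to_kmh(s20):.1f} km/h)")
print("Times diverge as speed approaches CS: below CS exercise is sustainable.")
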