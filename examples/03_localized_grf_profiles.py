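"""Localized ground-reaction-force decomposition over the stance phase.

Analyzes a simulated session and prints, for the vertical direction, the
mass-normalized total GRF and each sensor's percentage contribution per
10% stance segment. The heel dominates early stance and the toe dominates
push-off for the young (heel-first) contact style.
"""

import numpy as np

import shoegait as sg

young, _ = sg.default_profiles()
session, _ = sg.simulate_session(young, 8, rng_seed=12)
result = sg.analyze_session(session)
summary = result.segment_summary

print(f"{len(result.stances)} stances detected, each resampled to 101 points")
print("segment   total Fz (N/kg)   heel%   MT1%   MT5%   toe%")
for seg in range(10):
    contribs = summary.contributions[:, 2, seg]
    cells = "  ".join(
        f"{c:5.1f}" if np.isfinite(c) else "  n/a" for c in contribs
    )
    print(f"{seg * 10 + 1:>3}-{(seg + 1) * 10}%   {summary.total_per_mass[2, seg]:13.2f}   {cells}")
print("\n(contributions sum to 100% in every defined segment;"
      " n/a marks segments with near-zero total force)")
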