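"""PLV vs wPLI on an AD subject with injected theta coupling.

The AD eyes-closed effect specification plants a shared theta source at
F3-O1 and C3-O1 with zero lag (visible to PLV, largely invisible to
wPLI) and at F3-F4, F3-T4, F4-O1 with a pi/4 lag (visible to both).
"""

from resteeg import (
    CohortSpec,
    SubjectMeta,
    get_band,
    plv_matrix,
    run_preprocess,
    simulate_subject_condition,
    wpli_matrix,
)

spec = CohortSpec(seed=1)
meta = SubjectMeta("AD01", "AD", 71.0, "F", 3, "R")
ep = run_preprocess(simulate_subject_condition(meta, "EC", spec, seed=42))

theta = get_band("theta")
plv = plv_matrix(ep, theta)
wpli = wpli_matrix(ep, theta)

print("pair      PLV    wPLI   injected as")
rows = [
    (("F3", "O1"), "zero-lag shared source"),
    (("C3", "O1"), "zero-lag shared source"),
    (("F3", "F4"), "pi/4-lag shared source"),
    (("F3", "T4"), "pi/4-lag shared source"),
    (("T3", "O2"), "nothing (baseline)"),
]
for (a, b), label in rows:
    print(f"{a}-{b}    {plv.pair_value(a, b):.2f}   {wpli.pair_value(a, b):.2f}   {label}")
# Lagged pairs score high on both metrics; the baseline pair sits at the
# sampling floor (~0.25 for PLV with 30 x 4-s epochs, ~0.2 for wPLI with
# 23 windows). Zero-lag offsets between coupled channels raise PLV while
# wPLI responds only where a nonzero lag survives.
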