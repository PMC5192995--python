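"""Chemotherapy timing relative to the normalization window.

Simulates the population-typical vanucizumab-treated tumor under three
regimens of daily chemotherapy — the week before the window, the week
containing it, and a three-week course from treatment start — and checks
that the conclusions survive +-20% changes of the resistance rate.
"""

from vesselnorm import lambda_sensitivity, run_regimens

outcomes = run_regimens()
print("final tumor volume at day 73 (smaller = better):")
for o in outcomes:
    win = f"days {o.t_C_on:.0f}-{o.t_C_off:.0f}" if o.t_C_on else "none"
    print(f"  {o.label:12s} (chemo {win:12s}): T_end = {o.T_end:6.1f} mm^3")

tab = lambda_sensitivity()
ok = tab[tab.lambda_factor != 1.0].ordering_preserved.all()
print(f"\nregimen ordering preserved under resistance rate +-20%: {ok}")
print("\nDosing inside the window beats dosing before it (normalized vessels "
      "deliver more drug), and the long course starting at day 38 does worse "
      "than the targeted in-window week because resistance has eroded the "
      "drug's effect by the time the window opens.")
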