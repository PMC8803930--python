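"""Rank a metabolite proliferation screen.

Each condition has 6 treated wells normalized to a shared set of 6 vehicle
wells (confluence %); metabolites are ranked by their best relative
proliferation across tested concentrations.
"""

from regenconverge import SynthConfig, gen_screen_plate, rank_screen, relative_proliferation

cfg = SynthConfig(
    screen_effects={"uridine": 1.5, "sphingosine": 1.3, "inert": 1.0},
    seed=5,
)
plate = gen_screen_plate(cfg)
print(f"plate: {len(plate)} wells, "
      f"{plate[plate['group'] == 'vehicle'].shape[0]} vehicle")

print("\nrelative proliferation, uridine at 200 uM:",
      round(relative_proliferation(plate, "uridine", 200.0), 3))

ranked = rank_screen(plate)
print("\nranked screen (best concentration per metabolite):")
print(ranked)
# The planted 1.5x effect tops the table; the inert compound sits near 1.0.
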