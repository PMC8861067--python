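"""Correlations among the published per-island beta-diversity summaries.

The packaged island table carries the nine study islands' descriptors and
their published mean LCBD and BD_Ti values; islands that vary more between
years also contribute more to overall beta diversity, and maximum altitude
tracks both (driven by the tallest, most variable island).
"""

import stopover as st

tab = st.load_island_table()
for a, b in [("lcbd", "bd_ti"), ("max_alt", "bd_ti"), ("max_alt", "lcbd")]:
    r, p = st.correlation(tab[a], tab[b])
    print(f"Pearson r({a}, {b}) = {r:.3f}  (p = {p:.4f}, n = {len(tab)})")
print("\nThe LCBD-BD_Ti correlation (~0.92) says interannually variable "
      "islands dominate beta diversity; the altitude correlations (~0.79 "
      "and ~0.73) hinge on the tallest island.")
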