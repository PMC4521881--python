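"""Manly's alpha and Chesson's electivity on a hand-sized example.

One hare has four food types available; two are over-used relative to
availability, one is taken in proportion, one is ignored.
"""

import numpy as np

from hareselect import chesson_epsilon, manly_alpha

items = ["Beta vulgaris", "Medicago sativa", "Triticum aestivum", "Poa sp."]
use = np.array([0.40, 0.35, 0.25, 0.00])          # stomach proportions
availability = np.array([0.10, 0.20, 0.30, 0.40])  # plot proportions

alpha = manly_alpha(use, availability)
m = len(items)

print(f"{'item':<20}{'use':>6}{'avail':>7}{'alpha':>8}{'epsilon':>9}")
for item, u, a, al in zip(items, use, availability, alpha):
    eps = chesson_epsilon(al, m)
    print(f"{item:<20}{u:>6.2f}{a:>7.2f}{al:>8.3f}{eps:>9.3f}")

# alpha is the normalised use/availability ratio (sums to 1); epsilon maps
# it onto [-1, +1] with 0 at no selection (alpha = 1/m). Positive epsilon
# means the item is taken beyond its availability; -1 means available but
# never eaten.
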