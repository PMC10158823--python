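"""Published endpoint yields and Duncan's multiple range test.

Recomputes the substrate-to-product yields of the engineered producer
strain from its published 24-h batch endpoints, then demonstrates the
letter display of Duncan's test on simulated growth-rate replicates.
"""

import numpy as np

from kivdesign import compute_yields, duncan_mrt, make_table2_fixture

endpoints = make_table2_fixture()
print("endpoint yield arithmetic (g/g):")
for _, row in endpoints.iterrows():
    _, yps, ypx = compute_yields(
        row.delta_biomass_g_l, row.delta_substrate_g_l, row.product_g_l
    )
    print(f"  {row.condition:>8s}: Yp/s = {yps:.2f}, Yp/x = {ypx:.2f}")

# Duncan letters on three conditions: two with the same true growth rate,
# one faster. Groups sharing a letter are not significantly different.
rng = np.random.default_rng(42)
groups = [rng.normal(0.50, 0.01, 4), rng.normal(0.50, 0.01, 4), rng.normal(0.65, 0.01, 4)]
comparison = duncan_mrt(groups, alpha=0.05, labels=["glucose", "lactose", "whey"])
print("\nDuncan's multiple range test (alpha = 0.05):")
print(comparison.letter_table())
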