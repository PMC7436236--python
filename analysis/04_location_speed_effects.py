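#!/usr/bin/env python
"""Location x speed effects on intra-participant NRMSE.

Consumes the long table written by 02_intra_evaluation.py, fits a two-way
fixed-effects ANOVA (sensor location x belt speed, subjects as replicates)
and, when an effect is significant at alpha = 0.05, runs Tukey HSD
pairwise comparisons on the marginal means.
"""

from pathlib import Path

import pandas as pd

from gaitforce.evaluation import tukey_hsd, two_way_anova

out = Path("results")
long = pd.read_csv(out / "intra_per_subject_speed.csv")
df = long.rename(columns={"nrmse": "value"})[["location", "speed", "value"]]

res = two_way_anova(df)
res.table.to_csv(out / "anova_nrmse.csv")
print("two-way ANOVA on intra-participant NRMSE:")
print(f"  location:    F = {res.f_location:6.2f}, p = {res.p_location:.4f}")
print(f"  speed:       F = {res.f_speed:6.2f}, p = {res.p_speed:.4f}")
print(f"  interaction: F = {res.f_interaction:6.2f}, p = {res.p_interaction:.4f}")

for factor, p in (("location", res.p_location), ("speed", res.p_speed)):
    if p < res.alpha:
        tab = tukey_hsd(df, factor, res)
        tab.to_csv(out / f"tukey_{factor}_nrmse.csv", index=False)
        sig = tab[tab.significant]
        print(f"\nTukey HSD on {factor} marginal means "
              f"({len(sig)}/{len(tab)} pairs significant):")
        print(tab.round(4).to_string(index=False))
    else:
        print(f"\nno significant {factor} effect; Tukey HSD not run")
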