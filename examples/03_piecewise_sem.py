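"""Fit and select the piecewise SEM on a simulated island data set.

Generates the (island x site class) analysis table from a causal structure
with known standardized coefficients, fits the shipped 45-path hypothesis,
prunes it by AIC, and prints the surviving paths.  Fisher's C close to its
degrees of freedom (d-sep p well above 0.05) says the remaining missing
paths are consistent with the data.
"""

import warnings

from pollinet import synth
from pollinet.sem import backward_select, default_structure, effects_decomposition

table, truth = synth.generate_dag_dataset(synth.GeneratorConfig(seed=5))

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    final = backward_select(default_structure(), table)

print(f"retained {len(final.structure.paths)}/45 paths; "
      f"Fisher's C = {final.fisher_c:.2f} (df {final.dsep_df}, "
      f"p = {final.dsep_p:.2f}); AIC = {final.aic:.2f}\n")

print(f"{'path':>10} {'std coef':>9} {'p':>8}   true")
for row in final.coefficients.sort_values("path_id").itertuples():
    true = truth["coefficients"].get(f"{row.source}->{row.target}", 0.0)
    print(f"{row.source}->{row.target:>4} {row.std:9.2f} {row.p:8.3f}   {true:5.2f}")

effects = effects_decomposition(final, table, n_boot=100, seed=0)
total_da_ro = effects.effects.query(
    "source == 'DA' and response == 'RO' and effect == 'total'")
if len(total_da_ro):
    r = total_da_ro.iloc[0]
    print(f"\ntotal effect of decreased area on robustness: {r.estimate:.2f} "
          f"[{r.ci_low:.2f}, {r.ci_high:.2f}] (95% cluster bootstrap)")
print("\nStandardized coefficients near their true values, noise paths pruned.")
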