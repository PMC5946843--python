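"""Generate a synthetic country panel and inspect its structure.

The generator emits a 188-country x 21-year panel (1995-2015 by default)
whose GDP follows convergent growth, whose spending shares live in (0, 1),
and whose UHC index sits below a log-log frontier of pooled spending with
half-normal inefficiency.
"""

import numpy as np

from healthcast import GeneratorConfig, generate_panel
from healthcast.panel import pooled_spend_pc, total_spend_pc

config = GeneratorConfig(seed=1)
panel = generate_panel(config)

print(f"panel: {panel['country_id'].nunique()} countries x "
      f"{panel['year'].nunique()} years = {len(panel)} rows")
print(f"GDP per capita range:      ${panel['gdp_pc'].min():,.0f} - "
      f"${panel['gdp_pc'].max():,.0f}")
print(f"total health spending pc:  ${total_spend_pc(panel).median():,.0f} (median)")
print(f"pooled (prepaid) share:    "
      f"{(pooled_spend_pc(panel) / total_spend_pc(panel)).median():.1%} (median)")
print(f"UHC index range:           {panel['uhc_index'].min():.1f} - "
      f"{panel['uhc_index'].max():.1f}")
dah_recipients = (panel.groupby("country_id")["dah_pc"].max() > 0).sum()
print(f"countries receiving DAH:   {dah_recipients}")

# The spread of the index below the frontier is the inefficiency the
# downstream stochastic-frontier fit is designed to recover.
log_gap = (config.frontier_intercept
           + config.frontier_elasticity * np.log(pooled_spend_pc(panel))
           - np.log(panel["uhc_index"]))
print(f"mean log-gap to frontier:  {log_gap.mean():.3f} "
      f"(generator E[u] = {config.sigma_u * np.sqrt(2 / np.pi):.3f})")
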