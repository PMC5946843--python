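"""Build better and worse spending scenarios around a reference projection.

The 20-year growth of total health spending per capita is regressed on its
baseline log level (the convergence term); each country's better and worse
growth rates add the 85th and 15th percentiles of the residuals to its
fitted value.  After clipping, the scenarios always bracket the reference.
"""

import numpy as np
import pandas as pd

from healthcast import (
    GeneratorConfig,
    build_alternative_scenarios,
    clip_to_reference,
    compute_longterm_growth,
    fit_convergence_regression,
    generate_panel,
)
from healthcast.panel import total_spend_pc

panel = generate_panel(GeneratorConfig(seed=4))
last_year = int(panel["year"].max())

growth = compute_longterm_growth(panel)
base = panel[panel["year"] == panel["year"].min()].set_index("country_id")
reg = fit_convergence_regression(growth, np.log(total_spend_pc(base)))
print(f"long-term growth regression: intercept {reg.intercept:+.4f}, "
      f"convergence slope {reg.convergence_slope:+.4f}")
rates = reg.scenario_growth()
print(f"residual percentiles add {rates['better'].iloc[0] - reg.fitted.iloc[0]:+.4f} "
      f"(better) / {rates['worse'].iloc[0] - reg.fitted.iloc[0]:+.4f} (worse) "
      f"to each country's fitted growth")

# a simple reference: every country keeps growing at 2%/year
last = panel[panel["year"] == last_year].set_index("country_id")
levels = total_spend_pc(last)
reference = pd.DataFrame([
    {"country": c, "year": y, "reference": levels[c] * np.exp(0.02 * (y - last_year))}
    for c in levels.index for y in range(last_year + 1, 2041)
])
scen = clip_to_reference(
    build_alternative_scenarios(reg, reference, levels, last_year)
)

one = scen.frame[(scen.frame["country"] == "C000")
                 & scen.frame["year"].isin([2020, 2030, 2040])]
print("\ncountry C000, total health spending per capita ($):")
print(one[["year", "worse", "reference", "better"]].to_string(index=False,
      float_format=lambda v: f"{v:,.0f}"))
assert scen.is_ordered()
print("\nordering better >= reference >= worse holds for all "
      f"{len(scen.frame)} country-years")
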