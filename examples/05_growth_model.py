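"""Select and fit the mixed model for juvenile body length.

Runs the two-step AIC selection (random structure by REML, then nine fixed
structures by ML), refits the winner by REML, and prints ecotype
predictions at median habitat covariates.
"""

import pandas as pd

from codmix.growthmodel import predict_lengths, select_model
from codmix.synthio import GeneratorConfig, generate_all

bundle = generate_all(GeneratorConfig(seed=1, n_stations=60, n_regions=12,
                                      haul_rate=0.3))
survey = bundle["survey"].rename(columns={"ecotype_true": "ecotype"})

trace, fit = select_model(survey)
step2 = trace[trace["step"] == 2]
print("ML AIC by fixed structure:")
for r in step2.itertuples(index=False):
    print(f"  {r.structure:<34} {r.aic:9.1f}")
print(f"selected: {'+'.join(fit.terms)} (refit by REML, n = {fit.n})")
print(f"origin effect: {fit.params['CO[northsea]']:.3f} "
      f"+/- {fit.bse['CO[northsea]']:.3f} log-cm "
      f"(generating truth 0.149)")
print(f"region variance share: {100 * fit.variance_share_region:.1f}% "
      f"(generating truth 8%)")

grid = pd.DataFrame({
    "wave_exposure": survey["wave_exposure"].median(),
    "veg_type": "eelgrass", "veg_cover": 3,
    "ecotype": ["fjord", "northsea"],
})
pred = predict_lengths(fit, grid)
for r in pred.itertuples(index=False):
    print(f"predicted length ({r.ecotype}): {r.length_cm:.2f} cm")
# The North Sea ecotype is predicted ~2 cm longer than the fjord ecotype at
# the same habitat, mirroring the generating origin effect on the log scale.
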