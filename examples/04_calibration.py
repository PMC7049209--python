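"""Calibration of fitted rupture probabilities on a synthetic cohort.

Fits the boosting model on the complete data and bins the ordered fitted
probabilities into intervals of 50 aneurysms (remainder into the last),
comparing mean predicted probability with the observed rupture frequency.
"""

from mia_score import (
    BoostingConfig,
    GeneratorConfig,
    calibration_table,
    fit,
    predict_prob,
    sample_cohort,
    select_mstop,
)

cohort = sample_cohort(GeneratorConfig(n_patients=252, seed=3, signal_scale=3.0))
config = BoostingConfig(seed=3)
m_stop, _ = select_mstop(cohort, config)
fitted = fit(cohort, config, m_stop)
pred = predict_prob(fitted, cohort, use_random_effects=True)

table = calibration_table(pred.probability, pred.ruptured, bin_size=50)
print(table.to_string(index=False))
gap = (table.mean_predicted - table.observed_frequency).abs().max()
print(f"\nmax |observed - predicted| over bins: {gap:.3f}")
# Well-calibrated probabilities keep observed frequencies close to the mean
# prediction in every interval.
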