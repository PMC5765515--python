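"""Screen a single drug-event count series for an unexpected increase.

Two hand-made monthly histories illustrate the two branches of the
algorithm: a well-populated series handled by the negative binomial trend
regression, and a sparse series (mostly zero months) handled by the
threshold-only heuristic.
"""

from uifscan import ScreenConfig, detect, fit_nb_trend, forecast_t0

config = ScreenConfig(threshold_tau=5, bound_level=0.95, bound_type="ci_mean")

# --- Regression branch -----------------------------------------------------
# Six months of counts for an (immunoglobulin, deep vein thrombosis)-style
# combination, followed by a monitored month with 14 reports.
history = [4, 6, 5, 3, 6, 5]
y0 = 14

fit = fit_nb_trend(history)
forecast = forecast_t0(fit, level=config.bound_level, bound_type=config.bound_type)
print(f"history {history}, monitored count y0 = {y0}")
print(
    f"  fit: family={fit.family_used}, slope/month={fit.beta1:+.3f} (log scale), "
    f"forecast y_hat={forecast.y_hat:.2f}, 95% upper bound={forecast.upper_bound:.2f}"
)
detection = detect(history, y0, config)
print(f"  detection: {detection.branch if detection else None}")
# y0 = 14 exceeds both the threshold (5) and the forecast's upper bound, so
# the month is flagged by the regression branch.

# --- Heuristic branch ------------------------------------------------------
# Four of the six prior months are zero: the regression is unreliable, so
# the observed count is compared with the threshold alone.
sparse = [0, 0, 1, 0, 0, 2]
y0 = 6
detection = detect(sparse, y0, config)
print(f"\nhistory {sparse}, monitored count y0 = {y0}")
print(f"  detection: {detection.branch if detection else None}")
# Six reports after a mostly-null history meet the threshold: heuristic flag.
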