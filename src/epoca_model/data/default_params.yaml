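# Default model inputs: the published parameter table of the EPOCA vs
# standard-of-care cost-utility analysis (costs in €2025, rates per
# person-year measured on calendar time).
ed_entry_fraction: {epoca: 0.0, soc: 0.22}
annual_hosp_rate: {epoca: 2.4, soc: 4.4}
annual_ed_rate: {epoca: 1.6, soc: 3.4}
p_admit_after_ed: {epoca: 0.69, soc: 0.71}
mean_los: {epoca: 7.3, soc: 7.7}
mean_age: 87.9

program_cost_annual: 2210.0
cost_hosp: {epoca: 3714.0, soc: 3773.0}
cost_hosp_post_ed: 4249.0
cost_ed_visit_payer: 52.0
# back-derived from published collective ED totals (1008 € / 6.1 visits)
cost_ed_visit_collective: 165.25
outpatient_annual: {epoca: 5820.0, soc: 5337.0}
tariff_ratio: 1.27
outpatient_nhi_fraction: 0.65

utility_baseline: 0.8
disutility_hosp_day: 0.0013

discount_rate_annual: 0.025
horizon_years: 10.0
# undiscounted mean survival implied by the published outpatient totals
# (10,277 € / 5,820 €·y⁻¹ = 1.766 y; reported rounded as 1.8 y)
target_mean_survival_years: 1.766

program_share_6m: 0.59
program_share_12m: 0.41
program_continuation_year2: 0.22

count_entry_events: false
use_post_ed_admission_cost: false
nhi_ed_nonadmitted_only: false
nhi_outpatient_fraction_applied: false
program_cost_mortality_adjusted: true
los_model: geometric

seed: 20250514
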