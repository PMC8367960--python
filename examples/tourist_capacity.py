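"""Tourist carrying capacity under the two area scenarios.

PCC = (A/Au) × Rf sizes the physically possible visitation; RCC
discounts it by the heavy-rain and heavy-snow correction factors
Cfx = 1 − limiting days / season days, taken at two decimals.
"""

from meadow import tourism

factors = (
    tourism.correction_factor("rain", limiting_days=369, total_days=909),
    tourism.correction_factor("snow", limiting_days=51, total_days=186),
)
for f in factors:
    print(f"Cf({f.name}) = 1 - {f.limiting_days}/{f.total_days} = {f.value_2dp}")

for fraction in (0.12, 0.15):
    cfg = tourism.TourismAreaConfig(tourism_fraction=fraction)
    result = tourism.rcc(tourism.pcc(cfg), factors, cfg, daily_cap=200)
    print(f"{fraction:.0%} scenario: PCC {result.pcc:,.0f} -> "
          f"RCC {result.rcc_year:,} visits/yr = {result.rcc_day}/day")

report = tourism.compliance(rcc_day=274, current_daily_visits=54, cap=200)
print(f"current 54/day vs limit {report.effective_limit:.0f}/day -> "
      f"{'compliant' if report.compliant else 'non-compliant'}, "
      f"headroom {report.headroom:.0f}")
# Weather removes ~58% of the physical capacity; even so the meadow
# could admit ~274 visitors/day against today's ~54, within the
# court-ordered 200/day cap.
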