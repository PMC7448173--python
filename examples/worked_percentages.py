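"""Recompute the published summary percentages from their printed counts.

The raw facility logs behind the published review are not public, but every
percentage it prints is a quotient of printed counts.  Feeding those counts
through the package's summarizers shows the exact round-half-up values — and
exposes the handful of places where the printed value differs from exact
division by 0.01 points (mixed truncation/rounding in the original).
"""

from pumpguard import CauseLabel, Position
from pumpguard._stats import pct
from pumpguard.lasa import PositionSummary
from pumpguard.pipeline import AlertMixSummary, CancellationSummary

causes = CancellationSummary.from_counts(
    {
        CauseLabel.INCORRECT_MEDICATION: 10_017,
        CauseLabel.WRONG_DOSE: 8_533,
        CauseLabel.INDETERMINATE: 26_144,
        CauseLabel.WRONG_CHANNEL: 17,
        CauseLabel.DOSE_CANCELLED_CALC: 10,
        CauseLabel.CONC_LIMIT_BREACH: 603,
    },
    total_alerts=290_807,
)
print("cause shares of cancellations (n=44,721):")
for cause, row in causes.by_cause.items():
    share = "N/A" if row.pct_of_cancellations is None else f"{row.pct_of_cancellations:>6}%"
    print(f"  {cause.value:<22} {row.count:>6,}  {share}  ({row.pct_of_alerts}% of all alerts)")

mix = AlertMixSummary.from_counts(hard=40_184, soft=141_474, cancelled=44_721, other=64_428)
print(f"\nalert mix (n={mix.total:,}): hard {mix.percentages['hard']}%, "
      f"soft {mix.percentages['soft']}%, cancelled {mix.percentages['cancelled']}%, "
      f"other {mix.percentages['other']}%")
print("  (the original prints 13.81 and 15.37 — truncated, not rounded)")

positions = PositionSummary.from_counts(
    {Position.BEGINNING: 6_991, Position.MIDDLE: 2_144, Position.END: 882}
)
print(f"\ndivergence positions (n={positions.total:,}): "
      f"beginning {positions.percentages[Position.BEGINNING]}%, "
      f"middle {positions.percentages[Position.MIDDLE]}%, "
      f"end {positions.percentages[Position.END]}%")

print(f"\nlibrary compliance: {pct(1_050_531, 1_414_191)}% (1,050,531/1,414,191)")
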