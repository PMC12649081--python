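"""Monte Carlo detection time for a 20 mg IM dose against the 0.1 ng/mL
regulatory screening limit.

Simulates 1000 horses from the published population model (log-normal
between-subject variability on ka, V/F and CL/F), computes the 50th and
99th percentile plasma-concentration curves on a 0-408 h grid, and
reports when each falls below the screening limit.  The 99th-percentile
crossing, rounded up to whole days, is the recommended withdrawal time.
"""

from isoflupk import DoseEvent, TABLE_POP, detection_time_mc

result = detection_time_mc(
    TABLE_POP,
    DoseEvent(dose_mg=20.0, bw_kg=556.5),
    sl=0.1,  # screening limit, ng/mL (100 pg/mL)
    n=1000,
    seed=0,
)

t50, t99 = result.crossing_times
print(f"50% of the population below 0.1 ng/mL after {t50:.0f} h (~{t50/24:.0f} days)")
print(f"99% of the population below 0.1 ng/mL after {t99:.0f} h (~{t99/24:.0f} days)")
print(f"recommended withdrawal time: {result.withdrawal_days} days")
# The half of the population clears the limit in about 5 days, but the
# slow tail of the distribution needs roughly twice as long - which is
# why the withdrawal recommendation follows the 99th percentile.
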