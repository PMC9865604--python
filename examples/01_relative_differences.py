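"""Why a relative RR-difference threshold: the same absolute change means
different things at different heart rates."""

from prrx import relative_difference_at_hr, relative_differences

for rr0 in (500, 1200):
    diff = relative_differences([rr0, rr0 + 50]).values[0]
    hr = 60_000 / rr0
    print(f"50 ms change after a {rr0} ms interval (HR {hr:.0f} bpm): {diff:.1f}%")

print()
print("A fixed 50 ms threshold, expressed as a relative change, grows linearly with HR:")
for hr in (50, 80, 120, 180):
    print(f"  HR {hr:3d} bpm -> {relative_difference_at_hr(50, hr):5.2f}%")

# The first two lines show the core motivation: 50 ms is a 10% change at
# HR 120 but only a 4.2% change at HR 50, so counting absolute differences
# conflates irregularity with heart rate.  pRRx% normalises by the
# preceding interval and removes that dependence.
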