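"""Compute a per-window mappability track for a repeat-rich genome.

Mappability is the fraction of 100-bp tiles of each 10-kb window that align
uniquely; it bounds where short-read anchoring (and hence TIP detection)
can work at all.
"""

from tipscan import simulate
from tipscan.core import make_windows
from tipscan.mappability import mean_mappability, window_mappability

ref = simulate.simulate_reference(length=500_000, repeat_fraction=0.4, seed=11)
windows = make_windows(ref.genome)
track = window_mappability(ref.genome, windows)

print(f"genome: {ref.length} bp, {ref.repeat_bases()} bp in duplicated blocks")
print(f"mean mappability: {mean_mappability(track):.3f} "
      "(unique fraction over all 100-bp tiles)")
print("\nfirst windows:")
for wid, frac in list(track.items())[:8]:
    bar = "#" * int(frac * 40)
    print(f"  {wid:>22} {frac:5.2f} {bar}")
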