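"""Gate newborn (1N) cells in simulated flow cytometry and compare rCV.

Newly divided cells carry a 1N DNA content; gating the DNA-signal
histogram at the Otsu threshold of its log-transform isolates them, and
the robust coefficient of variance (rCV = sd/median) of their size signal
quantifies how variable newborn cell size is — wider division-plane
offsets produce more variable newborns.
"""

from sulfodiv import DELTA_CDVB2, MW001, gate_1n, rcv, simulate_cytometry

for preset in (MW001, DELTA_CDVB2):
    table = simulate_cytometry(preset, n_events=10_000, seed=7)
    gated = gate_1n(table)
    purity = (gated.true_ploidy == 1).mean()
    r = rcv(gated.size_signal)
    print(f"{preset.name:8s}  gated 1N events: {len(gated):5d}  "
          f"gate purity: {100 * purity:.1f}%  rCV(size) = {r:.3f}")
# The wide-offset strain shows a clearly larger rCV: its newborn sizes
# spread more around the median because the division plane wanders.
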