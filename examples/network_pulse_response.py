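"""Reference pulse response of the GnRH receptor network.

Runs 5-min pulses of 1e-7 M GnRH at 60-min period for 4 h and prints
the peak of each reported channel in the first and last cycle.  The
upstream channels (receptor occupancy, PLC, Ca2+, nuclear ppERK) pulse
on and off with the stimulus; nuclear NFAT and Egr1 accumulate across
pulses — the two timescales that downstream gates exploit.
"""
import numpy as np
from gnrhsim import NetworkParams, PulseProtocol, simulate_network

tc = simulate_network(NetworkParams(), PulseProtocol(1e-7, 5.0, 60.0, 240.0),
                      rtol=1e-6, atol=1e-9)
first = tc.time < 60
last = tc.time >= 180
print(f"{'channel':>10} {'peak cycle 1':>13} {'peak cycle 4':>13} {'trough cycle 4':>15}")
for ch in ("HR", "PLC", "Ca", "ppERK_nuc", "NFAT_NF", "Egr1"):
    print(f"{ch:>10} {tc[ch][first].max():13.4f} {tc[ch][last].max():13.4f} "
          f"{tc[ch][last].min():15.4f}")
print("\nUpstream peaks repeat almost identically each cycle and reset "
      "between pulses;\nNFAT_NF and Egr1 troughs stay far above baseline — "
      "slow accumulation across pulses.")
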