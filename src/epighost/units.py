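"""Unit conventions and physical constants.

All times are microseconds internally, gradients mT/m, k-space coordinates
cycles/mm. The reduced gyromagnetic ratio of the proton is 42.577 kHz/mT,
so one mT/m applied for one microsecond advances kx by 42.577e-6 cycles/mm.
"""

#: proton gyromagnetic ratio / 2pi, kHz per mT
GAMMA_BAR_KHZ_PER_MT = 42.577

#: cycles/mm of k-space per (mT/m * us) of gradient area
K_PER_AREA = GAMMA_BAR_KHZ_PER_MT * 1e-6

#: internal dense waveform grid spacing, us
GRID_DT_US = 1.0
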