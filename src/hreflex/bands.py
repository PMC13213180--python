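"""Canonical soleus response latency bands (ms post-trigger).

These windows serve double duty: the waveform generator normalizes its M and H
templates against them, and the manual delineation mode uses them as defaults.
Typical soleus latencies: direct motor response (M-wave) ~6-20 ms, monosynaptic
H-reflex ~28-45 ms.
"""

M_WINDOW_MS: tuple[float, float] = (6.0, 23.0)
H_WINDOW_MS: tuple[float, float] = (28.0, 45.0)
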