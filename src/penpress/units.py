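"""Unit conversion constants.

Everything inside the package is SI (m, s, Pa, m³).  Human-facing I/O (CSV
columns, CLI, plots) uses µL, µL/s and mbar, the units practitioners quote
for pen injections.  1 mbar = 100 Pa.
"""

UL = 1e-9
"""One microlitre in m³."""

UL_PER_S = 1e-9
"""One µL/s in m³/s."""

MBAR = 100.0
"""One millibar in Pa."""

MM = 1e-3
"""One millimetre in m."""

ATM = 101325.0
"""Standard atmospheric pressure in Pa."""

VOLUME_PER_CLICK = 10 * UL
"""Nominal delivered volume per device click (10 µL)."""
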