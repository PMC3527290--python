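"""Alignment-column symbols shared across modules.

A pairwise alignment column reduces to one of three symbols: both bases
called and equal (IDENTICAL), both called and unequal (DIFFERENT), or at
least one base missing/masked (MISSING).  Column sequences are stored as
``numpy`` ``int8`` arrays with these codes.
"""

IDENTICAL = 0
DIFFERENT = 1
MISSING = 2

SYMBOL_NAMES = ("IDENTICAL", "DIFFERENT", "MISSING")
N_SYMBOLS = 3
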