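"""Independent brute-force reference for the confusion-metric suite.

Kept separate from the package so the implementation under test shares no
code with it.
"""

import math


def oracle_suite(tp, fp, tn, fn):
    """Return (sen, spec, fpr, fnr, mcc) straight from the definitions."""
    pos = tp + fn
    neg = tn + fp
    sen = tp / pos if pos else None
    spec = tn / neg if neg else None
    fpr = fp / neg if neg else None
    fnr = fn / pos if pos else None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return sen, spec, fpr, fnr, mcc
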