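"""Independent brute-force oracles used by the test suite.

These deliberately re-implement analysis rules with explicit loops and plain
Python arithmetic, independent of the package's vectorised implementations.
"""

import math


def brute_force_reconstruct(experiments):
    """Explicit-loop re-implementation of the mask + cross-experiment average."""
    names = {}
    for e in experiments:
        for n, cls in e.table.classes.items():
            names[n] = cls
    out = {}
    for n, cls in names.items():
        vals = []
        for e in experiments:
            if e.loaded_class is cls:
                continue
            if n in e.table.values:
                vals.append(e.table.values[n])
        if not vals:
            continue
        mean = sum(vals) / len(vals)
        if len(vals) >= 2:
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
        else:
            sd = float("nan")
        out[n] = (mean, sd, len(vals))
    return out
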