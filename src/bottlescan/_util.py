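"""Small shared helpers."""
from __future__ import annotations

import math

UNDEFINED = float("nan")


def is_undefined(x) -> bool:
    """True if ``x`` is the undefined-marker (NaN) or None."""
    if x is None:
        return True
    try:
        return math.isnan(x)
    except TypeError:
        return False
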