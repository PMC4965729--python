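"""Time-unit parsing helpers.

All internal times are seconds. Config files may write durations with an
explicit unit suffix ("10ms", "0.01s", "5 s"); bare numbers are seconds.
"""

from __future__ import annotations

import re

from .errors import ConfigError

_TIME_RE = re.compile(r"^\s*([+-]?\d+(?:\.\d*)?(?:[eE][+-]?\d+)?)\s*(ms|s|us)?\s*$")

_SCALE = {"s": 1.0, "ms": 1e-3, "us": 1e-6, None: 1.0}


def parse_time(value: "float | int | str") -> float:
    """Parse a duration into seconds.

    Accepts floats/ints (seconds) or strings with an optional ``s``/``ms``/
    ``us`` suffix.
    """
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        m = _TIME_RE.match(value)
        if m is None:
            raise ConfigError(f"cannot parse duration {value!r} (expected e.g. '10ms' or '0.01s')")
        return float(m.group(1)) * _SCALE[m.group(2)]
    raise ConfigError(f"cannot parse duration of type {type(value).__name__}")
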