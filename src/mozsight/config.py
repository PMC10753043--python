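"""Plain-text key=value configuration files.

Format: one ``key = value`` pair per line; ``#`` starts a comment; blank
lines ignored. Dotted keys group naturally (e.g. ``target.large.area_cm2``);
values stay strings and are coerced by the consumer. Range-like values are
written as two whitespace-separated numbers (``x = 45 75``). All lengths are
centimetres.
"""

from __future__ import annotations

from pathlib import Path

__all__ = ["load_config", "parse_range", "parse_float", "parse_int"]


def load_config(path) -> dict[str, str]:
    out: dict[str, str] = {}
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def parse_range(value: str) -> tuple[float, float]:
    parts = value.split()
    if len(parts) != 2:
        raise ValueError(f"expected two numbers, got {value!r}")
    lo, hi = float(parts[0]), float(parts[1])
    return lo, hi


def parse_float(value: str) -> float:
    return float(value)


def parse_int(value: str) -> int:
    return int(value)
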