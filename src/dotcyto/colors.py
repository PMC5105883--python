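"""Color-value parsing for DOT attributes.

Supported: ``#RRGGBB``, ``#RRGGBBAA`` and X11 color names (Graphviz's
default colorscheme).  Unconvertible values — Brewer scheme references
(``/accent3/2``-style paths), HSV triples, and color lists (``a:b``,
the parallel/segmented-edge syntax) — yield ``None`` so the importer can
log and skip them.

The name table is matplotlib's CSS4 set corrected to X11 where the two
standards diverge (green, gray/grey, maroon, purple), plus the
``gray0``–``gray100`` / ``grey0``–``grey100`` ramps.
"""

from __future__ import annotations

import re
from typing import Optional

from matplotlib.colors import CSS4_COLORS

from .model import RGBA

# X11 values that differ from the CSS4/W3C definitions of the same name.
_X11_OVERRIDES = {
    "green": "#00FF00",
    "gray": "#BEBEBE",
    "grey": "#BEBEBE",
    "maroon": "#B03060",
    "purple": "#A020F0",
}


def _build_table() -> dict[str, RGBA]:
    table: dict[str, RGBA] = {}
    for name, hex_value in CSS4_COLORS.items():
        table[name.lower()] = _decode_hex(hex_value)
    for name, hex_value in _X11_OVERRIDES.items():
        table[name] = _decode_hex(hex_value)
    for i in range(101):
        level = round(i * 255 / 100)
        table[f"gray{i}"] = RGBA(level, level, level, 255)
        table[f"grey{i}"] = RGBA(level, level, level, 255)
    return table


def _decode_hex(value: str) -> RGBA:
    digits = value.lstrip("#")
    r, g, b = (int(digits[i : i + 2], 16) for i in (0, 2, 4))
    a = int(digits[6:8], 16) if len(digits) == 8 else 255
    return RGBA(r, g, b, a)


X11_COLORS: dict[str, RGBA] = _build_table()

_HEX_RE = re.compile(r"#\s*([0-9A-Fa-f]{6}|[0-9A-Fa-f]{8})\Z")
_HSV_RE = re.compile(r"[0-9.]+[\s,]+[0-9.]+[\s,]+[0-9.]+\Z")


def parse_color(value: str) -> Optional[RGBA]:
    """Decode a DOT color value, or return ``None`` if unconvertible."""
    value = value.strip()
    if ":" in value:  # color list (parallel / segmented edges)
        return None
    if value.startswith("/"):  # explicit colorscheme path (e.g. Brewer)
        return None
    m = _HEX_RE.match(value)
    if m:
        return _decode_hex(m.group(1))
    if _HSV_RE.match(value):
        return None
    return X11_COLORS.get(value.replace(" ", "").lower())


def format_color(color: RGBA) -> str:
    """Render as uppercase ``#RRGGBBAA``."""
    return f"#{color.r:02X}{color.g:02X}{color.b:02X}{color.a:02X}"


__all__ = ["parse_color", "format_color", "X11_COLORS"]
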