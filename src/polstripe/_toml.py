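"""Minimal TOML emitter for sidecar/config files.

Supports the subset this package writes: nested tables of scalars and
flat lists of scalars. Reading uses the stdlib ``tomllib``.
"""

from __future__ import annotations

from typing import Any


def _fmt_scalar(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    raise TypeError(f"cannot serialize {type(v).__name__} as TOML scalar")


def _fmt_value(v: Any) -> str:
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_fmt_value(x) for x in v) + "]"
    return _fmt_scalar(v)


def dumps(data: dict[str, Any]) -> str:
    """Serialize a dict (scalars, lists, one level of sub-tables) to TOML."""
    top, tables = [], []
    for key, val in data.items():
        if isinstance(val, dict):
            lines = [f"[{key}]"]
            for k, v in val.items():
                if isinstance(v, dict):
                    raise TypeError("nesting deeper than one table not supported")
                lines.append(f"{k} = {_fmt_value(v)}")
            tables.append("\n".join(lines))
        else:
            top.append(f"{key} = {_fmt_value(val)}")
    return "\n".join(top + ([""] if top and tables else []) + tables) + "\n"
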