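"""Flat key-value configuration files (``key = value`` or ``key value``)."""

from __future__ import annotations

from pathlib import Path

__all__ = ["read_config", "write_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict[str, float | int] = {
    "frequency_hz": 50_000.0,
    "desired_current_ma": 0.98,
    "samples_per_period": 55,
    "adc_bits": 10,
    "shunt_ohm": 100.0,
    "seed": 0,
}

_INT_KEYS = {"samples_per_period", "adc_bits", "seed"}


def read_config(path: str | Path) -> dict[str, float | int]:
    """Read a flat config file; unknown keys are kept, comments ignored."""
    cfg: dict[str, float | int] = dict(DEFAULT_CONFIG)
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace("=", " ").split()
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 'key value', got {line!r}")
        key, raw = parts
        try:
            cfg[key] = int(raw) if key in _INT_KEYS else float(raw)
        except ValueError:
            raise ValueError(f"line {lineno}: bad number {raw!r} for {key!r}") from None
    return cfg


def write_config(cfg: dict[str, float | int], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{k} = {v}\n" for k, v in cfg.items()), encoding="ascii"
    )
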