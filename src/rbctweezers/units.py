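"""Unit conversions between SI and the bench units used in the lab.

All internal computation is SI; measurement protocols and report tables
speak cP, dyne/cm, mV and µm/s. Conversions are exact scale factors.
"""

from __future__ import annotations

from .errors import UnitError

# Factor from unit -> SI base unit of its dimension. Unit strings are
# case-sensitive except for the micro prefix, which accepts 'u' or 'µ'.
_TO_SI: dict[str, tuple[str, float]] = {
    # dynamic viscosity -> Pa·s
    "cP": ("Pa*s", 1e-3),
    "Pa*s": ("Pa*s", 1.0),
    # stiffness -> N/m
    "dyne/cm": ("N/m", 1e-3),
    "N/m": ("N/m", 1.0),
    # potential -> V
    "mV": ("V", 1e-3),
    "V": ("V", 1.0),
    # speed -> m/s
    "um/s": ("m/s", 1e-6),
    "m/s": ("m/s", 1.0),
    # length -> m
    "um": ("m", 1e-6),
    "m": ("m", 1.0),
}


def _normalize(unit: str) -> str:
    return unit.replace("µ", "u").replace("·", "*").replace(" ", "")


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between two units of the same dimension.

    Supported pairs: cP<->Pa*s, dyne/cm<->N/m, mV<->V, um/s<->m/s, um<->m
    (µ and u are interchangeable). Raises :class:`UnitError` for unknown
    units or a cross-dimension pair.
    """
    src, dst = _normalize(from_unit), _normalize(to_unit)
    try:
        dim_src, f_src = _TO_SI[src]
        dim_dst, f_dst = _TO_SI[dst]
    except KeyError as exc:
        raise UnitError(f"unsupported unit {exc.args[0]!r}") from None
    if dim_src != dim_dst:
        raise UnitError(f"cannot convert {from_unit!r} ({dim_src}) to {to_unit!r} ({dim_dst})")
    return value * (f_src / f_dst)
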