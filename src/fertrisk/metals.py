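"""The seven trace metals tracked throughout the package.

Every tabular output uses the fixed ordering Cr, Ni, Cu, Zn, As, Cd, Pb.
As is a metalloid but is treated identically to the metals.
"""

from __future__ import annotations

from enum import Enum


class Metal(str, Enum):
    """Trace-metal identifier; behaves as its plain-string symbol."""

    Cr = "Cr"
    Ni = "Ni"
    Cu = "Cu"
    Zn = "Zn"
    As = "As"
    Cd = "Cd"
    Pb = "Pb"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


#: Canonical ordering for all per-metal tables.
METALS: tuple[Metal, ...] = (
    Metal.Cr,
    Metal.Ni,
    Metal.Cu,
    Metal.Zn,
    Metal.As,
    Metal.Cd,
    Metal.Pb,
)

#: Metals carrying a carcinogenic slope factor.
CARCINOGENS: tuple[Metal, ...] = (Metal.Cr, Metal.Ni, Metal.As, Metal.Cd)

#: Column names of a concentration table, in order.
METAL_COLUMNS: tuple[str, ...] = tuple(m.value for m in METALS)


def as_metal(value: "Metal | str") -> Metal:
    """Coerce a string symbol to a :class:`Metal`, with a helpful error."""
    try:
        return Metal(value)
    except ValueError:
        raise ValueError(
            f"unknown metal {value!r}; expected one of {', '.join(METAL_COLUMNS)}"
        ) from None
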