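"""Combinatorial fluorophore color codes.

A lineage barcode is the presence/absence pattern of 12 independently
integrable constructs: 6 fluorescent proteins (XFPs), each targeted either to
the nucleus or to the cytoplasm.  Cells inheriting the same pattern from a
common progenitor form a clone, so the code is the clone identity key.

The canonical serialization is two 6-digit strings, one per compartment,
``"N:<d1..d6>/C:<d1..d6>"`` where digit ``i`` at position ``i`` marks the
channel as present in that compartment and ``0`` marks it absent — the
field's conventional "code of six numbers" written out once per compartment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator

__all__ = [
    "CHANNEL_NAMES",
    "COMPARTMENTS",
    "N_CHANNELS",
    "N_CONSTRUCTS",
    "ColorCode",
    "serialize_code",
    "parse_code",
    "code_space_size",
    "code_complexity",
    "all_codes",
]

#: Fixed channel order; index i (1-based) <-> name.
CHANNEL_NAMES: tuple[str, ...] = (
    "YFP",
    "mKO",
    "mCerulean",
    "mCherry",
    "mT-Sapphire",
    "EGFP",
)
COMPARTMENTS: tuple[str, str] = ("nucleus", "cytoplasm")
N_CHANNELS = len(CHANNEL_NAMES)
N_CONSTRUCTS = N_CHANNELS * len(COMPARTMENTS)

_CODE_RE = re.compile(r"^N:([0-9]{6})/C:([0-9]{6})$")


def channel_index(name: str) -> int:
    """1-based channel index for an XFP name."""
    try:
        return CHANNEL_NAMES.index(name) + 1
    except ValueError:
        raise KeyError(f"unknown fluorophore channel: {name!r}") from None


@dataclass(frozen=True)
class ColorCode:
    """Presence pattern over (channel, compartment).

    Parameters
    ----------
    nucleus, cytoplasm
        6-tuples of booleans in fixed channel order
        (YFP, mKO, mCerulean, mCherry, mT-Sapphire, EGFP).
    """

    nucleus: tuple[bool, bool, bool, bool, bool, bool]
    cytoplasm: tuple[bool, bool, bool, bool, bool, bool]

    def __post_init__(self) -> None:
        for comp in (self.nucleus, self.cytoplasm):
            if len(comp) != N_CHANNELS:
                raise ValueError("a compartment pattern needs exactly 6 entries")
        # normalise to plain bools so hashing/equality ignore int-vs-bool
        object.__setattr__(self, "nucleus", tuple(bool(v) for v in self.nucleus))
        object.__setattr__(self, "cytoplasm", tuple(bool(v) for v in self.cytoplasm))

    @classmethod
    def from_channels(
        cls,
        nuclear: Iterable[str] = (),
        cytoplasmic: Iterable[str] = (),
    ) -> "ColorCode":
        """Build a code from XFP names present in each compartment."""
        nuc = [False] * N_CHANNELS
        cyt = [False] * N_CHANNELS
        for name in nuclear:
            nuc[channel_index(name) - 1] = True
        for name in cytoplasmic:
            cyt[channel_index(name) - 1] = True
        return cls(tuple(nuc), tuple(cyt))

    @classmethod
    def empty(cls) -> "ColorCode":
        return cls((False,) * N_CHANNELS, (False,) * N_CHANNELS)

    @classmethod
    def from_bits(cls, bits: Iterable[int]) -> "ColorCode":
        """Build a code from 12 booleans: 6 nuclear then 6 cytoplasmic."""
        vals = [bool(b) for b in bits]
        if len(vals) != N_CONSTRUCTS:
            raise ValueError(f"need {N_CONSTRUCTS} bits, got {len(vals)}")
        return cls(tuple(vals[:N_CHANNELS]), tuple(vals[N_CHANNELS:]))

    @property
    def bits(self) -> tuple[bool, ...]:
        """The 12 presence booleans, nuclear channels first."""
        return self.nucleus + self.cytoplasm

    @property
    def complexity(self) -> int:
        return sum(self.bits)

    @property
    def is_empty(self) -> bool:
        return not any(self.bits)

    def channel_present(self, channel: int) -> bool:
        """Presence of channel (1-based) in either compartment."""
        return self.nucleus[channel - 1] or self.cytoplasm[channel - 1]

    def six_digit(self) -> str:
        """Display-only 6-number projection: presence in either compartment."""
        return "".join(
            str(i) if self.channel_present(i) else "0"
            for i in range(1, N_CHANNELS + 1)
        )

    def __str__(self) -> str:
        return serialize_code(self)


def serialize_code(code: ColorCode) -> str:
    """Canonical string form ``N:<d1..d6>/C:<d1..d6>``.

    Position i holds digit i when channel i is present in that compartment
    and 0 otherwise, so the string is self-locating and unambiguous.
    """
    def digits(comp: tuple[bool, ...]) -> str:
        return "".join(str(i + 1) if comp[i] else "0" for i in range(N_CHANNELS))

    return f"N:{digits(code.nucleus)}/C:{digits(code.cytoplasm)}"


class CodeFormatError(ValueError):
    """Raised when a code string does not match the canonical grammar."""


def parse_code(text: str) -> ColorCode:
    """Inverse of :func:`serialize_code`.

    Raises
    ------
    CodeFormatError
        If the string does not match ``N:dddddd/C:dddddd`` or a digit is
        inconsistent with its position (position i admits only 0 or i).
    """
    m = _CODE_RE.match(text)
    if m is None:
        raise CodeFormatError(
            f"malformed code string {text!r}: expected 'N:dddddd/C:dddddd' "
            "with six digits per compartment"
        )

    def decode(part: str, label: str) -> tuple[bool, ...]:
        out = []
        for i, ch in enumerate(part, start=1):
            d = int(ch)
            if d not in (0, i):
                raise CodeFormatError(
                    f"inconsistent digit {d} at {label} position {i} in "
                    f"{text!r}: position {i} admits only 0 or {i}"
                )
            out.append(d == i)
        return tuple(out)

    return ColorCode(decode(m.group(1), "nucleus"), decode(m.group(2), "cytoplasm"))


def code_space_size(n_constructs: int) -> int:
    """Number of nonempty presence patterns over ``n_constructs`` constructs."""
    if n_constructs < 1:
        raise ValueError("n_constructs must be >= 1")
    return 2**n_constructs - 1


def code_complexity(code: ColorCode) -> int:
    """Number of constructs present in the code (0-12)."""
    return code.complexity


def all_codes(include_empty: bool = False) -> Iterator[ColorCode]:
    """Iterate over the full code space (4095 nonempty codes, 4096 with empty)."""
    for mask in range(0 if include_empty else 1, 2**N_CONSTRUCTS):
        yield ColorCode.from_bits((mask >> j) & 1 for j in range(N_CONSTRUCTS))
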