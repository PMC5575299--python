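"""Hierarchical Enzyme Commission (EC) labels with partial ("-") levels."""

from __future__ import annotations

from dataclasses import dataclass
from functools import total_ordering

WILD = None  # unknown level, rendered as "-"


@total_ordering
@dataclass(frozen=True)
class ECLabel:
    """A four-level EC identifier, e.g. ``3.2.1.21`` or the partial ``1.14.-.-``.

    The class digit is always known (1–6); a wildcard at any level forces
    wildcards at all deeper levels, matching how partial EC numbers are
    written in enzyme nomenclature.
    """

    class_digit: int
    subclass_digit: int | None = WILD
    subsubclass_digit: int | None = WILD
    serial: int | None = WILD

    def __post_init__(self) -> None:
        if self.class_digit not in range(1, 7):
            raise ValueError(f"EC class digit must be 1..6, got {self.class_digit}")
        levels = (self.subclass_digit, self.subsubclass_digit, self.serial)
        seen_wild = False
        for lv in levels:
            if lv is WILD:
                seen_wild = True
            elif seen_wild:
                raise ValueError(f"wildcard must propagate to deeper levels: {levels}")
            elif not (isinstance(lv, int) and lv >= 0):
                raise ValueError(f"EC level must be a non-negative int or wild: {lv!r}")

    # -- parsing / serialization ------------------------------------------
    @classmethod
    def parse(cls, text: str) -> "ECLabel":
        parts = text.strip().split(".")
        if len(parts) != 4:
            raise ValueError(f"EC label needs four dot-separated levels: {text!r}")
        digits = [WILD if p in ("-", "") else int(p) for p in parts]
        return cls(*digits)

    def __str__(self) -> str:
        return ".".join("-" if d is WILD else str(d)
                        for d in (self.class_digit, self.subclass_digit,
                                  self.subsubclass_digit, self.serial))

    # -- structure ---------------------------------------------------------
    @property
    def levels(self) -> tuple[int | None, ...]:
        return (self.class_digit, self.subclass_digit, self.subsubclass_digit, self.serial)

    @property
    def is_complete(self) -> bool:
        return all(d is not WILD for d in self.levels)

    def matches(self, other: "ECLabel") -> bool:
        """True if ``other`` agrees with every non-wild level of ``self``."""
        return all(q is WILD or q == t for q, t in zip(self.levels, other.levels))

    def __lt__(self, other: "ECLabel") -> bool:
        key = tuple(-1 if d is WILD else d for d in self.levels)
        okey = tuple(-1 if d is WILD else d for d in other.levels)
        return key < okey
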