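"""Slipped-strand three-way junction (3WJ) constructs and positional isomers.

A 3WJ forms when a tract of trinucleotide repeats (CAG or CTG) extrudes from
a duplex as an intrastrand hairpin (the *slip-out*).  If the flanking duplex
also contains ``m`` complementary repeat triplets, the slip-out can sit at
``m + 1`` different registers with an identical number of base pairs — the
*positional isomers* P1..P(m+1).  Constructs with ``m = 0`` have a fixed
branchpoint and are called *static*; constructs with ``m > 0`` are *mobile*.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class JunctionSpec:
    """A slipped-strand 3WJ construct.

    Parameters
    ----------
    slipout_repeats
        Number of trinucleotide repeats in the slip-out hairpin (>= 2).
    duplex_repeats
        Number of complementary repeat triplets in the flanking duplex
        (``m >= 0``).  ``m`` sets the register freedom of the slip-out.
    repeat_unit
        Trinucleotide label, e.g. ``"CAG"`` or ``"CTG"``.
    """

    slipout_repeats: int
    duplex_repeats: int = 0
    repeat_unit: str = "CTG"

    def __post_init__(self) -> None:
        if self.slipout_repeats < 2:
            raise ValueError(
                f"slipout_repeats must be >= 2, got {self.slipout_repeats}"
            )
        if self.duplex_repeats < 0:
            raise ValueError(
                f"duplex_repeats must be >= 0, got {self.duplex_repeats}"
            )
        if len(self.repeat_unit) != 3 or not self.repeat_unit.isalpha():
            raise ValueError(f"repeat_unit must be a trinucleotide label, got {self.repeat_unit!r}")

    @property
    def mobile(self) -> bool:
        """True iff the branchpoint can migrate (``duplex_repeats > 0``)."""
        return self.duplex_repeats > 0

    @property
    def n_isomers(self) -> int:
        """Number of positional isomers: one register per duplex offset."""
        return self.duplex_repeats + 1


def enumerate_isomers(spec: JunctionSpec) -> list[str]:
    """Enumerate positional isomer labels for a construct.

    The slip-out may occupy any register offset ``0..m`` relative to the
    ``m`` complementary duplex repeats, giving ``m + 1`` isomers labelled
    ``P1..P(m+1)``.  A static construct (``m = 0``) has the single placement
    ``P1`` (the fixed branchpoint).

    Returns
    -------
    list of str
        Isomer labels in register order, length ``spec.duplex_repeats + 1``.
    """
    return [f"P{i + 1}" for i in range(spec.n_isomers)]
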