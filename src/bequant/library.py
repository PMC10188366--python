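"""Library members and the protospacer coordinate frame.

A library member pairs a 20-nt sgRNA spacer with a genomically integrated
target cassette that carries the matching protospacer.  All user-facing
coordinates use the protospacer frame: protospacer bases are positions 1-20,
the PAM occupies positions 21-23, the base immediately upstream of the
protospacer is position 0, and further upstream bases are negative.  The
editing window analysed throughout the package spans positions -9..20.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

DNA_BASES = "ACGT"
VALID_READ_CHARS = frozenset("ACGTN")

#: Protospacer positions considered for mutation calls.
WINDOW_START = -9
WINDOW_END = 20
WINDOW_POSITIONS = tuple(range(WINDOW_START, WINDOW_END + 1))
WINDOW_LENGTH = len(WINDOW_POSITIONS)

#: Tracked mutation classes: (reference base, read base).
MUTATION_CLASSES = (("A", "G"), ("C", "T"), ("C", "G"), ("C", "A"))
C_TO_T = ("C", "T")
A_TO_G = ("A", "G")

SPACER_LENGTH = 20
PAM_LENGTH = 3


class LibraryValidationError(ValueError):
    """A library member violates its structural invariants."""


@dataclass(frozen=True)
class LibraryMember:
    """One paired spacer / target cassette.

    Parameters
    ----------
    member_id
        Unique identifier.
    spacer
        20-nt sgRNA spacer, identical to cassette protospacer positions 1-20.
    cassette
        Target-site sequence containing upstream flank, protospacer, PAM and
        (optionally) downstream flank.
    protospacer_start
        0-based offset of protospacer position 1 within ``cassette``.  Must be
        >= 10 so the upstream window positions -9..0 exist.
    target_base_pos
        Protospacer position of the designed substrate base (default 6).
    target_base
        'C' or 'A', the substrate base at ``target_base_pos``.
    """

    member_id: str
    spacer: str
    cassette: str
    protospacer_start: int
    target_base_pos: int = 6
    target_base: str = "C"

    def __post_init__(self) -> None:
        if not self.member_id:
            raise LibraryValidationError("member_id must be non-empty")
        if len(self.spacer) != SPACER_LENGTH:
            raise LibraryValidationError(
                f"{self.member_id}: spacer must be {SPACER_LENGTH} nt, "
                f"got {len(self.spacer)}"
            )
        if set(self.spacer) - set(DNA_BASES):
            raise LibraryValidationError(
                f"{self.member_id}: spacer contains non-ACGT symbols"
            )
        if set(self.cassette) - set(DNA_BASES):
            raise LibraryValidationError(
                f"{self.member_id}: cassette contains non-ACGT symbols"
            )
        # positions -9..0 must exist upstream of the protospacer
        if self.protospacer_start < 10:
            raise LibraryValidationError(
                f"{self.member_id}: protospacer_start must be >= 10 so window "
                f"positions -9..0 exist (got {self.protospacer_start})"
            )
        pam_end = self.protospacer_start + SPACER_LENGTH + PAM_LENGTH
        if len(self.cassette) < pam_end:
            raise LibraryValidationError(
                f"{self.member_id}: cassette too short ({len(self.cassette)} nt) "
                f"to hold protospacer and PAM ending at offset {pam_end}"
            )
        proto = self.cassette[
            self.protospacer_start : self.protospacer_start + SPACER_LENGTH
        ]
        if proto != self.spacer:
            raise LibraryValidationError(
                f"{self.member_id}: cassette does not contain the spacer at "
                f"protospacer_start={self.protospacer_start}"
            )
        if self.target_base not in ("C", "A"):
            raise LibraryValidationError(
                f"{self.member_id}: target_base must be 'C' or 'A', "
                f"got {self.target_base!r}"
            )
        if self.base_at(self.target_base_pos) != self.target_base:
            raise LibraryValidationError(
                f"{self.member_id}: cassette base at protospacer position "
                f"{self.target_base_pos} is {self.base_at(self.target_base_pos)!r}, "
                f"expected target base {self.target_base!r}"
            )

    # -- coordinate frame ---------------------------------------------------

    def offset_of(self, position: int) -> int:
        """Cassette offset (0-based) of a protospacer-frame position."""
        return self.protospacer_start + position - 1

    def position_of(self, offset: int) -> int:
        """Protospacer-frame position of a 0-based cassette offset."""
        return offset - self.protospacer_start + 1

    def base_at(self, position: int) -> str:
        return self.cassette[self.offset_of(position)]

    @property
    def window_offset(self) -> int:
        """Cassette offset of window position -9."""
        return self.offset_of(WINDOW_START)

    @property
    def window_sequence(self) -> str:
        """Cassette bases across the editing window -9..20."""
        start = self.window_offset
        return self.cassette[start : start + WINDOW_LENGTH]

    @property
    def pam(self) -> str:
        start = self.offset_of(21)
        return self.cassette[start : start + PAM_LENGTH]

    def context(self, position: int, offsets: tuple[int, ...]) -> dict[int, str]:
        """Bases at ``offsets`` relative to ``position`` (offset 0 excluded).

        Raises
        ------
        LibraryValidationError
            If a requested offset falls outside the cassette.
        """
        out: dict[int, str] = {}
        for off in offsets:
            if off == 0:
                continue
            idx = self.offset_of(position) + off
            if idx < 0 or idx >= len(self.cassette):
                raise LibraryValidationError(
                    f"{self.member_id}: context offset {off} of position "
                    f"{position} falls outside the cassette"
                )
            out[off] = self.cassette[idx]
        return out

    def window_positions_with_base(self, base: str) -> Iterator[int]:
        for pos in WINDOW_POSITIONS:
            if self.base_at(pos) == base:
                yield pos


def common_protospacer_start(members: list[LibraryMember]) -> int:
    """The shared protospacer_start of a library with a fixed cassette frame.

    The read-side window location used for k-mer nomination assumes every
    cassette places the protospacer at the same offset (true of the integrated
    library design emulated here).
    """
    starts = {m.protospacer_start for m in members}
    if len(starts) != 1:
        raise LibraryValidationError(
            f"library members disagree on protospacer_start: {sorted(starts)}"
        )
    return starts.pop()
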