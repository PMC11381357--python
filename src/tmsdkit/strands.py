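"""DNA strand types for toehold-mediated strand displacement (TMSD) systems.

A TMSD instance has three strands: the *invader* (I), the fluorophore-labelled
*substrate* (F) and the quencher-labelled *incumbent* (Q).  The substrate is
initially hybridized to the incumbent, leaving a short single-stranded
*toehold* overhang at its 3' end; the invader nucleates there and displaces
the incumbent by branch migration.  Sequences are written 5'->3' throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DNA_ALPHABET = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

__all__ = [
    "DNA_ALPHABET",
    "COMPLEMENT",
    "reverse_complement",
    "is_watson_crick",
    "DnaStrand",
    "DisplacementSystem",
]


def _validate_sequence(seq: str, what: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{what} must be nonempty")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{what} contains non-DNA characters: {sorted(bad)}")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a 5'->3' DNA sequence."""
    _validate_sequence(seq)
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def is_watson_crick(a: str, b: str) -> bool:
    """True if bases *a* and *b* form a Watson-Crick pair (A-T or G-C)."""
    return COMPLEMENT.get(a) == b


@dataclass(frozen=True)
class DnaStrand:
    """A named single strand with a role in the displacement reaction."""

    id: str
    sequence: str
    role: str = "invader"  # invader | substrate | incumbent

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence, f"strand {self.id!r}")
        if self.role not in ("invader", "substrate", "incumbent"):
            raise ValueError(f"unknown strand role {self.role!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DisplacementSystem:
    """Three-strand TMSD instance with a toehold/branch-migration partition.

    Invariants enforced at construction:

    * the substrate is the full reverse complement of the invader;
    * the incumbent covers exactly the branch-migration region, i.e. it
      equals the invader with the 5'-terminal toehold removed (both pair
      with the same stretch of the substrate);
    * toehold_len + branch_len == invader length.

    The toehold is the invader's 5'-terminal ``toehold_len`` bases, which
    bind the substrate's single-stranded 3' overhang in the initial duplex.
    """

    invader: DnaStrand
    substrate: DnaStrand
    incumbent: DnaStrand
    toehold_len: int = 6
    branch_len: int = field(init=False)

    def __post_init__(self) -> None:
        inv = self.invader.sequence
        if not 1 <= self.toehold_len < len(inv):
            raise ValueError(
                f"toehold_len {self.toehold_len} out of range for "
                f"{len(inv)} nt invader"
            )
        object.__setattr__(self, "branch_len", len(inv) - self.toehold_len)
        expected_sub = reverse_complement(inv)
        if self.substrate.sequence != expected_sub:
            diffs = [
                i
                for i, (a, b) in enumerate(zip(self.substrate.sequence, expected_sub))
                if a != b
            ]
            raise ValueError(
                f"substrate is not the reverse complement of the invader "
                f"(system {self.invader.id!r}, offending positions {diffs[:8]})"
            )
        expected_inc = inv[self.toehold_len :]
        if self.incumbent.sequence != expected_inc:
            diffs = [
                i
                for i, (a, b) in enumerate(zip(self.incumbent.sequence, expected_inc))
                if a != b
            ]
            raise ValueError(
                f"incumbent does not match the branch-migration region "
                f"(system {self.invader.id!r}, offending positions {diffs[:8]})"
            )

    @classmethod
    def from_invader(
        cls, system_id: str, invader_seq: str, toehold_len: int = 6
    ) -> "DisplacementSystem":
        """Build a consistent system from the invader sequence alone."""
        _validate_sequence(invader_seq, "invader")
        if not 1 <= toehold_len < len(invader_seq):
            raise ValueError("toehold_len out of range")
        return cls(
            invader=DnaStrand(f"{system_id}_I", invader_seq, "invader"),
            substrate=DnaStrand(
                f"{system_id}_F", reverse_complement(invader_seq), "substrate"
            ),
            incumbent=DnaStrand(
                f"{system_id}_Q", invader_seq[toehold_len:], "incumbent"
            ),
            toehold_len=toehold_len,
        )

    @property
    def system_id(self) -> str:
        return self.invader.id.removesuffix("_I")

    @property
    def toehold(self) -> str:
        """Invader toehold, 5'->3'."""
        return self.invader.sequence[: self.toehold_len]

    @property
    def branch(self) -> str:
        """Invader branch-migration region, 5'->3'."""
        return self.invader.sequence[self.toehold_len :]
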