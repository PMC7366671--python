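"""Sequence algebra for palindromic DNA duplexes.

A short self-complementary oligomer forms a duplex with twofold (dyad)
symmetry.  Intercalators read such a duplex one *dinucleotide step* at a
time: two stacked base pairs form the elementary binding cavity, written
5'-XY-3'/5'-WZ-3' where WZ is the complementary strand's dinucleotide.
Because the duplex is double-stranded, the 16 dinucleotides collapse into
10 equivalence classes under reverse complementation — 4 of them
self-complementary (AT, TA, CG, GC) and 6 doubletons.

Positions are 1-based along the top strand; a step is indexed by its
5' base, so the central step of an octamer sits at p = 4 (pairing bases
4 and 5).  The dyad maps step p to step L - p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = frozenset("ACGT")

#: Paper-style display label for each canonical class id, "front" strand
#: first.  Usage in the literature is not consistent ("CC/GG" vs "GG/CC");
#: the parser below accepts either order.
_DISPLAY = {
    "AA": "AA/TT",
    "AC": "GT/AC",
    "AG": "AG/CT",
    "AT": "AT/AT",
    "CA": "TG/CA",
    "CC": "GG/CC",
    "CG": "CG/CG",
    "GA": "GA/TC",
    "GC": "GC/GC",
    "TA": "TA/TA",
}


class AlphabetError(ValueError):
    """A sequence contains a character outside {A, C, G, T}."""


class ValidationError(ValueError):
    """A duplex fails a structural requirement (e.g. palindromy)."""


def _check_alphabet(seq: str) -> str:
    seq = seq.strip().upper()
    for i, base in enumerate(seq, start=1):
        if base not in _ALPHABET:
            raise AlphabetError(
                f"non-ACGT character {base!r} at position {i} in {seq!r}"
            )
    return seq


def reverse_complement(seq: str) -> str:
    """Base-complemented, order-reversed copy of ``seq`` (an involution)."""
    seq = _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class StepClass:
    """Canonical identity of a dinucleotide step.

    ``canonical_id`` is the lexicographically smaller of the dinucleotide
    and its reverse complement, so the two strand readings of one step
    compare equal.
    """

    canonical_id: str

    def __post_init__(self) -> None:
        if len(self.canonical_id) != 2:
            raise ValueError(f"dinucleotide expected, got {self.canonical_id!r}")
        cid = min(self.canonical_id, reverse_complement(self.canonical_id))
        object.__setattr__(self, "canonical_id", cid)

    @property
    def display_name(self) -> str:
        """Conventional 'XY/WZ' label, e.g. ``TG/CA`` for class CA."""
        return _DISPLAY[self.canonical_id]

    @property
    def self_complementary(self) -> bool:
        return self.canonical_id == reverse_complement(self.canonical_id)

    @classmethod
    def parse(cls, label: str) -> "StepClass":
        """Parse a 2-mer or an 'XY/WZ' label in either strand order."""
        label = label.strip().upper()
        if "/" in label:
            left, _, right = label.partition("/")
            left, right = _check_alphabet(left), _check_alphabet(right)
            if len(left) != 2 or len(right) != 2:
                raise ValueError(f"malformed step label {label!r}")
            if reverse_complement(left) != right and left != right:
                raise ValueError(
                    f"{label!r}: halves are not reverse complements"
                )
            return cls(left)
        return cls(_check_alphabet(label))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.display_name


def canonical_step(dinucleotide: str) -> StepClass:
    """Canonicalize a top-strand dinucleotide into its step class."""
    dinucleotide = _check_alphabet(dinucleotide)
    if len(dinucleotide) != 2:
        raise ValueError(f"dinucleotide expected, got {dinucleotide!r}")
    return StepClass(dinucleotide)


def enumerate_step_classes() -> set[StepClass]:
    """All distinct step classes over the DNA alphabet (exactly 10)."""
    return {canonical_step(a + b) for a in "ACGT" for b in "ACGT"}


@dataclass(frozen=True)
class DuplexSequence:
    """A double-stranded DNA oligomer built from its top strand.

    Strand "A" is the top strand; strand "B" is its reverse complement.
    Pair index i in 1..L pairs top[i] with bottom[L + 1 - i].
    """

    top_strand: str
    codename: str = ""
    palindromic: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        seq = _check_alphabet(self.top_strand)
        if len(seq) < 2:
            raise ValidationError(f"duplex needs >= 2 bp, got {len(seq)}")
        object.__setattr__(self, "top_strand", seq)
        object.__setattr__(
            self, "palindromic", seq == reverse_complement(seq)
        )

    @property
    def length(self) -> int:
        return len(self.top_strand)

    @property
    def bottom_strand(self) -> str:
        return reverse_complement(self.top_strand)

    def base(self, strand: str, residue: int) -> str:
        """Base letter at a 1-based residue of strand 'A' or 'B'."""
        if strand not in ("A", "B"):
            raise ValueError(f"strand must be 'A' or 'B', got {strand!r}")
        seq = self.top_strand if strand == "A" else self.bottom_strand
        if not 1 <= residue <= self.length:
            raise ValueError(f"residue {residue} outside 1..{self.length}")
        return seq[residue - 1]


def validate_palindrome(
    seq: str, codename: str = "", require: bool = False
) -> DuplexSequence:
    """Build a duplex, flagging (or enforcing) self-complementarity."""
    duplex = DuplexSequence(seq, codename=codename)
    if require and not duplex.palindromic:
        detail = "odd length" if duplex.length % 2 else "not self-complementary"
        raise ValidationError(
            f"{codename or seq}: palindromic duplex required ({detail})"
        )
    return duplex


@dataclass(frozen=True)
class StepSite:
    """A positioned occurrence of a step class in a duplex.

    ``position`` is the 1-based index of the 5' top-strand base;
    ``dyad_partner`` is the dyad-related position L - p.
    """

    step: StepClass
    position: int
    duplex_length: int

    @property
    def central(self) -> bool:
        L = self.duplex_length
        return L % 2 == 0 and self.position == L // 2

    @property
    def dyad_partner(self) -> int:
        return self.duplex_length - self.position

    @property
    def residues(self) -> tuple[int, int]:
        """Top-strand residues spanned by the step (p and p+1)."""
        return (self.position, self.position + 1)


def duplex_steps(
    duplex: DuplexSequence,
) -> tuple[list[StepSite], set[StepClass]]:
    """Scan the top strand into L-1 positioned step sites plus class set.

    In a palindrome the positioned list is dyad-symmetric: the class at
    position p equals the class at L - p.
    """
    sites = [
        StepSite(
            canonical_step(duplex.top_strand[p - 1 : p + 1]),
            p,
            duplex.length,
        )
        for p in range(1, duplex.length)
    ]
    return sites, {s.step for s in sites}


def sites_of(duplex: DuplexSequence, step: StepClass) -> list[tuple[StepSite, ...]]:
    """Occurrences of ``step``, grouped into dyad orbits {p, L - p}.

    A central occurrence forms a singleton orbit.  Orbits are ordered by
    their smallest position.
    """
    sites, _ = duplex_steps(duplex)
    hits = {s.position: s for s in sites if s.step == step}
    orbits: list[tuple[StepSite, ...]] = []
    seen: set[int] = set()
    for p in sorted(hits):
        if p in seen:
            continue
        partner = duplex.length - p
        members = [hits[p]]
        seen.add(p)
        if partner != p and partner in hits:
            members.append(hits[partner])
            seen.add(partner)
        orbits.append(tuple(members))
    return orbits


def read_fasta(path: str | Path) -> list[DuplexSequence]:
    """Read a duplex panel: one record per duplex, ID = codename."""
    return [
        DuplexSequence(str(rec.seq), codename=rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(duplexes: Iterable[DuplexSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(d.top_strand), id=d.codename or f"DUP{i}", description="")
        for i, d in enumerate(duplexes, start=1)
    ]
    SeqIO.write(records, str(path), "fasta")
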