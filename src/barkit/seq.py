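"""Sequence primitives and a restriction/ligation engine.

The model keeps double-stranded DNA as a top strand (5'->3') plus explicit
sticky-end metadata, so that digestion and ligation obey the physical
antiparallel base-pairing rules: a right end can only be joined to a left
end whose protrusion is its exact reverse complement.  This is the property
that makes directional (head-to-tail only) concatemerization of SfiI-excised
barcode monomers work, and it falls out of the representation rather than
being special-cased.

Coordinates are 0-based, half-open internally; user-facing reports are
1-based inclusive (see :mod:`barkit.io`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "Topology",
    "OverhangKind",
    "IUPAC_SETS",
    "iupac_revcomp",
    "NucSequence",
    "RestrictionEnzyme",
    "StickyEnd",
    "Fragment",
    "CutSite",
    "BUILTIN_ENZYMES",
    "revcomp",
    "find_sites",
    "digest",
    "ends_compatible",
    "join",
    "circularize",
    "InvalidEnzymeError",
    "LigationError",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC code -> set of concrete bases the code stands for.  A sequence 'N'
# (unknown base) is matched only by a pattern 'N': we never call a site on
# an unknown base.
IUPAC_SETS = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGTN"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class Topology(str, Enum):
    linear = "linear"
    circular = "circular"


class OverhangKind(str, Enum):
    blunt = "blunt"
    five_prime = "five_prime"
    three_prime = "three_prime"


class InvalidEnzymeError(ValueError):
    pass


class LigationError(ValueError):
    pass


def revcomp(bases: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return bases.translate(_COMPLEMENT)[::-1]


def iupac_revcomp(pattern: str) -> str:
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucSequence:
    """A DNA sequence: uppercase A/C/G/T/N, linear or circular."""

    id: str
    bases: str
    topology: Topology = Topology.linear

    def __post_init__(self) -> None:
        if set(self.bases) - set("ACGTN"):
            bad = sorted(set(self.bases) - set("ACGTN"))
            raise ValueError(f"sequence {self.id!r} has non-ACGTN characters: {bad}")
        if self.topology == Topology.circular and len(self.bases) < 1:
            raise ValueError("circular sequence must have length >= 1")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def is_circular(self) -> bool:
        return self.topology == Topology.circular

    def reverse_complement(self, new_id: str | None = None) -> "NucSequence":
        return NucSequence(new_id or self.id, revcomp(self.bases), self.topology)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A type II restriction enzyme as a recognition pattern plus cut offsets.

    ``cut_top`` / ``cut_bottom`` are offsets from the pattern start, both in
    top-strand coordinates: the top strand is cut between ``cut_top - 1`` and
    ``cut_top``, the bottom strand opposite ``cut_bottom``.  ``cut_top <
    cut_bottom`` leaves a 5' overhang, ``>`` a 3' overhang, equality is blunt.
    """

    name: str
    recognition: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self) -> None:
        bad = set(self.recognition.upper()) - set(IUPAC_SETS)
        if bad or not self.recognition:
            raise InvalidEnzymeError(
                f"{self.name}: recognition pattern {self.recognition!r} is not IUPAC"
            )

    @property
    def overhang_length(self) -> int:
        return abs(self.cut_top - self.cut_bottom)

    @property
    def overhang_kind(self) -> OverhangKind:
        if self.cut_top < self.cut_bottom:
            return OverhangKind.five_prime
        if self.cut_top > self.cut_bottom:
            return OverhangKind.three_prime
        return OverhangKind.blunt

    @property
    def is_palindromic(self) -> bool:
        return iupac_revcomp(self.recognition.upper()) == self.recognition.upper()


# Built-in enzymes used by the library workflows.
BUILTIN_ENZYMES: dict[str, RestrictionEnzyme] = {
    e.name: e
    for e in [
        # GGCCNNNN^N GGCC / 3-nt 3' overhang
        RestrictionEnzyme("SfiI", "GGCCNNNNNGGCC", 8, 5),
        RestrictionEnzyme("EcoRV", "GATATC", 3, 3),
        RestrictionEnzyme("SpeI", "ACTAGT", 1, 5),
        RestrictionEnzyme("XbaI", "TCTAGA", 1, 5),
        RestrictionEnzyme("BamHI", "GGATCC", 1, 5),
        RestrictionEnzyme("BlpI", "GCTNAGC", 2, 5),
    ]
}


@dataclass(frozen=True)
class StickyEnd:
    """One end of a double-stranded fragment.

    ``protrusion`` is the single-stranded portion of the protruding strand,
    read 5'->3' along that strand; empty iff blunt.
    """

    kind: OverhangKind
    protrusion: str = ""
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if self.kind == OverhangKind.blunt and self.protrusion:
            raise ValueError("blunt end cannot carry a protrusion")
        if self.kind != OverhangKind.blunt and not self.protrusion:
            raise ValueError(f"{self.kind.value} end requires a protrusion")


BLUNT = StickyEnd(OverhangKind.blunt)


@dataclass(frozen=True)
class Fragment:
    """A linear dsDNA fragment: top strand plus left/right end chemistry."""

    seq: NucSequence
    left_end: StickyEnd = BLUNT
    right_end: StickyEnd = BLUNT

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self, new_id: str | None = None) -> "Fragment":
        # Flipping a fragment swaps the ends; each protrusion string is
        # unchanged (the physical strand keeps its own 5'->3' reading).
        return Fragment(
            self.seq.reverse_complement(new_id),
            left_end=self.right_end,
            right_end=self.left_end,
        )


@dataclass(frozen=True)
class CutSite:
    """A resolved cut: recognition-site start plus strand-resolved positions."""

    start: int
    cut_top: int
    cut_bottom: int
    enzyme: str
    strand: str  # '+' pattern matched top strand, '-' matched bottom


def _match_at(bases: str, pattern: str, pos: int) -> bool:
    for j, pc in enumerate(pattern):
        if bases[pos + j] not in IUPAC_SETS[pc]:
            return False
    return True


def _pattern_regex(pattern: str) -> re.Pattern[str]:
    # Overlapping matches via lookahead; pattern 'N' may match sequence 'N',
    # any other code may not (conservative handling of unknown bases).
    parts = []
    for pc in pattern:
        opts = "".join(sorted(IUPAC_SETS[pc]))
        parts.append(f"[{opts}]" if len(opts) > 1 else opts)
    return re.compile("(?=" + "".join(parts) + ")")


def _scan(bases: str, pattern: str) -> list[int]:
    return [m.start() for m in _pattern_regex(pattern).finditer(bases)]


def find_sites(seq: NucSequence, enzyme: RestrictionEnzyme) -> list[CutSite]:
    """Locate every recognition site of ``enzyme`` in ``seq``.

    Both strands are scanned; palindromic patterns are reported once per
    locus.  Circular sequences are scanned across the origin and positions
    are reported modulo the sequence length.
    """
    if len(seq) == 0:
        raise ValueError("cannot scan an empty sequence")
    pattern = enzyme.recognition.upper()
    L = len(pattern)
    if seq.is_circular:
        # extend across the origin so sites spanning it are seen once
        bases = seq.bases + seq.bases[: L - 1] if len(seq) >= L else seq.bases
    else:
        bases = seq.bases

    sites: dict[tuple[int, int], CutSite] = {}
    n = len(seq)
    for s in _scan(bases, pattern):
        t, b = s + enzyme.cut_top, s + enzyme.cut_bottom
        if seq.is_circular:
            s, t, b = s % n, t % n, b % n
        sites[(t, b)] = CutSite(s, t, b, enzyme.name, "+")
    if not enzyme.is_palindromic:
        for s in _scan(bases, iupac_revcomp(pattern)):
            # mirror the cut offsets into top-strand coordinates
            t, b = s + L - enzyme.cut_bottom, s + L - enzyme.cut_top
            if seq.is_circular:
                s, t, b = s % n, t % n, b % n
            key = (t, b)
            if key not in sites:
                sites[key] = CutSite(s, t, b, enzyme.name, "-")
    return sorted(sites.values(), key=lambda c: (c.start, c.cut_top))


def _ends_from_cut(bases: str, t: int, b: int, enzyme: str) -> tuple[StickyEnd, StickyEnd]:
    """StickyEnds produced at one cut: (right end of left fragment,
    left end of right fragment)."""
    if t == b:
        return BLUNT, BLUNT
    if t < b:  # 5' overhang
        over = bases[t:b]
        return (
            StickyEnd(OverhangKind.five_prime, revcomp(over), enzyme),
            StickyEnd(OverhangKind.five_prime, over, enzyme),
        )
    over = bases[b:t]  # 3' overhang
    return (
        StickyEnd(OverhangKind.three_prime, over, enzyme),
        StickyEnd(OverhangKind.three_prime, revcomp(over), enzyme),
    )


def _as_fragment(obj: NucSequence | Fragment) -> Fragment:
    if isinstance(obj, Fragment):
        return obj
    return Fragment(obj)


def digest(
    seq: NucSequence | Fragment, enzymes: Iterable[RestrictionEnzyme] | RestrictionEnzyme
) -> list[Fragment]:
    """Complete digestion with one or more enzymes.

    Linear input with k cut loci yields k+1 fragments (zero sites returns the
    input as a single fragment); circular input yields k fragments.  Fragment
    top strands partition the input top strand, so lengths always sum to the
    input length.
    """
    if isinstance(enzymes, RestrictionEnzyme):
        enzymes = [enzymes]
    frag = _as_fragment(seq) if not isinstance(seq, NucSequence) or not seq.is_circular else None

    if isinstance(seq, NucSequence) and seq.is_circular:
        cuts: list[CutSite] = []
        for enz in enzymes:
            cuts.extend(find_sites(seq, enz))
        cuts.sort(key=lambda c: c.cut_top)
        if not cuts:
            return [Fragment(seq)]
        n = len(seq)
        # rotate so the first cut is the linearization point
        first = cuts[0]
        rotated = seq.bases[first.cut_top :] + seq.bases[: first.cut_top]
        lin = NucSequence(seq.id, rotated, Topology.linear)
        # positions of remaining cuts in rotated coordinates
        rel = sorted(
            (((c.cut_top - first.cut_top) % n, (c.cut_bottom - first.cut_top) % n, c.enzyme) for c in cuts[1:]),
        )
        # the linearization cut supplies the outer ends of the opened circle
        right_of_open, left_of_open = _circular_open_ends(seq.bases, first)
        opened = Fragment(lin, left_end=left_of_open, right_end=right_of_open)
        return _cut_fragment(opened, [(t, b if b >= 0 else b, e) for t, b, e in rel])

    assert frag is not None
    cuts = []
    for enz in enzymes:
        cuts.extend(find_sites(frag.seq, enz))
    cuts.sort(key=lambda c: c.cut_top)
    return _cut_fragment(frag, [(c.cut_top, c.cut_bottom, c.enzyme) for c in cuts])


def _circular_open_ends(bases: str, cut: CutSite) -> tuple[StickyEnd, StickyEnd]:
    """Ends created when a circle is opened at ``cut`` (may span the origin)."""
    n = len(bases)
    doubled = bases + bases
    t, b = cut.cut_top, cut.cut_bottom
    if b < t and cut.cut_top - cut.cut_bottom > n // 2:
        # overhang wrapped around the origin
        b += n
    elif t < b and cut.cut_bottom - cut.cut_top > n // 2:
        t += n
    return _ends_from_cut(doubled, t, b, cut.enzyme)


def _cut_fragment(frag: Fragment, cuts: Sequence[tuple[int, int, str]]) -> list[Fragment]:
    if not cuts:
        return [frag]
    bases = frag.seq.bases
    out: list[Fragment] = []
    prev_top = 0
    prev_left = frag.left_end
    for t, b, enzyme in cuts:
        right_end, next_left = _ends_from_cut(bases, t, b, enzyme)
        out.append(
            Fragment(
                NucSequence(f"{frag.seq.id}|{prev_top}-{t}", bases[prev_top:t]),
                left_end=prev_left,
                right_end=right_end,
            )
        )
        prev_top, prev_left = t, next_left
    out.append(
        Fragment(
            NucSequence(f"{frag.seq.id}|{prev_top}-{len(bases)}", bases[prev_top:]),
            left_end=prev_left,
            right_end=frag.right_end,
        )
    )
    return out


def ends_compatible(a: StickyEnd, b: StickyEnd) -> bool:
    """Can a fragment ending in ``a`` be ligated to one starting with ``b``?

    True iff both blunt, or same overhang kind with protrusions that are
    exact reverse complements (the antiparallel annealing rule).  Symmetric,
    since reverse complement is an involution.
    """
    if a.kind == OverhangKind.blunt and b.kind == OverhangKind.blunt:
        return True
    if a.kind != b.kind or len(a.protrusion) != len(b.protrusion):
        return False
    return b.protrusion == revcomp(a.protrusion)


def join(a: Fragment, b: Fragment, new_id: str | None = None) -> Fragment:
    """Ligate ``a``'s right end to ``b``'s left end.

    In this representation each single-stranded protrusion lives on exactly
    one fragment's top strand, so the ligated top strand is the plain
    concatenation and the shared overhang is automatically counted once.
    When both ends derive from the same enzyme the recognition site is
    reconstituted at the junction.
    """
    if not ends_compatible(a.right_end, b.left_end):
        raise LigationError(
            f"incompatible ends: {a.right_end.kind.value}/{a.right_end.protrusion!r} "
            f"vs {b.left_end.kind.value}/{b.left_end.protrusion!r}"
        )
    return Fragment(
        NucSequence(new_id or f"{a.seq.id}+{b.seq.id}", a.seq.bases + b.seq.bases),
        left_end=a.left_end,
        right_end=b.right_end,
    )


def circularize(frag: Fragment, new_id: str | None = None) -> NucSequence:
    """Intramolecular ligation of a fragment whose two ends are compatible."""
    if not ends_compatible(frag.right_end, frag.left_end):
        raise LigationError("fragment ends are not mutually compatible")
    return NucSequence(new_id or frag.seq.id, frag.seq.bases, Topology.circular)
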