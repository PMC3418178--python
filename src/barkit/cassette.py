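"""The insertion-vector cassette and its interrupted barcode.

The cassette is the ~2.1 kb linear DNA used for random non-homologous
integration into the fission yeast genome.  Ordered 5'->3' it carries:

* a 250 bp ATG-less lambda "buffer" that protects downstream elements from
  end resection during integration,
* a lexA-tagged HSP70 promoter stand-in,
* the barcode flanked by two SfiI sites (GGCCNNNNNGGCC) whose spacers are
  chosen so the excised 66 bp monomer ligates head-to-tail only,
* a lox71 site for one-way Cre-mediated integration of lox66 plasmids,
* a ura4+ selectable-marker stand-in carrying a single internal EcoRV site
  used by the inverse-splinkerette mapping workflow.

The barcode itself is 41 nt: 27 random positions interrupted by 14 fixed A's.
Fixed positions give the parser an anchor and bound how far a sequencing
error can move a barcode from its template.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .seq import (
    BUILTIN_ENZYMES,
    Fragment,
    NucSequence,
    digest,
    find_sites,
    revcomp,
)

__all__ = [
    "BarcodeTemplate",
    "Barcode",
    "LoxSite",
    "LoxVariant",
    "CassetteSpec",
    "Cassette",
    "DEFAULT_MASK",
    "LOX_SEQUENCES",
    "generate_barcode",
    "barcode_space_size",
    "validate_atg_less",
    "assemble_cassette",
    "random_dna",
    "constrained_filler",
    "InvalidTemplateError",
    "InconsistentSpecError",
]

# 27 random positions (N) with 14 interspersed fixed A's, length 41:
# (N N A) x 13 followed by N A.
DEFAULT_MASK = "NNA" * 13 + "NA"


class InvalidTemplateError(ValueError):
    pass


class InconsistentSpecError(ValueError):
    pass


@dataclass(frozen=True)
class BarcodeTemplate:
    """Mask over {N (random), A/C/G/T (fixed)} defining the barcode design."""

    mask: str = DEFAULT_MASK

    def __post_init__(self) -> None:
        bad = set(self.mask) - set("NACGT")
        if bad:
            raise InvalidTemplateError(f"mask contains invalid characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.mask)

    @property
    def n_random(self) -> int:
        return self.mask.count("N")

    @property
    def n_fixed(self) -> int:
        return self.length - self.n_random

    @property
    def fixed_positions(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.mask) if c != "N")

    def conforms(self, seq: str) -> bool:
        return self.mismatches(seq) == 0

    def mismatches(self, seq: str) -> int:
        """Number of fixed template positions that ``seq`` violates."""
        if len(seq) != self.length:
            return self.length
        return sum(1 for i in self.fixed_positions if seq[i] != self.mask[i])


@dataclass(frozen=True)
class Barcode:
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


class LoxVariant(str, Enum):
    loxP = "loxP"
    lox66 = "lox66"
    lox71 = "lox71"
    hybrid_66_71 = "hybrid_66_71"


# The standard published 34-bp variants: 13-bp left arm, 8-bp spacer,
# 13-bp right arm.  lox71 mutates the left arm, lox66 the right arm; Cre
# recombination between lox66 and lox71 produces one wild-type loxP and one
# double-mutant hybrid that Cre no longer acts on (one-way integration).
_LOXP_LEFT = "ATAACTTCGTATA"
_LOXP_SPACER = "ATGTATGC"
_LOXP_RIGHT = "TATACGAAGTTAT"
_LOX71_LEFT = "TACCGTTCGTATA"
_LOX66_RIGHT = "TATACGAACGGTA"

LOX_SEQUENCES: dict[LoxVariant, str] = {
    LoxVariant.loxP: _LOXP_LEFT + _LOXP_SPACER + _LOXP_RIGHT,
    LoxVariant.lox71: _LOX71_LEFT + _LOXP_SPACER + _LOXP_RIGHT,
    LoxVariant.lox66: _LOXP_LEFT + _LOXP_SPACER + _LOX66_RIGHT,
    LoxVariant.hybrid_66_71: _LOX71_LEFT + _LOXP_SPACER + _LOX66_RIGHT,
}


@dataclass(frozen=True)
class LoxSite:
    variant: LoxVariant

    @property
    def seq(self) -> str:
        return LOX_SEQUENCES[self.variant]

    @property
    def arms(self) -> tuple[str, str, str]:
        s = self.seq
        return s[:13], s[13:21], s[21:]


@dataclass(frozen=True)
class CassetteSpec:
    """Element lengths and SfiI spacer choices for cassette assembly.

    The two SfiI spacers share their middle three bases, which makes the
    excised monomer's right-end 3' protrusion the reverse complement of its
    left-end protrusion: monomers anneal head-to-tail and in no other
    orientation.
    """

    template: BarcodeTemplate = field(default_factory=BarcodeTemplate)
    atgless_lambda_len: int = 250
    promoter_len: int = 240
    pad_len: int = 6  # constant context between each SfiI site and the barcode
    lox71_len: int = 34
    ura4_len: int = 1497
    sfi_spacer_left: str = "AGGTT"
    sfi_spacer_right: str = "AGGTT"
    ura4_ecorv_offset: int = 1000  # single EcoRV site planted inside ura4
    # census amplicon flank sizes (distance from each SfiI cut to the primer)
    amplicon_left_flank: int = 197
    amplicon_right_flank: int = 497

    def __post_init__(self) -> None:
        for sp in (self.sfi_spacer_left, self.sfi_spacer_right):
            if len(sp) != 5 or set(sp) - set("ACGT"):
                raise InconsistentSpecError(f"SfiI spacer must be 5 concrete bases: {sp!r}")
        if self.sfi_spacer_left[1:4] != self.sfi_spacer_right[1:4]:
            raise InconsistentSpecError(
                "SfiI spacers must share their middle 3 bases for head-to-tail "
                "monomer chemistry"
            )
        if self.monomer_len != 13 + 2 * self.pad_len + self.template.length:
            raise InconsistentSpecError("inconsistent monomer arithmetic")

    @property
    def monomer_len(self) -> int:
        # distance between the two SfiI site starts == excised monomer length
        return 13 + self.pad_len + self.template.length + self.pad_len

    def sfi_site(self, spacer: str) -> str:
        return "GGCC" + spacer + "GGCC"

    @property
    def element_lengths(self) -> list[tuple[str, int]]:
        return [
            ("atgless_lambda", self.atgless_lambda_len),
            ("lexa_hsp70_promoter", self.promoter_len),
            ("sfi_site_left", 13),
            ("pad_left", self.pad_len),
            ("barcode", self.template.length),
            ("pad_right", self.pad_len),
            ("sfi_site_right", 13),
            ("lox71", self.lox71_len),
            ("ura4_marker", self.ura4_len),
        ]

    @property
    def total_len(self) -> int:
        return sum(n for _, n in self.element_lengths)


@dataclass(frozen=True)
class Cassette:
    """An assembled cassette: sequence plus a 0-based half-open element map."""

    seq: NucSequence
    elements: dict[str, tuple[int, int]]
    barcode: Barcode
    spec: CassetteSpec

    def element_seq(self, name: str) -> str:
        s, e = self.elements[name]
        return self.seq.bases[s:e]

    @property
    def sfi_cut_left(self) -> int:
        """Top-strand SfiI cut position of the left site (monomer start)."""
        return self.elements["sfi_site_left"][0] + 8

    @property
    def sfi_cut_right(self) -> int:
        return self.elements["sfi_site_right"][0] + 8

    @property
    def census_amplicon(self) -> NucSequence:
        """The PCR product used for barcode census (~760 bp by default)."""
        start = self.sfi_cut_left - self.spec.amplicon_left_flank
        end = self.sfi_cut_right + self.spec.amplicon_right_flank
        return NucSequence(f"{self.seq.id}|amplicon", self.seq.bases[start:end])

    def excise_monomer(self) -> Fragment:
        """SfiI digestion of the census amplicon; returns the barcode monomer."""
        frags = digest(self.census_amplicon, BUILTIN_ENZYMES["SfiI"])
        if len(frags) != 3:
            raise InconsistentSpecError(f"expected 3 SfiI fragments, got {len(frags)}")
        return frags[1]


def barcode_space_size(n_random: int):
    """Number of possible barcodes, 4**n_random, exact arbitrary precision."""
    if n_random < 0:
        raise ValueError("n_random must be >= 0")
    return 4**n_random


def validate_atg_less(seq: NucSequence | str) -> list[int]:
    """Start indices of every ATG on the transcribed (top) strand."""
    bases = seq.bases if isinstance(seq, NucSequence) else seq
    out, i = [], bases.find("ATG")
    while i != -1:
        out.append(i)
        i = bases.find("ATG", i + 1)
    return out


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def constrained_filler(
    rng: np.random.Generator,
    n: int,
    forbidden: tuple[str, ...] = (),
    atg_less: bool = False,
    max_tries: int = 2000,
) -> str:
    """Pseudo-random filler avoiding given motifs (checked on both strands).

    Stands in for vector elements whose real sequences are not modelled;
    only length and motif constraints matter to the workflows simulated here.
    """
    from .seq import iupac_revcomp  # local to avoid cycle at import time

    pats = []
    for motif in forbidden:
        pats.append(motif)
        rc = iupac_revcomp(motif)
        if rc != motif:
            pats.append(rc)
    if atg_less:
        pats.append("ATG")
    for _ in range(max_tries):
        cand = random_dna(rng, n)
        if not any(_iupac_contains(cand, p) for p in pats):
            return cand
        # local repair: mutate one base inside each offending window
        cand = _scrub(rng, cand, pats)
        if cand is not None:
            return cand
    raise RuntimeError("could not generate constrained filler")


def _iupac_find(bases: str, pattern: str) -> list[int]:
    from .seq import _scan  # reuse the engine's conservative IUPAC scan

    return _scan(bases, pattern)


def _iupac_contains(bases: str, pattern: str) -> bool:
    return bool(_iupac_find(bases, pattern))


def _scrub(rng: np.random.Generator, bases: str, pats: list[str], rounds: int = 50) -> str | None:
    arr = list(bases)
    for _ in range(rounds):
        hit = None
        for p in pats:
            pos = _iupac_find("".join(arr), p)
            if pos:
                hit = (pos[0], len(p))
                break
        if hit is None:
            return "".join(arr)
        i = hit[0] + int(rng.integers(0, hit[1]))
        arr[i] = "ACGT"[int(rng.integers(0, 4))]
    return None


def generate_barcode(
    template: BarcodeTemplate,
    rng_seed: int | np.random.Generator,
    *,
    context: tuple[str, str] | None = None,
    max_resample: int = 100,
) -> Barcode:
    """Draw a barcode: i.i.d. uniform bases at random positions, fixed
    positions from the mask.

    ``context`` is the (left, right) constant sequence that will flank the
    barcode in the cassette.  Candidates are screened (in context when
    given) against the workflow's restriction sites -- SfiI obviously, but
    also the enzymes the mapping protocols assume never cut the vector --
    and resampled on a hit (a few percent of draws).
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    left, right = context if context is not None else ("", "")
    for _ in range(max_resample):
        chars = []
        for c in template.mask:
            chars.append("ACGT"[int(rng.integers(0, 4))] if c == "N" else c)
        cand = "".join(chars)
        probe = left + cand + right
        if any(_iupac_contains(probe, motif) for motif in _VECTOR_FORBIDDEN):
            continue
        return Barcode(cand)
    raise RuntimeError("barcode resampling limit exceeded")


# motifs that must not appear by chance inside filler elements: they would
# create phantom restriction sites or primer-binding sites in the vector
_VECTOR_FORBIDDEN = (
    "GGCCNNNNNGGCC",  # SfiI
    "GATATC",  # EcoRV (planted once, deliberately, in ura4)
    "ACTAGT",  # SpeI
    "TCTAGA",  # XbaI
    "GGATCC",  # BamHI
)


def assemble_cassette(
    spec: CassetteSpec,
    barcode: Barcode,
    rng_seed: int | np.random.Generator,
    extra_forbidden: tuple[str, ...] = (),
) -> Cassette:
    """Assemble the full cassette around ``barcode``.

    Filler elements (lambda buffer, promoter, pads, ura4 stand-in) are
    deterministic pseudo-random sequences for a given seed, constrained to be
    free of the workflow's restriction sites; the buffer is additionally
    ATG-free on the transcribed strand, and ura4 carries exactly one EcoRV
    site at ``spec.ura4_ecorv_offset``.
    """
    if not spec.template.conforms(barcode.seq):
        raise InvalidTemplateError("barcode does not conform to the spec's template")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    forbidden = _VECTOR_FORBIDDEN + tuple(extra_forbidden)

    lam = constrained_filler(rng, spec.atgless_lambda_len, forbidden, atg_less=True)
    promoter = constrained_filler(rng, spec.promoter_len, forbidden)
    pad_left = constrained_filler(rng, spec.pad_len, forbidden)
    pad_right = constrained_filler(rng, spec.pad_len, forbidden)
    off = spec.ura4_ecorv_offset
    ura4_a = constrained_filler(rng, off, forbidden)
    ura4_b = constrained_filler(rng, spec.ura4_len - off - 6, forbidden)
    ura4 = ura4_a + "GATATC" + ura4_b

    parts = {
        "atgless_lambda": lam,
        "lexa_hsp70_promoter": promoter,
        "sfi_site_left": spec.sfi_site(spec.sfi_spacer_left),
        "pad_left": pad_left,
        "barcode": barcode.seq,
        "pad_right": pad_right,
        "sfi_site_right": spec.sfi_site(spec.sfi_spacer_right),
        "lox71": LOX_SEQUENCES[LoxVariant.lox71],
        "ura4_marker": ura4,
    }
    elements: dict[str, tuple[int, int]] = {}
    pos = 0
    chunks = []
    for name, ln in spec.element_lengths:
        s = parts[name]
        assert len(s) == ln, (name, len(s), ln)
        elements[name] = (pos, pos + ln)
        chunks.append(s)
        pos += ln
    seq = NucSequence("cassette", "".join(chunks))
    cas = Cassette(seq, elements, barcode, spec)

    sfi = find_sites(seq, BUILTIN_ENZYMES["SfiI"])
    if len(sfi) != 2:
        raise InconsistentSpecError(f"assembled cassette has {len(sfi)} SfiI sites, want 2")
    if len(cas.excise_monomer()) != spec.monomer_len:
        raise InconsistentSpecError("monomer length does not meet the spec")
    return cas


def barcode_context(cassette: Cassette, pad: int = 13) -> tuple[str, str]:
    """Constant sequence flanking the barcode slot, for rejection screening."""
    s, e = cassette.elements["barcode"]
    return cassette.seq.bases[max(0, s - pad) : s], cassette.seq.bases[e : e + pad]


def draw_clone(cassette: Cassette, rng_seed: int | np.random.Generator) -> Cassette:
    """A fresh library clone: same backbone, new screened barcode."""
    bc = generate_barcode(cassette.spec.template, rng_seed, context=barcode_context(cassette))
    return with_barcode(cassette, bc)


def with_barcode(cassette: Cassette, barcode: Barcode) -> Cassette:
    """Same cassette backbone with a different barcode (one vector
    preparation, many clones)."""
    if not cassette.spec.template.conforms(barcode.seq):
        raise InvalidTemplateError("barcode does not conform to the template")
    s, e = cassette.elements["barcode"]
    bases = cassette.seq.bases[:s] + barcode.seq + cassette.seq.bases[e:]
    out = Cassette(NucSequence(cassette.seq.id, bases), cassette.elements, barcode, cassette.spec)
    if len(find_sites(out.seq, BUILTIN_ENZYMES["SfiI"])) != 2:
        raise InconsistentSpecError("barcode creates a spurious SfiI site in context")
    window = bases[max(0, s - 13) : e + 13]
    for motif in _VECTOR_FORBIDDEN[1:]:
        if _iupac_contains(window, motif):
            raise InconsistentSpecError(f"barcode creates a {motif} site in context")
    return out
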