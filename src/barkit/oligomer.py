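"""Barcode monomer concatemerization and concatemer-read deconvolution.

Barcode monomers excised with SfiI carry non-palindromic 3-nt 3' overhangs
whose two ends are reverse complements of each other, so T4 ligase can only
chain them head-to-tail.  A single Sanger read of a cloned concatemer then
yields several barcodes at fixed offsets from the reconstituted SfiI
junctions; parsing is the inverse operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .cassette import BarcodeTemplate, CassetteSpec
from .seq import Fragment, NucSequence, OverhangKind, join

__all__ = [
    "Concatemer",
    "BarcodeCall",
    "CallStatus",
    "OligomerParams",
    "oligomerize",
    "size_select",
    "parse_concatemer",
    "ChemistryError",
]

SFI_PATTERN = "GGCCNNNNNGGCC"
# indices of the constant bases within the 13-nt SfiI junction motif
_JUNCTION_FIXED = tuple(i for i, c in enumerate(SFI_PATTERN) if c != "N")


class ChemistryError(ValueError):
    pass


class CallStatus(str, Enum):
    passed = "pass"
    ambiguous = "ambiguous"
    failed = "fail"


@dataclass(frozen=True)
class OligomerParams:
    """Tunables for chain-length simulation and junction-tolerant parsing.

    ``chain_extend_prob`` is the truncated-geometric extension probability;
    0.69 puts the post-size-selection (0.3-1 kb) mean at ~7 monomers per
    concatemer, the routine yield of the cloning protocol this emulates.
    """

    chain_extend_prob: float = 0.69
    max_chain: int = 30
    junction_mismatches: int = 1
    max_template_mismatches: int = 2


@dataclass(frozen=True)
class Concatemer:
    fragment: Fragment
    monomer_count: int
    junction_positions: tuple[int, ...]
    source_barcodes: tuple[str, ...] = ()

    @property
    def seq(self) -> NucSequence:
        return self.fragment.seq

    def __len__(self) -> int:
        return len(self.fragment)


@dataclass(frozen=True)
class BarcodeCall:
    seq: str
    mismatches_to_template: int
    status: CallStatus
    read_id: str = ""
    segment_index: int = -1


def _chain_length(rng: np.random.Generator, p_extend: float, max_chain: int) -> int:
    k = 1
    while k < max_chain and rng.random() < p_extend:
        k += 1
    return k


def oligomerize(
    monomers: list[Fragment],
    rng_seed: int | np.random.Generator,
    params: OligomerParams = OligomerParams(),
    *,
    n_concatemers: int = 1,
    spec: CassetteSpec | None = None,
) -> list[Concatemer]:
    """Ligate random chains of barcode monomers.

    Monomers are drawn from the pool with replacement; chain lengths follow
    a truncated geometric distribution.  Every junction is made by
    :func:`barkit.seq.join`, so only head-to-tail chemistry is possible and
    each junction reconstitutes a full SfiI site.
    """
    if not monomers:
        raise ValueError("empty monomer pool")
    for m in monomers:
        if m.left_end.kind == OverhangKind.blunt or m.right_end.kind == OverhangKind.blunt:
            raise ChemistryError("monomers must carry SfiI sticky ends, not blunt ends")
    spec = spec or CassetteSpec()
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    off = monomer_barcode_offset(spec)
    blen = spec.template.length

    out: list[Concatemer] = []
    for i in range(n_concatemers):
        k = _chain_length(rng, params.chain_extend_prob, params.max_chain)
        picks = [monomers[int(j)] for j in rng.integers(0, len(monomers), size=k)]
        frag = picks[0]
        junctions = []
        for nxt in picks[1:]:
            junctions.append(len(frag) - 8)  # reconstituted site starts 8 nt back
            frag = join(frag, nxt)
        frag = Fragment(
            NucSequence(f"concatemer_{i}", frag.seq.bases),
            frag.left_end,
            frag.right_end,
        )
        barcodes = tuple(m.seq.bases[off : off + blen] for m in picks)
        out.append(Concatemer(frag, k, tuple(junctions), barcodes))
    return out


def monomer_barcode_offset(spec: CassetteSpec) -> int:
    """Offset of the barcode within an excised monomer's top strand."""
    # monomer top strand starts at the left SfiI cut (offset 8 into the
    # 13-nt site), so 5 nt of the site remain, then the constant pad
    return (13 - 8) + spec.pad_len


def size_select(oligomers: list[Concatemer], min_bp: int, max_bp: int) -> list[Concatemer]:
    """Gel size selection: retain concatemers with min_bp <= length <= max_bp."""
    if min_bp > max_bp:
        raise ValueError("min_bp must be <= max_bp")
    return [c for c in oligomers if min_bp <= len(c) <= max_bp]


def _junction_matches(bases: str, max_mm: int) -> list[int]:
    """Starts of SfiI junction motifs, allowing substitutions at up to
    ``max_mm`` of the 8 constant positions (spacer bases are free)."""
    hits = []
    for s in range(len(bases) - 13 + 1):
        mm = 0
        for j in _JUNCTION_FIXED:
            if bases[s + j] != SFI_PATTERN[j]:
                mm += 1
                if mm > max_mm:
                    break
        else:
            hits.append(s)
    # suppress overlapping calls (a true junction plus a shifted noisy one)
    pruned: list[int] = []
    for h in hits:
        if not pruned or h - pruned[-1] >= 13:
            pruned.append(h)
    return pruned


def parse_concatemer(
    read: NucSequence,
    template: BarcodeTemplate,
    params: OligomerParams = OligomerParams(),
    *,
    spec: CassetteSpec | None = None,
) -> list[BarcodeCall]:
    """Deconvolve a concatemer read into per-monomer barcode calls.

    The read is split at (error-tolerant) SfiI junction motifs; each segment
    should be one monomer with the barcode at a fixed offset.  Segments whose
    length is off (indels, truncation) are re-anchored from the right; when
    the two anchors disagree and fit the template equally well the call is
    ambiguous, and segments with no usable window fail -- nothing is
    silently dropped.
    """
    spec = spec or CassetteSpec()
    off = monomer_barcode_offset(spec)
    blen = template.length
    mono = spec.monomer_len
    bases = read.bases
    if not bases:
        return []

    # candidate junctions must sit on the monomer grid (the parser knows the
    # cassette design): this rejects chance motif look-alikes inside random
    # barcode sequence while keeping error-bearing true junctions
    junctions = [
        j for j in _junction_matches(bases, params.junction_mismatches) if (j + 8) % mono == 0
    ]
    starts = [0] + [j + 8 for j in junctions]
    calls: list[BarcodeCall] = []
    for idx, s in enumerate(starts):
        e = (junctions[idx] + 8) if idx < len(junctions) else len(bases)
        seg = bases[s:e]
        expected = mono if idx < len(junctions) else mono  # full monomer either way
        cand: list[str] = []
        if len(seg) >= off + blen:
            cand.append(seg[off : off + blen])
        # right-anchored window: barcode ends (pad+5) nt before the segment end
        tail = (13 - 8) + spec.pad_len
        if len(seg) != expected and len(seg) >= tail + blen:
            right = seg[len(seg) - tail - blen : len(seg) - tail]
            if right not in cand:
                cand.append(right)
        if not cand:
            calls.append(BarcodeCall("", blen, CallStatus.failed, read.id, idx))
            continue
        scored = sorted((template.mismatches(c), c) for c in cand)
        best_mm, best = scored[0]
        if len(scored) > 1 and scored[1][0] == best_mm and scored[1][1] != best:
            calls.append(BarcodeCall(best, best_mm, CallStatus.ambiguous, read.id, idx))
        elif best_mm <= params.max_template_mismatches:
            calls.append(BarcodeCall(best, best_mm, CallStatus.passed, read.id, idx))
        else:
            calls.append(BarcodeCall(best, best_mm, CallStatus.failed, read.id, idx))
    return calls
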