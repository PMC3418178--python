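"""Insertion alleles and in-silico prediction of insertion-site mapping.

Non-homologous integration of the linear cassette produces complex alleles:
single copies, tandem arrays in head-to-tail / head-to-head / tail-to-tail
orientation, end resection of the vector (5 bp up to 1.8 kb), small (<= 5 bp)
deletions of flanking genome, and occasional co-integration of mitochondrial
DNA.  This module builds such alleles into a genome while keeping a
base-level provenance map, and predicts the product and outcome of the four
mapping strategies used to locate them:

* TAIL-PCR -- nested vector primers against arbitrary degenerate primers;
  fails with vector-only products on head-to-head arrays and with
  mitochondrial products on co-integrants.
* splinkerette PCR -- SpeI/XbaI digestion, hairpin adaptor ligation, vector
  x adaptor PCR across the vector 5' junction.
* inverse splinkerette PCR -- EcoRV digestion, intramolecular
  circularization, SfiI re-linearization, adaptor ligation and nested PCR;
  bounds the insertion by the nearest genomic EcoRV site.
* Cre-lox cloning -- one-way integration of a lox66 plasmid into the
  cassette's lox71, then SpeI/XbaI excision and re-circularization of an
  origin/marker-bearing plasmid that carries flanking genomic DNA.

PCR is modelled as primer-site geometry with a product-length cap, not
thermodynamics; that is enough to reproduce the methods' outcome classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .cassette import Cassette, LOX_SEQUENCES, LoxVariant, constrained_filler, random_dna
from .io import Feature
from .seq import (
    BUILTIN_ENZYMES,
    NucSequence,
    RestrictionEnzyme,
    Topology,
    find_sites,
    revcomp,
)
from .seq import _scan as _iupac_scan
from .seq import iupac_revcomp

__all__ = [
    "Orientation",
    "CopySpec",
    "Cointegrant",
    "InsertionStructure",
    "Segment",
    "MutantGenome",
    "MappingResult",
    "MappingParams",
    "Resolution",
    "FeatureClass",
    "Outcome",
    "Method",
    "Lox66Plasmid",
    "apply_insertion",
    "predict_tail_pcr",
    "predict_splinkerette",
    "predict_inverse_splinkerette",
    "map_junction_read",
    "cre_lox_integrate",
    "clone_flank",
    "make_lox66_plasmid",
    "DEFAULT_AD_PRIMERS",
    "InvalidStructureError",
    "InvalidSubstrateError",
    "NonClonableError",
]


class InvalidStructureError(ValueError):
    pass


class InvalidSubstrateError(ValueError):
    pass


class NonClonableError(ValueError):
    pass


class Orientation(str, Enum):
    forward = "forward"
    reverse = "reverse"


@dataclass(frozen=True)
class CopySpec:
    orientation: Orientation
    left_trim: int = 0  # bp removed from the cassette 5' (lambda) end
    right_trim: int = 0  # bp removed from the cassette 3' (ura4) end


@dataclass(frozen=True)
class Cointegrant:
    """A span of another contig (typically mitochondrial) co-integrated
    5' of the first cassette copy."""

    source_id: str
    start: int
    end: int


@dataclass(frozen=True)
class InsertionStructure:
    copies: tuple[CopySpec, ...]
    cointegrant: Cointegrant | None = None
    genomic_deletion_bp: int = 0

    def __post_init__(self) -> None:
        if not self.copies:
            raise InvalidStructureError("structure needs at least one cassette copy")
        for c in self.copies:
            if c.left_trim < 0 or c.right_trim < 0:
                raise InvalidStructureError("trims must be >= 0")
        if self.genomic_deletion_bp < 0:
            raise InvalidStructureError("genomic deletion must be >= 0")


@dataclass(frozen=True)
class Segment:
    """Provenance of one run of bases in a mutant chromosome."""

    start: int
    end: int
    kind: str  # genome | cassette | cointegrant | plasmid
    name: str  # contig id, "copy<i>", or plasmid id
    src_start: int
    src_end: int
    strand: str = "+"

    def __len__(self) -> int:
        return self.end - self.start

    def to_source(self, pos: int) -> int:
        """Map a mutant-chromosome coordinate inside this segment to source
        coordinates."""
        if not self.start <= pos < self.end:
            raise ValueError("position outside segment")
        if self.strand == "+":
            return self.src_start + (pos - self.start)
        return self.src_end - 1 - (pos - self.start)


@dataclass
class MutantGenome:
    contigs: dict[str, NucSequence]
    chromosome: str
    position: int  # pre-insertion 0-based coordinate of the insertion point
    structure: InsertionStructure
    provenance: tuple[Segment, ...]
    cassette: Cassette
    barcode: str = ""
    mutant_id: str = ""
    event_log: list[str] = field(default_factory=list)

    @property
    def mutated(self) -> NucSequence:
        return self.contigs[self.chromosome]

    def truth(self) -> dict:
        st = self.structure
        return {
            "mutant_id": self.mutant_id,
            "chromosome": self.chromosome,
            "position": self.position,
            "genomic_deletion_bp": st.genomic_deletion_bp,
            "barcode": self.barcode,
            "copies": [
                {"orientation": c.orientation.value, "left_trim": c.left_trim, "right_trim": c.right_trim}
                for c in st.copies
            ],
            "cointegrant": (
                {"source_id": st.cointegrant.source_id, "start": st.cointegrant.start, "end": st.cointegrant.end}
                if st.cointegrant
                else None
            ),
        }

    def segments_overlapping(self, start: int, end: int) -> list[Segment]:
        return [s for s in self.provenance if s.start < end and s.end > start]


class Resolution(str, Enum):
    exact_junction = "exact_junction"
    bounded_by_site = "bounded_by_site"


class FeatureClass(str, Enum):
    ORF = "ORF"
    ncRNA = "ncRNA"
    intergenic = "intergenic"


class Method(str, Enum):
    tail_pcr = "tail_pcr"
    splinkerette = "splinkerette"
    inverse_splinkerette = "inverse_splinkerette"
    lox_cloning = "lox_cloning"


class Outcome(str, Enum):
    genomic_junction = "genomic_junction"
    vector_only = "vector_only"
    mito_cointegrant = "mito_cointegrant"
    no_product = "no_product"


@dataclass(frozen=True)
class MappingResult:
    method: Method
    outcome: Outcome
    chromosome: str | None = None
    interval: tuple[int, int] | None = None  # 0-based inclusive endpoints
    resolution: Resolution | None = None
    feature_class: FeatureClass | None = None
    ambiguous: bool = False
    note: str = ""


# Arbitrary degenerate primers for TAIL-PCR: IUPAC body with a concrete
# 8-nt 3' anchor (the anchor is what must pair exactly at low stringency).
DEFAULT_AD_PRIMERS: tuple[str, ...] = (
    "WNSNWNSNCAGTCTGA",
    "NSNWNSNWGTACAGCT",
)


@dataclass(frozen=True)
class MappingParams:
    max_product_bp: int = 3000
    isp_max_product_bp: int = 5000
    circularization_cap_bp: int = 20000
    adaptor_len: int = 30
    anchor_len: int = 8
    exact_threshold: int = 30
    min_seed: int = 20
    max_genomic_deletion: int = 5
    ad_primers: tuple[str, ...] = DEFAULT_AD_PRIMERS


# ---------------------------------------------------------------------------
# building mutant genomes


def apply_insertion(
    genome: dict[str, NucSequence],
    chromosome: str,
    position: int,
    structure: InsertionStructure,
    cassette: Cassette,
    *,
    mutant_id: str = "",
) -> MutantGenome:
    """Splice an insertion allele into ``chromosome`` at ``position``.

    The mutant chromosome is original[:position] + block + original[position
    + deletion:], where the block is the optional co-integrant followed by
    the trimmed, oriented cassette copies.  A provenance map recording the
    source of every base is kept for downstream mapping predictors and for
    the length bookkeeping invariant.
    """
    if chromosome not in genome:
        raise KeyError(chromosome)
    chrom = genome[chromosome]
    if not 0 <= position <= len(chrom):
        raise InvalidStructureError("position outside chromosome")
    if position + structure.genomic_deletion_bp > len(chrom):
        raise InvalidStructureError("genomic deletion runs off the chromosome")
    cas_len = len(cassette.seq)
    for c in structure.copies:
        if c.left_trim + c.right_trim >= cas_len:
            raise InvalidStructureError("trims exceed cassette length")
    if structure.cointegrant is not None:
        co = structure.cointegrant
        if co.source_id not in genome:
            raise KeyError(co.source_id)
        if not 0 <= co.start < co.end <= len(genome[co.source_id]):
            raise InvalidStructureError("cointegrant span outside source contig")

    parts: list[str] = []
    segs: list[Segment] = []
    cursor = position

    def push(bases: str, kind: str, name: str, s: int, e: int, strand: str) -> None:
        nonlocal cursor
        parts.append(bases)
        segs.append(Segment(cursor, cursor + len(bases), kind, name, s, e, strand))
        cursor += len(bases)

    if structure.cointegrant is not None:
        co = structure.cointegrant
        push(genome[co.source_id].bases[co.start : co.end], "cointegrant", co.source_id, co.start, co.end, "+")
    for i, c in enumerate(structure.copies):
        s, e = c.left_trim, cas_len - c.right_trim
        sub = cassette.seq.bases[s:e]
        if c.orientation == Orientation.reverse:
            push(revcomp(sub), "cassette", f"copy{i}", s, e, "-")
        else:
            push(sub, "cassette", f"copy{i}", s, e, "+")

    del_bp = structure.genomic_deletion_bp
    block = "".join(parts)
    new_bases = chrom.bases[:position] + block + chrom.bases[position + del_bp :]
    provenance = (
        Segment(0, position, "genome", chromosome, 0, position, "+"),
        *segs,
        Segment(
            position + len(block),
            len(new_bases),
            "genome",
            chromosome,
            position + del_bp,
            len(chrom),
            "+",
        ),
    )
    contigs = dict(genome)
    contigs[chromosome] = NucSequence(chrom.id, new_bases)
    barcode = cassette.barcode.seq
    return MutantGenome(
        contigs, chromosome, position, structure, provenance, cassette, barcode, mutant_id
    )


# ---------------------------------------------------------------------------
# shared PCR geometry helpers


def _find_exact(bases: str, query: str) -> list[int]:
    out, i = [], bases.find(query)
    while i != -1:
        out.append(i)
        i = bases.find(query, i + 1)
    return out


def _genomic_interval(
    mutant: MutantGenome, start: int, end: int, params: MappingParams
) -> tuple[int, int]:
    """Original-genome interval covered by the genomic part of a product,
    widened at each edge by the configured residual-deletion bound so that
    the true pre-insertion coordinate is inside it."""
    lo, hi = None, None
    chrom_len = None
    for s in mutant.segments_overlapping(start, end):
        if s.kind != "genome":
            continue
        a = s.to_source(max(start, s.start))
        b = s.to_source(min(end, s.end) - 1)
        a, b = min(a, b), max(a, b)
        lo = a if lo is None else min(lo, a)
        hi = b if hi is None else max(hi, b)
    if lo is None:
        raise ValueError("no genomic provenance in span")
    pad = params.max_genomic_deletion
    return max(0, lo - pad), hi + pad


def _feature_class(
    annotations: Sequence[Feature] | None, contig: str, start: int, end: int
) -> FeatureClass | None:
    if annotations is None:
        return None
    best = FeatureClass.intergenic
    for f in annotations:
        if f.contig != contig or f.start >= end + 1 or f.end <= start:
            continue
        if f.type in ("gene", "CDS", "mRNA"):
            return FeatureClass.ORF
        if "ncRNA" in f.type:
            best = FeatureClass.ncRNA
    return best


@dataclass(frozen=True)
class _PrimerSite:
    pos: int  # leftmost coordinate of the annealed primer
    length: int
    direction: str  # 'R' extends rightward, 'L' extends leftward

    @property
    def left(self) -> int:
        return self.pos

    @property
    def right(self) -> int:
        return self.pos + self.length


def _specific_sites(bases: str, window_seq: str) -> list[_PrimerSite]:
    """Sites of a cassette-window primer.  The primer is the reverse
    complement of the cassette top-strand window, so at a forward copy it
    extends leftward (toward the cassette 5' end), at a reverse copy
    rightward."""
    w = len(window_seq)
    sites = [_PrimerSite(p, w, "L") for p in _find_exact(bases, window_seq)]
    sites += [_PrimerSite(p, w, "R") for p in _find_exact(bases, revcomp(window_seq))]
    return sites


def _ad_sites(bases: str, ad_primers: Sequence[str]) -> list[_PrimerSite]:
    sites: list[_PrimerSite] = []
    for pat in ad_primers:
        p = pat.upper()
        for pos in _iupac_scan(bases, p):
            sites.append(_PrimerSite(pos, len(p), "R"))
        for pos in _iupac_scan(bases, iupac_revcomp(p)):
            sites.append(_PrimerSite(pos, len(p), "L"))
    return sites


def _products(
    anchors: Iterable[_PrimerSite], partners: Iterable[_PrimerSite], cap: int
) -> list[tuple[tuple[int, int], _PrimerSite]]:
    """Amplicons between an anchor primer and any facing partner, shortest
    first."""
    out = {}
    for a in anchors:
        for b in partners:
            if a.direction == "L" and b.direction == "R" and b.right <= a.left:
                span = (b.left, a.right)
            elif a.direction == "R" and b.direction == "L" and b.left >= a.right:
                span = (a.left, b.right)
            else:
                continue
            if span[1] - span[0] <= cap and span not in out:
                out[span] = a
    return sorted(out.items(), key=lambda kv: (kv[0][1] - kv[0][0], kv[0]))


def _first_noncassette(
    mutant: MutantGenome, s0: int, s1: int, anchor: _PrimerSite
) -> Segment | None:
    """First non-cassette provenance segment a polymerase (or a sequencing
    read) meets extending from ``anchor`` within the product span: this is
    what the experimenter actually observes beyond the vector end."""
    if anchor.direction == "L":
        cands = [
            s for s in mutant.segments_overlapping(s0, anchor.left) if s.kind != "cassette"
        ]
        return max(cands, key=lambda s: s.end) if cands else None
    cands = [s for s in mutant.segments_overlapping(anchor.right, s1) if s.kind != "cassette"]
    return min(cands, key=lambda s: s.start) if cands else None


_KIND_OUTCOME = {"genome": Outcome.genomic_junction, "cointegrant": Outcome.mito_cointegrant}


def _segment_interval(
    seg: Segment, s0: int, s1: int, params: MappingParams
) -> tuple[int, int]:
    """Original-genome interval of the part of ``seg`` inside the product
    span, widened by the configured residual-deletion bound so that the
    true pre-insertion coordinate is inside it."""
    a = seg.to_source(max(s0, seg.start))
    b = seg.to_source(min(s1, seg.end) - 1)
    a, b = min(a, b), max(a, b)
    pad = params.max_genomic_deletion
    return max(0, a - pad), b + pad


# ---------------------------------------------------------------------------
# TAIL-PCR


def _nested_windows(cassette: Cassette) -> list[tuple[int, int]]:
    """Default nested vector-primer windows, outermost to innermost, inside
    the constant promoter element, all pointing toward the cassette 5' end."""
    ps, pe = cassette.elements["lexa_hsp70_promoter"]
    return [(pe - 35, pe - 15), (pe - 65, pe - 45), (pe - 95, pe - 75)]


def predict_tail_pcr(
    mutant: MutantGenome,
    ad_primers: Sequence[str] | None = None,
    nested_windows: Sequence[tuple[int, int]] | None = None,
    params: MappingParams = MappingParams(),
    annotations: Sequence[Feature] | None = None,
) -> tuple[list[NucSequence], MappingResult]:
    """Three nested rounds of specific x arbitrary-degenerate PCR.

    The shortest tertiary product is classified by the provenance of the
    bases it spans: any nuclear genomic content means the junction was
    reached; a product staying inside cassette copies reproduces the
    vector-only failure of head-to-head arrays; a product entering
    co-integrated mitochondrial DNA reproduces the mitochondrial failure
    class.
    """
    if ad_primers is not None and len(ad_primers) == 0:
        raise ValueError("empty AD primer set")
    ad_primers = tuple(ad_primers) if ad_primers is not None else params.ad_primers
    windows = list(nested_windows) if nested_windows is not None else _nested_windows(mutant.cassette)
    if len(windows) != 3:
        raise ValueError("TAIL-PCR needs exactly 3 nested vector primers")
    bases = mutant.mutated.bases
    cas = mutant.cassette.seq.bases

    ad = _ad_sites(bases, ad_primers)
    products: list[tuple[tuple[int, int], _PrimerSite]] | None = None
    for a, b in windows:  # outermost first
        specific = _specific_sites(bases, cas[a:b])
        round_products = _products(specific, ad + specific, params.max_product_bp)
        if products is not None:
            prior = [p[0] for p in products]
            round_products = [
                p for p in round_products if any(p[0][0] >= q[0] and p[0][1] <= q[1] for q in prior)
            ]
        if not round_products:
            return [], MappingResult(Method.tail_pcr, Outcome.no_product)
        products = round_products

    assert products
    (s0, s1), anchor = products[0]  # shortest tertiary product
    product = NucSequence(f"{mutant.mutant_id or 'mutant'}|tail_pcr", bases[s0:s1])
    beyond = _first_noncassette(mutant, s0, s1, anchor)
    if beyond is None:
        return [product], MappingResult(Method.tail_pcr, Outcome.vector_only)
    outcome = _KIND_OUTCOME.get(beyond.kind, Outcome.vector_only)
    if outcome != Outcome.genomic_junction:
        return [product], MappingResult(Method.tail_pcr, outcome)
    interval = _segment_interval(beyond, s0, s1, params)
    width = interval[1] - interval[0]
    return [product], MappingResult(
        Method.tail_pcr,
        outcome,
        chromosome=mutant.chromosome,
        interval=interval,
        resolution=Resolution.exact_junction if width <= 1 else Resolution.bounded_by_site,
        feature_class=_feature_class(annotations, mutant.chromosome, *interval),
        note="junction read; interval widened by the residual genomic-deletion bound",
    )


# ---------------------------------------------------------------------------
# splinkerette PCR


def predict_splinkerette(
    mutant: MutantGenome,
    enzymes: Sequence[RestrictionEnzyme] | None = None,
    adaptor_overhang: str = "CTAG",
    params: MappingParams = MappingParams(),
    annotations: Sequence[Feature] | None = None,
) -> tuple[list[NucSequence], MappingResult]:
    """SpeI/XbaI digestion, adaptor ligation, vector x adaptor PCR.

    The vector primer sits in the constant promoter element pointing toward
    the cassette 5' end; the product runs from the primer across whatever
    abuts that end, to the nearest compatible restriction cut, plus the
    adaptor.
    """
    enzymes = list(enzymes) if enzymes is not None else [BUILTIN_ENZYMES["SpeI"], BUILTIN_ENZYMES["XbaI"]]
    for enz in enzymes:
        t, b = enz.cut_top, enz.cut_bottom
        over = enz.recognition[min(t, b) : max(t, b)]
        if over.upper() != adaptor_overhang.upper():
            raise InvalidSubstrateError(
                f"adaptor overhang {adaptor_overhang!r} incompatible with {enz.name}"
            )
    bases = mutant.mutated.bases
    cas = mutant.cassette.seq.bases
    windows = _nested_windows(mutant.cassette)
    a, b = windows[1]  # the nested (second-round) primer defines the product
    specific = _specific_sites(bases, cas[a:b])
    if not specific:
        return [], MappingResult(Method.splinkerette, Outcome.no_product)

    cuts = sorted(
        {c.cut_top for enz in enzymes for c in find_sites(mutant.mutated, enz)}
    )
    products: list[tuple[int, int, _PrimerSite]] = []
    for site in specific:
        if site.direction == "L":
            left_cuts = [c for c in cuts if c <= site.left]
            if not left_cuts:
                continue
            span = (left_cuts[-1], site.right)
        else:
            right_cuts = [c for c in cuts if c >= site.right]
            if not right_cuts:
                continue
            span = (site.left, right_cuts[0])
        if span[1] - span[0] + params.adaptor_len <= params.max_product_bp:
            products.append((*span, site))
    if not products:
        return [], MappingResult(Method.splinkerette, Outcome.no_product)

    products.sort(key=lambda p: p[1] - p[0])
    s0, s1, site = products[0]
    prod_seqs = [
        NucSequence(f"{mutant.mutant_id or 'mutant'}|splinkerette_{i}", bases[p0:p1])
        for i, (p0, p1, _) in enumerate(products)
    ]
    beyond = _first_noncassette(mutant, s0, s1, site)
    outcome = _KIND_OUTCOME.get(beyond.kind, Outcome.vector_only) if beyond else Outcome.vector_only
    if outcome != Outcome.genomic_junction:
        return prod_seqs, MappingResult(Method.splinkerette, outcome)
    interval = _segment_interval(beyond, s0, s1, params)
    return prod_seqs, MappingResult(
        Method.splinkerette,
        outcome,
        chromosome=mutant.chromosome,
        interval=interval,
        resolution=Resolution.bounded_by_site,
        feature_class=_feature_class(annotations, mutant.chromosome, *interval),
        note="bounded by the nearest SpeI/XbaI cut",
    )


# ---------------------------------------------------------------------------
# inverse splinkerette PCR


def _ura4_primer_windows(cassette: Cassette) -> list[tuple[int, int]]:
    """Nested marker-side primers 5' of the cassette's internal EcoRV site,
    pointing across it (outermost first)."""
    ec = cassette.elements["ura4_marker"][0] + cassette.spec.ura4_ecorv_offset
    return [(ec - 153, ec - 133), (ec - 83, ec - 63)]


def predict_inverse_splinkerette(
    mutant: MutantGenome,
    enzyme: RestrictionEnzyme | None = None,
    params: MappingParams = MappingParams(),
    annotations: Sequence[Feature] | None = None,
) -> tuple[NucSequence | None, MappingResult]:
    """Digest / circularize / SfiI-linearize / adaptor-ligate / nested PCR.

    The enzyme must cut the cassette exactly once (EcoRV, inside the ura4
    stand-in) and frequently in the genome.  The amplifiable circle spans
    from that internal cut, across the cassette 5' end, to the nearest
    neighbouring cut; its non-vector content determines the outcome and the
    reported interval is bounded by that neighbouring (genomic) cut.
    """
    enzyme = enzyme or BUILTIN_ENZYMES["EcoRV"]
    cas_sites = find_sites(mutant.cassette.seq, enzyme)
    if len(cas_sites) != 1:
        raise InvalidSubstrateError(
            f"{enzyme.name} must cut the cassette exactly once, found {len(cas_sites)}"
        )
    bases = mutant.mutated.bases
    cas = mutant.cassette.seq.bases
    cuts = sorted({c.cut_top for c in find_sites(mutant.mutated, enzyme)})
    if not cuts:
        return None, MappingResult(Method.inverse_splinkerette, Outcome.no_product)

    w_out, w_in = _ura4_primer_windows(mutant.cassette)
    sfi_left = mutant.cassette.sfi_cut_left

    # For each cassette copy with an intact nested-primer + EcoRV region,
    # walk from its internal EcoRV cut across the cassette 5' end to the
    # neighbouring cut: that is the fragment that circularizes.
    results: list[tuple[int, int, int, str]] = []  # (circle_len, lo, hi, dirn)
    ec = mutant.cassette.elements["ura4_marker"][0] + mutant.cassette.spec.ura4_ecorv_offset
    for seg in mutant.provenance:
        if seg.kind != "cassette":
            continue
        # internal EcoRV present in this copy?
        if not (seg.src_start <= ec and ec + 6 <= seg.src_end):
            continue
        # primer windows and both SfiI sites present?
        need_lo = min(w_out[0], mutant.cassette.elements["sfi_site_left"][0])
        if not (seg.src_start <= need_lo):
            continue
        if seg.strand == "+":
            cut_m = seg.start + (ec + 3 - seg.src_start)  # EcoRV blunt cut at +3
            left_cuts = [c for c in cuts if c < cut_m]
            if not left_cuts:
                continue
            other = left_cuts[-1]
            lo, hi = other, cut_m
        else:
            cut_m = seg.start + (seg.src_end - (ec + 3))
            right_cuts = [c for c in cuts if c > cut_m]
            if not right_cuts:
                continue
            other = right_cuts[0]
            lo, hi = cut_m, other
        circle_len = hi - lo
        if circle_len > params.circularization_cap_bp:
            continue
        results.append((circle_len, lo, hi, seg.strand))

    if not results:
        return None, MappingResult(Method.inverse_splinkerette, Outcome.no_product)

    # classify each circle by what sits at its far (neighbouring-cut) end:
    # the nested read runs from the marker primer across the re-ligated
    # EcoRV junction and that is the first sequence it shows; prefer the
    # genomic circle (the one the experimenter would pursue), then
    # mitochondrial, then vector-only
    scored: list[tuple[int, Outcome, int, int, str, Segment]] = []
    for circle_len, lo, hi, strand in results:
        far = lo if strand == "+" else hi - 1
        seg_far = next(s for s in mutant.provenance if s.start <= far < s.end)
        outcome = _KIND_OUTCOME.get(seg_far.kind, Outcome.vector_only)
        rank = {Outcome.genomic_junction: 0, Outcome.mito_cointegrant: 1, Outcome.vector_only: 2}[outcome]
        scored.append((rank, outcome, lo, hi, strand, seg_far))
    scored.sort(key=lambda r: (r[0], r[3] - r[2]))
    _, outcome, lo, hi, strand, seg_far = scored[0]

    # product: marker primer -> internal cut -> around the circle to the
    # cassette 5' SfiI cut, plus the adaptor
    const_marker = ec + 3 - w_in[0]  # primer to internal EcoRV cut
    const_lambda = sfi_left  # cassette start to the left SfiI cut
    product_len = const_marker + const_lambda + params.adaptor_len
    genomic_bp = sum(
        min(hi, s.end) - max(lo, s.start)
        for s in mutant.segments_overlapping(lo, hi)
        if s.kind != "cassette"
    )
    product_len += genomic_bp
    if product_len > params.isp_max_product_bp:
        return None, MappingResult(Method.inverse_splinkerette, Outcome.no_product)
    # assemble the product top strand: marker primer -> internal EcoRV cut,
    # then (around the circle) from the neighbouring cut through the
    # junction up to the copy's 5' SfiI cut, where the adaptor sits
    if strand == "+":
        carrier = [s for s in mutant.segments_overlapping(lo, hi) if s.kind == "cassette"][-1]
        sfi_mut = carrier.start + (sfi_left - carrier.src_start)
        prod_bases = bases[hi - const_marker : hi] + bases[lo:sfi_mut]
    else:
        carrier = [s for s in mutant.segments_overlapping(lo, hi) if s.kind == "cassette"][0]
        sfi_mut = carrier.end - (sfi_left - carrier.src_start)
        prod_bases = revcomp(bases[lo : lo + const_marker]) + revcomp(bases[sfi_mut:hi])
    product = NucSequence(f"{mutant.mutant_id or 'mutant'}|inverse_splinkerette", prod_bases)

    if outcome != Outcome.genomic_junction:
        return product, MappingResult(Method.inverse_splinkerette, outcome)
    interval = _segment_interval(seg_far, lo, hi, params)
    d = interval[1] - interval[0]
    resolution = (
        Resolution.exact_junction if d <= params.exact_threshold else Resolution.bounded_by_site
    )
    return product, MappingResult(
        Method.inverse_splinkerette,
        outcome,
        chromosome=mutant.chromosome,
        interval=interval,
        resolution=resolution,
        feature_class=_feature_class(annotations, mutant.chromosome, *interval),
        note=f"bounded by the nearest genomic {enzyme.name} cut",
    )


# ---------------------------------------------------------------------------
# junction-read mapping


def map_junction_read(
    read: NucSequence,
    genome: dict[str, NucSequence],
    annotations: Sequence[Feature] | None = None,
    cassette: Cassette | None = None,
    params: MappingParams = MappingParams(),
) -> MappingResult:
    """Locate the genomic portion of a junction-crossing read.

    Cassette-derived prefixes/suffixes are stripped by exact matching
    against the cassette (either strand, either read end); the remainder is
    placed by an exact seed of ``params.min_seed`` nt extended to the full
    remainder, on both strands of every contig.  Multi-locus seeds are
    reported ambiguous rather than picked arbitrarily.
    """
    bases = read.bases
    if cassette is not None:
        bases = _strip_vector(bases, cassette.seq.bases)
    if len(bases) < params.min_seed:
        return MappingResult(Method.tail_pcr, Outcome.no_product, note="unmappable: remainder too short")

    hits: list[tuple[str, int, str]] = []
    for end in ("left", "right"):
        seed = bases[: params.min_seed] if end == "left" else bases[-params.min_seed :]
        for cid, contig in genome.items():
            for p in _find_exact(contig.bases, seed):
                hits.append((cid, p if end == "left" else p - (len(bases) - params.min_seed), "+"))
            for p in _find_exact(contig.bases, revcomp(seed)):
                hits.append((cid, p, "-"))
        if hits:
            break
    # deduplicate full-remainder placements
    placements = set()
    for cid, p, strand in hits:
        if strand == "+":
            if 0 <= p and contig_slice(genome[cid], p, p + len(bases)) == bases:
                placements.add((cid, p, p + len(bases), "+"))
        else:
            rc = revcomp(bases)
            for q in _find_exact(genome[cid].bases, rc):
                placements.add((cid, q, q + len(bases), "-"))
    if not placements:
        return MappingResult(Method.tail_pcr, Outcome.no_product, note="unmappable: no exact placement")
    if len(placements) > 1:
        return MappingResult(
            Method.tail_pcr, Outcome.no_product, ambiguous=True, note="ambiguous: multiple loci"
        )
    cid, s, e, strand = next(iter(placements))
    pad = max(1, params.max_genomic_deletion)  # junction sits at one edge
    return MappingResult(
        Method.tail_pcr,
        Outcome.genomic_junction,
        chromosome=cid,
        interval=(max(0, s - pad), e - 1 + pad),
        resolution=Resolution.bounded_by_site,
        feature_class=_feature_class(annotations, cid, s, e),
    )


def contig_slice(contig: NucSequence, s: int, e: int) -> str:
    if s < 0 or e > len(contig):
        return ""
    return contig.bases[s:e]


def _strip_vector(bases: str, cas: str, k: int = 15) -> str:
    """Remove a cassette-derived run from either end of the read."""
    casrc = revcomp(cas)
    for template in (cas, casrc):
        # grow a prefix match
        while len(bases) >= k and bases[:k] in template:
            n = k
            while n < len(bases) and bases[: n + 1] in template:
                n += 1
            bases = bases[n:]
        while len(bases) >= k and bases[-k:] in template:
            n = k
            while n < len(bases) and bases[-(n + 1) :] in template:
                n += 1
            bases = bases[:-n]
    return bases


# ---------------------------------------------------------------------------
# Cre-lox integration and flank cloning


@dataclass(frozen=True)
class Lox66Plasmid:
    """A circular lox66 integration plasmid with named elements."""

    seq: NucSequence
    elements: dict[str, tuple[int, int]]  # lox66, puc_origin, kanmx_marker, ...

    def __post_init__(self) -> None:
        if not self.seq.is_circular:
            raise InvalidSubstrateError("integration plasmid must be circular")


def make_lox66_plasmid(
    rng_seed: int | np.random.Generator,
    origin_len: int = 600,
    marker_len: int = 800,
    filler_len: int = 120,
    release_site: str = "ACTAGT",
) -> Lox66Plasmid:
    """Synthetic stand-in for a lox66 cloning plasmid.

    Layout (circular): lox66 | pUC origin | kanMX marker | SpeI release
    site | filler.  Origin and marker are kept free of the workflow's
    restriction sites; the single release site lets SpeI/XbaI digestion
    drop a fragment carrying origin + marker + one genomic flank.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    forbidden = ("GGCCNNNNNGGCC", "GATATC", "ACTAGT", "TCTAGA", "GGATCC") + DEFAULT_AD_PRIMERS
    origin = constrained_filler(rng, origin_len, forbidden)
    marker = constrained_filler(rng, marker_len, forbidden)
    filler = constrained_filler(rng, filler_len, forbidden)
    lox66 = LOX_SEQUENCES[LoxVariant.lox66]
    parts = [
        ("lox66", lox66),
        ("puc_origin", origin),
        ("kanmx_marker", marker),
        ("release_site", release_site),
        ("filler", filler),
    ]
    elements, pos, chunks = {}, 0, []
    for name, s in parts:
        elements[name] = (pos, pos + len(s))
        chunks.append(s)
        pos += len(s)
    return Lox66Plasmid(NucSequence("pLox66", "".join(chunks), Topology.circular), elements)


def cre_lox_integrate(
    mutant: MutantGenome, plasmid: Lox66Plasmid, cre_present: bool
) -> MutantGenome:
    """Cre-mediated one-way integration of a lox66 plasmid at the lox71 site.

    The crossover swaps arms: the product carries one wild-type loxP (both
    wild-type arms) and one lox66/71 double-mutant hybrid (both mutant
    arms), which Cre no longer recombines -- integration is irreversible.
    Without Cre the genome is returned unchanged.
    """
    lox71 = LOX_SEQUENCES[LoxVariant.lox71]
    lox66 = LOX_SEQUENCES[LoxVariant.lox66]
    hybrid = LOX_SEQUENCES[LoxVariant.hybrid_66_71]
    loxp = LOX_SEQUENCES[LoxVariant.loxP]
    chrom = mutant.mutated.bases

    fwd = _find_exact(chrom, lox71)
    rev = _find_exact(chrom, revcomp(lox71))
    n_sites = len(fwd) + len(rev)
    if n_sites == 0:
        if _find_exact(chrom, hybrid) or _find_exact(chrom, revcomp(hybrid)):
            out = replace_contig(mutant, chrom)
            out.event_log = mutant.event_log + ["no recombination: hybrid/loxP pair is one-way"]
            return out
        raise InvalidSubstrateError("substrate carries no lox71 site")
    if n_sites > 1:
        raise InvalidSubstrateError(f"substrate carries {n_sites} lox71 sites, need exactly 1")

    p_sites = _find_exact(plasmid.seq.bases, lox66)
    if len(p_sites) != 1:
        raise InvalidSubstrateError(
            f"plasmid carries {len(p_sites)} lox66 sites, need exactly 1"
        )
    if not cre_present:
        out = replace_contig(mutant, chrom)
        out.event_log = mutant.event_log + ["no recombination: Cre absent"]
        return out

    q = p_sites[0]
    pb = plasmid.seq.bases
    rest = pb[q + 34 :] + pb[:q]  # plasmid minus its lox66, in circle order
    insert = hybrid + rest + loxp  # lox71L+spacer+lox66R ... lox66L+spacer+lox71R
    if fwd:
        s = fwd[0]
        new = chrom[:s] + insert + chrom[s + 34 :]
        plasmid_span = (s, s + len(insert))
        strand = "+"
    else:
        s = rev[0]
        new = chrom[:s] + revcomp(insert) + chrom[s + 34 :]
        plasmid_span = (s, s + len(insert))
        strand = "-"

    out = replace_contig(mutant, new)
    out.provenance = _splice_provenance(
        mutant.provenance, s, s + 34, len(insert), "plasmid", "pLox66", 0, len(insert), strand
    )
    out.event_log = mutant.event_log + [
        f"Cre integration at lox71 ({mutant.chromosome}:{s + 1}); "
        "junctions: one loxP, one lox66/71 hybrid"
    ]
    return out


def replace_contig(mutant: MutantGenome, new_bases: str) -> MutantGenome:
    contigs = dict(mutant.contigs)
    contigs[mutant.chromosome] = NucSequence(mutant.mutated.id, new_bases)
    return MutantGenome(
        contigs,
        mutant.chromosome,
        mutant.position,
        mutant.structure,
        mutant.provenance,
        mutant.cassette,
        mutant.barcode,
        mutant.mutant_id,
        list(mutant.event_log),
    )


def _splice_provenance(
    provenance: tuple[Segment, ...],
    at_start: int,
    at_end: int,
    new_len: int,
    kind: str,
    name: str,
    src_start: int,
    src_end: int,
    strand: str,
) -> tuple[Segment, ...]:
    """Replace [at_start, at_end) of the mutant chromosome with a new
    ``new_len``-bp segment, shifting downstream provenance."""
    delta = new_len - (at_end - at_start)
    out: list[Segment] = []
    for s in provenance:
        if s.end <= at_start:
            out.append(s)
        elif s.start >= at_end:
            out.append(replace(s, start=s.start + delta, end=s.end + delta))
        else:
            if s.start < at_start:
                cut = at_start - s.start
                out.append(
                    replace(
                        s,
                        end=at_start,
                        src_end=s.src_start + cut if s.strand == "+" else s.src_end,
                        src_start=s.src_start if s.strand == "+" else s.src_end - cut,
                    )
                )
            if s.end > at_end:
                cut = s.end - at_end
                out.append(
                    replace(
                        s,
                        start=at_end + delta,
                        end=s.end + delta,
                        src_start=s.src_end - cut if s.strand == "+" else s.src_start,
                        src_end=s.src_end if s.strand == "+" else s.src_start + cut,
                    )
                )
    out.append(Segment(at_start, at_start + new_len, kind, name, src_start, src_end, strand))
    return tuple(sorted(out, key=lambda s: s.start))


def clone_flank(
    integrated: MutantGenome,
    plasmid: Lox66Plasmid,
    enzymes: Sequence[RestrictionEnzyme] | None = None,
    params: MappingParams = MappingParams(),
) -> tuple[NucSequence, MappingResult]:
    """Excise and re-circularize the origin/marker fragment after Cre
    integration; the recovered plasmid carries the insertion-adjacent
    genomic flank up to the nearest compatible restriction cut."""
    enzymes = list(enzymes) if enzymes is not None else [BUILTIN_ENZYMES["SpeI"], BUILTIN_ENZYMES["XbaI"]]
    plasmid_segs = [s for s in integrated.provenance if s.kind == "plasmid"]
    if not plasmid_segs:
        raise InvalidSubstrateError("genome carries no integrated plasmid")
    seg = plasmid_segs[0]

    def to_mut(src: int) -> int:
        if seg.strand == "+":
            return seg.start + (src - seg.src_start)
        return seg.start + (seg.src_end - src)

    # element coordinates inside the integrated construct: the construct is
    # hybrid(34) + plasmid-after-lox66 + loxP(34); plasmid element coords
    # must be rotated accordingly
    q = plasmid.elements["lox66"][0]
    pb_len = len(plasmid.seq)

    def construct_coord(plasmid_pos: int) -> int:
        # position in 'rest' (plasmid minus lox66, starting right after it)
        return 34 + ((plasmid_pos - (q + 34)) % pb_len)

    spans = {}
    for name in ("puc_origin", "kanmx_marker"):
        a, b = plasmid.elements[name]
        ca, cb = construct_coord(a), construct_coord(b - 1) + 1
        lo, hi = sorted((to_mut(seg.src_start + ca), to_mut(seg.src_start + cb - 1)))
        spans[name] = (lo, hi + 1)

    cuts = sorted(
        {c.cut_top for enz in enzymes for c in find_sites(integrated.mutated, enz)}
    )
    for name, (a, b) in spans.items():
        for c in cuts:
            if a < c < b:
                raise NonClonableError(f"restriction cut inside the {name} element")

    lo = min(a for a, _ in spans.values())
    hi = max(b for _, b in spans.values())
    left_cuts = [c for c in cuts if c <= lo]
    right_cuts = [c for c in cuts if c >= hi]
    if not left_cuts or not right_cuts:
        raise NonClonableError("origin/marker fragment has no flanking cuts")
    a, b = left_cuts[-1], right_cuts[0]
    if b - a > params.circularization_cap_bp:
        raise NonClonableError("fragment exceeds the intramolecular-ligation cap")
    # origin and marker must sit on the same fragment (no cut between them)
    inner = [c for c in cuts if lo <= c <= hi]
    if inner:
        raise NonClonableError("origin and marker separated by the digest")

    circle = NucSequence(f"{integrated.mutant_id or 'mutant'}|cloned_flank", integrated.mutated.bases[a:b], Topology.circular)
    genomic = [
        s for s in integrated.segments_overlapping(a, b) if s.kind == "genome"
    ]
    if not genomic:
        return circle, MappingResult(Method.lox_cloning, Outcome.vector_only)
    interval = _genomic_interval(integrated, a, b, params)
    return circle, MappingResult(
        Method.lox_cloning,
        Outcome.genomic_junction,
        chromosome=integrated.chromosome,
        interval=interval,
        resolution=Resolution.bounded_by_site,
        note="flank bounded by the nearest SpeI/XbaI cut",
    )
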