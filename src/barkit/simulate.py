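"""Synthetic genomes, mutant libraries, reads and selection draws.

Everything downstream is testable against these generators without any
download.  The toy genome reproduces, at desk scale, the statistics the
library-design formulas use: three nuclear chromosomes plus one
mitochondrial contig, ~57% of the nuclear genome in protein-coding genes
with a ~2 kb mean gene size, and a guaranteed density of the restriction
and degenerate-primer sites the mapping workflows rely on.  Every function
is a pure function of its seed and spec, and each generated mutant carries
a machine-readable truth record; recovery tests read truth only from those
records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cassette import (
    Barcode,
    BarcodeTemplate,
    Cassette,
    CassetteSpec,
    assemble_cassette,
    draw_clone,
    generate_barcode,
    random_dna,
)
from .io import Feature
from .mapping import (
    Cointegrant,
    CopySpec,
    DEFAULT_AD_PRIMERS,
    InsertionStructure,
    MutantGenome,
    Orientation,
    apply_insertion,
)
from .seq import IUPAC_SETS, NucSequence, revcomp
from .seq import _scan as _iupac_scan

__all__ = [
    "ToyGenomeSpec",
    "ToyGenome",
    "StructureMix",
    "make_toy_genome",
    "make_library",
    "simulate_sanger_read",
    "simulate_selection",
]


@dataclass(frozen=True)
class ToyGenomeSpec:
    n_nuclear: int = 3
    chrom_length: int = 120_000
    mito_length: int = 20_000
    coding_fraction: float = 0.57
    gene_length_mean: float = 2_000.0
    gene_length_sd: float = 400.0
    ncrna_fraction: float = 0.05
    # guaranteed landmark spacing (bp); chance extra sites are left in place
    ecorv_every: int = 3_000
    spei_every: int = 2_400
    xbai_every: int = 2_400
    ad_site_every: int = 1_500
    mito_ad_site_every: int = 1_000  # below the minimum co-integrant span
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.coding_fraction < 1:
            raise ValueError("coding fraction must be in (0, 1)")


@dataclass
class ToyGenome:
    contigs: dict[str, NucSequence]
    features: list[Feature]
    mito_id: str
    spec: ToyGenomeSpec

    @property
    def nuclear_ids(self) -> list[str]:
        return [c for c in self.contigs if c != self.mito_id]

    def coding_fraction(self) -> float:
        nuc = sum(len(self.contigs[c]) for c in self.nuclear_ids)
        coding = sum(
            f.end - f.start for f in self.features if f.type == "gene" and f.contig != self.mito_id
        )
        return coding / nuc


def _concrete_instance(rng: np.random.Generator, pattern: str) -> str:
    out = []
    for c in pattern:
        opts = sorted(IUPAC_SETS[c] - {"N"}) or list("ACGT")
        if c == "N":
            opts = list("ACGT")
        out.append(opts[int(rng.integers(0, len(opts)))])
    return "".join(out)


def _plant(bases: list[str], pos: int, motif: str) -> None:
    if 0 <= pos and pos + len(motif) <= len(bases):
        bases[pos : pos + len(motif)] = list(motif)


def _scrub_sfi(rng: np.random.Generator, bases: list[str]) -> None:
    # SfiI sites in the genome would confuse the inverse-splinkerette
    # circle; mutate one constant base of any chance occurrence
    while True:
        hits = _iupac_scan("".join(bases), "GGCCNNNNNGGCC")
        if not hits:
            return
        for h in hits:
            i = h + int(rng.choice([0, 1, 2, 3, 9, 10, 11, 12]))
            cur = bases[i]
            bases[i] = "ACGT"[("ACGT".index(cur) + 1 + int(rng.integers(0, 3))) % 4]


def _make_contig(
    rng: np.random.Generator, name: str, length: int, spec: ToyGenomeSpec, ad_every: int | None = None
) -> NucSequence:
    bases = list(random_dna(rng, length))
    # deterministic landmark grid with per-contig phase jitter
    for every, motif_fn in (
        (spec.ecorv_every, lambda: "GATATC"),
        (spec.spei_every, lambda: "ACTAGT"),
        (spec.xbai_every, lambda: "TCTAGA"),
    ):
        phase = int(rng.integers(200, every))
        for p in range(phase, length - 20, every):
            _plant(bases, p, motif_fn())
    # planted degenerate-primer sites, both orientations side by side so a
    # facing partner exists within one grid spacing of any point
    ad_every = ad_every or spec.ad_site_every
    phase = int(rng.integers(200, ad_every))
    for p in range(phase, length - 60, ad_every):
        pat = DEFAULT_AD_PRIMERS[int(rng.integers(0, len(DEFAULT_AD_PRIMERS)))]
        inst = _concrete_instance(rng, pat)
        _plant(bases, p, inst)
        _plant(bases, p + len(inst) + 4, revcomp(inst))
    _scrub_sfi(rng, bases)
    return NucSequence(name, "".join(bases))


def _tile_genes(
    rng: np.random.Generator, contig: str, length: int, spec: ToyGenomeSpec, start_index: int
) -> list[Feature]:
    c = spec.coding_fraction
    gap_mean = spec.gene_length_mean * (1 - c) / c
    feats: list[Feature] = []
    pos = max(50, int(rng.normal(gap_mean / 2, gap_mean / 6)))
    i = start_index
    while True:
        glen = int(np.clip(rng.normal(spec.gene_length_mean, spec.gene_length_sd), 500, 4000))
        if pos + glen > length - 50:
            break
        is_nc = rng.random() < spec.ncrna_fraction
        ftype = "ncRNA_gene" if is_nc else "gene"
        strand = "+" if rng.random() < 0.5 else "-"
        feats.append(Feature(contig, pos, pos + glen, ftype, f"{ftype}_{i:05d}", strand))
        i += 1
        gap = int(np.clip(rng.normal(gap_mean, gap_mean / 4), 150, 6000))
        pos += glen + gap
    return feats


def make_toy_genome(spec: ToyGenomeSpec = ToyGenomeSpec()) -> ToyGenome:
    """Deterministic toy genome: nuclear chromosomes + mitochondrial contig.

    Gene features are tiled to hit the coding-fraction target (re-tiled with
    a derived seed if the realized fraction drifts outside +-0.03); landmark
    restriction/primer sites are planted on a jittered grid so every mapping
    workflow has a reachable site near any insertion point.
    """
    for attempt in range(20):
        rng = np.random.default_rng((spec.rng_seed, attempt))
        contigs: dict[str, NucSequence] = {}
        feats: list[Feature] = []
        idx = 0
        for k in range(spec.n_nuclear):
            name = f"chr{k + 1}"
            contigs[name] = _make_contig(rng, name, spec.chrom_length, spec)
            new = _tile_genes(rng, name, spec.chrom_length, spec, idx)
            idx += len(new)
            feats.extend(new)
        mito = "mito"
        contigs[mito] = _make_contig(rng, mito, spec.mito_length, spec, ad_every=spec.mito_ad_site_every)
        genome = ToyGenome(contigs, feats, mito, spec)
        if abs(genome.coding_fraction() - spec.coding_fraction) <= 0.03:
            return genome
    raise RuntimeError("could not realize the coding-fraction target")


@dataclass(frozen=True)
class StructureMix:
    """Probabilities of the observed insertion-structure classes.

    Defaults reflect that tandem arrays dominated the fully characterized
    alleles, with head-to-head/tail-to-tail junctions and mitochondrial
    co-integration as recurrent minority classes.
    """

    single: float = 0.15
    tandem_head_to_tail: float = 0.55
    head_to_head: float = 0.075
    tail_to_tail: float = 0.075
    mito_cointegrant: float = 0.15

    def __post_init__(self) -> None:
        if abs(sum(self.as_dict().values()) - 1.0) > 1e-9:
            raise ValueError("structure mix must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "single": self.single,
            "tandem_head_to_tail": self.tandem_head_to_tail,
            "head_to_head": self.head_to_head,
            "tail_to_tail": self.tail_to_tail,
            "mito_cointegrant": self.mito_cointegrant,
        }


def _draw_trim(rng: np.random.Generator, modest: bool = False) -> int:
    """Vector-end resection: mostly tens of bp, occasionally up to 1.8 kb."""
    if modest or rng.random() < 0.85:
        return int(rng.integers(5, 61))
    return int(rng.integers(61, 1801))


def _draw_marker_left_trim(rng: np.random.Generator) -> int:
    """Buffer-end resection of the copy that must keep a working marker:
    may eat deep into the buffer/promoter (degrading mappability) but stops
    short of the ura4 stand-in."""
    if rng.random() < 0.85:
        return int(rng.integers(5, 61))
    return int(rng.integers(61, 551))


def _draw_structure(
    rng: np.random.Generator, mix: StructureMix, mito_id: str, mito_len: int, cas_len: int = 2100
) -> InsertionStructure:
    classes = list(mix.as_dict().items())
    names = [n for n, _ in classes]
    probs = np.array([p for _, p in classes])
    cls = names[int(rng.choice(len(names), p=probs))]
    F, R = Orientation.forward, Orientation.reverse
    deletion = int(rng.integers(0, 6))

    def copy(orient, modest_left=False, modest_right=False):
        left = _draw_trim(rng, modest_left)
        right = min(_draw_trim(rng, modest_right), cas_len - left - 200)
        return CopySpec(orient, left, right)

    def marker_copy(orient):
        return CopySpec(orient, _draw_marker_left_trim(rng), _draw_trim(rng, True))

    if cls == "single":
        # resection of the marker end is lethal under selection, resection
        # of the buffer end is not -- it only degrades mappability
        return InsertionStructure((marker_copy(F),), None, deletion)
    if cls == "tandem_head_to_tail":
        k = int(rng.integers(2, 5))
        copies = tuple(
            marker_copy(F) if i == k - 1 else copy(F) for i in range(k)
        )
        return InsertionStructure(copies, None, deletion)
    if cls == "head_to_head":
        return InsertionStructure(
            (copy(R, True, True), copy(F, True, True)), None, deletion
        )
    if cls == "tail_to_tail":
        return InsertionStructure(
            (copy(F, True, True), copy(R, True, True)), None, deletion
        )
    # mitochondrial co-integrant 5' of a single copy
    span = int(rng.integers(1200, 2501))
    start = int(rng.integers(0, mito_len - span))
    return InsertionStructure(
        (copy(F, True, True),), Cointegrant(mito_id, start, start + span), deletion
    )


def make_library(
    genome: ToyGenome,
    n_mutants: int,
    rng_seed: int,
    structure_mix: StructureMix = StructureMix(),
    spec: CassetteSpec = CassetteSpec(),
    backbone_seed: int = 7,
    edge_margin: int = 6_000,
) -> list[MutantGenome]:
    """Simulate a barcode-tagged insertion mutant library.

    Insertion positions are uniform over the nuclear chromosomes (clear of
    contig edges), structures are drawn from ``structure_mix``, and each
    mutant receives a fresh barcode on a shared cassette backbone
    (``backbone_seed`` fixes the constant elements across the library, as
    one vector preparation would).
    """
    rng = np.random.default_rng(rng_seed)
    mito_len = len(genome.contigs[genome.mito_id])
    backbone = assemble_cassette(
        spec, generate_barcode(spec.template, 0), backbone_seed, extra_forbidden=DEFAULT_AD_PRIMERS
    )
    out: list[MutantGenome] = []
    for i in range(n_mutants):
        cassette = draw_clone(backbone, rng)
        chrom = genome.nuclear_ids[int(rng.integers(0, len(genome.nuclear_ids)))]
        L = len(genome.contigs[chrom])
        pos = int(rng.integers(edge_margin, L - edge_margin))
        structure = _draw_structure(
            rng, structure_mix, genome.mito_id, mito_len, len(backbone.seq)
        )
        out.append(
            apply_insertion(
                genome.contigs, chrom, pos, structure, cassette, mutant_id=f"mut_{i:04d}"
            )
        )
    return out


def simulate_sanger_read(
    seq: NucSequence,
    sub_rate: float,
    max_len: int = 900,
    rng_seed: int | np.random.Generator = 0,
) -> NucSequence:
    """Substitution-only Sanger-like read: truncate at ``max_len``, then
    apply i.i.d. substitutions at ``sub_rate``."""
    if not 0 <= sub_rate < 1:
        raise ValueError("sub_rate must be in [0, 1)")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    bases = list(seq.bases[:max_len])
    if sub_rate > 0:
        hits = np.nonzero(rng.random(len(bases)) < sub_rate)[0]
        for i in hits:
            cur = bases[i]
            if cur in "ACGT":
                bases[i] = "ACGT"[("ACGT".index(cur) + 1 + int(rng.integers(0, 3))) % 4]
    return NucSequence(f"{seq.id}|read", "".join(bases))


def simulate_selection(
    n_transformants: int, p_stable: float, rng_seed: int | np.random.Generator = 0
) -> tuple[int, int]:
    """Binomial split of transformants into stable integrants vs cells
    carrying the marker on unstable extrachromosomal circles."""
    if not 0 <= p_stable <= 1:
        raise ValueError("p_stable must be in [0, 1]")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    stable = int(rng.binomial(n_transformants, p_stable))
    return stable, n_transformants - stable
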