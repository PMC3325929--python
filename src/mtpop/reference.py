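"""Reference mitochondrial genome model.

Coordinates are 1-based and inclusive throughout, in the numbering frame of
the revised Cambridge Reference Sequence (rCRS, 16,569 bp) — the frame in
which mtDNA variants are conventionally reported.  The module provides

* :class:`MitoReference` — circular genome with gene annotation and the
  vertebrate mitochondrial genetic code;
* :class:`Variant` plus :func:`parse_variant_label` / :func:`format_variant`
  for the standard label dialects (``m.1806T>C``, ``3909T``, ``4769!``,
  ``m.16295C insA``, ``8281-8289d``);
* coordinate arithmetic (:func:`locate_feature`, :func:`codon_position`) and
  coding-effect annotation (:func:`annotate_effect`);
* :func:`apply_profile` to realise a sample sequence from a variant profile.

The actual rCRS base string is not bundled; a sparse ``known_bases`` map
carries the reference alleles needed by the bundled datasets, and any
operation that needs full base information accepts a user-supplied sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable
from Bio.SeqUtils import seq3

from .errors import (
    MissingSequenceError,
    PositionRangeError,
    ProfileConflictError,
    VariantParseError,
)

#: NCBI translation table 2, the vertebrate mitochondrial code.
VERTEBRATE_MITO_CODE = CodonTable.unambiguous_dna_by_id[2]

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"

_HEAVY = "heavy"
_LIGHT = "light"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneFeature:
    """An annotated feature on the circular genome.

    ``start <= end`` unless the feature wraps the origin (the control
    region).  Protein features span a whole number of codons unless
    ``incomplete_stop`` flags the conventional polyadenylation-completed
    stop codon.
    """

    name: str
    start: int
    end: int
    strand: str = _HEAVY  # "heavy" | "light"
    kind: str = "protein"  # "protein" | "rRNA" | "tRNA" | "control"
    incomplete_stop: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise PositionRangeError(f"{self.name}: coordinates must be >= 1")
        if self.strand not in (_HEAVY, _LIGHT):
            raise ValueError(f"{self.name}: strand must be 'heavy' or 'light'")

    @property
    def wraps_origin(self) -> bool:
        return self.end < self.start

    def span(self, genome_length: int) -> int:
        if self.wraps_origin:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        if self.wraps_origin:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end

    def n_complete_codons(self, genome_length: int) -> int:
        return self.span(genome_length) // 3


@dataclass(frozen=True)
class Variant:
    """One difference from the reference, in 1-based reference coordinates.

    ``ref`` is empty for insertions (the inserted bases anchor *after*
    ``position``); ``alt`` is empty for deletions, whose extent is
    ``len(ref)`` bases starting at ``position``.  A ``back_mutation`` entry
    asserts the reference-state allele at a site where the haplotype
    background carries a derived allele (phylotree "!" notation); its
    ``alt`` equals the reference base where known.
    """

    position: int
    kind: str = SUBSTITUTION
    ref: str = "N"
    alt: str = "N"
    back_mutation: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise PositionRangeError(f"variant position {self.position} must be >= 1")
        if self.kind not in (SUBSTITUTION, INSERTION, DELETION):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.kind == SUBSTITUTION:
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise ValueError("substitution requires single ref and alt bases")
            if not self.back_mutation and self.ref == self.alt and self.ref != "N":
                raise ValueError("substitution ref and alt must differ")
        elif self.kind == INSERTION:
            if not self.alt:
                raise ValueError("insertion requires at least one inserted base")
            if self.ref:
                raise ValueError("insertion ref allele must be empty")
        elif self.kind == DELETION:
            if not self.ref:
                raise ValueError("deletion must span at least one base")
            if self.alt:
                raise ValueError("deletion alt allele must be empty")

    @property
    def end(self) -> int:
        """Last reference position affected (== position except deletions)."""
        if self.kind == DELETION:
            return self.position + len(self.ref) - 1
        return self.position

    def site_key(self) -> tuple:
        """Identity key used when asking whether two samples share a site."""
        if self.kind == SUBSTITUTION:
            return (self.position, SUBSTITUTION, self.alt)
        if self.kind == INSERTION:
            return (self.position, INSERTION, self.alt)
        return (self.position, DELETION, len(self.ref))


@dataclass(frozen=True)
class CodingEffect:
    """Predicted effect of a variant at the protein level."""

    gene: str  # gene name, "control", or "intergenic"
    protein_position: int | None = None
    codon_offset: int | None = None
    effect: str = "not_applicable"  # synonymous | nonsynonymous | not_applicable
    aa_change: str | None = None  # e.g. "Pro17Ser"
    note: str = ""


@dataclass(frozen=True)
class MitoReference:
    """Circular reference genome with annotation.

    ``sequence`` is optional; when absent, ``known_bases`` (a sparse
    position→base map) still allows label parsing and orientation checks at
    catalogued sites.
    """

    id: str = "rCRS"
    length: int = 16569
    sequence: str | None = None
    genes: tuple[GeneFeature, ...] = ()
    known_bases: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("reference length must be positive")
        if self.sequence is not None:
            object.__setattr__(self, "sequence", self.sequence.upper())
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"sequence length {len(self.sequence)} != declared {self.length}"
                )
        for g in self.genes:
            if g.start > self.length or g.end > self.length:
                raise PositionRangeError(f"{g.name} exceeds genome length {self.length}")
            if g.kind == "protein" and not g.incomplete_stop:
                if g.span(self.length) % 3:
                    raise ValueError(
                        f"protein gene {g.name} span not divisible by 3 "
                        "and not flagged incomplete_stop"
                    )

    def check_position(self, position: int) -> None:
        if not 1 <= position <= self.length:
            raise PositionRangeError(
                f"position {position} outside [1, {self.length}]"
            )

    def base_at(self, position: int) -> str | None:
        """Reference base, from the full sequence or the sparse known-base map."""
        self.check_position(position)
        if self.sequence is not None:
            return self.sequence[position - 1]
        return dict(self.known_bases).get(position)

    def gene(self, name: str) -> GeneFeature:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)


# ---------------------------------------------------------------------------
# bundled rCRS annotation
# ---------------------------------------------------------------------------

# Standard rCRS heavy-strand gene map.  Genes whose reading frame ends in a
# polyadenylation-completed stop codon are flagged incomplete_stop.
RCRS_GENES: tuple[GeneFeature, ...] = (
    GeneFeature("12SrRNA", 648, 1601, _HEAVY, "rRNA"),
    GeneFeature("16SrRNA", 1671, 3229, _HEAVY, "rRNA"),
    GeneFeature("ND1", 3307, 4262, _HEAVY, "protein", incomplete_stop=True),
    GeneFeature("ND2", 4470, 5511, _HEAVY, "protein", incomplete_stop=True),
    GeneFeature("COI", 5904, 7445, _HEAVY, "protein"),
    GeneFeature("COII", 7586, 8269, _HEAVY, "protein"),
    GeneFeature("ATP8", 8366, 8572, _HEAVY, "protein"),
    GeneFeature("ATP6", 8527, 9207, _HEAVY, "protein"),
    GeneFeature("COIII", 9207, 9990, _HEAVY, "protein", incomplete_stop=True),
    GeneFeature("ND3", 10059, 10404, _HEAVY, "protein", incomplete_stop=True),
    GeneFeature("ND4L", 10470, 10766, _HEAVY, "protein"),
    GeneFeature("ND4", 10760, 12137, _HEAVY, "protein", incomplete_stop=True),
    GeneFeature("ND5", 12337, 14148, _HEAVY, "protein"),
    GeneFeature("ND6", 14149, 14673, _LIGHT, "protein"),
    GeneFeature("CYTB", 14747, 15887, _HEAVY, "protein", incomplete_stop=True),
    GeneFeature("control", 16024, 576, _HEAVY, "control"),
    GeneFeature("HVRI", 16024, 16383, _HEAVY, "control"),
    GeneFeature("HVRII", 57, 372, _HEAVY, "control"),
)

# In overlapping protein pairs (ATP8/ATP6, ND4L/ND4, ATP6/COIII boundary) the
# primary gene is the reading frame conventionally reported for variants in
# the overlap.
_PRIMARY_OVERLAP_GENES = frozenset({"ATP6", "ND4"})

# rCRS alleles at the positions catalogued in the bundled datasets.
RCRS_KNOWN_BASES: dict[int, str] = {
    73: "A", 146: "T", 151: "C", 263: "A", 750: "A", 1185: "C", 1438: "A",
    1692: "A", 1806: "T", 2416: "T", 2706: "A", 3909: "C", 4769: "A",
    5465: "T", 6261: "G", 6719: "T", 6782: "T", 6905: "A", 7028: "C",
    8860: "A", 8865: "G", 9123: "G", 9145: "G", 9255: "C", 9722: "T",
    10238: "T", 11719: "G", 14022: "A", 14766: "C", 15014: "T", 15746: "A",
    16126: "T", 16189: "T", 16217: "T", 16247: "A", 16261: "C", 16295: "C",
}


def rcrs(sequence: str | None = None) -> MitoReference:
    """The bundled rCRS coordinate model (optionally with a full sequence)."""
    return MitoReference(
        id="rCRS",
        length=16569,
        sequence=sequence,
        genes=RCRS_GENES,
        known_bases=dict(RCRS_KNOWN_BASES),
    )


def load_gene_table(path, zero_based: bool = False) -> tuple[GeneFeature, ...]:
    """Read a gene annotation override from a BED-like tab file.

    Columns: name, start, end, strand(heavy|light), kind; 1-based inclusive
    by default, 0-based half-open with ``zero_based=True``.
    """
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("name\t"):
                continue
            name, start, end, strand, kind = line.split("\t")[:5]
            s, e = int(start), int(end)
            if zero_based:
                s += 1
            incomplete = kind == "protein" and (e - s + 1) % 3 != 0 and e >= s
            feats.append(GeneFeature(name, s, e, strand, kind, incomplete_stop=incomplete))
    return tuple(feats)


# ---------------------------------------------------------------------------
# variant labels
# ---------------------------------------------------------------------------

_RE_SUB = re.compile(r"^(?:m\.)?(\d+)([ACGTN])>([ACGTN])$")
_RE_SHORT = re.compile(r"^(\d+)([ACGT])$")
_RE_BACK = re.compile(r"^(?:m\.)?(\d+)!$")
_RE_INS = re.compile(r"^(?:m\.)?(\d+)([ACGT])?\s*ins([ACGT]+)$")
_RE_DEL = re.compile(r"^(?:m\.)?(\d+)(?:-(\d+))?d(?:el)?$")


def parse_variant_label(label: str, reference: MitoReference | None = None) -> Variant:
    """Parse a variant label in any supported dialect into a :class:`Variant`.

    Supported forms: ``m.1806T>C`` / ``1806T>C``, shorthand ``3909T``,
    reference-state assertion ``4769!``, ``m.16295C insA`` / ``16295insA``,
    and ``8281-8289d``.  When ``reference`` is given, unknown ref alleles
    are filled in from it and positions are range-checked.
    """
    token = label.strip()
    if not token:
        raise VariantParseError("empty variant label")

    def _check(pos: int) -> int:
        if pos < 1:
            raise VariantParseError(f"position out of range in {token!r}")
        if reference is not None:
            try:
                reference.check_position(pos)
            except PositionRangeError as exc:
                raise VariantParseError(f"position out of range in {token!r}") from exc
        return pos

    m = _RE_SUB.match(token)
    if m:
        pos = _check(int(m.group(1)))
        ref_base, alt = m.group(2), m.group(3)
        if reference is not None:
            known = reference.base_at(pos)
            if known is not None and ref_base == "N":
                ref_base = known
        if ref_base == alt and ref_base != "N":
            raise VariantParseError(f"ref and alt identical in {token!r}")
        return Variant(pos, SUBSTITUTION, ref_base, alt)

    m = _RE_SHORT.match(token)
    if m:
        pos = _check(int(m.group(1)))
        alt = m.group(2)
        ref_base = "N"
        if reference is not None:
            known = reference.base_at(pos)
            if known is not None:
                ref_base = known
        if ref_base == alt:
            raise VariantParseError(
                f"shorthand {token!r} names the reference allele; use '{pos}!'"
            )
        return Variant(pos, SUBSTITUTION, ref_base, alt)

    m = _RE_BACK.match(token)
    if m:
        pos = _check(int(m.group(1)))
        base = reference.base_at(pos) if reference is not None else None
        allele = base if base is not None else "N"
        return Variant(pos, SUBSTITUTION, ref=allele, alt=allele, back_mutation=True)

    m = _RE_INS.match(token)
    if m:
        pos = _check(int(m.group(1)))
        anchor, inserted = m.group(2), m.group(3)
        if reference is not None and anchor is not None:
            known = reference.base_at(pos)
            if known is not None and known != anchor:
                raise VariantParseError(
                    f"anchor base {anchor} in {token!r} does not match reference {known}"
                )
        return Variant(pos, INSERTION, ref="", alt=inserted)

    m = _RE_DEL.match(token)
    if m:
        start = _check(int(m.group(1)))
        end = _check(int(m.group(2))) if m.group(2) else start
        if end < start:
            raise VariantParseError(f"deletion end before start in {token!r}")
        span = end - start + 1
        if reference is not None and reference.sequence is not None:
            deleted = reference.sequence[start - 1 : end]
        else:
            deleted = "N" * span
        return Variant(start, DELETION, ref=deleted, alt="")

    raise VariantParseError(f"unrecognised variant label {token!r}")


def format_variant(variant: Variant) -> str:
    """Canonical label for a variant (round-trips through the parser)."""
    if variant.back_mutation:
        return f"{variant.position}!"
    if variant.kind == SUBSTITUTION:
        return f"m.{variant.position}{variant.ref}>{variant.alt}"
    if variant.kind == INSERTION:
        return f"m.{variant.position}ins{variant.alt}"
    return f"{variant.position}-{variant.end}d"


# ---------------------------------------------------------------------------
# coordinate arithmetic and annotation
# ---------------------------------------------------------------------------


def locate_all_features(ref: MitoReference, position: int) -> tuple[GeneFeature, ...]:
    """All features containing ``position``, primary first.

    Primary ranking: the conventionally reported reading frame for protein
    overlaps (ATP6, ND4), then the most specific (shortest) feature.
    """
    ref.check_position(position)
    hits = [g for g in ref.genes if g.contains(position)]
    hits.sort(
        key=lambda g: (
            g.name not in _PRIMARY_OVERLAP_GENES,
            g.span(ref.length),
            g.start,
        )
    )
    return tuple(hits)


def locate_feature(ref: MitoReference, position: int) -> GeneFeature | None:
    """Primary feature at ``position``, or None for intergenic sites."""
    hits = locate_all_features(ref, position)
    return hits[0] if hits else None


def codon_position(
    ref: MitoReference, gene: GeneFeature, position: int
) -> tuple[int, int]:
    """(protein_position, codon_offset) of a site inside a protein gene.

    Heavy strand: codon index = floor((position - start)/3) + 1, offset =
    (position - start) mod 3.  Light strand (ND6): the same arithmetic on the
    reverse-complement frame, counting from ``gene.end`` downward.
    """
    if gene.kind != "protein":
        raise ValueError(f"{gene.name} is not a protein gene")
    if not gene.contains(position):
        raise PositionRangeError(f"position {position} outside {gene.name}")
    if gene.strand == _HEAVY:
        offset_from_start = position - gene.start
        if offset_from_start < 0:  # wrapped feature
            offset_from_start += ref.length
    else:
        offset_from_start = gene.end - position
        if offset_from_start < 0:
            offset_from_start += ref.length
    return offset_from_start // 3 + 1, offset_from_start % 3


def position_from_codon(
    ref: MitoReference, gene: GeneFeature, protein_position: int, codon_offset: int
) -> int:
    """Inverse of :func:`codon_position` (codon arithmetic is a bijection)."""
    if not 1 <= protein_position or codon_offset not in (0, 1, 2):
        raise ValueError("invalid codon coordinates")
    offset_from_start = 3 * (protein_position - 1) + codon_offset
    if gene.strand == _HEAVY:
        pos = gene.start + offset_from_start
    else:
        pos = gene.end - offset_from_start
    pos = (pos - 1) % ref.length + 1
    if not gene.contains(pos):
        raise PositionRangeError(
            f"codon ({protein_position},{codon_offset}) outside {gene.name}"
        )
    return pos


def translate_codon(codon: str) -> str:
    """Single-letter amino acid under the vertebrate mitochondrial code."""
    codon = codon.upper()
    if codon in VERTEBRATE_MITO_CODE.stop_codons:
        return "*"
    return VERTEBRATE_MITO_CODE.forward_table[codon]


def _codon_bases(ref: MitoReference, gene: GeneFeature, protein_position: int) -> str:
    """Reference codon (coding-strand orientation) at a codon index."""
    if ref.sequence is None:
        raise MissingSequenceError(
            "reference sequence required for codon translation"
        )
    bases = []
    for off in range(3):
        pos = position_from_codon(ref, gene, protein_position, off)
        bases.append(ref.sequence[pos - 1])
    codon = "".join(bases)
    if gene.strand == _LIGHT:
        # position_from_codon already walks 5'→3' on the light strand; the
        # collected bases are heavy-strand, so complement them.
        codon = codon.translate(_COMPLEMENT)
    return codon


def annotate_effect(ref: MitoReference, variant: Variant) -> CodingEffect:
    """Classify a variant's coding effect against the reference.

    Substitutions in protein genes are translated with the vertebrate
    mitochondrial code; rRNA/tRNA/control and intergenic sites yield
    ``not_applicable``; indels yield ``not_applicable`` with a length-change
    note.  Requires ``ref.sequence`` for the synonymous/non-synonymous call.
    """
    feature = locate_feature(ref, variant.position)
    gene_name = feature.name if feature is not None else "intergenic"
    if variant.kind != SUBSTITUTION:
        delta = len(variant.alt) - len(variant.ref)
        return CodingEffect(
            gene=gene_name, effect="not_applicable", note=f"length change {delta:+d}"
        )
    if feature is None or feature.kind != "protein":
        return CodingEffect(gene=gene_name, effect="not_applicable")

    prot_pos, offset = codon_position(ref, feature, variant.position)
    if prot_pos > feature.n_complete_codons(ref.length):
        return CodingEffect(
            gene=gene_name,
            protein_position=prot_pos,
            codon_offset=offset,
            effect="not_applicable",
            note="incomplete terminal codon",
        )
    if variant.back_mutation or variant.alt == ref.base_at(variant.position):
        return CodingEffect(
            gene=gene_name,
            protein_position=prot_pos,
            codon_offset=offset,
            effect="synonymous",
            note="reference-state assertion",
        )

    ref_codon = _codon_bases(ref, feature, prot_pos)
    alt_base = variant.alt
    if feature.strand == _LIGHT:
        alt_base = alt_base.translate(_COMPLEMENT)
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    aa_ref = translate_codon(ref_codon)
    aa_alt = translate_codon(alt_codon)
    if aa_ref == aa_alt:
        return CodingEffect(
            gene=gene_name,
            protein_position=prot_pos,
            codon_offset=offset,
            effect="synonymous",
        )
    change = f"{seq3(aa_ref)}{prot_pos}{seq3(aa_alt)}" if "*" not in (aa_ref, aa_alt) else (
        f"{aa_ref}{prot_pos}{aa_alt}"
    )
    return CodingEffect(
        gene=gene_name,
        protein_position=prot_pos,
        codon_offset=offset,
        effect="nonsynonymous",
        aa_change=change,
    )


# ---------------------------------------------------------------------------
# sequence realisation
# ---------------------------------------------------------------------------


def apply_profile(ref: MitoReference, variants: Iterable[Variant]) -> str:
    """Realise a sample sequence by applying variants to the reference.

    Variants must not collide (overlapping affected ranges).  Indels shift
    the output length; the reference is unchanged.  Back-mutation entries
    assert the reference allele and leave the sequence untouched.
    """
    if ref.sequence is None:
        raise MissingSequenceError("reference sequence required to apply a profile")
    ordered = sorted(variants, key=lambda v: (v.position, v.kind))
    occupied: list[tuple[int, int, Variant]] = []
    for v in ordered:
        ref.check_position(v.position)
        if v.end > ref.length:
            raise PositionRangeError(f"variant at {v.position} extends past genome end")
        for s, e, other in occupied:
            if v.kind == INSERTION and other.kind == INSERTION and v.position == other.position:
                pass  # two insertions at one anchor collide
            elif v.kind == INSERTION or other.kind == INSERTION:
                continue  # an insertion between bases never collides with a site change
            if not (v.end < s or v.position > e):
                raise ProfileConflictError(
                    f"variants collide at positions {v.position} and {other.position}"
                )
        occupied.append((v.position, v.end, v))

    seq = list(ref.sequence)
    for v in sorted(ordered, key=lambda v: v.position, reverse=True):
        if v.back_mutation:
            continue
        if v.kind == SUBSTITUTION:
            if v.ref not in ("N", seq[v.position - 1]):
                raise ProfileConflictError(
                    f"ref allele mismatch at {v.position}: profile says {v.ref}, "
                    f"reference has {seq[v.position - 1]}"
                )
            seq[v.position - 1] = v.alt
        elif v.kind == DELETION:
            del seq[v.position - 1 : v.position - 1 + len(v.ref)]
        else:  # insertion anchors after position
            seq[v.position : v.position] = list(v.alt)
    return "".join(seq)
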