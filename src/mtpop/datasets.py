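"""Bundled example data: the published 20-genome Māori mtDNA survey.

The cohort is distributed here as per-sample variant states at the 23
coding-region and HVRII positions of the published variation matrix (the
per-sample placement of HVRI singletons was never printed, so the bundled
profiles cover exactly the printed panel).  All coordinates are rCRS,
1-based; ``.`` cells mean the sample carries the reference allele.
"""

from __future__ import annotations

from .calling import SampleSet, VariantProfile
from .motifs import MotifDefinition, default_motif_table
from .populations import FrequencyQuery
from .reference import SUBSTITUTION, MitoReference, Variant, rcrs

#: Panel positions of the published variation matrix (coding + HVRII).
COHORT_POSITIONS: tuple[int, ...] = (
    73, 146, 151, 263, 750, 1185, 1438, 1692, 1806, 2416, 2706, 3909,
    4769, 5465, 6261, 6719, 6782, 6905, 7028, 8860, 8865, 9123, 9145,
)

#: rCRS alleles at the panel positions.
_CRS_ROW = "ATCAACAATTACATGTTACAGGG"

#: Per-sample states; "." = reference allele at that column.
_COHORT_ROWS: dict[str, str] = {
    "mt3":  "GC.GGTG...G..C.C..TG.A.",
    "mt6":  "GC.GG.G...G.GC.C..TG.A.",
    "mt8":  "GC.GGTG...G..C.C..TG.A.",
    "mt9":  "GC.GG.G...GTGC.C..TG.A.",
    "mt10": "GCTGG.GG.CG.GC.C..TG.A.",
    "mt11": "GC.GG.G...G.GC.C..TGAA.",
    "mt12": "GC.GG.G...G.GC.C..TGAA.",
    "mt13": "GC.GGTG...G..C.C..TG.A.",
    "mt14": "GC.GGTG...G..C.C..TG.A.",
    "mt16": "GC.GG.G...G.GC.C..TG.A.",
    "mt18": "GC.GG.G...G.GCAC.GTG.AA",
    "mt19": "GC.GG.G...GTGCAC..TG.A.",
    "mt21": "GC.GG.G...GTGC.C..TG.A.",
    "mt23": "GC.GG.G...G.GC.C..TG.A.",
    "mt24": "GC.GG.G...G.GC.C..TG.A.",
    "mt25": "GC.GGTG...G..C.C..TG.A.",
    "mt26": "GC.GG.G...G.GC.CC.TG.A.",
    "mt28": "GC.GGTG...G..C.C..TG.A.",
    "mt29": "GC.GGTG.CCG..C.C..TG.A.",
    "mt30": "GCTGG.GG..G.GC.C..TG.A.",
}

#: Rare-allele frequency labels (major allele, position, counted allele)
#: restricted to panel positions, so every frequency is recomputable from
#: the bundled profiles.
CODING_VARIANT_QUERIES: tuple[str, ...] = (
    "C3909T",
    "G4769A",
    "T5465C",
    "G6261A",
    "T6719C",
    "T6782C",
    "A6905G",
    "C7028T",
    "G8865A",
    "G9123A",
    "G9145A",
)


def maori_reference() -> MitoReference:
    """The rCRS coordinate model used by the bundled cohort."""
    return rcrs()


def maori_cohort(reference: MitoReference | None = None) -> SampleSet:
    """The 20 bundled profiles as a :class:`SampleSet` (population 'Maori')."""
    ref = reference if reference is not None else rcrs()
    profiles = []
    for sid, row in _COHORT_ROWS.items():
        if len(row) != len(COHORT_POSITIONS):
            raise ValueError(f"malformed bundled row for {sid}")
        variants = []
        for pos, crs_base, cell in zip(COHORT_POSITIONS, _CRS_ROW, row):
            if cell == ".":
                continue
            variants.append(Variant(pos, SUBSTITUTION, ref=crs_base, alt=cell))
        profiles.append(VariantProfile(sid, "Maori", tuple(variants)))
    return SampleSet(ref, tuple(profiles), "Maori")


def maori_motifs(reference: MitoReference | None = None) -> list[MotifDefinition]:
    """The bundled B4a1a1 sub-haplotype motif table."""
    return default_motif_table(reference if reference is not None else rcrs())


def maori_frequency_queries() -> list[FrequencyQuery]:
    return [FrequencyQuery.from_label(lab) for lab in CODING_VARIANT_QUERIES]
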