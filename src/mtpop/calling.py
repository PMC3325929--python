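"""Variant calling against the reference and site-spectrum summaries.

Samples are assumed pre-aligned to the reference coordinate frame (equal
length, ``-`` gaps marking deletions; insertions relative to the reference
are represented by gap columns in an optional aligned reference row).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import AlignmentFrameError, ProfileConflictError
from .reference import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    MitoReference,
    Variant,
    format_variant,
    parse_variant_label,
)

VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantProfile:
    """One sample's ordered set of differences from the reference."""

    sample_id: str
    population: str = ""
    variants: tuple[Variant, ...] = ()

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.variants, key=lambda v: (v.position, v.kind, v.alt)))
        object.__setattr__(self, "variants", ordered)
        sub_positions = [v.position for v in ordered if v.kind == SUBSTITUTION]
        dupes = [p for p, c in Counter(sub_positions).items() if c > 1]
        if dupes:
            raise ProfileConflictError(
                f"{self.sample_id}: duplicate substitution positions {sorted(dupes)}"
            )

    def substitutions(self, include_back_mutations: bool = False) -> dict[int, str]:
        """position → alt allele for substitution entries."""
        return {
            v.position: v.alt
            for v in self.variants
            if v.kind == SUBSTITUTION and (include_back_mutations or not v.back_mutation)
        }

    def variant_at(self, position: int) -> Variant | None:
        for v in self.variants:
            if v.position == position:
                return v
        return None

    def haplotype_key(self) -> frozenset:
        """Sequence-identity key: back-mutation assertions change no base."""
        return frozenset(
            v.site_key() for v in self.variants if not v.back_mutation
        )


@dataclass(frozen=True)
class SampleSet:
    """A cohort of profiles called against one shared reference."""

    reference: MitoReference
    profiles: tuple[VariantProfile, ...]
    population: str = ""

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("a sample set requires at least one profile")

    @property
    def n(self) -> int:
        return len(self.profiles)

    def sample_ids(self) -> tuple[str, ...]:
        return tuple(p.sample_id for p in self.profiles)


@dataclass(frozen=True)
class SiteSpectrum:
    """Carrier counts per variant site, partitioned into fixed/shared/singleton."""

    n_samples: int
    carriers: dict[tuple, int] = field(default_factory=dict)

    @property
    def total_variable_sites(self) -> int:
        return len(self.carriers)

    def _count(self, predicate) -> int:
        return sum(1 for c in self.carriers.values() if predicate(c))

    @property
    def n_fixed(self) -> int:
        return self._count(lambda c: c == self.n_samples)

    @property
    def n_singleton(self) -> int:
        return self._count(lambda c: c == 1)

    @property
    def n_shared(self) -> int:
        return self._count(lambda c: 1 < c < self.n_samples)

    def carriers_at(self, position: int) -> int:
        """Total carriers of derived states at a position (summed over alleles)."""
        return sum(c for key, c in self.carriers.items() if key[0] == position)

    def classify(self, key: tuple) -> str:
        c = self.carriers[key]
        if c == self.n_samples:
            return "fixed"
        return "singleton" if c == 1 else "shared"


def call_variants(
    sample_seq: str,
    ref: MitoReference,
    sample_id: str = "sample",
    population: str = "",
    aligned_reference: str | None = None,
) -> VariantProfile:
    """Derive a variant profile from an aligned sample sequence.

    Every mismatch column becomes a substitution; a run of ``-`` in the
    sample becomes one deletion; a run of ``-`` in ``aligned_reference``
    (when provided) becomes one insertion.  Ambiguity codes (N) yield no
    call.  Raises :class:`AlignmentFrameError` on a frame mismatch.
    """
    if ref.sequence is None and aligned_reference is None:
        raise AlignmentFrameError("reference sequence required to call variants")
    ref_row = aligned_reference if aligned_reference is not None else ref.sequence
    sample_row = sample_seq.upper()
    ref_row = ref_row.upper()
    if len(sample_row) != len(ref_row):
        raise AlignmentFrameError(
            f"sample length {len(sample_row)} != reference frame {len(ref_row)} "
            "and no gaps supplied"
        )
    if len(ref_row.replace("-", "")) != ref.length:
        raise AlignmentFrameError("aligned reference does not match declared length")

    variants: list[Variant] = []
    ref_pos = 0  # 1-based position of the last consumed reference base
    i = 0
    L = len(ref_row)
    while i < L:
        r, s = ref_row[i], sample_row[i]
        if r == "-":  # insertion column(s) relative to the reference
            j = i
            inserted = []
            while j < L and ref_row[j] == "-":
                if sample_row[j] != "-":
                    inserted.append(sample_row[j])
                j += 1
            if inserted and ref_pos >= 1:
                variants.append(
                    Variant(ref_pos, INSERTION, ref="", alt="".join(inserted))
                )
            i = j
            continue
        ref_pos += 1
        if s == "-":  # deletion run in the sample
            j = i
            start = ref_pos
            deleted = []
            while j < L and ref_row[j] != "-" and sample_row[j] == "-":
                deleted.append(ref_row[j])
                j += 1
            variants.append(Variant(start, DELETION, ref="".join(deleted), alt=""))
            ref_pos += len(deleted) - 1
            i = j
            continue
        if s != r and s in VALID_BASES and r in VALID_BASES:
            variants.append(Variant(ref_pos, SUBSTITUTION, ref=r, alt=s))
        i += 1
    return VariantProfile(sample_id, population, tuple(variants))


def call_cohort(
    sequences: dict[str, str], ref: MitoReference, population: str = ""
) -> SampleSet:
    profiles = tuple(
        call_variants(seq, ref, sample_id=sid, population=population)
        for sid, seq in sequences.items()
    )
    return SampleSet(ref, profiles, population)


def site_spectrum(samples: SampleSet) -> SiteSpectrum:
    """Carrier counts per distinct site key across the cohort.

    Counting follows the derived-allele convention: each distinct
    (position, kind, allele) is a site, and back-mutation assertions are not
    derived carriers (e.g. at 4769 the carriers of the non-reference allele
    G are counted; samples asserting the rCRS allele A are not carriers).
    """
    if samples.n < 2:
        raise ValueError("site spectrum requires at least 2 profiles")
    counts: Counter = Counter()
    for profile in samples.profiles:
        for v in profile.variants:
            if v.back_mutation:
                continue
            counts[v.site_key()] += 1
    return SiteSpectrum(n_samples=samples.n, carriers=dict(counts))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

PROFILE_COLUMNS = ["sample_id", "population", "position", "kind", "ref", "alt", "back_mutation"]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def profiles_to_frame(samples: SampleSet) -> pd.DataFrame:
    rows = []
    for p in samples.profiles:
        for v in p.variants:
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "population": p.population or samples.population,
                    "position": v.position,
                    "kind": v.kind,
                    "ref": v.ref,
                    "alt": v.alt,
                    "back_mutation": v.back_mutation,
                }
            )
        if not p.variants:  # keep empty profiles visible in the table
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "population": p.population or samples.population,
                    "position": 0,
                    "kind": "none",
                    "ref": "",
                    "alt": "",
                    "back_mutation": False,
                }
            )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def write_profiles(samples: SampleSet, path) -> None:
    profiles_to_frame(samples).to_csv(path, sep="\t", index=False)


def read_profiles(path, ref: MitoReference) -> list[SampleSet]:
    """Load profile TSVs back into per-population sample sets."""
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    sets: list[SampleSet] = []
    for pop, pop_df in df.groupby("population", sort=False):
        profiles = []
        for sid, sdf in pop_df.groupby("sample_id", sort=False):
            variants = []
            for _, row in sdf.iterrows():
                if row["kind"] == "none":
                    continue
                variants.append(
                    Variant(
                        int(row["position"]),
                        row["kind"],
                        str(row["ref"]),
                        str(row["alt"]),
                        bool(row["back_mutation"]),
                    )
                )
            profiles.append(VariantProfile(str(sid), str(pop), tuple(variants)))
        sets.append(SampleSet(ref, tuple(profiles), str(pop)))
    return sets
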