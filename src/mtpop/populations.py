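"""Cross-population variant frequency tables and novelty screening.

Frequencies follow the rare-allele-versus-rCRS convention of population
mtDNA surveys: each table row names a position and the counted allele
(e.g. ``C7028T`` counts T carriers even though T is the global major
allele; ``G4769A`` counts A carriers — the rCRS allele, rare because the
rCRS itself carries a rare state there).  The novelty screen is a purely
local comparison against a user-supplied catalog snapshot; no live
database queries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .calling import SampleSet, site_spectrum
from .errors import VariantParseError
from .reference import (
    INSERTION,
    SUBSTITUTION,
    MitoReference,
    Variant,
    annotate_effect,
    format_variant,
    locate_feature,
)

_RE_FREQ_LABEL = re.compile(r"^([ACGT])(\d+)([ACGT])$")


@dataclass(frozen=True)
class FrequencyQuery:
    """A (position, counted allele) pair with its display label."""

    position: int
    allele: str
    label: str

    @classmethod
    def from_label(cls, label: str) -> "FrequencyQuery":
        m = _RE_FREQ_LABEL.match(label.strip())
        if not m:
            raise VariantParseError(
                f"frequency label {label!r} must look like C7028T (<major><pos><rare>)"
            )
        return cls(int(m.group(2)), m.group(3), label.strip())


@dataclass(frozen=True)
class VariantCatalog:
    """A local snapshot of known variants, keyed by (position, change)."""

    records: frozenset[tuple[int, str]] = frozenset()
    sources: dict = field(default_factory=dict)

    @staticmethod
    def _key(variant: Variant) -> tuple[int, str]:
        if variant.kind == SUBSTITUTION:
            return (variant.position, variant.alt)
        if variant.kind == INSERTION:
            return (variant.position, f"ins{variant.alt}")
        return (variant.position, f"del{len(variant.ref)}")

    def __contains__(self, variant: Variant) -> bool:
        return self._key(variant) in self.records

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, str]], source: str = "") -> "VariantCatalog":
        recs = frozenset((int(p), str(a)) for p, a in pairs)
        return cls(recs, {r: source for r in recs})

    @classmethod
    def from_variants(cls, variants: Iterable[Variant], source: str = "") -> "VariantCatalog":
        return cls.from_pairs((cls._key(v) for v in variants), source)

    @classmethod
    def from_tsv(cls, path) -> "VariantCatalog":
        df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
        recs = frozenset(
            (int(row["position"]), str(row["alt"])) for _, row in df.iterrows()
        )
        sources = {
            (int(row["position"]), str(row["alt"])): str(row.get("source", ""))
            for _, row in df.iterrows()
        }
        return cls(recs, sources)

    def to_tsv(self, path) -> None:
        rows = [
            {"position": p, "alt": a, "source": self.sources.get((p, a), "")}
            for p, a in sorted(self.records)
        ]
        pd.DataFrame(rows, columns=["position", "alt", "source"]).to_csv(
            path, sep="\t", index=False
        )

    def union(self, other: "VariantCatalog") -> "VariantCatalog":
        return VariantCatalog(self.records | other.records, {**self.sources, **other.sources})


def allele_counts(samples: SampleSet, position: int) -> dict[str, int]:
    """Realised allele counts at one position across a sample set.

    A sample's allele is its substitution alt if present, otherwise the
    reference allele (back-mutation assertions count as reference state).
    """
    ref_base = samples.reference.base_at(position)
    counts: dict[str, int] = {}
    for p in samples.profiles:
        v = p.variant_at(position)
        if v is not None and v.kind == SUBSTITUTION and not v.back_mutation:
            allele = v.alt
        else:
            allele = ref_base if ref_base is not None else "ref"
        counts[allele] = counts.get(allele, 0) + 1
    return counts


def frequency_table(
    samplesets: Sequence[SampleSet],
    ref: MitoReference,
    queries: Sequence[FrequencyQuery | str] | None = None,
    coding_only: bool = False,
) -> pd.DataFrame:
    """Per-gene rare-allele frequency table across population groups.

    Without explicit ``queries``, every substitution observed in any group
    becomes a row oriented toward its non-reference allele.  Frequencies
    are carriers of the counted allele divided by group size, so
    ``frequency * n`` is always an integer carrier count.
    """
    groups = [ss for ss in samplesets if ss.n > 0]
    if not groups:
        raise ValueError("at least one non-empty group required")

    if queries is None:
        observed: dict[tuple[int, str], None] = {}
        for ss in groups:
            for p in ss.profiles:
                for v in p.variants:
                    if v.kind == SUBSTITUTION and not v.back_mutation:
                        observed.setdefault((v.position, v.alt), None)
        qlist = []
        for pos, alt in sorted(observed):
            base = ref.base_at(pos) or "N"
            qlist.append(FrequencyQuery(pos, alt, f"{base}{pos}{alt}"))
    else:
        qlist = [
            q if isinstance(q, FrequencyQuery) else FrequencyQuery.from_label(q)
            for q in queries
        ]

    rows = []
    for q in qlist:
        feature = locate_feature(ref, q.position)
        gene = feature.name if feature is not None else "intergenic"
        if coding_only and (feature is None or feature.kind != "protein"):
            continue
        row = {"gene": gene, "variant": q.label, "position": q.position}
        for ss in groups:
            counts = allele_counts(ss, q.position)
            carriers = counts.get(q.allele, 0)
            label = ss.population or "group"
            row[f"freq_{label}"] = carriers / ss.n
            row[f"carriers_{label}"] = carriers
            row[f"n_{label}"] = ss.n
        rows.append(row)

    df = pd.DataFrame(rows)
    if not df.empty:
        # genomic order, grouped by gene order of first appearance
        gene_order = {g: i for i, g in enumerate(dict.fromkeys(df["gene"]))}
        df = (
            df.assign(_g=df["gene"].map(gene_order))
            .sort_values(["_g", "position"])
            .drop(columns=["_g", "position"])
            .reset_index(drop=True)
        )
    return df


def novelty_screen(
    samples: SampleSet, catalog: VariantCatalog, ref: MitoReference
) -> pd.DataFrame:
    """Observed variants absent from the catalog, annotated Table-style.

    Columns: gene, nucleotide_change, protein_change, n_individuals,
    percentage (carriers / n × 100).  Back-mutation assertions are states,
    not observations, and are never reported.
    """
    carriers: dict[tuple, list] = {}
    exemplar: dict[tuple, Variant] = {}
    for p in samples.profiles:
        for v in p.variants:
            if v.back_mutation:
                continue
            key = v.site_key()
            carriers.setdefault(key, []).append(p.sample_id)
            exemplar.setdefault(key, v)

    rows = []
    for key in sorted(carriers, key=lambda k: k[0]):
        v = exemplar[key]
        if v in catalog:
            continue
        feature = locate_feature(ref, v.position)
        gene = feature.name if feature is not None else "intergenic"
        if ref.sequence is not None and v.kind == SUBSTITUTION:
            effect = annotate_effect(ref, v)
            if effect.effect == "nonsynonymous":
                protein_change = f"p.MT-{gene}:{effect.aa_change}"
            elif effect.effect == "synonymous":
                protein_change = "Syn"
            else:
                protein_change = "NA"
        else:
            protein_change = "NA" if (feature is None or feature.kind != "protein") else ""
        n_car = len(carriers[key])
        rows.append(
            {
                "gene": gene,
                "nucleotide_change": format_variant(v),
                "protein_change": protein_change,
                "n_individuals": n_car,
                "n_total": samples.n,
                "percentage": 100.0 * n_car / samples.n,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "nucleotide_change",
            "protein_change",
            "n_individuals",
            "n_total",
            "percentage",
        ],
    )
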