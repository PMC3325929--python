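"""Motif-based haplotype classification.

A *motif* is the set of defining states that diagnoses a named haplotype:
derived alleles (``1185T``), indels (``8281-8289d``), and reference-state
assertions (``4769!`` — the sample must NOT carry a derived allele at the
site).  Reference-state assertions are checked actively: two haplotypes may
differ only by presence versus required absence of one derived allele.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .calling import SampleSet, VariantProfile
from .errors import MotifConfigError, VariantParseError
from .reference import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    MitoReference,
    Variant,
    format_variant,
    parse_variant_label,
)

REFERENCE_STATE = "."


@dataclass(frozen=True)
class Requirement:
    """One required state at one position.

    ``state`` is a derived allele (``"T"``), an insertion (``"ins:ACT"``),
    a deletion (``"del:<span>"``), or :data:`REFERENCE_STATE` for an active
    reference-state assertion.
    """

    position: int
    state: str

    @classmethod
    def from_label(cls, label: str, reference: MitoReference | None = None) -> "Requirement":
        token = label.strip()
        if token.endswith("!"):
            v = parse_variant_label(token, reference)
            return cls(v.position, REFERENCE_STATE)
        v = parse_variant_label(token, reference)
        if v.kind == SUBSTITUTION:
            return cls(v.position, v.alt)
        if v.kind == INSERTION:
            return cls(v.position, f"ins:{v.alt}")
        return cls(v.position, f"del:{len(v.ref)}")

    @property
    def is_reference_assertion(self) -> bool:
        return self.state == REFERENCE_STATE

    def satisfied_by(self, profile: VariantProfile) -> bool:
        v = profile.variant_at(self.position)
        if self.is_reference_assertion:
            return v is None or v.back_mutation
        if v is None or v.back_mutation:
            return False
        if self.state.startswith("ins:"):
            return v.kind == INSERTION and v.alt == self.state[4:]
        if self.state.startswith("del:"):
            return v.kind == DELETION and len(v.ref) == int(self.state[4:])
        return v.kind == SUBSTITUTION and v.alt == self.state

    def label(self) -> str:
        if self.is_reference_assertion:
            return f"{self.position}!"
        if self.state.startswith("ins:"):
            return f"m.{self.position}ins{self.state[4:]}"
        if self.state.startswith("del:"):
            end = self.position + int(self.state[4:]) - 1
            return f"{self.position}-{end}d"
        return f"{self.position}{self.state}"


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    requirements: tuple[Requirement, ...]
    parent: str | None = None

    def __post_init__(self) -> None:
        if not self.requirements:
            raise MotifConfigError(f"motif {self.name!r} has no requirements")
        positions = [r.position for r in self.requirements]
        if len(positions) != len(set(positions)):
            raise MotifConfigError(f"motif {self.name!r} repeats a position")

    @property
    def derived_requirements(self) -> tuple[Requirement, ...]:
        return tuple(r for r in self.requirements if not r.is_reference_assertion)

    def induced_variants(self, reference: MitoReference | None = None) -> tuple[Variant, ...]:
        """The variant set a sample carrying exactly this motif would show."""
        out = []
        for r in self.derived_requirements:
            out.append(parse_variant_label(r.label(), reference))
        return tuple(out)


@dataclass(frozen=True)
class Assignment:
    """Classification result for one sample."""

    sample_id: str
    best_motif: str | None
    matched: int
    missed: tuple[str, ...]
    score: float
    ambiguous: bool = False


# ---------------------------------------------------------------------------
# motif tables
# ---------------------------------------------------------------------------


def _motifs_from_mapping(
    mapping: Mapping, reference: MitoReference | None
) -> list[MotifDefinition]:
    motifs: list[MotifDefinition] = []
    seen: set[str] = set()
    for name, body in mapping.items():
        if name in seen:
            raise MotifConfigError(f"duplicate motif name {name!r}")
        seen.add(name)
        if isinstance(body, Mapping):
            labels = body.get("requires", [])
            parent = body.get("parent")
        else:
            labels, parent = body, None
        try:
            reqs = tuple(Requirement.from_label(str(lab), reference) for lab in labels)
        except VariantParseError as exc:
            raise MotifConfigError(f"motif {name!r}: {exc}") from exc
        motifs.append(MotifDefinition(str(name), reqs, parent))
    if not motifs:
        raise MotifConfigError("motif table is empty")
    return motifs


def _motifs_from_matrix(text: str, reference: MitoReference | None) -> list[MotifDefinition]:
    """Parse a whitespace matrix: header of positions, one row per motif.

    ``.`` cells are reference-state assertions at that column's position;
    base cells are derived-allele requirements.  An optional ``f`` count
    column after the name is ignored.
    """
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if len(lines) < 2:
        raise MotifConfigError("motif matrix needs a header and at least one row")
    header = lines[0].split()
    start = 1
    if header[0].lower() in ("haplotype", "motif", "name"):
        start = 2 if len(header) > 1 and header[1].lower() == "f" else 1
        positions = [int(tok) for tok in header[start:]]
    else:
        positions = [int(tok) for tok in header]
        start = 1
    mapping: dict[str, list[str]] = {}
    for ln in lines[1:]:
        toks = ln.split()
        name = toks[0]
        cells = toks[start:]
        if len(cells) != len(positions):
            raise MotifConfigError(f"row {name!r} has {len(cells)} cells for {len(positions)} positions")
        labels = []
        for pos, cell in zip(positions, cells):
            if cell == REFERENCE_STATE:
                labels.append(f"{pos}!")
            elif set(cell) <= set("ACGT"):
                labels.append(f"{pos}{cell}")
            else:
                raise MotifConfigError(f"unknown state symbol {cell!r} in row {name!r}")
        if name in mapping:
            raise MotifConfigError(f"duplicate motif name {name!r}")
        mapping[name] = labels
    return _motifs_from_mapping(mapping, reference)


def load_motif_table(source, reference: MitoReference | None = None) -> list[MotifDefinition]:
    """Load motifs from a YAML mapping, a dict, or a whitespace matrix file."""
    if isinstance(source, Mapping):
        if "motifs" in source and isinstance(source["motifs"], Mapping):
            source = source["motifs"]
        return _motifs_from_mapping(source, reference)
    try:
        with open(source) as fh:
            text = fh.read()
    except (OSError, TypeError, ValueError):
        text = str(source)
    if not text.strip():
        raise MotifConfigError("motif table is empty")
    first = text.lstrip().splitlines()[0]
    if first.split() and first.split()[0].lower() in ("haplotype", "motif", "name"):
        return _motifs_from_matrix(text, reference)
    data = yaml.safe_load(text)
    if not isinstance(data, Mapping) or not data:
        raise MotifConfigError("motif table is empty or not a mapping")
    if "motifs" in data:
        data = data["motifs"]
    return _motifs_from_mapping(data, reference)


def default_motif_table(reference: MitoReference | None = None) -> list[MotifDefinition]:
    """The bundled B4a1a1 sub-haplotype motifs plus the Polynesian motif."""
    text = (
        importlib.resources.files("mtpop.data")
        .joinpath("motifs_b4a1a1.yaml")
        .read_text()
    )
    return load_motif_table(yaml.safe_load(text), reference)


def restrict_motifs(
    motifs: Sequence[MotifDefinition], positions: Iterable[int]
) -> list[MotifDefinition]:
    """Keep only requirements at the given positions (for partial panels).

    Motifs left with no requirement are dropped.
    """
    keep = set(positions)
    out = []
    for m in motifs:
        reqs = tuple(r for r in m.requirements if r.position in keep)
        if reqs:
            out.append(MotifDefinition(m.name, reqs, m.parent))
    return out


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify(
    profile: VariantProfile,
    motifs: Sequence[MotifDefinition],
    min_score: float = 1.0,
) -> Assignment:
    """Assign the best-matching motif to one profile.

    Among fully satisfied motifs the most specific wins (most derived
    requirements, then most total requirements); remaining ties break
    lexicographically and are flagged ambiguous.  Without a full match the
    best-scoring partial match is reported, with ``best_motif=None`` unless
    its score reaches ``min_score``.
    """
    if not motifs:
        raise MotifConfigError("cannot classify against an empty motif table")
    scored = []
    for m in motifs:
        hits = [r.satisfied_by(profile) for r in m.requirements]
        matched = sum(hits)
        missed = tuple(r.label() for r, ok in zip(m.requirements, hits) if not ok)
        score = matched / len(m.requirements)
        scored.append((m, matched, missed, score))

    full = [t for t in scored if t[3] == 1.0]
    if full:
        full.sort(key=lambda t: (-len(t[0].derived_requirements), -len(t[0].requirements), t[0].name))
        best, matched, missed, score = full[0]
        ambiguous = (
            len(full) > 1
            and len(full[1][0].derived_requirements) == len(best.derived_requirements)
            and len(full[1][0].requirements) == len(best.requirements)
        )
        return Assignment(profile.sample_id, best.name, matched, missed, 1.0, ambiguous)

    scored.sort(key=lambda t: (-t[3], t[0].name))
    best, matched, missed, score = scored[0]
    name = best.name if score >= min_score else None
    return Assignment(profile.sample_id, name, matched, missed, score)


def classify_all(
    samples: SampleSet, motifs: Sequence[MotifDefinition], min_score: float = 1.0
) -> list[Assignment]:
    return [classify(p, motifs, min_score) for p in samples.profiles]


def motif_frequencies(
    samples: SampleSet, motifs: Sequence[MotifDefinition], min_score: float = 1.0
) -> pd.DataFrame:
    """Count and fraction of samples assigned to each motif.

    Fractions sum to at most 1; samples with no acceptable motif are
    reported on an ``unclassified`` row.
    """
    assignments = classify_all(samples, motifs, min_score)
    counts = {m.name: 0 for m in motifs}
    unclassified = 0
    for a in assignments:
        if a.best_motif is None:
            unclassified += 1
        else:
            counts[a.best_motif] += 1
    rows = [
        {"motif": name, "count": c, "fraction": c / samples.n}
        for name, c in counts.items()
    ]
    rows.append(
        {"motif": "unclassified", "count": unclassified, "fraction": unclassified / samples.n}
    )
    return pd.DataFrame(rows, columns=["motif", "count", "fraction"])


def assignments_to_frame(assignments: Sequence[Assignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": a.sample_id,
                "motif": a.best_motif if a.best_motif is not None else "",
                "score": round(a.score, 4),
                "matched": a.matched,
                "missed": ";".join(a.missed),
                "ambiguous": a.ambiguous,
            }
            for a in assignments
        ],
        columns=["sample_id", "motif", "score", "matched", "missed", "ambiguous"],
    )
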