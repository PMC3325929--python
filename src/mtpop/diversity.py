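"""Haplotype and nucleotide diversity statistics.

Haplotype diversity follows Nei's unbiased estimator
``h = n (1 - sum p_i^2) / (n - 1)`` over identical-sequence classes;
nucleotide diversity is the mean pairwise proportion of differing sites,
``pi = sum_{i<j} d_ij / C(n,2) / L_eff``, with alignment columns touched by
an indel in any sample excluded from numerator and denominator
(complete-deletion convention).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import pandas as pd

from .calling import SampleSet, VariantProfile
from .errors import UndefinedStatisticError
from .reference import DELETION, SUBSTITUTION


@dataclass(frozen=True)
class HaplotypePartition:
    """Samples collapsed into identical-sequence classes."""

    classes: tuple[tuple[VariantProfile, tuple[str, ...]], ...]  # (representative, members)
    n: int

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("partition requires at least one class")
        if sum(len(m) for _, m in self.classes) != self.n:
            raise ValueError("class multiplicities must sum to n")

    @property
    def multiplicities(self) -> tuple[int, ...]:
        return tuple(sorted((len(m) for _, m in self.classes), reverse=True))

    @property
    def n_haplotypes(self) -> int:
        return len(self.classes)

    @classmethod
    def from_multiplicities(cls, multiplicities: Sequence[int]) -> "HaplotypePartition":
        """Build an anonymous partition from class sizes alone."""
        classes = []
        k = 0
        for size in multiplicities:
            if size < 1:
                raise ValueError("class sizes must be >= 1")
            members = tuple(f"class{k}_{i}" for i in range(size))
            classes.append((VariantProfile(f"class{k}"), members))
            k += 1
        return cls(tuple(classes), sum(multiplicities))


@dataclass(frozen=True)
class DiversityResult:
    population: str
    n_ind: int
    n_haplo: int
    h: float
    pi: float
    sites_used: int


def collapse_haplotypes(samples: SampleSet) -> HaplotypePartition:
    """Group samples whose variant sets are identical (indels included)."""
    groups: dict[frozenset, list[VariantProfile]] = defaultdict(list)
    for p in samples.profiles:
        groups[p.haplotype_key()].append(p)
    classes = tuple(
        (members[0], tuple(m.sample_id for m in members))
        for members in sorted(groups.values(), key=lambda ms: (-len(ms), ms[0].sample_id))
    )
    return HaplotypePartition(classes, samples.n)


def haplotype_diversity(
    partition: HaplotypePartition | Sequence[int],
    n: int | None = None,
    unbiased: bool = True,
) -> float:
    """Nei's haplotype diversity from a partition or raw class sizes.

    ``unbiased=True`` applies the n/(n-1) small-sample correction (the
    conventional estimator); ``unbiased=False`` gives the maximum-likelihood
    ``1 - sum p_i^2``.
    """
    if isinstance(partition, HaplotypePartition):
        sizes = partition.multiplicities
        n = partition.n
    else:
        sizes = tuple(partition)
        n = n if n is not None else sum(sizes)
    if n < 2:
        raise UndefinedStatisticError("haplotype diversity requires n >= 2")
    if sum(sizes) != n:
        raise ValueError("class sizes must sum to n")
    sum_p2 = sum((s / n) ** 2 for s in sizes)
    h = 1.0 - sum_p2
    if unbiased:
        h *= n / (n - 1)
    return h


def _excluded_positions(samples: SampleSet) -> set[int]:
    """Reference positions involved in an indel in any sample."""
    excluded: set[int] = set()
    for p in samples.profiles:
        for v in p.variants:
            if v.kind == DELETION:
                excluded.update(range(v.position, v.end + 1))
    return excluded


def pairwise_differences(a: VariantProfile, b: VariantProfile, excluded: set[int] = frozenset()) -> int:
    """Number of substitution sites at which two profiles differ."""
    sa = {p: x for p, x in a.substitutions().items() if p not in excluded}
    sb = {p: x for p, x in b.substitutions().items() if p not in excluded}
    return sum(1 for p in set(sa) | set(sb) if sa.get(p) != sb.get(p))


def mean_pairwise_differences(samples: SampleSet) -> float:
    if samples.n < 2:
        raise UndefinedStatisticError("pairwise differences require n >= 2")
    excluded = _excluded_positions(samples)
    total = sum(
        pairwise_differences(a, b, excluded)
        for a, b in combinations(samples.profiles, 2)
    )
    return total / (samples.n * (samples.n - 1) / 2)


def nucleotide_diversity(samples: SampleSet, length: int | None = None) -> float:
    """Per-site nucleotide diversity over the cohort.

    ``length`` defaults to the reference length; indel-involved sites are
    excluded from both the pairwise counts and the effective length.
    """
    if samples.n < 2:
        raise UndefinedStatisticError("nucleotide diversity requires n >= 2")
    L = length if length is not None else samples.reference.length
    if L <= 0:
        raise ValueError("length must be positive")
    excluded = _excluded_positions(samples)
    l_eff = L - len(excluded)
    if l_eff <= 0:
        raise ValueError("no sites left after indel exclusion")
    total = sum(
        pairwise_differences(a, b, excluded)
        for a, b in combinations(samples.profiles, 2)
    )
    n_pairs = samples.n * (samples.n - 1) / 2
    return total / n_pairs / l_eff


def diversity_result(samples: SampleSet, length: int | None = None) -> DiversityResult:
    partition = collapse_haplotypes(samples)
    L = length if length is not None else samples.reference.length
    excluded = _excluded_positions(samples)
    return DiversityResult(
        population=samples.population,
        n_ind=samples.n,
        n_haplo=partition.n_haplotypes,
        h=haplotype_diversity(partition),
        pi=nucleotide_diversity(samples, length),
        sites_used=L - len(excluded),
    )


def diversity_table(
    samplesets: Sequence[SampleSet], length: int | None = None, pooled_label: str = "All populations"
) -> pd.DataFrame:
    """Per-population diversity rows plus a pooled row, Table-style.

    ``h`` is reported to 3 decimals and ``pi`` to 5, matching conventional
    population-survey formatting.
    """
    rows = []
    for ss in samplesets:
        r = diversity_result(ss, length)
        rows.append(r)
    if len(samplesets) > 1:
        pooled_profiles = tuple(p for ss in samplesets for p in ss.profiles)
        pooled = SampleSet(samplesets[0].reference, pooled_profiles, pooled_label)
        rows.append(diversity_result(pooled, length))
    return pd.DataFrame(
        [
            {
                "population": r.population,
                "N_ind": r.n_ind,
                "N_haplo": r.n_haplo,
                "h": round(r.h, 3),
                "pi": round(r.pi, 5),
            }
            for r in rows
        ],
        columns=["population", "N_ind", "N_haplo", "h", "pi"],
    )
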