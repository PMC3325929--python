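"""Founder-effect cohort simulator with known truth labels.

Emulates a maternal lineage cohort descending from a single founder
haplotype — the regime of a recently founded island population: most
variation is the founder's own motif (appearing fixed against the
reference), plus a small number of private mutations per lineage.

Genealogy is a star by default (every lineage independently descends from
the founder), which keeps expectations analytic: each lineage accumulates
``Poisson(rate × length × generations)`` substitutions placed uniformly
without repeat positions, so the expected pairwise difference between two
lineages is about twice that mean.  An optional serial-founder mode routes
lineages through scheduled bottlenecks, creating shared internal branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .calling import SampleSet, VariantProfile
from .errors import SaturationError
from .reference import (
    SUBSTITUTION,
    GeneFeature,
    MitoReference,
    Variant,
    apply_profile,
)

_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a founder-effect cohort simulation.

    ``mutation_rate`` is per site per generation; with the default star
    genealogy the expected number of private mutations per lineage is
    ``mutation_rate × length × generations``.
    """

    n_samples: int
    mutation_rate: float
    generations: int = 1
    founder: tuple[Variant, ...] = ()
    founder_label: str = "founder"
    bottlenecks: tuple[int, ...] = ()
    seed: int = 0
    include_9bp_deletion: bool = False

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.mutation_rate < 0:
            raise ValueError("mutation rate must be >= 0")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")

    def expected_mutations(self, length: int) -> float:
        return self.mutation_rate * length * self.generations


@dataclass(frozen=True)
class TruthSet:
    """Ground truth for a simulated cohort."""

    founder_label: str
    events: dict[str, tuple[Variant, ...]]  # private mutations per sample
    class_ids: dict[str, int]  # identical-sequence class per sample

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid in self.events:
            rows.append(
                {
                    "sample_id": sid,
                    "founder": self.founder_label,
                    "class_id": self.class_ids[sid],
                    "n_private": len(self.events[sid]),
                    "events": ";".join(
                        f"{v.position}{v.ref}>{v.alt}" for v in self.events[sid]
                    ),
                }
            )
        return pd.DataFrame(
            rows, columns=["sample_id", "founder", "class_id", "n_private", "events"]
        )


@dataclass(frozen=True)
class SimulationResult:
    sample_set: SampleSet
    truth: TruthSet
    sequences: dict[str, str]
    config: SimulationConfig


def random_reference(length: int = 16569, seed: int = 0) -> MitoReference:
    """A reproducible uniform-random reference with a synthetic gene map.

    The map carries one rRNA region, two protein genes (one designed
    overlapping pair) and a control region wrapping the origin — enough
    structure to exercise every annotation code path.
    """
    if length < 60:
        raise ValueError("length must be >= 60 to fit the synthetic gene map")
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(_BASES), size=length))

    rrna_start = max(2, length // 20)
    rrna_end = rrna_start + max(3, length // 10)
    p1_start = rrna_end + 2
    p1_len = 3 * max(2, length // 9 // 3)
    p1_end = p1_start + p1_len - 1
    # second protein gene overlapping the tail of the first by one codon
    p2_start = p1_end - 2
    p2_len = 3 * max(2, length // 9 // 3)
    p2_end = p2_start + p2_len - 1
    ctrl_start = length - max(4, length // 20)
    ctrl_end = max(1, length // 50)  # wraps the origin
    if p2_end >= ctrl_start:
        raise ValueError("length too small for the synthetic gene map")
    genes = (
        GeneFeature("rrna-1", rrna_start, rrna_end, "heavy", "rRNA"),
        GeneFeature("orf-1", p1_start, p1_end, "heavy", "protein"),
        GeneFeature("orf-2", p2_start, p2_end, "heavy", "protein"),
        GeneFeature("control", ctrl_start, ctrl_end, "heavy", "control"),
    )
    return MitoReference(id=f"synthetic-{seed}", length=length, sequence=seq, genes=genes)


def _mutate_lineage(
    alleles: dict[int, str],
    ref_seq: str,
    n_mutations: int,
    rng: np.random.Generator,
) -> tuple[dict[int, str], list[Variant]]:
    """Apply n uniform substitutions (no repeat positions within the batch)."""
    L = len(ref_seq)
    alleles = dict(alleles)
    events: list[Variant] = []
    if n_mutations == 0:
        return alleles, events
    positions = rng.choice(L, size=min(n_mutations, L), replace=False) + 1
    for pos in sorted(int(p) for p in positions):
        current = alleles.get(pos, ref_seq[pos - 1])
        others = [b for b in _BASES if b != current]
        alt = others[int(rng.integers(3))]
        events.append(Variant(pos, SUBSTITUTION, ref=current, alt=alt))
        if alt == ref_seq[pos - 1]:
            alleles.pop(pos, None)  # true back mutation to the reference state
        else:
            alleles[pos] = alt
    return alleles, events


def simulate_cohort(config: SimulationConfig, ref: MitoReference) -> SimulationResult:
    """Simulate a cohort of lineages descending from one founder.

    Refuses configurations whose expected mutation load per lineage exceeds
    half the genome (saturation).  The same (config, ref) pair always
    yields byte-identical sequences.
    """
    if ref.sequence is None:
        raise ValueError("simulation requires a reference with a sequence")
    L = ref.length
    if config.expected_mutations(L) > L / 2:
        raise SaturationError(
            f"expected mutation load {config.expected_mutations(L):.0f} exceeds "
            f"half the genome length {L}"
        )
    rng = np.random.default_rng(config.seed)

    founder_alleles: dict[int, str] = {}
    for v in config.founder:
        if v.kind != SUBSTITUTION or v.back_mutation:
            continue
        founder_alleles[v.position] = v.alt

    mu_total = config.expected_mutations(L)

    if config.bottlenecks:
        schedule = list(config.bottlenecks) + [config.n_samples]
        epoch_mu = mu_total / len(schedule)
        pool = [founder_alleles]
        pool_events: list[list[Variant]] = [[]]
        for size in schedule:
            ancestors = [int(a) for a in rng.integers(0, len(pool), size=size)]
            new_pool, new_events = [], []
            for a in ancestors:
                n_mut = int(rng.poisson(epoch_mu))
                alleles, events = _mutate_lineage(pool[a], ref.sequence, n_mut, rng)
                new_pool.append(alleles)
                new_events.append(pool_events[a] + events)
            pool, pool_events = new_pool, new_events
        lineages = list(zip(pool, pool_events))
    else:  # star genealogy
        lineages = []
        for _ in range(config.n_samples):
            n_mut = int(rng.poisson(mu_total))
            alleles, events = _mutate_lineage(founder_alleles, ref.sequence, n_mut, rng)
            lineages.append((alleles, events))

    extra: tuple[Variant, ...] = ()
    if config.include_9bp_deletion:
        if L < 8290:
            raise ValueError("reference too short for the 9-bp deletion option")
        extra = (Variant(8281, "deletion", ref=ref.sequence[8280:8289], alt=""),)

    profiles, sequences, events_by_sample = [], {}, {}
    for i, (alleles, events) in enumerate(lineages):
        sid = f"sim{i:03d}"
        variants = tuple(
            Variant(pos, SUBSTITUTION, ref=ref.sequence[pos - 1], alt=alt)
            for pos, alt in sorted(alleles.items())
        ) + extra
        profile = VariantProfile(sid, "simulated", variants)
        profiles.append(profile)
        sequences[sid] = apply_profile(ref, variants)
        events_by_sample[sid] = tuple(events)

    class_map: dict[frozenset, int] = {}
    class_ids = {}
    for p in profiles:
        key = p.haplotype_key()
        class_ids[p.sample_id] = class_map.setdefault(key, len(class_map))

    truth = TruthSet(config.founder_label, events_by_sample, class_ids)
    sample_set = SampleSet(ref, tuple(profiles), "simulated")
    return SimulationResult(sample_set, truth, sequences, config)


def write_truth(truth: TruthSet, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def write_config(config: SimulationConfig, ref: MitoReference, path) -> None:
    """Echo the simulation conditions as structured text for provenance."""
    payload = {
        "reference": {"id": ref.id, "length": ref.length},
        "n_samples": config.n_samples,
        "mutation_rate": config.mutation_rate,
        "generations": config.generations,
        "founder_label": config.founder_label,
        "founder": [f"{v.position}{v.alt}" for v in config.founder],
        "bottlenecks": list(config.bottlenecks),
        "seed": config.seed,
        "include_9bp_deletion": config.include_9bp_deletion,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
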