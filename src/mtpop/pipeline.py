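"""End-to-end orchestration: call → classify → diversity → tree → freqs → novel.

Every output table starts with a comment header carrying the tool version
and a hash of the run configuration, so any emitted file can be traced to
the exact run that produced it.  Identical configuration and seed yield
byte-identical tables and newick output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .calling import (
    SampleSet,
    call_cohort,
    read_fasta,
    read_profiles,
    profiles_to_frame,
    site_spectrum,
)
from .diversity import diversity_table
from .errors import StageError
from .motifs import (
    assignments_to_frame,
    classify_all,
    default_motif_table,
    load_motif_table,
    motif_frequencies,
)
from .phylo import bootstrap_support, write_newick
from .populations import VariantCatalog, frequency_table, novelty_screen
from .reference import MitoReference, apply_profile, rcrs

log = logging.getLogger("mtpop.pipeline")

STAGE_EXIT_CODES = {
    "load": 2,
    "call": 3,
    "classify": 4,
    "diversity": 5,
    "tree": 6,
    "freqs": 7,
    "novel": 8,
}

REGIONS = ("all", "coding", "control")


@dataclass(frozen=True)
class RunConfig:
    """Inputs and knobs of one pipeline run."""

    fasta: str | None = None
    profiles: str | None = None
    reference_fasta: str | None = None
    motif_config: str | None = None
    catalog: str | None = None
    out_dir: str = "mtpop-out"
    seed: int = 0
    bootstrap_reps: int = 500
    region: str = "all"
    population: str = "cohort"

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}")
        if self.fasta is None and self.profiles is None:
            raise ValueError("either a FASTA or a profile TSV input is required")

    def to_dict(self) -> dict:
        return {
            "fasta": self.fasta,
            "profiles": self.profiles,
            "reference_fasta": self.reference_fasta,
            "motif_config": self.motif_config,
            "catalog": self.catalog,
            "seed": self.seed,
            "bootstrap_reps": self.bootstrap_reps,
            "region": self.region,
            "population": self.population,
        }

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class RunReport:
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def record(self, stage: str, summary: dict, paths: Sequence[Path] = ()) -> None:
        self.stages[stage] = summary
        self.outputs.extend(str(p) for p in paths)

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "config_hash": self.config_hash,
                "stages": self.stages,
                "outputs": self.outputs,
            },
            indent=2,
            sort_keys=True,
        )


def _in_region(position: int, ref: MitoReference, region: str) -> bool:
    if region == "all":
        return True
    control = next((g for g in ref.genes if g.kind == "control" and g.name == "control"), None)
    in_control = control.contains(position) if control is not None else False
    return in_control if region == "control" else not in_control


def restrict_region(samples: SampleSet, region: str) -> SampleSet:
    """Drop variants outside the requested region (all|coding|control)."""
    if region == "all":
        return samples
    profiles = tuple(
        type(p)(
            p.sample_id,
            p.population,
            tuple(v for v in p.variants if _in_region(v.position, samples.reference, region)),
        )
        for p in samples.profiles
    )
    return SampleSet(samples.reference, profiles, samples.population)


def _region_length(ref: MitoReference, region: str) -> int:
    if region == "all":
        return ref.length
    return sum(1 for pos in range(1, ref.length + 1) if _in_region(pos, ref, region))


def _write_table(df: pd.DataFrame, path: Path, config_hash: str, sep: str = ",") -> None:
    with open(path, "w") as fh:
        fh.write(f"# mtpop {__version__} config={config_hash}\n")
        df.to_csv(fh, sep=sep, index=False)


def _run_classify(samples, motifs, out: Path, chash: str, report: RunReport) -> None:
    assignments = classify_all(samples, motifs)
    apath = out / "assignments.tsv"
    _write_table(assignments_to_frame(assignments), apath, chash, sep="\t")
    fpath = out / "motif_frequencies.csv"
    freqs = motif_frequencies(samples, motifs)
    _write_table(freqs, fpath, chash)
    report.record(
        "classify",
        {"n_motifs": len(motifs), "n_classified": int(freqs["count"].iloc[:-1].sum())},
        [apath, fpath],
    )


def run_all(config: RunConfig) -> RunReport:
    """Run the full analysis and write every output under ``config.out_dir``.

    Any stage failure raises :class:`StageError` carrying the stage name
    and its distinct exit code; the partially written output (if any) is
    renamed with a ``.partial`` suffix.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.hash(), version=__version__)
    chash = config.hash()

    def _stage(name: str):
        class _Ctx:
            def __init__(self, name):
                self.name = name
                self.t0 = time.perf_counter()

            def __enter__(self):
                log.info("[%s] starting", self.name)
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    for p in out.glob("*.tmp"):
                        p.rename(p.with_suffix(".partial"))
                    raise StageError(self.name, STAGE_EXIT_CODES[self.name], str(exc)) from exc
                log.info("[%s] done in %.2fs", self.name, time.perf_counter() - self.t0)
                return False

        return _Ctx(name)

    # --- load / call ------------------------------------------------------
    with _stage("load"):
        if config.reference_fasta:
            seqs = read_fasta(config.reference_fasta)
            ref_id, ref_seq = next(iter(seqs.items()))
            ref = MitoReference(id=ref_id, length=len(ref_seq), sequence=ref_seq,
                                genes=rcrs().genes if len(ref_seq) == 16569 else ())
        else:
            ref = rcrs()

    sequences: dict[str, str] | None = None
    with _stage("call"):
        if config.fasta:
            sequences = read_fasta(config.fasta)
            samples = call_cohort(sequences, ref, population=config.population)
            samplesets = [samples]
        else:
            samplesets = read_profiles(config.profiles, ref)
            samples = SampleSet(
                ref,
                tuple(p for ss in samplesets for p in ss.profiles),
                config.population if len(samplesets) > 1 else samplesets[0].population,
            )
        samples = restrict_region(samples, config.region)
        samplesets = [restrict_region(ss, config.region) for ss in samplesets]
        profile_path = out / "profiles.tsv"
        with open(profile_path, "w") as fh:
            fh.write(f"# mtpop {__version__} config={chash}\n")
            profiles_to_frame(samples).to_csv(fh, sep="\t", index=False)
        spectrum = site_spectrum(samples) if samples.n >= 2 else None
        summary = {"n_samples": samples.n}
        if spectrum:
            summary.update(
                variable_sites=spectrum.total_variable_sites,
                fixed=spectrum.n_fixed,
                shared=spectrum.n_shared,
                singleton=spectrum.n_singleton,
            )
        report.record("call", summary, [profile_path])

    # --- classify ---------------------------------------------------------
    with _stage("classify"):
        if config.motif_config:
            motifs = load_motif_table(config.motif_config, ref)
        elif ref.length >= 16569:
            motifs = default_motif_table(ref)
        else:
            motifs = []  # bundled rCRS motifs do not fit a shorter reference
        if not motifs:
            report.record("classify", {"skipped": "no applicable motif table"})
        else:
            _run_classify(samples, motifs, out, chash, report)

    # --- diversity --------------------------------------------------------
    with _stage("diversity"):
        length = _region_length(ref, config.region)
        dtable = diversity_table(samplesets, length=length)
        dpath = out / "diversity.csv"
        _write_table(dtable, dpath, chash)
        report.record("diversity", {"populations": len(samplesets)}, [dpath])
    # --- tree -------------------------------------------------------------
    with _stage("tree"):
        if sequences is None and ref.sequence is not None:
            sequences = {p.sample_id: apply_profile(ref, p.variants) for p in samples.profiles}
        if sequences is not None and len(sequences) >= 3:
            tree = bootstrap_support(
                sequences, reps=config.bootstrap_reps, seed=config.seed
            )
            tpath = out / "tree.nwk"
            write_newick(tree, tpath)
            report.record(
                "tree", {"n_taxa": len(sequences), "reps": config.bootstrap_reps}, [tpath]
            )
        else:
            report.record(
                "tree",
                {"skipped": "no sample sequences available (profiles-only input "
                            "with a sequence-less reference) or fewer than 3 taxa"},
            )

    # --- frequencies ------------------------------------------------------
    with _stage("freqs"):
        ftable = frequency_table(samplesets, ref)
        fqpath = out / "frequencies.csv"
        _write_table(ftable, fqpath, chash)
        report.record("freqs", {"n_rows": len(ftable)}, [fqpath])

    # --- novelty ----------------------------------------------------------
    with _stage("novel"):
        catalog = (
            VariantCatalog.from_tsv(config.catalog)
            if config.catalog
            else VariantCatalog()
        )
        ntable = novelty_screen(samples, catalog, ref)
        npath = out / "novel.tsv"
        _write_table(ntable, npath, chash, sep="\t")
        report.record(
            "novel", {"n_novel": len(ntable), "catalog_size": len(catalog.records)}, [npath]
        )

    rpath = out / "report.json"
    rpath.write_text(report.to_json())
    report.outputs.append(str(rpath))
    return report
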