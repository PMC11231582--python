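"""End-to-end experiment orchestration.

One config drives the whole simulation study: synthesize the family genome,
simulate reads under the requested technology profiles at equalized
coverage, align them against the annotated loci, quantify with the three
strategies (naive best-hit, MAP-EM reassignment, family aggregation) and
emit a consolidated bias report per run.

The high-error long-read profile (``pacbio_standard``) is processed twice
from the same simulated reads, mirroring a two-aligner treatment: a strict
mode (min_identity 0.9, emulating an end-to-end short-read aligner that
rejects most high-error long reads) quantified with the naive and family
methods only, and a lenient mode (min_identity 0.6, long-read-tolerant)
quantified with all three.

All stage seeds derive from the master seed via a stable hash of the stage
and profile names, so adding a profile never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import bias_eval, family_synth, locus_align, quantify, read_sim
from .bias_eval import BiasReport, build_report, mann_whitney_u, spearman_rho
from .family_synth import FamilyGenome, build_family_genome
from .locus_align import AlignParams, align_read, build_index
from .quantify import (
    CountTable,
    EmParams,
    fragments_from_read_hits,
    quantify_em,
    quantify_family,
    quantify_naive,
)
from .read_sim import (
    ErrorProfile,
    get_profile,
    preset_profiles,
    reads_per_locus,
    simulate_reads,
)

__all__ = [
    "ExperimentConfig",
    "RunSpec",
    "ProfileResult",
    "StageError",
    "derive_seed",
    "runs_for_profile",
    "simulate_profile_reads",
    "execute_profile",
    "run_experiment",
    "compare_conditions",
    "load_report",
]

logger = logging.getLogger("retrobench")

DEFAULT_PROFILES = [
    "illumina76se",
    "illumina76pe",
    "illumina150se",
    "illumina150pe",
    "pacbio_standard",
    "pacbio_hifi",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage label as context."""


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    # genome block
    n_young: int = 10
    n_intermediate: int = 10
    n_old: int = 10
    duplicate: bool = True
    background_length: int = 300_000
    solo_length: int = 1000
    provirus_length: int = 10_000
    rate: float = family_synth.DEFAULT_RATE
    gc_fraction: float = 0.41
    # read simulation
    coverage: float = 10.0
    profiles: list[str] = field(default_factory=lambda: list(DEFAULT_PROFILES))
    zero_error: bool = False  # override all profile error rates to 0
    # alignment
    k: int = 13
    band_fraction: float = 0.25
    min_identity: float = 0.8
    strict_min_identity: float = 0.9
    lenient_min_identity: float = 0.6
    max_hits: int = 100
    # quantification
    em: EmParams = field(default_factory=EmParams)
    tie_policy: str = "random"
    master_seed: int = 0

    def align_params(self, min_identity: float) -> AlignParams:
        return AlignParams(
            k=self.k,
            band_fraction=self.band_fraction,
            min_identity=min_identity,
            max_hits=self.max_hits,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConfig":
        d = dict(d)
        if "em" in d and isinstance(d["em"], Mapping):
            d["em"] = EmParams(**d["em"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class RunSpec:
    """One quantification run: a profile plus an aligner stringency mode."""

    label: str
    profile: str
    min_identity: float
    run_em: bool = True


@dataclass
class ProfileResult:
    """Everything produced for one run label."""

    label: str
    profile: ErrorProfile
    truth: dict[str, int]  # locus_id -> fragments simulated
    reads: list
    hits_by_read: dict
    tables: list[CountTable]
    report: BiasReport


def derive_seed(master_seed: int, *parts: str) -> int:
    """Stable per-stage seed below 2**31 from the master seed and labels."""
    key = "/".join([str(master_seed), *parts]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def runs_for_profile(name: str, config: ExperimentConfig) -> list[RunSpec]:
    """Stringency modes for a profile (two for the high-error long reads)."""
    if name == "pacbio_standard":
        return [
            RunSpec("pacbio_standard_strict", name, config.strict_min_identity, False),
            RunSpec("pacbio_standard_lenient", name, config.lenient_min_identity, True),
        ]
    return [RunSpec(name, name, config.min_identity, True)]


def _profile_for(config: ExperimentConfig, name: str) -> ErrorProfile:
    profile = get_profile(name)
    if config.zero_error:
        profile = replace(profile, subst_rate=0.0, ins_rate=0.0, del_rate=0.0)
    return profile


def simulate_profile_reads(
    genome: FamilyGenome, profile: ErrorProfile, config: ExperimentConfig
) -> tuple[list, dict[str, int]]:
    """Simulate the full read set for one profile at equalized coverage.

    Returns (records, truth) where truth maps locus_id to the number of
    simulated fragments (reads for single-end, pairs for paired-end).
    """
    records: list = []
    truth: dict[str, int] = {}
    for locus in genome.simulated_loci:
        n = reads_per_locus(
            config.coverage,
            locus.element_class,
            profile.read_length,
            profile.layout,
            effective_lengths={locus.element_class: locus.length},
        )
        seed = derive_seed(config.master_seed, "reads", profile.name, locus.locus_id)
        records.extend(simulate_reads(genome, locus, n, profile, seed))
        truth[locus.locus_id] = n if profile.layout == "single_end" else n // 2
    return records, truth


def _align_all(reads, index, params: AlignParams) -> dict:
    return {rec.read_id: align_read(rec, index, None, params) for rec in reads}


def _filter_hits(hits_by_read: Mapping, min_identity: float) -> dict:
    return {
        rid: [h for h in hits if h.identity >= min_identity]
        for rid, hits in hits_by_read.items()
    }


def execute_profile(
    genome: FamilyGenome, name: str, config: ExperimentConfig
) -> list[ProfileResult]:
    """Simulate, align and quantify one profile under all its run modes."""
    profile = _profile_for(config, name)
    specs = runs_for_profile(name, config)
    logger.info("profile %s: simulating reads", name)
    reads, truth = simulate_profile_reads(genome, profile, config)

    # Align once at the most lenient threshold; per-mode hit sets are then
    # identity re-filters (identical to aligning at the stricter threshold
    # because max_hits exceeds the number of loci, so truncation never bites).
    loosest = min(spec.min_identity for spec in specs)
    index = build_index(genome.locus_sequences(), config.k)
    logger.info("profile %s: aligning %d reads", name, len(reads))
    base_hits = _align_all(reads, index, config.align_params(loosest))

    results = []
    loci_ids = sorted(genome.locus_sequences())
    for spec in specs:
        hits_by_read = (
            base_hits
            if spec.min_identity == loosest
            else _filter_hits(base_hits, spec.min_identity)
        )
        fragments = fragments_from_read_hits(hits_by_read)
        tables = [
            quantify_naive(
                fragments,
                tie_policy=config.tie_policy,
                seed=derive_seed(config.master_seed, "naive", spec.label),
            )
        ]
        if spec.run_em:
            tables.append(
                quantify_em(
                    fragments,
                    loci_ids,
                    config.em,
                    seed=derive_seed(config.master_seed, "em", spec.label),
                )
            )
        tables.append(quantify_family(fragments))
        report = build_report(truth, tables, genome.loci, profile=spec.label)
        results.append(
            ProfileResult(spec.label, profile, truth, reads, hits_by_read, tables, report)
        )
    return results


def run_experiment(
    config: ExperimentConfig, outdir: str | Path
) -> dict[str, BiasReport]:
    """Run the full experiment and write every artifact under ``outdir``.

    Deterministic given the config; a run manifest records parameters and
    derived seeds.  On failure a FAILED marker naming the stage is left next
    to any partial outputs and the error is re-raised with stage context.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    manifest: dict = {
        "config": config.to_dict(),
        "seeds": {"genome": derive_seed(config.master_seed, "genome")},
        "versions": {
            "retrobench": _package_version(),
            "numpy": np.__version__,
        },
    }
    reports: dict[str, BiasReport] = {}
    try:
        stage = "genome"
        genome = build_family_genome(
            n_young=config.n_young,
            n_intermediate=config.n_intermediate,
            n_old=config.n_old,
            duplicate=config.duplicate,
            background_length=config.background_length,
            seed=manifest["seeds"]["genome"],
            solo_length=config.solo_length,
            provirus_length=config.provirus_length,
            rate=config.rate,
            gc_fraction=config.gc_fraction,
        )
        family_synth.write_fasta(genome, outdir / "genome.fa")
        family_synth.write_bed(genome, outdir / "loci.bed")
        family_synth.write_locus_table(genome, outdir / "loci.tsv")
        config.to_yaml(outdir / "config.yaml")

        for name in config.profiles:
            stage = f"profile:{name}"
            profile = _profile_for(config, name)
            results = execute_profile(genome, name, config)
            first = results[0]
            if profile.layout == "paired_end":
                read_sim.write_fastq_pair(
                    first.reads,
                    outdir / f"{name}_1.fastq",
                    outdir / f"{name}_2.fastq",
                )
            else:
                read_sim.write_fastq(first.reads, outdir / f"{name}.fastq")
            with open(outdir / f"{name}_truth.tsv", "w") as fh:
                fh.write("locus_id\tassigned\n")
                for lid in sorted(first.truth):
                    fh.write(f"{lid}\t{first.truth[lid]}\n")
            for res in results:
                stage = f"run:{res.label}"
                locus_align.hits_to_tsv(res.hits_by_read, outdir / f"{res.label}_hits.tsv")
                quantify.write_counts_tsv(res.tables, outdir / f"{res.label}_counts.tsv")
                res.report.write_tsv(outdir / f"{res.label}_report.tsv")
                res.report.write_summary_tsv(outdir / f"{res.label}_summary.tsv")
                em_tables = [t for t in res.tables if t.method == "em"]
                run_meta = {
                    "label": res.label,
                    "profile": res.profile.name,
                    "seeds": {
                        "naive": derive_seed(config.master_seed, "naive", res.label),
                    },
                    "em": None
                    if not em_tables
                    else {
                        "iterations": em_tables[0].meta["iterations"],
                        "converged": em_tables[0].meta["converged"],
                    },
                }
                with open(outdir / f"{res.label}_run.yaml", "w") as fh:
                    yaml.safe_dump(run_meta, fh, sort_keys=False)
                reports[res.label] = res.report
                manifest.setdefault("runs", []).append(run_meta)

        stage = "manifest"
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise StageError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return reports


def _package_version() -> str:
    from . import __version__

    return __version__


# ---------------------------------------------------------------------------
# Cross-condition comparisons


def _pe_vector(report: BiasReport, method: str, proviral_only: bool) -> Optional[pd.DataFrame]:
    df = report.method_rows(method)
    if df.empty:
        return None
    if proviral_only:
        df = df[df["element_class"] == "provirus"]
    return df.sort_values("locus_id")


def compare_conditions(
    reports: Mapping[str, BiasReport],
    methods: Sequence[str] = ("naive", "em"),
    proviral_only: bool = False,
) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparisons of percent-error distributions.

    Compares every pair of runs sharing a layout (single-end read lengths
    against each other, paired-end likewise) per method, plus naive-vs-em
    within each run, plus Spearman rho of percent error against age per run
    and method.  ``proviral_only`` restricts to provirus rows (sensitivity
    analysis).  Runs with mismatched locus sets raise an error.
    """
    if len(reports) < 1:
        raise ValueError("need at least one report")
    rows: list[dict] = []
    labels = list(reports)

    def layout_of(label: str) -> str:
        base = label.replace("_strict", "").replace("_lenient", "")
        try:
            return get_profile(base).layout
        except Exception:
            return "unknown"

    for method in methods:
        vecs: dict[str, pd.DataFrame] = {}
        for label in labels:
            df = _pe_vector(reports[label], method, proviral_only)
            if df is not None:
                vecs[label] = df
        keys = list(vecs)
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                if layout_of(a) != layout_of(b):
                    continue
                if list(vecs[a]["locus_id"]) != list(vecs[b]["locus_id"]):
                    raise ValueError(f"locus sets differ between {a} and {b}")
                u, p = mann_whitney_u(
                    vecs[a]["percent_error"], vecs[b]["percent_error"]
                )
                rows.append(
                    dict(
                        comparison="run_vs_run",
                        method=method,
                        a=a,
                        b=b,
                        statistic=u,
                        p_value=p,
                        median_a=float(vecs[a]["percent_error"].median()),
                        median_b=float(vecs[b]["percent_error"].median()),
                    )
                )
        for label, df in vecs.items():
            ages = df["age_my"].to_numpy()
            pe = df["percent_error"].to_numpy()
            if np.unique(ages).size >= 3 and np.unique(pe).size > 1:
                rho, p = spearman_rho(pe, ages)
                rows.append(
                    dict(
                        comparison="percent_error_vs_age",
                        method=method,
                        a=label,
                        b="",
                        statistic=rho,
                        p_value=p,
                        median_a=float(np.median(pe)),
                        median_b=np.nan,
                    )
                )
    for label in labels:
        rep = reports[label]
        dfs = {m: _pe_vector(rep, m, proviral_only) for m in ("naive", "em")}
        if dfs["naive"] is not None and dfs["em"] is not None:
            u, p = mann_whitney_u(
                dfs["naive"]["percent_error"], dfs["em"]["percent_error"]
            )
            rows.append(
                dict(
                    comparison="naive_vs_em",
                    method="both",
                    a=label,
                    b=label,
                    statistic=u,
                    p_value=p,
                    median_a=float(dfs["naive"]["percent_error"].median()),
                    median_b=float(dfs["em"]["percent_error"].median()),
                )
            )
    return pd.DataFrame(rows)


def load_report(path: str | Path, profile: str = "") -> BiasReport:
    """Rebuild a BiasReport from a per-locus report TSV."""
    df = pd.read_csv(path, sep="\t")
    if not profile and len(df):
        profile = str(df["profile"].iloc[0])
    return BiasReport(profile=profile, per_locus=df)
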