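"""Truth-tagged read simulation under technology error profiles.

Simulates sequencing reads directly from annotated family loci at equalized
coverage.  Six presets emulate the layouts of common technologies: Illumina
76/150 nt single- and paired-end (substitution-only error), a standard
long-read "CLR" profile (750 nt, 12% total error dominated by indels) and a
HiFi-like profile (750 nt, 0.2% total error).

Every read name encodes its ground truth (source locus, fragment start,
strand, mate, serial), so downstream quantification can always be compared
against a known assignment without auxiliary files.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .family_synth import (
    FamilyGenome,
    LocusSpec,
    ParameterError,
    codes_to_seq,
    seq_to_codes,
)

__all__ = [
    "ErrorProfile",
    "ReadRecord",
    "ReadTruth",
    "InfeasibleLocusError",
    "preset_profiles",
    "get_profile",
    "reads_per_locus",
    "simulate_reads",
    "encode_read_id",
    "parse_read_id",
    "fragment_id",
    "write_fastq",
    "write_fastq_pair",
    "EFFECTIVE_LENGTHS",
]

#: Effective lengths (nt) used for coverage equalization per element class.
EFFECTIVE_LENGTHS = {"solo_ltr": 1000, "provirus": 10_000}


class InfeasibleLocusError(ValueError):
    """Locus too short for the requested read/fragment layout."""


@dataclass(frozen=True)
class ErrorProfile:
    """A sequencing technology: read geometry plus per-base error rates."""

    name: str
    read_length: int
    layout: str  # "single_end" | "paired_end"
    subst_rate: float
    ins_rate: float = 0.0
    del_rate: float = 0.0
    mean_fragment: Optional[float] = None
    sd_fragment: Optional[float] = None
    base_quality: int = 35

    def __post_init__(self) -> None:
        if self.layout not in ("single_end", "paired_end"):
            raise ParameterError(f"unknown layout {self.layout!r}")
        rates = (self.subst_rate, self.ins_rate, self.del_rate)
        if any(r < 0 for r in rates) or sum(rates) >= 1.0:
            raise ParameterError("error rates must be >= 0 and sum to < 1")
        if self.layout == "paired_end":
            if self.mean_fragment is None or self.sd_fragment is None:
                raise ParameterError("paired_end requires fragment length model")
            if self.mean_fragment < 2 * self.read_length:
                raise ParameterError("mean_fragment must be >= 2 * read_length")

    @property
    def total_error(self) -> float:
        return self.subst_rate + self.ins_rate + self.del_rate


def preset_profiles() -> list[ErrorProfile]:
    """The six bundled technology presets."""
    return [
        ErrorProfile("illumina76se", 76, "single_end", 0.002),
        ErrorProfile(
            "illumina76pe", 76, "paired_end", 0.002,
            mean_fragment=300.0, sd_fragment=30.0,
        ),
        ErrorProfile("illumina150se", 150, "single_end", 0.002),
        ErrorProfile(
            "illumina150pe", 150, "paired_end", 0.002,
            mean_fragment=300.0, sd_fragment=30.0,
        ),
        # CLR-like chemistry: 12% total error, indel-dominated.
        ErrorProfile(
            "pacbio_standard", 750, "single_end",
            subst_rate=0.02, ins_rate=0.06, del_rate=0.04, base_quality=13,
        ),
        # HiFi-like: 99.8% accuracy -> 0.002 total error.
        ErrorProfile(
            "pacbio_hifi", 750, "single_end",
            subst_rate=0.001, ins_rate=0.0005, del_rate=0.0005,
        ),
    ]


def get_profile(name: str) -> ErrorProfile:
    for profile in preset_profiles():
        if profile.name == name:
            return profile
    raise ParameterError(f"unknown profile {name!r}")


def reads_per_locus(
    coverage: float,
    element_class: str,
    read_length: int,
    layout: str,
    effective_lengths: dict[str, int] = EFFECTIVE_LENGTHS,
) -> int:
    """Read count giving ``coverage``-fold depth over the effective length.

    Single-end: floor(coverage * L / read_length).  Paired-end:
    2 * floor(coverage * L / (2 * read_length)) — whole pairs only.  The
    count depends only on read length and layout, never on the error model,
    so profiles of equal geometry receive identical input.
    """
    if coverage <= 0:
        raise ParameterError("coverage must be > 0")
    if element_class not in effective_lengths:
        raise ParameterError(f"unknown element_class {element_class!r}")
    L = effective_lengths[element_class]
    if layout == "single_end":
        return int(coverage * L // read_length)
    if layout == "paired_end":
        return 2 * int(coverage * L // (2 * read_length))
    raise ParameterError(f"unknown layout {layout!r}")


@dataclass(frozen=True)
class ReadTruth:
    """Decoded ground truth of one read."""

    locus_id: str
    start: int  # fragment start offset within the locus
    strand: str  # '+' or '-'
    mate: int  # 0 = single-end; 1/2 = paired mates
    serial: int


def encode_read_id(truth: ReadTruth) -> str:
    return f"{truth.locus_id}|{truth.start}|{truth.strand}|{truth.mate}|{truth.serial}"


def parse_read_id(read_id: str) -> ReadTruth:
    locus_id, start, strand, mate, serial = read_id.rsplit("|", 4)
    return ReadTruth(locus_id, int(start), strand, int(mate), int(serial))


def fragment_id(read_id: str) -> str:
    """Collapse a read id to its fragment id (drops the mate index)."""
    locus_id, start, strand, _mate, serial = read_id.rsplit("|", 4)
    return f"{locus_id}|{start}|{strand}|{serial}"


@dataclass
class ReadRecord:
    """One FASTQ-ready read.

    ``n_errors`` and ``n_template`` are simulation metadata: the number of
    error events applied and the number of template bases consumed (used by
    the error-rate recovery tests); they are not written to FASTQ.
    """

    read_id: str
    sequence: str
    qualities: str
    n_errors: int = 0
    n_template: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ParameterError("sequence/quality length mismatch")


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def _apply_errors(
    template: np.ndarray,
    read_length: int,
    profile: ErrorProfile,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int, int]:
    """Copy ``read_length`` bases off ``template`` applying per-base errors.

    Per template base consumed (independent draws): deletion with p_del
    (base skipped); otherwise the base is emitted, substituted with p_subst
    to a uniformly chosen different base; and with p_ins a uniform random
    base is inserted after it.  Deletions draw extra template, keeping the
    read length fixed; if the template runs out (fragment near the locus
    end under heavy deletion) the tail is padded with uniform random bases.
    Returns (read codes, error events, template bases consumed).
    """
    sub, ins, dele = profile.subst_rate, profile.ins_rate, profile.del_rate
    if ins == 0.0 and dele == 0.0:
        out = template[:read_length].copy()
        mask = rng.random(read_length) < sub
        n = int(mask.sum())
        if n:
            shifts = rng.integers(1, 4, size=n).astype(np.uint8)
            out[mask] = (out[mask] + shifts) % 4
        return out, n, read_length

    n_tpl = template.size
    draws = rng.random((3, n_tpl))
    out = np.empty(read_length, dtype=np.uint8)
    filled = 0
    consumed = 0
    n_err = 0
    for t in range(n_tpl):
        if filled >= read_length:
            break
        consumed += 1
        if draws[0, t] < dele:
            n_err += 1
            continue
        base = template[t]
        if draws[1, t] < sub:
            base = (base + 1 + int(rng.integers(3))) % 4
            n_err += 1
        out[filled] = base
        filled += 1
        if filled < read_length and draws[2, t] < ins:
            out[filled] = rng.integers(4)
            filled += 1
            n_err += 1
    if filled < read_length:  # template exhausted: pad uniformly
        pad = read_length - filled
        out[filled:] = rng.integers(4, size=pad)
    return out, n_err, consumed


def _template_margin(profile: ErrorProfile) -> int:
    return int(3 * profile.del_rate * profile.read_length) + 8


def simulate_reads(
    genome: FamilyGenome,
    locus: LocusSpec,
    n_reads: int,
    profile: ErrorProfile,
    seed: int,
) -> list[ReadRecord]:
    """Simulate ``n_reads`` truth-tagged reads from one locus.

    Fragment starts are uniform over valid positions inside the locus and the
    strand is uniform; reverse-strand reads are emitted reverse-complemented.
    Reads are contained entirely within the locus (no junction reads into the
    flanks).  Deterministic under ``seed``.
    """
    if not locus.simulated:
        raise ParameterError(f"locus {locus.locus_id} is not simulated")
    if n_reads < 0:
        raise ParameterError("n_reads must be >= 0")
    seq = genome.locus_sequence(locus)
    L = len(seq)
    rl = profile.read_length
    rng = np.random.default_rng(seed)
    codes = seq_to_codes(seq)
    rc_codes = _revcomp_codes(codes)
    margin = _template_margin(profile)
    qual = chr(33 + profile.base_quality)
    records: list[ReadRecord] = []

    if profile.layout == "single_end":
        if L < rl:
            raise InfeasibleLocusError(
                f"locus {locus.locus_id} ({L} nt) shorter than read length {rl}"
            )
        for serial in range(n_reads):
            start = int(rng.integers(0, L - rl + 1))
            strand = "+" if rng.integers(2) == 0 else "-"
            if strand == "+":
                tpl = codes[start : start + rl + margin]
            else:
                # read off the reverse strand, extending leftwards in genome
                # coordinates as deletions consume template
                rc_start = L - (start + rl)
                tpl = rc_codes[rc_start : rc_start + rl + margin]
            read, n_err, consumed = _apply_errors(tpl, rl, profile, rng)
            truth = ReadTruth(locus.locus_id, start, strand, 0, serial)
            records.append(
                ReadRecord(
                    encode_read_id(truth),
                    codes_to_seq(read),
                    qual * rl,
                    n_err,
                    consumed,
                )
            )
        return records

    # paired-end
    if n_reads % 2:
        raise ParameterError("paired_end n_reads must be even")
    if L < profile.mean_fragment:
        raise InfeasibleLocusError(
            f"locus {locus.locus_id} ({L} nt) shorter than mean fragment "
            f"{profile.mean_fragment}"
        )
    n_pairs = n_reads // 2
    for serial in range(n_pairs):
        frag = int(round(rng.normal(profile.mean_fragment, profile.sd_fragment)))
        frag = max(2 * rl, min(L, frag))
        start = int(rng.integers(0, L - frag + 1))
        strand = "+" if rng.integers(2) == 0 else "-"
        # mate 1 reads inward from the fragment's 5' end on `strand`,
        # mate 2 inward from the opposite end.
        if strand == "+":
            tpl1 = codes[start : start + rl + margin]
            rc_start2 = L - (start + frag)
            tpl2 = rc_codes[rc_start2 : rc_start2 + rl + margin]
        else:
            rc_start1 = L - (start + frag)
            tpl1 = rc_codes[rc_start1 : rc_start1 + rl + margin]
            tpl2 = codes[start : start + rl + margin]
        for mate, tpl in ((1, tpl1), (2, tpl2)):
            read, n_err, consumed = _apply_errors(tpl, rl, profile, rng)
            truth = ReadTruth(locus.locus_id, start, strand, mate, serial)
            records.append(
                ReadRecord(
                    encode_read_id(truth),
                    codes_to_seq(read),
                    qual * rl,
                    n_err,
                    consumed,
                )
            )
    return records


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    """Plain 4-line FASTQ, Sanger Phred+33 qualities."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.qualities}\n")


def write_fastq_pair(
    records: Iterable[ReadRecord], path1: str | Path, path2: str | Path
) -> None:
    """Split paired records into /1 and /2 files by their mate index."""
    recs = list(records)
    write_fastq([r for r in recs if parse_read_id(r.read_id).mate == 1], path1)
    write_fastq([r for r in recs if parse_read_id(r.read_id).mate == 2], path2)
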