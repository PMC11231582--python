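"""Synthetic retroelement family generation.

Builds an HML-2-like family of integration sites on a synthetic background
contig.  Every locus descends from a single ancestral ("master") element and
diverges from it in proportion to its assigned integration age under a
Jukes-Cantor substitution model, so young loci are near-identical repeats and
old loci are individually recognizable — the age/repetitiveness gradient that
drives multi-mapping ambiguity in real retroelement families.

The default family mirrors a 30-site study design: ten loci in each of three
age strata (young / intermediate / old), 18 solo-LTRs of 1000 nt and 12
proviruses of 10 000 nt, plus one annotation-only locus that is an exact
duplicate of a simulated young provirus (emulating a post-integration
segmental duplication).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bias_eval import assign_age_group

__all__ = [
    "LocusSpec",
    "FamilyGenome",
    "ParameterError",
    "CapacityError",
    "AGE_SAMPLING_RANGES",
    "DEFAULT_RATE",
    "generate_master",
    "expected_divergence",
    "evolve_locus",
    "build_family_genome",
    "write_fasta",
    "write_bed",
    "write_locus_table",
    "load_family_genome",
]


class ParameterError(ValueError):
    """Invalid parameter passed to a generator operation."""


class CapacityError(RuntimeError):
    """Background contig too short to place all loci with required flanks."""


#: substitutions / site / MY, approximately the human neutral rate.
DEFAULT_RATE = 0.0022

#: Uniform sampling ranges (MY) per age stratum.  Chosen disjoint and
#: consistent with the <10 / 10-20 / >20 MY grouping cutpoints so that a
#: locus's sampling stratum always equals its assigned age group.
AGE_SAMPLING_RANGES = {
    "young": (1.9, 9.38),
    "intermediate": (10.0, 20.0),
    "old": (24.25, 53.79),
}

DEFAULT_SOLO_LENGTH = 1000
DEFAULT_PROVIRUS_LENGTH = 10_000

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode an ACGT string as uint8 codes 0..3."""
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if codes.max(initial=0) > 3:
        raise ParameterError("sequence contains non-ACGT characters")
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


@dataclass(frozen=True)
class LocusSpec:
    """One simulated integration site.

    Coordinates are 0-based half-open on ``chrom``.  ``simulated`` marks
    whether reads are generated from this locus; the duplicate twin is
    annotated but never simulated.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    age_my: float
    element_class: str  # "solo_ltr" | "provirus"
    age_group: str  # "young" | "intermediate" | "old"
    duplicate_of: Optional[str] = None
    simulated: bool = True

    def __post_init__(self) -> None:
        if "|" in self.locus_id:
            raise ParameterError("locus_id must not contain '|'")
        if self.start < 0 or self.end <= self.start:
            raise ParameterError("invalid locus interval")
        if self.element_class not in ("solo_ltr", "provirus"):
            raise ParameterError(f"unknown element_class {self.element_class!r}")
        if self.age_group != assign_age_group(self.age_my):
            raise ParameterError(
                f"age_group {self.age_group!r} inconsistent with age {self.age_my}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FamilyGenome:
    """A background contig plus all family loci; the simulation ground truth."""

    contigs: dict[str, str]
    loci: list[LocusSpec]
    master: str
    realized_divergence: dict[str, float]
    rng_seed: int

    def locus_sequence(self, locus: LocusSpec | str) -> str:
        if isinstance(locus, str):
            locus = self.locus_by_id(locus)
        return self.contigs[locus.chrom][locus.start : locus.end]

    def locus_by_id(self, locus_id: str) -> LocusSpec:
        for loc in self.loci:
            if loc.locus_id == locus_id:
                return loc
        raise KeyError(locus_id)

    @property
    def simulated_loci(self) -> list[LocusSpec]:
        return [loc for loc in self.loci if loc.simulated]

    def locus_sequences(self) -> dict[str, str]:
        """All annotated locus sequences keyed by id (alignment targets)."""
        return {loc.locus_id: self.locus_sequence(loc) for loc in self.loci}


def generate_master(length: int, gc_fraction: float, seed: int) -> str:
    """I.i.d. ancestral sequence of ``length`` nt at the given expected GC."""
    if length < 1:
        raise ParameterError("length must be >= 1")
    if not 0.0 < gc_fraction < 1.0:
        raise ParameterError("gc_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    codes = rng.choice(4, size=length, p=[at, gc, gc, at])
    return codes_to_seq(codes.astype(np.uint8))


def expected_divergence(age_my: float, rate: float = DEFAULT_RATE) -> float:
    """Expected observable mismatch fraction after ``age_my`` MY.

    Jukes-Cantor: p = (3/4) * (1 - exp(-(4/3) * rate * age)).  Monotone in
    age and saturating at 3/4 (random sequence against random sequence).
    """
    if age_my < 0:
        raise ParameterError("age_my must be >= 0")
    if rate <= 0:
        raise ParameterError("rate must be > 0")
    return 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * rate * age_my))


def evolve_locus(
    master: str, age_my: float, rate: float, seed: int
) -> tuple[str, float]:
    """Diverge ``master`` by i.i.d. per-site substitution.

    Each site substitutes with probability ``expected_divergence(age_my,
    rate)``, uniformly among the three alternative bases.  Returns the evolved
    sequence and the realized mismatch fraction against the master.
    Substitution-only, so sequence length is preserved.
    """
    if not master:
        raise ParameterError("master must be non-empty")
    p = expected_divergence(age_my, rate)
    rng = np.random.default_rng(seed)
    codes = seq_to_codes(master).copy()
    mask = rng.random(codes.size) < p
    n_sub = int(mask.sum())
    if n_sub:
        shifts = rng.integers(1, 4, size=n_sub).astype(np.uint8)
        codes[mask] = (codes[mask] + shifts) % 4
    realized = n_sub / codes.size
    return codes_to_seq(codes), realized


def _default_classes(n: int) -> list[str]:
    """Default per-stratum class mix: ~60% solo-LTR, rest provirus."""
    n_solo = int(np.ceil(0.6 * n))
    return ["solo_ltr"] * n_solo + ["provirus"] * (n - n_solo)


def build_family_genome(
    n_young: int = 10,
    n_intermediate: int = 10,
    n_old: int = 10,
    class_assignment: Optional[Sequence[str]] = None,
    duplicate: bool = True,
    background_length: int = 300_000,
    seed: int = 0,
    *,
    solo_length: int = DEFAULT_SOLO_LENGTH,
    provirus_length: int = DEFAULT_PROVIRUS_LENGTH,
    rate: float = DEFAULT_RATE,
    gc_fraction: float = 0.41,
    min_flank: int = 1000,
    contig_name: str = "synth1",
) -> FamilyGenome:
    """Generate the full synthetic family genome.

    Each stratum's ages are drawn uniformly from its sampling range; each
    locus evolves independently from the shared master (solo-LTRs from the
    master's first ``solo_length`` nt).  Loci are placed non-overlapping on a
    single i.i.d. background contig with >= ``min_flank`` nt flanks.  When
    ``duplicate`` is true one extra provirus locus is added that is an exact
    copy of a randomly chosen simulated young provirus, annotated with
    ``simulated=False``.
    """
    for n in (n_young, n_intermediate, n_old):
        if n < 0:
            raise ParameterError("group counts must be >= 0")
    rng = np.random.default_rng(seed)
    master = generate_master(provirus_length, gc_fraction, int(rng.integers(2**31)))

    counts = {"young": n_young, "intermediate": n_intermediate, "old": n_old}
    if class_assignment is None:
        classes: list[str] = []
        for group in ("young", "intermediate", "old"):
            classes.extend(_default_classes(counts[group]))
    else:
        classes = list(class_assignment)
        if len(classes) != sum(counts.values()):
            raise ParameterError("class_assignment length mismatch")

    prefix = {"young": "y", "intermediate": "i", "old": "o"}
    entries: list[dict] = []  # staged loci before placement
    idx = 0
    for group in ("young", "intermediate", "old"):
        lo, hi = AGE_SAMPLING_RANGES[group]
        ages = np.sort(rng.uniform(lo, hi, size=counts[group]))
        for j in range(counts[group]):
            element_class = classes[idx]
            length = solo_length if element_class == "solo_ltr" else provirus_length
            template = master[:solo_length] if element_class == "solo_ltr" else master
            seq, div = evolve_locus(
                template, float(ages[j]), rate, int(rng.integers(2**31))
            )
            entries.append(
                dict(
                    locus_id=f"{prefix[group]}{j + 1:02d}",
                    age_my=float(ages[j]),
                    element_class=element_class,
                    age_group=group,
                    duplicate_of=None,
                    simulated=True,
                    sequence=seq,
                    divergence=div,
                )
            )
            idx += 1

    if duplicate:
        young_prov = [
            e
            for e in entries
            if e["age_group"] == "young" and e["element_class"] == "provirus"
        ]
        if not young_prov:
            raise ParameterError("duplicate=True requires a simulated young provirus")
        src = young_prov[int(rng.integers(len(young_prov)))]
        entries.append(
            dict(
                locus_id=src["locus_id"] + "_dup",
                age_my=src["age_my"],
                element_class="provirus",
                age_group="young",
                duplicate_of=src["locus_id"],
                simulated=False,
                sequence=src["sequence"],
                divergence=src["divergence"],
            )
        )

    # Random non-overlapping placement: a random order, then gaps of at least
    # min_flank with the residual space split randomly among the n+1 gaps.
    order = rng.permutation(len(entries))
    total_locus = sum(len(entries[i]["sequence"]) for i in range(len(entries)))
    n_gaps = len(entries) + 1
    slack = background_length - total_locus - n_gaps * min_flank
    if slack < 0:
        raise CapacityError(
            f"background_length {background_length} cannot hold {len(entries)} loci "
            f"({total_locus} nt) with {min_flank} nt flanks"
        )
    extra = rng.multinomial(slack, np.full(n_gaps, 1.0 / n_gaps))
    gaps = (min_flank + extra).tolist()

    gap_total = sum(gaps)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    bg_codes = rng.choice(4, size=gap_total, p=[at, gc, gc, at]).astype(np.uint8)
    bg = codes_to_seq(bg_codes)

    pieces: list[str] = []
    loci: list[LocusSpec] = []
    realized: dict[str, float] = {}
    pos = 0
    bg_pos = 0
    for gi, ei in enumerate(order):
        gap = gaps[gi]
        pieces.append(bg[bg_pos : bg_pos + gap])
        bg_pos += gap
        pos += gap
        e = entries[ei]
        seq = e["sequence"]
        loci.append(
            LocusSpec(
                locus_id=e["locus_id"],
                chrom=contig_name,
                start=pos,
                end=pos + len(seq),
                age_my=e["age_my"],
                element_class=e["element_class"],
                age_group=e["age_group"],
                duplicate_of=e["duplicate_of"],
                simulated=e["simulated"],
            )
        )
        realized[e["locus_id"]] = e["divergence"]
        pieces.append(seq)
        pos += len(seq)
    pieces.append(bg[bg_pos : bg_pos + gaps[-1]])
    contig = "".join(pieces)
    assert len(contig) == background_length

    loci.sort(key=lambda loc: loc.start)
    return FamilyGenome(
        contigs={contig_name: contig},
        loci=loci,
        master=master,
        realized_divergence=realized,
        rng_seed=seed,
    )


# ---------------------------------------------------------------------------
# File output (FASTA / BED / locus table)


def write_fasta(genome: FamilyGenome, path: str | Path) -> None:
    """Write all contigs as FASTA wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_bed(genome: FamilyGenome, path: str | Path) -> None:
    """6-column BED: chrom, start, end, locus_id, age_my*100 as score, '+'."""
    with open(path, "w") as fh:
        for loc in genome.loci:
            score = int(round(loc.age_my * 100))
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.locus_id}\t{score}\t+\n"
            )


def write_locus_table(genome: FamilyGenome, path: str | Path) -> None:
    """Sidecar TSV with ages, classes, duplicate linkage and divergences."""
    with open(path, "w") as fh:
        fh.write(
            "locus_id\tage_my\tage_group\telement_class\tduplicate_of"
            "\tsimulated\trealized_divergence\n"
        )
        for loc in genome.loci:
            fh.write(
                f"{loc.locus_id}\t{loc.age_my:.6g}\t{loc.age_group}\t"
                f"{loc.element_class}\t{loc.duplicate_of or '.'}\t"
                f"{int(loc.simulated)}\t{genome.realized_divergence[loc.locus_id]:.8g}\n"
            )


def load_family_genome(
    fasta: str | Path, locus_table: str | Path, bed: str | Path, rng_seed: int = -1
) -> FamilyGenome:
    """Rebuild a FamilyGenome from its on-disk artifacts.

    The master sequence is not stored on disk; the loaded genome carries an
    empty master and the recorded realized divergences.
    """
    contigs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
    meta: dict[str, dict] = {}
    with open(locus_table) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            meta[row["locus_id"]] = row
    loci: list[LocusSpec] = []
    realized: dict[str, float] = {}
    with open(bed) as fh:
        for line in fh:
            chrom, start, end, locus_id, _score, _strand = line.split()[:6]
            row = meta[locus_id]
            loci.append(
                LocusSpec(
                    locus_id=locus_id,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    age_my=float(row["age_my"]),
                    element_class=row["element_class"],
                    age_group=row["age_group"],
                    duplicate_of=None
                    if row["duplicate_of"] == "."
                    else row["duplicate_of"],
                    simulated=bool(int(row["simulated"])),
                )
            )
            realized[locus_id] = float(row["realized_divergence"])
    return FamilyGenome(
        contigs=contigs,
        loci=loci,
        master="",
        realized_divergence=realized,
        rng_seed=rng_seed,
    )
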