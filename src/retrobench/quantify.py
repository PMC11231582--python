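"""Fragment-to-locus quantification strategies.

Three ways to turn per-fragment alignment hit lists into per-locus counts:

* ``quantify_naive`` — standard locus-specific counting: each fragment goes
  to its single best-scoring locus, score ties broken at random (seeded) or
  by locus id.
* ``quantify_em`` — maximum-a-posteriori EM reassignment of ambiguous
  fragments over a mixture of source loci (Telescope-style).  Alignment
  scores become fragment-locus likelihood weights through a softmax relative
  to the fragment's best score; locus mixing proportions get a symmetric
  Dirichlet pseudo-count prior whose total mass is ``theta_prior``.  Final
  integer counts come from hard assignment to the highest-responsibility
  locus.
* ``quantify_family`` — family-level aggregation: the number of fragments
  with at least one accepted hit anywhere in the family, trading locus
  resolution for unbiasedness.

Fragments are single-end reads, or read pairs merged by
:func:`fragments_from_read_hits` (a fragment's score at a locus is the sum of
its mates' best scores there; mates hitting disjoint loci make the fragment
ambiguous across the union).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .family_synth import ParameterError
from .read_sim import fragment_id

__all__ = [
    "EmParams",
    "CountTable",
    "FAMILY_ID",
    "fragments_from_read_hits",
    "quantify_naive",
    "quantify_em",
    "quantify_family",
    "write_counts_tsv",
]

FAMILY_ID = "FAMILY"


@dataclass(frozen=True)
class EmParams:
    """MAP-EM hyperparameters.

    ``theta_prior`` is the total Dirichlet pseudo-count mass, split evenly
    over all annotated loci (alpha0 = theta_prior / n_loci); ``temperature``
    scales alignment-score differences into likelihood weights
    (q = exp((score - best)/temperature)); ``epsilon`` is the convergence
    tolerance on the max absolute change in mixing proportions.
    """

    max_iter: int = 200
    theta_prior: float = 200_000.0
    epsilon: float = 1e-6
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")
        if self.theta_prior <= 0:
            raise ParameterError("theta_prior must be > 0")
        if self.epsilon <= 0:
            raise ParameterError("epsilon must be > 0")
        if self.temperature <= 0:
            raise ParameterError("temperature must be > 0")


@dataclass
class CountTable:
    """Per-locus integer counts from one quantification method."""

    method: str  # "naive" | "em" | "family"
    counts: dict[str, int]
    unassigned: int
    total_input: int
    meta: dict = field(default_factory=dict)

    def total_counted(self) -> int:
        return sum(self.counts.values())


FragmentHits = Mapping[str, Sequence[tuple[str, float]]]


def _norm_hits(hits) -> list[tuple[str, float]]:
    """Accept AlignmentHit objects or (locus_id, score) tuples."""
    out = []
    for h in hits:
        if isinstance(h, tuple):
            out.append((h[0], float(h[1])))
        else:
            out.append((h.locus_id, float(h.score)))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def fragments_from_read_hits(hits_by_read: Mapping[str, Sequence]) -> dict[str, list[tuple[str, float]]]:
    """Merge per-read hits into per-fragment (locus, score) lists.

    Reads sharing a fragment id (same locus/start/strand/serial, different
    mate) are combined: per locus, each mate contributes its best score and
    the fragment score is the sum over mates with a hit there.
    """
    frags: dict[str, dict[str, float]] = {}
    for read_id, hits in hits_by_read.items():
        fid = fragment_id(read_id)
        scores = frags.setdefault(fid, {})
        per_locus: dict[str, float] = {}
        for locus_id, score in _norm_hits(hits):
            if locus_id not in per_locus:
                per_locus[locus_id] = score
        for locus_id, score in per_locus.items():
            scores[locus_id] = scores.get(locus_id, 0.0) + score
    return {
        fid: sorted(scores.items(), key=lambda t: (-t[1], t[0]))
        for fid, scores in frags.items()
    }


def quantify_naive(
    hits_by_fragment: FragmentHits,
    tie_policy: str = "random",
    seed: int = 0,
) -> CountTable:
    """Best-hit counting: one locus per fragment.

    Top-score ties go to a uniformly random tied locus (``tie_policy=
    "random"``, seeded) or to the lexicographically first (``"first"``).
    Fragments without hits are tallied as unassigned.
    """
    if tie_policy not in ("random", "first"):
        raise ParameterError(f"unknown tie_policy {tie_policy!r}")
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    unassigned = 0
    total = 0
    for fid in sorted(hits_by_fragment):
        total += 1
        hits = _norm_hits(hits_by_fragment[fid])
        if not hits:
            unassigned += 1
            continue
        best = hits[0][1]
        tied = [lid for lid, s in hits if s == best]
        if len(tied) == 1 or tie_policy == "first":
            chosen = tied[0]
        else:
            chosen = tied[int(rng.integers(len(tied)))]
        counts[chosen] = counts.get(chosen, 0) + 1
    return CountTable("naive", counts, unassigned, total, {"tie_policy": tie_policy})


def _em_log_posterior(pi, q_rows, alpha0) -> float:
    ll = sum(float(np.log((pi[cols] * q).sum())) for cols, q in q_rows)
    return ll + alpha0 * float(np.log(pi).sum())


def quantify_em(
    hits_by_fragment: FragmentHits,
    loci: Sequence[str],
    em: EmParams = EmParams(),
    seed: int = 0,
) -> CountTable:
    """MAP-EM reassignment of multi-mapping fragments.

    E-step: responsibilities r(f,t) proportional to pi(t) * q(f,t) with
    q(f,t) = exp((score(f,t) - best_score(f)) / temperature).  M-step: MAP
    update pi(t) proportional to sum_f r(f,t) + alpha0, alpha0 =
    theta_prior / n_loci over all annotated loci.  Iterates until the max
    change in pi drops below epsilon or ``max_iter``; final counts assign
    each fragment to its argmax-responsibility locus, exact ties to the
    lexicographically smallest locus id.  Deterministic; ``seed`` is unused
    under the default deterministic tie policy and kept for interface parity.
    """
    loci = list(loci)
    if not loci:
        raise ParameterError("loci must be non-empty")
    alpha0 = em.theta_prior / len(loci)

    frag_ids = sorted(hits_by_fragment)
    active: set[str] = set()
    norm: dict[str, list[tuple[str, float]]] = {}
    for fid in frag_ids:
        hits = _norm_hits(hits_by_fragment[fid])
        norm[fid] = hits
        active.update(lid for lid, _ in hits)
    unknown = active - set(loci)
    if unknown:
        raise ParameterError(f"hits reference unannotated loci: {sorted(unknown)}")

    total = len(frag_ids)
    if not active:
        return CountTable(
            "em", {}, total, total, {"iterations": 0, "converged": True}
        )

    cols = sorted(active)  # lexicographic column order -> argmax tie-break
    col_of = {lid: t for t, lid in enumerate(cols)}
    T = len(cols)

    assigned_fids = [fid for fid in frag_ids if norm[fid]]
    q_rows: list[tuple[np.ndarray, np.ndarray]] = []
    for fid in assigned_fids:
        hits = norm[fid]
        best = hits[0][1]
        idx = np.array([col_of[lid] for lid, _ in hits], dtype=np.int64)
        q = np.exp(
            (np.array([s for _, s in hits]) - best) / em.temperature
        )
        q_rows.append((idx, q))

    pi = np.full(T, 1.0 / T)
    converged = False
    log_post_trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, em.max_iter + 1):
        log_post_trace.append(_em_log_posterior(pi, q_rows, alpha0))
        nt = np.zeros(T)
        for idx, q in q_rows:
            r = pi[idx] * q
            nt[idx] += r / r.sum()
        pi_new = (nt + alpha0) / (nt.sum() + alpha0 * T)
        delta = float(np.max(np.abs(pi_new - pi)))
        pi = pi_new
        if delta < em.epsilon:
            converged = True
            break
    log_post_trace.append(_em_log_posterior(pi, q_rows, alpha0))

    counts: dict[str, int] = {}
    for (idx, q), fid in zip(q_rows, assigned_fids):
        r = pi[idx] * q
        order = np.argsort(idx)  # ensure ties resolve to smallest locus id
        chosen = idx[order][int(np.argmax(r[order]))]
        lid = cols[chosen]
        counts[lid] = counts.get(lid, 0) + 1
    unassigned = total - len(assigned_fids)
    return CountTable(
        "em",
        counts,
        unassigned,
        total,
        {
            "iterations": n_iter,
            "converged": converged,
            "log_posterior": log_post_trace,
            "pi": dict(zip(cols, pi.tolist())),
        },
    )


def quantify_family(hits_by_fragment: FragmentHits) -> CountTable:
    """Family-level total: fragments with at least one accepted hit."""
    total = len(hits_by_fragment)
    family_total = sum(1 for hits in hits_by_fragment.values() if len(hits))
    return CountTable(
        "family", {FAMILY_ID: family_total}, total - family_total, total
    )


def write_counts_tsv(tables: Iterable[CountTable], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("method\tlocus_id\tcount\n")
        for table in tables:
            for lid in sorted(table.counts):
                fh.write(f"{table.method}\t{lid}\t{table.counts[lid]}\n")
            fh.write(f"{table.method}\tUNASSIGNED\t{table.unassigned}\n")
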