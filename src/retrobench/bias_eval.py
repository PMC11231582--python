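"""Quantification-bias metrics and statistical comparisons.

Given the ground-truth number of fragments simulated from each locus
("assigned") and the number a quantification strategy credited to it
("mapped"), this module computes the per-locus percent error, the
mapped/assigned fold change with its false-regulation call, family-level
recovery, and the rank statistics (Mann-Whitney U, Spearman rho) used to
compare methods, read lengths and age strata.

Definitions:

* percent error = |assigned - mapped| / assigned * 100
* fold change = mapped / assigned; a locus is called falsely upregulated when
  the fold change is > 1.1 and falsely downregulated when < 0.9 (the
  boundaries themselves count as unchanged).
* family recovery = 100 * (fragments assigned to any family locus) /
  (fragments simulated).
* age groups: young < 10 MY, intermediate 10-20 MY (inclusive), old > 20 MY.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UndefinedStatisticError",
    "percent_error",
    "fold_change_class",
    "family_recovery",
    "assign_age_group",
    "mann_whitney_u",
    "spearman_rho",
    "BiasReport",
    "build_report",
]

FOLD_UP = 1.1
FOLD_DOWN = 0.9

#: locus_id used for the family-level aggregate row.
FAMILY_ID = "FAMILY"


class UndefinedStatisticError(ValueError):
    """A metric's denominator is zero or a statistic is undefined."""


def percent_error(assigned: int, mapped: int) -> float:
    """|assigned - mapped| / assigned * 100.  Requires assigned > 0."""
    if assigned <= 0:
        raise UndefinedStatisticError("percent error undefined for assigned == 0")
    return abs(assigned - mapped) / assigned * 100.0


def fold_change_class(assigned: int, mapped: int) -> tuple[float, str]:
    """Fold change mapped/assigned and its regulation call.

    Returns (fold_change, class) with class in {"up", "down", "unchanged"};
    the thresholds are strict, so exactly 0.9 or 1.1 is "unchanged".
    """
    if assigned <= 0:
        raise UndefinedStatisticError("fold change undefined for assigned == 0")
    fold = mapped / assigned
    if fold > FOLD_UP:
        cls = "up"
    elif fold < FOLD_DOWN:
        cls = "down"
    else:
        cls = "unchanged"
    return fold, cls


def family_recovery(family_total: int, total_simulated: int) -> float:
    """Percentage of simulated fragments recovered at the family level."""
    if total_simulated <= 0:
        raise UndefinedStatisticError("family recovery undefined for zero input")
    return 100.0 * family_total / total_simulated


def assign_age_group(age_my: float) -> str:
    """Age-stratum call: young < 10 MY, intermediate 10-20 MY, old > 20 MY."""
    if age_my <= 0:
        raise UndefinedStatisticError("age must be positive")
    if age_my < 10.0:
        return "young"
    if age_my <= 20.0:
        return "intermediate"
    return "old"


def mann_whitney_u(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test.

    Exact enumeration p-value for small tie-free samples (both n <= 8),
    otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise UndefinedStatisticError("samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def spearman_rho(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation with tie-averaged ranks, two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise UndefinedStatisticError("samples must have equal length")
    if x.size < 3:
        raise UndefinedStatisticError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise UndefinedStatisticError("rank correlation undefined for constant input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class BiasReport:
    """Per-locus bias rows plus a per-method summary block.

    ``per_locus`` has one row per (locus_id, method) for a single profile run:
    assigned, mapped, percent_error (NaN and flagged where assigned == 0),
    fold_change, regulation_class, age_my, age_group, element_class.  The
    family method contributes a single FAMILY row.
    """

    profile: str
    per_locus: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def method_rows(self, method: str, simulated_only: bool = True) -> pd.DataFrame:
        df = self.per_locus[self.per_locus["method"] == method]
        if simulated_only:
            df = df[df["simulated"] & (df["locus_id"] != FAMILY_ID)]
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.per_locus.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def write_summary_tsv(self, path: str | Path) -> None:
        rows = []
        for method, block in self.summary.items():
            for key, value in block.items():
                rows.append({"method": method, "statistic": key, "value": value})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def _summarize_method(df: pd.DataFrame) -> dict:
    pe = df["percent_error"].to_numpy(dtype=float)
    out = {
        "n_loci": int(df.shape[0]),
        "median_percent_error": float(np.median(pe)),
        "min_percent_error": float(np.min(pe)),
        "max_percent_error": float(np.max(pe)),
        "n_up": int((df["regulation_class"] == "up").sum()),
        "n_down": int((df["regulation_class"] == "down").sum()),
    }
    for cls, key in (("up", "up_fold"), ("down", "down_fold")):
        sub = df[df["regulation_class"] == cls]["fold_change"]
        if len(sub):
            out[f"{key}_min"] = float(sub.min())
            out[f"{key}_max"] = float(sub.max())
    for group in ("young", "intermediate", "old"):
        sub = df[df["age_group"] == group]["percent_error"]
        if len(sub):
            out[f"median_percent_error_{group}"] = float(np.median(sub))
    ages = df["age_my"].to_numpy(dtype=float)
    if np.unique(ages).size > 2 and np.unique(pe).size > 1:
        rho, p = spearman_rho(pe, ages)
        out["spearman_rho_vs_age"] = rho
        out["spearman_p_vs_age"] = p
    return out


def build_report(
    truth: Mapping[str, int],
    tables: Iterable,
    loci: Sequence,
    profile: str = "run",
) -> BiasReport:
    """Assemble the per-locus bias table and summary for one profile run.

    ``truth`` maps locus_id -> fragments simulated (simulated loci only);
    ``tables`` are CountTable objects from the quantify module; ``loci`` are
    LocusSpec-like objects carrying locus_id, age_my, age_group,
    element_class, simulated.  Single-assignment tables whose total_input
    disagrees with the truth total raise a consistency error.
    """
    loci = list(loci)
    known = {getattr(loc, "locus_id") for loc in loci}
    missing = set(truth) - known
    if missing:
        raise ValueError(f"truth loci missing from annotation: {sorted(missing)}")
    total_simulated = int(sum(truth.values()))

    rows: list[dict] = []
    for table in tables:
        method = table.method
        if method == "family":
            family_total = int(table.counts.get(FAMILY_ID, sum(table.counts.values())))
            fold, cls = fold_change_class(total_simulated, family_total)
            rows.append(
                dict(
                    profile=profile,
                    method=method,
                    locus_id=FAMILY_ID,
                    assigned=total_simulated,
                    mapped=family_total,
                    percent_error=percent_error(total_simulated, family_total),
                    fold_change=fold,
                    regulation_class=cls,
                    age_my=np.nan,
                    age_group=".",
                    element_class=".",
                    simulated=True,
                    flagged=False,
                )
            )
            continue
        if table.total_input != total_simulated:
            raise ValueError(
                f"{method} table total_input {table.total_input} != "
                f"simulated total {total_simulated}"
            )
        for loc in loci:
            lid = loc.locus_id
            assigned = int(truth.get(lid, 0))
            mapped = int(table.counts.get(lid, 0))
            if assigned > 0:
                pe = percent_error(assigned, mapped)
                fold, cls = fold_change_class(assigned, mapped)
                flagged = False
            else:  # annotation-only locus: denominator undefined, keep row
                pe, fold, cls, flagged = np.nan, np.nan, ".", True
            rows.append(
                dict(
                    profile=profile,
                    method=method,
                    locus_id=lid,
                    assigned=assigned,
                    mapped=mapped,
                    percent_error=pe,
                    fold_change=fold,
                    regulation_class=cls,
                    age_my=loc.age_my,
                    age_group=loc.age_group,
                    element_class=loc.element_class,
                    simulated=loc.simulated,
                    flagged=flagged,
                )
            )

    per_locus = pd.DataFrame(rows)
    report = BiasReport(profile=profile, per_locus=per_locus)

    methods = [m for m in per_locus["method"].unique() if m != "family"]
    for method in methods:
        df = report.method_rows(method)
        report.summary[method] = _summarize_method(df)
    fam = per_locus[per_locus["method"] == "family"]
    if len(fam):
        report.summary["family"] = {
            "family_total": int(fam["mapped"].iloc[0]),
            "total_simulated": total_simulated,
            "recovery_percent": family_recovery(
                int(fam["mapped"].iloc[0]), total_simulated
            ),
        }
    if "naive" in report.summary and "em" in report.summary:
        pe_naive = report.method_rows("naive")["percent_error"].to_numpy()
        pe_em = report.method_rows("em")["percent_error"].to_numpy()
        u, p = mann_whitney_u(pe_naive, pe_em)
        report.summary["naive"]["mann_whitney_u_vs_em"] = u
        report.summary["naive"]["mann_whitney_p_vs_em"] = p
    return report
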