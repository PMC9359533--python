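"""Library-complexity estimation from read fractions and colony counts.

The estimator treats the sequencing run as a survey of the colony pool: a
variant's read fraction f_i, multiplied by the number of
transformation-positive colonies N_c, reconstructs how many colonies that
variant plausibly occupies.  This quantity — the variant's *cumulative
probability of occurrence* (CPO, cumulative because synonymous reads are
summed at the peptide level) — is >= 1 for variants almost certainly
present and acts as a presence probability below 1.  The library's unique
variant count is then estimated as

    N_hat = #{i : CPO_i >= 1} + round(sum of CPO_i over CPO_i < 1)

with half-away-from-zero rounding.  By construction sum(CPO) = N_c, so the
estimate never exceeds N_c + 1.  The estimator inherits any error in the
colony count (an imaging-based user input) proportionally; no correction
for colony miscounts or plasmid copy-number effects is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import pandas as pd

from .template_alignment import INSUFFICIENTLY_RANDOMIZED, RANDOMIZED

__all__ = ["compute_cpo", "partition_by_cpo", "estimate_library_variants",
           "round_half_away_from_zero", "summarize_library",
           "CpoGroupSummary", "LibrarySummary"]


def round_half_away_from_zero(x: float) -> int:
    """Round to the nearest integer, halves away from zero (4.5 -> 5)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def compute_cpo(variants: pd.DataFrame, colony_count: int) -> pd.DataFrame:
    """Fill the ``cpo`` column: cpo_i = fraction_i * colony_count.

    No rounding is applied at this stage.  Returns a copy.
    """
    if colony_count < 1:
        raise ValueError(f"colony_count must be >= 1, got {colony_count}")
    out = variants.copy()
    out["cpo"] = out["fraction"] * float(colony_count)
    return out


def partition_by_cpo(variants: pd.DataFrame
                     ) -> Tuple[pd.DataFrame, pd.DataFrame, float, float]:
    """Split variants at CPO >= 1 (inclusive) vs CPO < 1.

    Returns ``(group_ge1, group_lt1, cpo_sum_ge1, cpo_sum_lt1)``.
    """
    ge1 = variants[variants["cpo"] >= 1.0]
    lt1 = variants[variants["cpo"] < 1.0]
    return ge1, lt1, float(ge1["cpo"].sum()), float(lt1["cpo"].sum())


def estimate_library_variants(n_ge1: int, cpo_sum_lt1: float) -> int:
    """Estimated unique variants: confident count plus residual colony mass.

    ``n_ge1`` variants are counted as certainly present; the summed CPO of
    the sub-unity group approximates the number of colonies its members
    occupy and, since colonies almost always carry a single variant, the
    number of additional variants.  Rounding is half-away-from-zero.
    """
    if n_ge1 < 0 or cpo_sum_lt1 < 0:
        raise ValueError("estimate_library_variants requires non-negative inputs")
    return n_ge1 + round_half_away_from_zero(cpo_sum_lt1)


@dataclass(frozen=True)
class CpoGroupSummary:
    """CPO bookkeeping for one set of variants (whole library or one class)."""

    n_reads: int
    n_reads_ge1: int
    n_reads_lt1: int
    n_unique: int
    n_unique_ge1: int
    n_unique_lt1: int
    cpo_total: float
    cpo_ge1: float
    cpo_lt1: float
    estimated_variants: int


def _summarize_group(variants: pd.DataFrame) -> CpoGroupSummary:
    ge1, lt1, sum_ge1, sum_lt1 = partition_by_cpo(variants)
    return CpoGroupSummary(
        n_reads=int(variants["read_count"].sum()),
        n_reads_ge1=int(ge1["read_count"].sum()),
        n_reads_lt1=int(lt1["read_count"].sum()),
        n_unique=int(len(variants)),
        n_unique_ge1=int(len(ge1)),
        n_unique_lt1=int(len(lt1)),
        cpo_total=float(variants["cpo"].sum()),
        cpo_ge1=sum_ge1,
        cpo_lt1=sum_lt1,
        estimated_variants=estimate_library_variants(len(ge1), sum_lt1),
    )


@dataclass(frozen=True)
class LibrarySummary:
    """Machine-readable per-library characteristics table.

    Percentages are stored at full precision; render with the precision
    you need.  ``passed_pct`` is relative to ``total_reads``; class read
    percentages are relative to the passed-read count R.
    """

    library: str
    colony_count: int
    total_reads: int
    mean_read_length: float
    passed_reads: int
    passed_pct: float
    overall: CpoGroupSummary
    insufficiently_randomized: CpoGroupSummary
    randomized: CpoGroupSummary
    insufficient_read_pct: float
    randomized_read_pct: float
    fail_reason_counts: Dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> Dict:
        def group(g: CpoGroupSummary) -> Dict:
            return {
                "reads": g.n_reads,
                "reads_cpo_ge1": g.n_reads_ge1,
                "reads_cpo_lt1": g.n_reads_lt1,
                "unique": g.n_unique,
                "unique_cpo_ge1": g.n_unique_ge1,
                "unique_cpo_lt1": g.n_unique_lt1,
                "cpo_total": g.cpo_total,
                "cpo_ge1": g.cpo_ge1,
                "cpo_lt1": g.cpo_lt1,
                "estimated_variants": g.estimated_variants,
            }

        return {
            "library": self.library,
            "colony_count": self.colony_count,
            "total_reads": self.total_reads,
            "mean_read_length": self.mean_read_length,
            "passed_reads": self.passed_reads,
            "passed_pct": self.passed_pct,
            "insufficient_read_pct": self.insufficient_read_pct,
            "randomized_read_pct": self.randomized_read_pct,
            "overall": group(self.overall),
            "insufficiently_randomized": group(self.insufficiently_randomized),
            "randomized": group(self.randomized),
            "fail_reason_counts": dict(self.fail_reason_counts),
        }

    def to_series(self) -> pd.Series:
        """Flat one-column view with characteristics-table row names."""
        d = self.to_dict()
        rows = {
            "Number of observed colonies": d["colony_count"],
            "Number of sequencing reads": d["total_reads"],
            "Mean read length (nt)": d["mean_read_length"],
            "Number of target region sequence reads (passed filters)":
                d["passed_reads"],
            "Target region reads, % of total": d["passed_pct"],
        }
        labels = {
            "overall": "", "insufficiently_randomized":
                "insufficiently randomized ", "randomized": "randomized "}
        for key, prefix in labels.items():
            g = d[key]
            rows[f"Number of {prefix}reads encoding peptides with CPO >= 1"] = \
                g["reads_cpo_ge1"]
            rows[f"Number of {prefix}reads encoding peptides with CPO < 1"] = \
                g["reads_cpo_lt1"]
            rows[f"Number of unique {prefix}protein coding sequences"] = \
                g["unique"]
            rows[f"Number of unique {prefix}protein coding sequences with CPO >= 1"] = \
                g["unique_cpo_ge1"]
            rows[f"Number of unique {prefix}protein coding sequences with CPO < 1"] = \
                g["unique_cpo_lt1"]
            rows[f"CPO of all unique {prefix}protein coding sequences"] = \
                g["cpo_total"]
            rows[f"CPO of unique {prefix}protein coding sequences with CPO >= 1"] = \
                g["cpo_ge1"]
            rows[f"CPO of unique {prefix}protein coding sequences with CPO < 1"] = \
                g["cpo_lt1"]
            rows[f"Estimated number of unique {prefix}protein coding sequences "
                 "within library"] = g["estimated_variants"]
        rows["Insufficiently randomized reads, % of passed"] = \
            d["insufficient_read_pct"]
        rows["Randomized reads, % of passed"] = d["randomized_read_pct"]
        return pd.Series(rows, name=self.library)


def percent(numerator: float, denominator: float) -> float:
    """Percentage with a zero-denominator guard (returns 0.0)."""
    return 100.0 * numerator / denominator if denominator else 0.0


def summarize_library(variants: pd.DataFrame, colony_count: int,
                      total_reads: int, mean_read_length: float,
                      library: str = "library",
                      fail_reason_counts: Optional[Dict[str, int]] = None
                      ) -> LibrarySummary:
    """Assemble the per-library characteristics summary.

    ``variants`` must carry ``read_count``, ``fraction``, ``bias_class``
    and ``cpo`` (see :func:`compute_cpo`).  Class-level read counts are
    derived from the variant table (majority bias class), so per-class
    quantities sum exactly to the overall ones.
    """
    overall = _summarize_group(variants)
    by_class = {
        label: _summarize_group(variants[variants["bias_class"] == label])
        for label in (INSUFFICIENTLY_RANDOMIZED, RANDOMIZED)
    }
    passed = overall.n_reads
    return LibrarySummary(
        library=library,
        colony_count=colony_count,
        total_reads=total_reads,
        mean_read_length=mean_read_length,
        passed_reads=passed,
        passed_pct=percent(passed, total_reads),
        overall=overall,
        insufficiently_randomized=by_class[INSUFFICIENTLY_RANDOMIZED],
        randomized=by_class[RANDOMIZED],
        insufficient_read_pct=percent(
            by_class[INSUFFICIENTLY_RANDOMIZED].n_reads, passed),
        randomized_read_pct=percent(by_class[RANDOMIZED].n_reads, passed),
        fail_reason_counts=dict(fail_reason_counts or {}),
    )
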