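"""Accuracy metrics, recovery rates, CDS-count distributions, and
composition-profile comparison.

Per-class accuracy at a taxonomic rank follows the adapted sensitivity /
specificity convention used for binning benchmarks: for class *i*

    Sn_i = TP_i / (TP_i + FN_i + U_i)        Sp_i = TP_i / (TP_i + FP_i)

where U_i counts fragments of class *i* that were unclassified or whose
assignment has no node at the rank (assigned "above" it).  Sp_i is
undefined (None) when nothing was predicted as class *i*.

Recovery rates are reported the way the per-sample tables print them:
truncated (not rounded) to one decimal; aggregate summaries (mean ± SD)
round half-up instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .adjacency_binning import Assignment
from .taxonomy import TaxonomyTree, project_to_rank


@dataclass
class ConfusionCounts:
    """TP/FP/FN/U fragment counts for one class at one rank."""

    rank: str
    class_taxon: int
    tp: int = 0
    fp: int = 0
    fn: int = 0
    u: int = 0


@dataclass
class CompositionProfile:
    """Fragment counts per phylotype at one rank; excluded = reads without
    a node at the rank (unclassified or assigned above it)."""

    rank: str
    counts: dict = field(default_factory=dict)
    n_excluded: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def confusion_counts(
    assignments: Iterable[Assignment],
    truth: Mapping[str, int],
    tree: TaxonomyTree,
    rank: str,
) -> dict[int, ConfusionCounts]:
    """Per-class confusion counts at a rank.

    Both the truth taxon and the assigned taxon are projected to the rank.
    Truth fragments with no node at the rank are outside the evaluation
    universe at that rank.  Reads present in ``truth`` but absent from
    ``assignments`` count as unclassified.
    """
    by_read = {a.read_id: a for a in assignments}
    counts: dict[int, ConfusionCounts] = {}

    def cell(taxon: int) -> ConfusionCounts:
        return counts.setdefault(taxon, ConfusionCounts(rank=rank, class_taxon=taxon))

    for read_id, truth_taxon in truth.items():
        if truth_taxon not in tree:
            raise KeyError(f"truth taxon {truth_taxon} for read {read_id!r} not in tree")
        truth_class = project_to_rank(tree, truth_taxon, rank)
        if truth_class is None:
            continue
        a = by_read.get(read_id)
        if a is None or not a.assigned:
            cell(truth_class).u += 1
            continue
        pred_class = project_to_rank(tree, a.taxon_id, rank)
        if pred_class is None:
            cell(truth_class).u += 1
        elif pred_class == truth_class:
            cell(truth_class).tp += 1
        else:
            cell(truth_class).fn += 1
            cell(pred_class).fp += 1
    return counts


def sensitivity(c: ConfusionCounts) -> Optional[float]:
    """TP / (TP + FN + U); None when the class is absent from the truth."""
    denom = c.tp + c.fn + c.u
    return c.tp / denom if denom else None


def specificity(c: ConfusionCounts) -> Optional[float]:
    """TP / (TP + FP); None when nothing was predicted as this class."""
    denom = c.tp + c.fp
    return c.tp / denom if denom else None


def accuracy_table(
    assignments: Iterable[Assignment],
    truth: Mapping[str, int],
    tree: TaxonomyTree,
    ranks: Sequence[str] = ("phylum", "order", "family", "genus"),
) -> pd.DataFrame:
    """Per-rank, per-class Sn/Sp as a tidy DataFrame (fractions in [0, 1])."""
    assignments = list(assignments)
    rows = []
    for rank in ranks:
        for taxon, c in sorted(confusion_counts(assignments, truth, tree, rank).items()):
            rows.append(
                {
                    "rank": rank,
                    "class_taxon": taxon,
                    "tp": c.tp,
                    "fp": c.fp,
                    "fn": c.fn,
                    "u": c.u,
                    "sn": sensitivity(c),
                    "sp": specificity(c),
                }
            )
    return pd.DataFrame(
        rows, columns=["rank", "class_taxon", "tp", "fp", "fn", "u", "sn", "sp"]
    )


def macro_average(table: pd.DataFrame, rank: str) -> dict[str, Optional[float]]:
    """Unweighted mean Sn/Sp over classes at one rank.

    Sn averages classes present in the truth; Sp averages classes with at
    least one prediction (undefined Sp values are excluded, not zeroed).
    """
    sub = table[table["rank"] == rank]
    sn_vals = sub["sn"].dropna()
    sp_vals = sub["sp"].dropna()
    return {
        "sn": float(sn_vals.mean()) if len(sn_vals) else None,
        "sp": float(sp_vals.mean()) if len(sp_vals) else None,
    }


# ---------------------------------------------------------------------------
# Recovery rates and summary formatting
# ---------------------------------------------------------------------------

def truncate_to_decimals(x: float, decimals: int = 1) -> float:
    """Truncate toward zero at the given number of decimals."""
    scale = 10**decimals
    return math.trunc(x * scale) / scale


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (so 0.05 -> 0.1, unlike banker's rounding)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def recovery_rate(n_assigned: int, n_discarded: int) -> float:
    """Percentage of discarded fragments re-assigned, truncated to one decimal.

    Per-sample rates print truncated: 2050/7078 = 28.96% reports as 28.9.
    """
    if n_discarded <= 0:
        raise ValueError("n_discarded must be > 0")
    if n_assigned > n_discarded:
        raise ValueError("n_assigned cannot exceed n_discarded")
    if isinstance(n_assigned, (int, np.integer)) and isinstance(
        n_discarded, (int, np.integer)
    ):
        # exact integer arithmetic avoids float truncation artifacts
        return (1000 * int(n_assigned) // int(n_discarded)) / 10
    return truncate_to_decimals(100.0 * n_assigned / n_discarded, 1)


def summarize_rates(rates: Sequence[float], decimals: int = 1) -> tuple[float, float]:
    """Mean ± sample SD of a set of per-sample rates, rounded half-up."""
    arr = np.asarray(rates, dtype=float)
    mean = round_half_up(float(arr.mean()), decimals)
    sd = round_half_up(float(arr.std(ddof=1)), decimals) if len(arr) > 1 else 0.0
    return mean, sd


# ---------------------------------------------------------------------------
# CDS-count distribution
# ---------------------------------------------------------------------------

CDS_BINS = ("0", "1", "2", "3+")


def cds_count_distribution(loci_per_read: Mapping[str, int]) -> pd.DataFrame:
    """Distribution of candidate-CDS counts per read in bins {0, 1, 2, 3+}.

    Percentages are rounded half-up to one decimal; counts sum to the total.
    """
    binned = {b: 0 for b in CDS_BINS}
    for n in loci_per_read.values():
        if n >= 3:
            binned["3+"] += 1
        else:
            binned[str(n)] += 1
    total = sum(binned.values())
    rows = [
        {
            "cds_count": b,
            "reads": binned[b],
            "percent": round_half_up(100.0 * binned[b] / total, 1) if total else 0.0,
        }
        for b in CDS_BINS
    ]
    return pd.DataFrame(rows)


def fraction_with_two_or_more(distribution: pd.DataFrame) -> float:
    """Percent of reads carrying >= 2 candidate CDSs (exact, not re-rounded)."""
    total = int(distribution["reads"].sum())
    if total == 0:
        return 0.0
    multi = int(distribution.loc[distribution["cds_count"].isin(["2", "3+"]), "reads"].sum())
    return 100.0 * multi / total


# ---------------------------------------------------------------------------
# Composition profiles and their comparison
# ---------------------------------------------------------------------------

def composition_profile(
    assignments: Iterable[Assignment], tree: TaxonomyTree, rank: str
) -> CompositionProfile:
    """Counts of assigned reads per taxon at a rank.

    Unclassified reads, and assigned reads whose lineage has no node at the
    rank, are excluded from the profile (tallied in ``n_excluded``).
    """
    profile = CompositionProfile(rank=rank)
    for a in assignments:
        if not a.assigned:
            profile.n_excluded += 1
            continue
        taxon = project_to_rank(tree, a.taxon_id, rank)
        if taxon is None:
            profile.n_excluded += 1
        else:
            profile.counts[taxon] = profile.counts.get(taxon, 0) + 1
    return profile


def pool_rare_phylotypes(
    a: CompositionProfile,
    b: CompositionProfile,
    threshold: int = 5,
    mode: str = "both",
    other_label: str = "other",
) -> tuple[CompositionProfile, CompositionProfile]:
    """Combine rare phylotypes into a shared "other" category.

    The category set becomes the union of both profiles' taxa (absent
    categories count 0).  With ``mode="both"`` (default) a taxon is pooled
    when its count is below ``threshold`` in *both* profiles; ``"either"``
    pools when it is rare in at least one.  Totals are preserved exactly.
    """
    if a.rank != b.rank:
        raise ValueError(f"profiles at different ranks: {a.rank!r} vs {b.rank!r}")
    if mode not in ("both", "either"):
        raise ValueError(f"unknown pooling mode {mode!r}")
    categories = set(a.counts) | set(b.counts)
    pooled_a = CompositionProfile(rank=a.rank, n_excluded=a.n_excluded)
    pooled_b = CompositionProfile(rank=b.rank, n_excluded=b.n_excluded)
    for cat in categories:
        ca, cb = a.counts.get(cat, 0), b.counts.get(cat, 0)
        rare = (ca < threshold and cb < threshold) if mode == "both" else (
            ca < threshold or cb < threshold
        )
        if rare:
            pooled_a.counts[other_label] = pooled_a.counts.get(other_label, 0) + ca
            pooled_b.counts[other_label] = pooled_b.counts.get(other_label, 0) + cb
        else:
            pooled_a.counts[cat] = ca
            pooled_b.counts[cat] = cb
    return pooled_a, pooled_b


def pearson_compare(a: CompositionProfile, b: CompositionProfile) -> Optional[float]:
    """Pearson product-moment correlation of two aligned composition profiles.

    Requires identical category sets (pool first), at least two categories
    and nonzero variance in both count vectors; otherwise returns None with
    a warning.
    """
    cats_a, cats_b = set(a.counts), set(b.counts)
    if cats_a != cats_b:
        raise ValueError(
            "profiles must share an identical category set; pool_rare_phylotypes first"
        )
    cats = sorted(cats_a, key=str)
    if len(cats) < 2:
        warnings.warn("fewer than 2 shared categories: correlation undefined")
        return None
    x = np.array([a.counts[c] for c in cats], dtype=float)
    y = np.array([b.counts[c] for c in cats], dtype=float)
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance in a profile: correlation undefined")
        return None
    r, _ = stats.pearsonr(x, y)
    return float(r)
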