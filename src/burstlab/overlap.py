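"""Background-normalized gene-set overlap and expression-variability statistics.

Comparing gene sets derived from different assays requires a common
background: a gene can only overlap if both assays could have reported it.
:func:`normalize_background` intersects the two universes and filters the
sets to it; :func:`hypergeometric_overlap` then tests the overlap against
the hypergeometric null (draw |A| genes from the universe, count hits in
B).  :func:`cv_by_group` compares expression variability (coefficient of
variation across cells) between two gene groups with a Welch t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSet",
    "OverlapResult",
    "normalize_background",
    "hypergeometric_overlap",
    "overlap_test",
    "cv_by_group",
]


def _clean(symbols) -> list[str]:
    """Uppercased, de-duplicated gene symbols with input order preserved."""
    seen, out = set(), []
    for s in symbols:
        u = str(s).strip().upper()
        if u and u not in seen:
            seen.add(u)
            out.append(u)
    return out


@dataclass
class GeneSet:
    """A named gene set with the universe it was drawn from.

    Symbols are case-folded to upper case on construction; members must lie
    within the universe.
    """

    name: str
    members: list
    universe: list

    def __post_init__(self):
        self.members = _clean(self.members)
        self.universe = _clean(self.universe)
        missing = set(self.members) - set(self.universe)
        if missing:
            raise ValueError(
                f"{len(missing)} members of {self.name!r} are not in its universe "
                f"(e.g. {sorted(missing)[:3]})"
            )


@dataclass
class OverlapResult:
    n_universe: int
    n_set_a: int
    n_set_b: int
    n_overlap: int
    overlap_percent: float  # % of set A
    p_value: float  # upper tail, P(X >= n_overlap)

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def normalize_background(set_a: GeneSet, set_b: GeneSet) -> tuple[GeneSet, GeneSet, dict]:
    """Harmonize two gene sets onto the intersection of their universes.

    Returns the filtered sets plus a report of member/universe counts
    before and after.  An empty intersected universe is an error.
    """
    common = set(set_a.universe) & set(set_b.universe)
    if not common:
        raise ValueError("the two universes share no genes")
    new_a = GeneSet(set_a.name, [g for g in set_a.members if g in common],
                    [g for g in set_a.universe if g in common])
    new_b = GeneSet(set_b.name, [g for g in set_b.members if g in common],
                    [g for g in set_b.universe if g in common])
    report = {
        "n_universe_a_before": len(set_a.universe),
        "n_universe_b_before": len(set_b.universe),
        "n_universe_after": len(common),
        "n_set_a_before": len(set_a.members),
        "n_set_a_after": len(new_a.members),
        "n_set_b_before": len(set_b.members),
        "n_set_b_after": len(new_b.members),
    }
    return new_a, new_b, report


def hypergeometric_overlap(
    n_universe: int, n_set_a: int, n_set_b: int, n_overlap: int
) -> OverlapResult:
    """Upper-tail hypergeometric test of a gene-set overlap.

    With X ~ Hypergeometric(universe ``n_universe``, successes ``n_set_b``,
    draws ``n_set_a``), reports p = P(X >= n_overlap) — the observed value
    is included, the standard enrichment convention — and the overlap as a
    percentage of set A.
    """
    if min(n_universe, n_set_a, n_set_b, n_overlap) < 0:
        raise ValueError("counts must be non-negative")
    if max(n_set_a, n_set_b) > n_universe:
        raise ValueError("set larger than universe")
    if n_overlap > min(n_set_a, n_set_b):
        raise ValueError("overlap exceeds a set size")
    if n_set_a == 0:
        raise ValueError("set A is empty; overlap percentage undefined")
    # sf(k-1) = P(X >= k)
    p = float(stats.hypergeom.sf(n_overlap - 1, n_universe, n_set_b, n_set_a))
    return OverlapResult(
        n_universe=n_universe,
        n_set_a=n_set_a,
        n_set_b=n_set_b,
        n_overlap=n_overlap,
        overlap_percent=100.0 * n_overlap / n_set_a,
        p_value=p,
    )


def overlap_test(set_a: GeneSet, set_b: GeneSet, normalize: bool = True) -> OverlapResult:
    """End-to-end overlap test: background-normalize, count, test."""
    if normalize:
        set_a, set_b, _ = normalize_background(set_a, set_b)
    n_overlap = len(set(set_a.members) & set(set_b.members))
    return hypergeometric_overlap(
        len(set_a.universe), len(set_a.members), len(set_b.members), n_overlap
    )


def cv_by_group(
    counts: pd.DataFrame,
    group_a: list,
    group_b: list,
    normalize_depth: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Coefficient of variation per gene and a two-group Welch t-test.

    ``counts`` is a genes x cells table (index = gene symbols).  Per gene,
    CV = sample sd (ddof=1) / mean across cells; genes with zero mean are
    excluded (reported in the summary) rather than given infinite CV.  The
    two groups must be disjoint, lie within the matrix and keep >= 2 genes
    each after filtering.  With ``normalize_depth`` the matrix columns are
    first scaled to the median cell total (library-size normalization).

    Returns the per-gene CV table (mean, sd, cv, group) and a summary dict
    with the Welch t statistic and two-sided p-value.
    """
    counts = pd.DataFrame(counts)
    if (counts.to_numpy() < 0).any():
        raise ValueError("count matrix must be non-negative")
    counts.index = [str(g).strip().upper() for g in counts.index]
    ga, gb = _clean(group_a), _clean(group_b)
    if set(ga) & set(gb):
        raise ValueError("groups must be disjoint")
    for name, g in (("A", ga), ("B", gb)):
        missing = set(g) - set(counts.index)
        if missing:
            raise ValueError(f"group {name} genes absent from matrix: {sorted(missing)[:3]}")

    mat = counts.copy()
    if normalize_depth:
        totals = mat.sum(axis=0)
        mat = mat * (totals.median() / totals)

    rows = []
    n_zero_mean = 0
    for label, genes in (("A", ga), ("B", gb)):
        sub = mat.loc[genes]
        means = sub.mean(axis=1)
        sds = sub.std(axis=1, ddof=1)
        for g in genes:
            if means[g] <= 0:
                n_zero_mean += 1
                continue
            rows.append(
                {"gene": g, "mean": float(means[g]), "sd": float(sds[g]),
                 "cv": float(sds[g] / means[g]), "group": label}
            )
    table = pd.DataFrame(rows)
    cv_a = table.loc[table["group"] == "A", "cv"].to_numpy()
    cv_b = table.loc[table["group"] == "B", "cv"].to_numpy()
    if len(cv_a) < 2 or len(cv_b) < 2:
        raise ValueError("each group needs >= 2 genes with positive mean")
    t, p = stats.ttest_ind(cv_a, cv_b, equal_var=False)
    summary = {
        "t_statistic": float(t),
        "p_value": float(p),
        "n_group_a": int(len(cv_a)),
        "n_group_b": int(len(cv_b)),
        "mean_cv_a": float(cv_a.mean()),
        "mean_cv_b": float(cv_b.mean()),
        "n_zero_mean_excluded": n_zero_mean,
        "normalize_depth": normalize_depth,
    }
    return table, summary
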