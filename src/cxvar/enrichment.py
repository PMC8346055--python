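"""Contingency tables, the exact test and ratio statistics for variant
domain-enrichment comparisons.

The unit of counting throughout is the unique variant (not alleles or
carriers). The two-sided Fisher exact p-value is computed by
point-probability ordering — the sum of hypergeometric probabilities of
all tables with the observed margins whose probability does not exceed
the observed table's — evaluated in log space. Group conservation-score
comparisons use the Student pooled-variance unpaired t-test. No
multiple-testing correction is applied: each comparison is reported at
its own per-comparison p-value.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "TTestResult",
    "PARTITIONS",
    "contingency_counts",
    "fisher_exact_two_sided",
    "distribution_ratio",
    "normalized_density",
    "unpaired_t_test",
    "enrichment_test",
]

# partition name -> (in-partition predicate column setup, restriction)
PARTITIONS = ("structured_vs_unstructured", "pore_vs_nonpore", "CL_vs_CT", "sector_vs_nonsector")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = cohort (disease, population) and columns =
    (in-partition, out-partition)."""

    a: int  # disease, in
    b: int  # disease, out
    c: int  # population, in
    d: int  # population, out

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError(f"counts must be non-negative integers, got {v}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def row(self, cohort: str) -> tuple[int, int]:
        if cohort == "disease":
            return self.a, self.b
        if cohort == "population":
            return self.c, self.d
        raise ValueError(f"unknown cohort {cohort!r}")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def contingency_counts(annotated: pd.DataFrame, partition: str) -> ContingencyTable2x2:
    """Build the 2x2 cohort-by-partition table of unique variant counts.

    ``annotated`` is the per-variant annotation frame from
    :func:`cxvar.domains.locate_variants` (optionally with a boolean
    ``sector`` column for the sector partition). The pore/non-pore
    partition is restricted to structured-domain variants and CL/CT to
    unstructured ones, matching how the comparisons are defined.
    """
    if partition == "structured_vs_unstructured":
        sub = annotated
        in_flag = sub["structured"].astype(bool)
    elif partition == "pore_vs_nonpore":
        sub = annotated[annotated["structured"]]
        in_flag = sub["pore"].astype(bool)
    elif partition == "CL_vs_CT":
        sub = annotated[~annotated["structured"].astype(bool)]
        in_flag = sub["domain"] == "CL"
    elif partition == "sector_vs_nonsector":
        if "sector" not in annotated.columns:
            raise ValueError("sector partition requires a 'sector' annotation column")
        sub = annotated
        in_flag = sub["sector"].astype(bool)
    else:
        raise ValueError(f"unknown partition {partition!r}")
    is_disease = sub["cohort"] == "disease"
    return ContingencyTable2x2(
        a=int((is_disease & in_flag).sum()),
        b=int((is_disease & ~in_flag).sum()),
        c=int((~is_disease & in_flag).sum()),
        d=int((~is_disease & ~in_flag).sum()),
    )


def _log_hypergeom_pmf(k: np.ndarray, r1: int, r2: int, c1: int) -> np.ndarray:
    """log P(X=k) for the table [[k, r1-k], [c1-k, r2-c1+k]] under fixed margins."""
    n = r1 + r2
    return (
        gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
        + gammaln(r2 + 1) - gammaln(c1 - k + 1) - gammaln(r2 - (c1 - k) + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )


def fisher_exact_two_sided(table: ContingencyTable2x2, rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher exact p-value by point-probability ordering.

    Enumerates the hypergeometric support in log space and sums the
    probabilities of all tables at most as probable as the observed one;
    ``rel_tol`` guards against float ties at the observed probability.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    if table.total == 0:
        return 1.0
    k = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    logp = _log_hypergeom_pmf(k, r1, r2, c1)
    log_obs = _log_hypergeom_pmf(np.array([a]), r1, r2, c1)[0]
    keep = logp <= log_obs + math.log1p(rel_tol)
    p = float(np.exp(logsumexp(logp[keep])))
    return min(p, 1.0)


def distribution_ratio(table: ContingencyTable2x2, cohort: str) -> float:
    """In-partition / out-partition count ratio for one cohort.

    Returns 0.0 when the in-count is zero and ``math.inf`` (flagged
    undefined by callers) when the out-count is zero.
    """
    inside, outside = table.row(cohort)
    if outside == 0:
        return math.inf if inside > 0 else math.nan
    return inside / outside


def normalized_density(counts: dict[str, int], lengths: dict[str, int]) -> dict[str, float]:
    """Variants per residue: count / number of residues, per domain or partition."""
    out = {}
    for key, n in counts.items():
        length = lengths.get(key)
        if length is None or length <= 0:
            raise ValueError(f"missing or non-positive length for {key!r}")
        out[key] = n / length
    return out


@dataclass
class EnrichmentResult:
    """One cohort-by-partition comparison: table, exact p, ratios, densities."""

    partition: str
    table: ContingencyTable2x2
    p_value: float
    ratio_disease: float
    ratio_population: float
    density_disease: dict[str, float]
    density_population: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "partition": self.partition,
            "table": {"a": self.table.a, "b": self.table.b,
                      "c": self.table.c, "d": self.table.d},
            "p_value": self.p_value,
            "ratio_disease": None if math.isnan(self.ratio_disease) else self.ratio_disease,
            "ratio_population": None if math.isnan(self.ratio_population) else self.ratio_population,
            "density_disease": self.density_disease,
            "density_population": self.density_population,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)


_PARTITION_SIDES = {
    "structured_vs_unstructured": ("structured", "unstructured"),
    "pore_vs_nonpore": ("pore", "nonpore"),
    "CL_vs_CT": ("CL", "CT"),
    "sector_vs_nonsector": ("sector", "nonsector"),
}


def enrichment_test(
    annotated: pd.DataFrame, partition: str, partition_lengths: dict[str, int] | None = None
) -> EnrichmentResult:
    """Full comparison for one partition: counts, Fisher p, ratios and
    (when partition residue counts are given) length-normalized densities."""
    table = contingency_counts(annotated, partition)
    in_name, out_name = _PARTITION_SIDES[partition]
    densities_d, densities_p = {}, {}
    if partition_lengths is not None:
        lengths = {in_name: partition_lengths[in_name], out_name: partition_lengths[out_name]}
        densities_d = normalized_density(
            {in_name: table.a, out_name: table.b}, lengths)
        densities_p = normalized_density(
            {in_name: table.c, out_name: table.d}, lengths)
    return EnrichmentResult(
        partition=partition,
        table=table,
        p_value=fisher_exact_two_sided(table),
        ratio_disease=distribution_ratio(table, "disease"),
        ratio_population=distribution_ratio(table, "population"),
        density_disease=densities_d,
        density_population=densities_p,
    )


@dataclass
class TTestResult:
    mean1: float
    mean2: float
    n1: int
    n2: int
    t: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "mean1": self.mean1, "mean2": self.mean2,
            "n1": self.n1, "n2": self.n2,
            "t": self.t, "df": self.df, "p_value": self.p_value,
        }


def unpaired_t_test(group1, group2) -> TTestResult:
    """Student pooled-variance two-sided t-test (equal variances assumed).

    Welch's correction is deliberately not applied, matching the plain
    "unpaired t-test" convention of common GUI statistics packages. Two
    groups with zero variance and equal means return t=0, p=1.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least two observations")
    df = g1.size + g2.size - 2
    if np.ptp(g1) == 0 and np.ptp(g2) == 0 and g1[0] == g2[0]:
        return TTestResult(float(g1.mean()), float(g2.mean()),
                           g1.size, g2.size, 0.0, df, 1.0)
    t, p = stats.ttest_ind(g1, g2, equal_var=True)
    return TTestResult(float(g1.mean()), float(g2.mean()),
                       g1.size, g2.size, float(t), df, float(p))
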