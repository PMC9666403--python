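"""Composition-proportional null, chi-squared goodness of fit, exact Fisher
enrichment scan.

The null model: if N missense variants land uniformly at random on the
protein, the expected count in category i is E_i = f_i * N, where f_i is the
fraction of residues in that category. A chi-squared goodness-of-fit test
compares observed per-category counts against these expectations; a
two-sided Fisher exact test per (phenotype, category) cell asks whether the
variants of one cortical-malformation phenotype concentrate in one category
beyond the residue composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .structure import CompositionTable
from .variants import PHENOTYPES, MutationTable, tabulate


@dataclass
class GoodnessOfFitResult:
    observed: dict[str, int]
    expected: dict[str, float]
    statistic: float
    df: int
    p_value: float
    n: int


@dataclass
class FisherResult:
    phenotype: str
    category: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    background_mode: str
    warning: str | None = None


@dataclass
class EnrichmentReport:
    rows: list[FisherResult]
    gof: GoodnessOfFitResult | None
    alpha: float = 0.05
    background_mode: str = "residues"
    n_total: int = 0
    n_labeled: int = 0
    n_dropped: int = 0
    adjusted_p: dict[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    def significant(self) -> list[FisherResult]:
        return [r for r in self.rows if r.p_value < self.alpha]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            (a, b), (c, d) = r.table
            rec = {
                "phenotype": r.phenotype,
                "category": r.category,
                "a": a, "b": b, "c": c, "d": d,
                "p_value": r.p_value,
                "significant": r.p_value < self.alpha,
                "warning": r.warning or "",
            }
            if self.adjusted_p is not None:
                rec["p_bh"] = self.adjusted_p[(r.phenotype, r.category)]
            recs.append(rec)
        return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# Chi-squared machinery
# ---------------------------------------------------------------------------


def expected_counts(
    composition: CompositionTable, n: int
) -> dict[str, float]:
    """E_i = f_i * N, kept as reals (rounding is display-only)."""
    if n < 0:
        raise ValueError("N must be non-negative")
    return {
        c: composition.fraction_of(c) * n for c in composition.categories
    }


def chi2_sf(x: float, df: int) -> float:
    """Upper-tail probability of the chi-squared distribution."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if x < 0:
        raise ValueError("statistic must be non-negative")
    return float(sps.chi2.sf(x, df))


def chi2_quantile(q: float, df: int) -> float:
    """Lower-tail quantile (inverse CDF) of the chi-squared distribution."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(sps.chi2.ppf(q, df))


def chi2_gof(
    observed: Mapping[str, int] | Sequence[int],
    expected: Mapping[str, float] | Sequence[float],
) -> GoodnessOfFitResult:
    """Chi-squared goodness of fit of observed counts to expected reals.

    statistic = sum (O_i - E_i)^2 / E_i, df = k - 1. A zero expected cell is
    a hard error (merge categories instead).
    """
    if isinstance(observed, Mapping):
        cats = list(observed)
        obs = np.array([observed[c] for c in cats], dtype=float)
        if isinstance(expected, Mapping):
            exp = np.array([expected[c] for c in cats], dtype=float)
        else:
            exp = np.asarray(list(expected), dtype=float)
    else:
        obs = np.asarray(list(observed), dtype=float)
        exp = (
            np.array(list(expected.values()), dtype=float)
            if isinstance(expected, Mapping)
            else np.asarray(list(expected), dtype=float)
        )
        cats = [str(i) for i in range(len(obs))]
    if len(obs) != len(exp):
        raise ValueError("observed/expected length mismatch")
    if np.any(exp <= 0):
        raise ValueError(
            "expected count of zero; merge sparse categories before testing"
        )
    stat = float(np.sum((obs - exp) ** 2 / exp))
    df = len(obs) - 1
    if df < 1:
        raise ValueError("need at least two categories")
    return GoodnessOfFitResult(
        observed={c: int(o) for c, o in zip(cats, obs)},
        expected=dict(zip(cats, exp)),
        statistic=stat,
        df=df,
        p_value=chi2_sf(stat, df),
        n=int(obs.sum()),
    )


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p by the point-probability rule.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed that of the observed table
    (relative tolerance 1e-12 on the comparison). A degenerate table (a zero
    row or column margin) has p = 1 by convention.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cells must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    rv = sps.hypergeom(n, c1, r1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    return min(1.0, p)


def fisher_one_sided_greater(table) -> float:
    """One-sided (enrichment) Fisher exact p: P(X >= a) under the margins."""
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    return float(min(1.0, sps.hypergeom(n, c1, r1).sf(a - 1)))


# ---------------------------------------------------------------------------
# Enrichment scan
# ---------------------------------------------------------------------------


def enrichment_scan(
    table: MutationTable,
    label_of,
    composition: CompositionTable,
    mode: str = "residues",
    alpha: float = 0.05,
    phenotypes: Sequence[str] = PHENOTYPES,
    adjust: bool = False,
    sided: str = "two",
    gof: bool = True,
    _fisher_cache: dict | None = None,
) -> EnrichmentReport:
    """Fisher enrichment scan per (phenotype, category) plus a global GOF.

    For each clinical phenotype m and category s the 2x2 table is, in the
    default ``residues`` background mode::

        [[x_ms, n_m - x_ms], [R_s, R_tot - R_s]]

    where x_ms counts phenotype-m variants in category s, n_m is the
    phenotype total (clinically labeled records only), and R_s the number of
    residues in the category. Mode ``expected`` replaces the residue row by
    rounded expected variant counts; ``other_mutations`` uses the variants
    of all other phenotypes. The global chi-squared goodness of fit is
    computed over ALL records, including those without clinical data.
    """
    if mode not in ("residues", "expected", "other_mutations"):
        raise ValueError(f"unknown background mode {mode!r}")
    if sided not in ("two", "greater"):
        raise ValueError(f"unknown sidedness {sided!r}")
    categories = list(composition.categories)
    labeled = table.clinically_labeled()
    per_pheno: dict[str, dict[str, int]] = {}
    for m in phenotypes:
        sub = MutationTable([r for r in labeled.records if r.phenotype == m])
        per_pheno[m] = tabulate(sub, label_of, categories=categories)
    all_labeled = tabulate(labeled, label_of, categories=categories)

    r_tot = composition.total_residues
    n_lab = labeled.count
    test = fisher_two_sided if sided == "two" else fisher_one_sided_greater
    cache = _fisher_cache if _fisher_cache is not None else {}

    rows: list[FisherResult] = []
    for m in phenotypes:
        n_m = sum(per_pheno[m].values())
        for s in categories:
            x = per_pheno[m][s]
            if mode == "residues":
                bg = (composition.count_of(s), r_tot - composition.count_of(s))
            elif mode == "expected":
                e = expected_counts(composition, n_lab)[s]
                bg = (round(e), n_lab - round(e))
            else:
                xo = all_labeled[s] - x
                bg = (xo, (n_lab - n_m) - xo)
            t = ((x, n_m - x), bg)
            warning = None
            if n_m == 0:
                p, warning = 1.0, "empty phenotype group"
            else:
                key = (sided, t)
                p = cache.get(key)
                if p is None:
                    p = test(t)
                    cache[key] = p
            rows.append(
                FisherResult(
                    phenotype=m, category=s, table=t, p_value=p,
                    background_mode=mode, warning=warning,
                )
            )

    gof_res = None
    if gof:
        observed_all = tabulate(table, label_of, categories=categories)
        gof_res = chi2_gof(
            observed_all, expected_counts(composition, table.count)
        )

    adjusted = None
    if adjust:
        from statsmodels.stats.multitest import multipletests

        pvals = [r.p_value for r in rows]
        _, p_bh, _, _ = multipletests(pvals, method="fdr_bh")
        adjusted = {
            (r.phenotype, r.category): float(q) for r, q in zip(rows, p_bh)
        }

    return EnrichmentReport(
        rows=rows,
        gof=gof_res,
        alpha=alpha,
        background_mode=mode,
        n_total=table.count,
        n_labeled=n_lab,
        n_dropped=table.n_dropped(),
        adjusted_p=adjusted,
    )


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------


def format_p(p: float, floor: float = 0.005) -> str:
    """Two-decimal display with a "<0.01" floor below 0.005."""
    if p < floor:
        return "<0.01"
    return f"{p:.2f}"


def wide_report(report: EnrichmentReport) -> pd.DataFrame:
    """Categories as rows, phenotypes as columns, display-formatted p-values."""
    df = report.to_frame()
    wide = df.pivot(index="category", columns="phenotype", values="p_value")
    # preserve scan category order
    order = list(dict.fromkeys(r.category for r in report.rows))
    wide = wide.reindex(order)
    return wide.map(format_p)
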