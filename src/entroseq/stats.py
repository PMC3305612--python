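"""Cohort-level statistics on per-sequence relative-entropy results.

Works on a "cohort table": a pandas DataFrame with one row per sequence and
(at least) the columns ``id, dkl, douv, at_content, gc_content, length``
plus the metadata columns ``class, phylum, domain, species`` where an
analysis needs them.  :func:`entroseq.io.cohort_table` builds it.

The analyses mirror a standard comparative workflow:

* rank-sum (Mann-Whitney) comparisons of D_KL between sequence classes;
* OLS regression of log D_KL on AT content per class;
* class-specific size-vs-AT regressions, each with the transform that
  normalises that class's size distribution (sqrt for chromosomes, log for
  phages and plasmids, reciprocal for genomic islands);
* a combined untransformed model AT = a + b*D_KL + c*size + d*size^2 with
  incremental-R^2 decomposition;
* likelihood-ratio tests between nested linear models;
* phylum-factor and GC models of D_KL with an interaction check;
* a Welch unequal-variance t-test between domains;
* paired signed-rank comparison of matched gene sets (ortholog pairs).

No multiplicity correction is applied to the class-pair tests by default
(raw p-values are reported); pass ``holm=True`` for Holm-adjusted values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .signature import EntropyResult

__all__ = [
    "RegressionReport",
    "SIZE_TRANSFORMS",
    "compare_classes",
    "regress_dkl_on_at",
    "regress_size_on_at",
    "regress_at_on_dkl_and_size",
    "lrt_nested",
    "phylum_model",
    "welch_two_groups",
    "paired_gene_set_compare",
]

logger = logging.getLogger(__name__)

CLASS_ORDER = ("chromosome", "island", "phage", "plasmid")

#: response transform applied to sequence size, per class
SIZE_TRANSFORMS: dict[str, tuple[str, callable]] = {
    "chromosome": ("sqrt", np.sqrt),
    "phage": ("log", np.log),
    "plasmid": ("log", np.log),
    "island": ("reciprocal", lambda y: 1.0 / y),
}


@dataclass
class RegressionReport:
    """Summary of one fitted linear model."""

    model: str
    response_transform: str
    params: dict[str, float]
    pvalues: dict[str, float]
    r_squared: float
    n: int
    resid_std: float
    extra: dict[str, float] = field(default_factory=dict)

    def __str__(self) -> str:  # compact one-line rendering for run logs
        coefs = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return (f"{self.model} [{self.response_transform}] n={self.n} "
                f"R2={self.r_squared:.3f} ({coefs})")


def _require_columns(table: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns {missing}")


def _r2(fit) -> float:
    # a constant response has zero total SS; define R^2 = 0 there
    val = float(fit.rsquared)
    return val if np.isfinite(val) else 0.0


def _report(fit, model: str, transform: str, **extra) -> RegressionReport:
    return RegressionReport(
        model=model,
        response_transform=transform,
        params={k: float(v) for k, v in fit.params.items()},
        pvalues={k: float(v) for k, v in fit.pvalues.items()},
        r_squared=_r2(fit),
        n=int(fit.nobs),
        resid_std=float(np.sqrt(fit.mse_resid)) if fit.df_resid > 0 else 0.0,
        extra=extra,
    )


def compare_classes(table: pd.DataFrame, value: str = "dkl",
                    holm: bool = False) -> pd.DataFrame:
    """Two-sided rank-sum test of ``value`` for every unordered class pair.

    Classes with fewer than 5 members are excluded with a warning.  Returns
    one row per pair: medians, Mann-Whitney U, p-value and direction.
    """
    _require_columns(table, ("class", value))
    counts = table["class"].value_counts()
    usable = [c for c in counts.index if counts[c] >= 5]
    for c in counts.index.difference(usable):
        logger.warning("class %r has %d < 5 members; excluded", c, counts[c])
    if len(usable) < 2:
        raise ValueError("need >= 2 classes with >= 5 members each")
    usable = sorted(usable, key=lambda c: (CLASS_ORDER.index(c)
                                           if c in CLASS_ORDER else 99, c))
    rows = []
    for a, b in combinations(usable, 2):
        xa = table.loc[table["class"] == a, value].to_numpy()
        xb = table.loc[table["class"] == b, value].to_numpy()
        stat, p = sps.mannwhitneyu(xa, xb, alternative="two-sided")
        med_a, med_b = float(np.median(xa)), float(np.median(xb))
        direction = ">" if med_a > med_b else ("<" if med_a < med_b else "none")
        rows.append({"class_a": a, "class_b": b, "n_a": xa.size, "n_b": xb.size,
                     "median_a": med_a, "median_b": med_b,
                     "statistic": float(stat), "p_value": float(p),
                     "direction": direction})
    out = pd.DataFrame(rows)
    if holm:
        order = np.argsort(out["p_value"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p_value"].iloc[idx])
            adj[idx] = min(1.0, running)
        out["p_holm"] = adj
    return out


def regress_dkl_on_at(table: pd.DataFrame,
                      class_filter: str | None = None) -> RegressionReport:
    """OLS fit of ln(D_KL) on AT content; slope is negative on cohort-like data.

    Rows with D_KL = 0 are dropped (log undefined) with a warning.
    """
    _require_columns(table, ("dkl", "at_content"))
    df = table if class_filter is None else table[table["class"] == class_filter]
    zero = df["dkl"] <= 0
    if zero.any():
        logger.warning("dropping %d rows with dkl <= 0 from log fit",
                       int(zero.sum()))
        df = df[~zero]
    if len(df) < 10:
        raise ValueError(f"need >= 10 rows, have {len(df)}")
    df = df.assign(log_dkl=np.log(df["dkl"]))
    fit = smf.ols("log_dkl ~ at_content", data=df).fit()
    name = "ln(dkl) ~ at" + (f" [{class_filter}]" if class_filter else "")
    return _report(fit, name, "log")


def regress_size_on_at(table: pd.DataFrame, class_label: str) -> RegressionReport:
    """Class-specific transformed-size regression on AT content."""
    _require_columns(table, ("class", "length", "at_content"))
    if class_label not in SIZE_TRANSFORMS:
        raise ValueError(f"unknown class {class_label!r}; expected one of "
                         f"{sorted(SIZE_TRANSFORMS)}")
    tname, tfun = SIZE_TRANSFORMS[class_label]
    df = table[table["class"] == class_label]
    bad = df["length"] <= 0
    if bad.any():
        logger.warning("dropping %d rows with non-positive size", int(bad.sum()))
        df = df[~bad]
    if len(df) < 10:
        raise ValueError(f"need >= 10 rows of class {class_label!r}, have "
                         f"{len(df)}")
    df = df.assign(t_size=tfun(df["length"].astype(float)))
    fit = smf.ols("t_size ~ at_content", data=df).fit()
    return _report(fit, f"{tname}(size) ~ at [{class_label}]", tname)


def regress_at_on_dkl_and_size(table: pd.DataFrame,
                               class_filter: str | None = None,
                               ) -> RegressionReport:
    """Untransformed model AT = a + b*dkl + c*size + d*size^2.

    Size is centered before squaring to tame collinearity; coefficients are
    reported on the centered scale.  ``extra`` carries the incremental R^2
    of the size block alone and of adding dkl after size.
    """
    _require_columns(table, ("dkl", "at_content", "length"))
    df = table if class_filter is None else table[table["class"] == class_filter]
    if len(df) < 20:
        raise ValueError(f"need >= 20 rows, have {len(df)}")
    size_c = df["length"].astype(float) - df["length"].mean()
    df = df.assign(size_c=size_c, size_c2=size_c**2)
    full = smf.ols("at_content ~ dkl + size_c + size_c2", data=df).fit()
    size_only = smf.ols("at_content ~ size_c + size_c2", data=df).fit()
    name = "at ~ dkl + size + size^2" + (f" [{class_filter}]"
                                         if class_filter else "")
    return _report(full, name, "none",
                   r2_size_only=_r2(size_only),
                   r2_incremental_dkl=_r2(full) - _r2(size_only))


def _terms(formula: str) -> set[str]:
    rhs = formula.split("~", 1)[1]
    return {t.strip() for t in rhs.replace("+", "\n").splitlines()
            if t.strip() and t.strip() != "1"}


def lrt_nested(table: pd.DataFrame, full: str,
               reduced: str) -> tuple[float, float]:
    """Likelihood-ratio test between nested Gaussian linear models.

    ``full`` and ``reduced`` are patsy formulas fit by OLS on the same rows;
    2*(ll_full - ll_reduced) is referred to chi-square with df equal to the
    difference in fitted parameters.
    """
    if not _terms(reduced) <= _terms(full):
        raise ValueError("models are not nested: reduced terms "
                         f"{_terms(reduced)} not a subset of {_terms(full)}")
    fit_full = smf.ols(full, data=table).fit()
    fit_red = smf.ols(reduced, data=table).fit()
    if int(fit_full.nobs) != int(fit_red.nobs):
        raise ValueError("models were fit on different row sets")
    stat = 2.0 * (fit_full.llf - fit_red.llf)
    df = fit_full.df_model - fit_red.df_model
    if df <= 0:
        return max(float(stat), 0.0), 1.0
    return float(stat), float(sps.chi2.sf(stat, df))


def phylum_model(table: pd.DataFrame) -> dict[str, object]:
    """D_KL explained by phylum, by GC content, and by both.

    Expects one row per species (deduplicate upstream).  Returns the three
    R^2 values, the p-values of the phylum factor (F) and GC slope, and an
    F-test of the phylum x GC interaction on top of the additive model.
    """
    _require_columns(table, ("dkl", "phylum", "gc_content"))
    counts = table["phylum"].value_counts()
    usable = counts[counts >= 5].index
    if len(usable) < 2:
        raise ValueError("need >= 2 phyla with >= 5 members each")
    df = table[table["phylum"].isin(usable)]
    m_phy = smf.ols("dkl ~ C(phylum)", data=df).fit()
    m_gc = smf.ols("dkl ~ gc_content", data=df).fit()
    m_both = smf.ols("dkl ~ C(phylum) + gc_content", data=df).fit()
    m_inter = smf.ols("dkl ~ C(phylum) * gc_content", data=df).fit()
    f_inter = m_inter.compare_f_test(m_both)
    return {
        "r2_phylum": _r2(m_phy),
        "r2_gc": _r2(m_gc),
        "r2_combined": _r2(m_both),
        "p_phylum": float(m_phy.f_pvalue),
        "p_gc": float(m_gc.pvalues["gc_content"]),
        "interaction_F": float(f_inter[0]),
        "interaction_p": float(f_inter[1]),
        "n": int(m_both.nobs),
    }


def welch_two_groups(table: pd.DataFrame, grouping: str = "domain",
                     value: str = "dkl") -> tuple[float, float]:
    """Welch unequal-variance t-test of ``value`` between the two groups."""
    _require_columns(table, (grouping, value))
    groups = [g for _, g in table.groupby(grouping, observed=True)]
    if len(groups) != 2:
        raise ValueError(f"grouping {grouping!r} must define exactly 2 groups, "
                         f"found {len(groups)}")
    a, b = (g[value].to_numpy() for g in groups)
    if min(a.size, b.size) < 2:
        raise ValueError("both groups need >= 2 members")
    stat, p = sps.ttest_ind(a, b, equal_var=False)
    return float(stat), float(p)


def paired_gene_set_compare(set_a: list[EntropyResult],
                            set_b: list[EntropyResult],
                            pairing: dict[str, str]) -> pd.Series:
    """Paired signed-rank comparison of per-gene D_KL between matched sets.

    ``pairing`` maps ids in ``set_a`` to ids in ``set_b`` and must be a
    bijection between the two sets.  Returns a Series with the median
    within-pair difference (a - b), the Wilcoxon statistic, the two-sided
    p-value and the direction of the median difference.
    """
    by_a = {r.id: r for r in set_a}
    by_b = {r.id: r for r in set_b}
    bad = (sorted(set(pairing) ^ set(by_a))
           + sorted(set(pairing.values()) ^ set(by_b)))
    if bad:
        raise ValueError(f"pairing is not a bijection; offending ids: {bad}")
    diffs = np.array([by_a[a].dkl - by_b[b].dkl for a, b in pairing.items()])
    if np.all(diffs == 0):
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.wilcoxon(diffs, alternative="two-sided")
    med = float(np.median(diffs))
    direction = "a>b" if med > 0 else ("a<b" if med < 0 else "none")
    return pd.Series({"n_pairs": len(diffs), "median_diff": med,
                      "statistic": float(stat), "p_value": float(p),
                      "direction": direction})
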