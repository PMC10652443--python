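"""Cohort-level statistics: mutation-frequency tables and group comparisons.

Proportions (per-gene mutation frequencies, MSI-H rates, PD-L1 positivity
categories) are compared with a chi-square test on the 2x2 table, falling
back to Fisher's exact test when any expected cell count is below 5.
Continuous biomarkers (TMB) are compared with Welch's t-test for two groups
(pooled-variance Student t behind a flag) or one-way ANOVA for more, and
summarized as mean +/- SEM.  Gene-level p-value lists can be adjusted with
Benjamini-Hochberg; both raw and adjusted values are reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

SITES = ("duodenum", "jejunum", "ileum")

#: Conventional 22C3 PD-L1 TPS bins: negative, low-positive, high-positive.
DEFAULT_PDL1_BINS = (1.0, 50.0)


@dataclass
class PatientRecord:
    """One profiled patient: metadata plus derived molecular summaries."""

    patient_id: str
    sex: str
    age: float
    site: str
    mutated_genes: frozenset[str] = field(default_factory=frozenset)
    msi_class: str = "MSS"
    tmb_per_mb: float = 0.0
    pdl1_tps: Optional[float] = None

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValidationError(f"{self.patient_id}: unknown site {self.site!r}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"{self.patient_id}: unknown sex {self.sex!r}")
        if self.pdl1_tps is not None and not (0.0 <= self.pdl1_tps <= 100.0):
            raise ValidationError(
                f"{self.patient_id}: pdl1_tps {self.pdl1_tps} outside [0,100]"
            )
        self.mutated_genes = frozenset(self.mutated_genes)


@dataclass(frozen=True)
class CohortComparison:
    """Per-gene mutation-frequency contrast between two groups."""

    gene: str
    group_a: str
    group_b: str
    a_mut: int
    a_total: int
    b_mut: int
    b_total: int
    p_value: float
    test_used: str
    p_adjusted: float = float("nan")

    @property
    def freq_a(self) -> float:
        return self.a_mut / self.a_total

    @property
    def freq_b(self) -> float:
        return self.b_mut / self.b_total


def frequency_table(
    cohort: Sequence[PatientRecord], genes: Sequence[str]
) -> pd.DataFrame:
    """Per-gene mutated-patient counts and percentages for a cohort.

    Percentages are 100*count/total, rounded to two decimals for reporting;
    genes mutated in no patient report 0.
    """
    if not cohort:
        raise ValidationError("empty cohort")
    total = len(cohort)
    rows = []
    for gene in genes:
        count = sum(1 for p in cohort if gene in p.mutated_genes)
        rows.append(
            {
                "gene": gene,
                "count": count,
                "total": total,
                "percentage": round(100.0 * count / total, 2),
            }
        )
    return pd.DataFrame(rows)


def categorical_breakdown(cohort: Sequence[PatientRecord], field: str) -> pd.DataFrame:
    """Cohort composition by ``sex``, ``site`` or the dichotomy ``age_ge_60``."""
    if not cohort:
        raise ValidationError("empty cohort")
    if field == "sex":
        levels = [p.sex for p in cohort]
    elif field == "site":
        levels = [p.site for p in cohort]
    elif field == "age_ge_60":
        levels = ["age>=60" if p.age >= 60 else "age<60" for p in cohort]
    else:
        raise ValidationError(f"unknown breakdown field {field!r}")
    total = len(levels)
    counts = pd.Series(levels).value_counts().sort_index()
    return pd.DataFrame(
        {
            "level": counts.index,
            "count": counts.values,
            "percentage": np.round(100.0 * counts.values / total, 2),
        }
    )


def compare_proportions(
    a_mut: int, a_total: int, b_mut: int, b_total: int
) -> tuple[str, float, float]:
    """Compare two proportions on the 2x2 table.

    Chi-square without continuity correction, unless any expected cell count
    falls below 5, in which case the two-sided Fisher exact test is used.
    Returns (test_used, statistic, p_value); Fisher reports the odds ratio as
    its statistic.
    """
    for name, mut, tot in (("a", a_mut, a_total), ("b", b_mut, b_total)):
        if tot <= 0:
            raise ValidationError(f"group {name} has zero total")
        if not (0 <= mut <= tot):
            raise ValidationError(f"group {name}: {mut} mutated of {tot}")
    table = np.array(
        [[a_mut, a_total - a_mut], [b_mut, b_total - b_mut]], dtype=float
    )
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    n = table.sum()
    expected = row @ col / n
    if (expected < 5).any() or (col == 0).any():
        stat, p = sps.fisher_exact(table.astype(int))
        return "fisher", float(stat), float(p)
    stat = float(((table - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(stat, df=1))
    return "chi-square", stat, p


def mean_sem(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error of the mean (sd with n-1 denominator / sqrt(n))."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValidationError("mean +/- SEM needs at least 2 values")
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size))


def compare_means(
    groups: Sequence[Sequence[float]], welch: bool = True
) -> dict:
    """Compare group means: Welch/Student t for two groups, one-way ANOVA beyond.

    Returns a dict with test_used, statistic, p_value and per-group
    (mean, sem, n) summaries.
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, arr in enumerate(arrays):
        if arr.size < 2:
            raise ValidationError(f"group {i} has fewer than 2 values")
    summaries = [
        {"mean": m, "sem": s, "n": int(a.size)}
        for a, (m, s) in ((a, mean_sem(a)) for a in arrays)
    ]
    if len(arrays) == 2:
        if np.array_equal(arrays[0], arrays[1]):
            # degenerate: identical samples; scipy returns nan when variance is 0
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.ttest_ind(arrays[0], arrays[1], equal_var=not welch)
        test = "welch-t" if welch else "student-t"
    else:
        stat, p = sps.f_oneway(*arrays)
        test = "anova"
    return {
        "test_used": test,
        "statistic": float(stat),
        "p_value": float(p),
        "groups": summaries,
    }


def adjust_pvalues(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order preserved."""
    p = list(p_values)
    if not p:
        return []
    if any((v < 0 or v > 1 or not math.isfinite(v)) for v in p):
        raise ValidationError("p-values must lie in [0,1]")
    return [float(v) for v in multipletests(p, method="fdr_bh")[1]]


def compare_gene_frequencies(
    genes: Sequence[str],
    counts_a: Mapping[str, int],
    total_a: int,
    counts_b: Mapping[str, int],
    total_b: int,
    label_a: str = "A",
    label_b: str = "B",
    adjust: bool = True,
) -> list[CohortComparison]:
    """Per-gene proportion tests between two cohorts given mutated counts.

    The second cohort can be any external frequency table (e.g. a published
    cohort's per-gene counts); only counts and totals are needed.
    """
    raw: list[CohortComparison] = []
    for gene in genes:
        am = int(counts_a.get(gene, 0))
        bm = int(counts_b.get(gene, 0))
        test, _, p = compare_proportions(am, total_a, bm, total_b)
        raw.append(
            CohortComparison(
                gene=gene, group_a=label_a, group_b=label_b,
                a_mut=am, a_total=total_a, b_mut=bm, b_total=total_b,
                p_value=p, test_used=test,
            )
        )
    if adjust and raw:
        adj = adjust_pvalues([c.p_value for c in raw])
        raw = [
            CohortComparison(**{**c.__dict__, "p_adjusted": a})
            for c, a in zip(raw, adj)
        ]
    return raw


def compare_cohorts_by_group(
    cohort: Sequence[PatientRecord],
    genes: Sequence[str],
    group_of,
    label_a: str,
    label_b: str,
    adjust: bool = True,
) -> list[CohortComparison]:
    """Per-gene contrasts between two patient groups defined by ``group_of``."""
    a = [p for p in cohort if group_of(p) == label_a]
    b = [p for p in cohort if group_of(p) == label_b]
    if not a or not b:
        raise ValidationError("both groups must be non-empty")
    counts_a = {g: sum(1 for p in a if g in p.mutated_genes) for g in genes}
    counts_b = {g: sum(1 for p in b if g in p.mutated_genes) for g in genes}
    return compare_gene_frequencies(
        genes, counts_a, len(a), counts_b, len(b),
        label_a=label_a, label_b=label_b, adjust=adjust,
    )


def _pdl1_category(tps: float, bins: tuple[float, float]) -> str:
    lo, hi = bins
    if tps < lo:
        return f"TPS<{lo:g}"
    if tps < hi:
        return f"{lo:g}<=TPS<{hi:g}"
    return f"TPS>={hi:g}"


def biomarker_site_comparison(
    cohort: Sequence[PatientRecord],
    merge_jejunum_ileum: bool = False,
    pdl1_bins: tuple[float, float] = DEFAULT_PDL1_BINS,
    welch: bool = True,
) -> dict:
    """Compare immunotherapy biomarkers across anatomic sites.

    Produces, per represented site: MSI-H proportion (pairwise proportion
    tests plus an overall test), TMB level (Welch t / ANOVA on per-patient
    mut/Mb), and PD-L1 TPS categories (chi-square/Fisher on the R x C table
    via pairwise 2x2 category collapses for the two-group case, chi-square on
    the full table otherwise).  Sites with no patients are dropped with a
    warning.
    """
    if not cohort:
        raise ValidationError("empty cohort")
    site_of = (
        (lambda p: "duodenum" if p.site == "duodenum" else "jejunum/ileum")
        if merge_jejunum_ileum
        else (lambda p: p.site)
    )
    groups: dict[str, list[PatientRecord]] = {}
    for p in cohort:
        groups.setdefault(site_of(p), []).append(p)
    order = (
        ["duodenum", "jejunum/ileum"] if merge_jejunum_ileum else list(SITES)
    )
    present = [s for s in order if groups.get(s)]
    dropped = [s for s in order if not groups.get(s)]
    for s in dropped:
        warnings.warn(f"site {s!r} has no patients and is dropped", stacklevel=2)
    if len(present) < 2:
        raise ValidationError("need patients at >= 2 sites to compare")

    report: dict = {"sites": {}, "dropped_sites": dropped}
    for s in present:
        ps = groups[s]
        msih = sum(1 for p in ps if p.msi_class == "MSI-H")
        report["sites"][s] = {
            "n": len(ps),
            "msi_h": msih,
            "msi_h_proportion": msih / len(ps),
        }

    # MSI-H proportions: pairwise 2x2 tests, plus an overall test when >2 sites
    pairwise = {}
    for i, sa in enumerate(present):
        for sb in present[i + 1:]:
            ga, gb = groups[sa], groups[sb]
            test, stat, p = compare_proportions(
                report["sites"][sa]["msi_h"], len(ga),
                report["sites"][sb]["msi_h"], len(gb),
            )
            pairwise[f"{sa} vs {sb}"] = {
                "test_used": test, "statistic": stat, "p_value": p,
            }
    report["msi_h"] = {"pairwise": pairwise}
    if len(present) > 2:
        table = np.array(
            [
                [report["sites"][s]["msi_h"],
                 report["sites"][s]["n"] - report["sites"][s]["msi_h"]]
                for s in present
            ]
        )
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
        report["msi_h"]["overall"] = {
            "test_used": "chi-square", "statistic": float(chi2),
            "p_value": float(p),
        }

    # TMB: mean +/- SEM per site, Welch t or ANOVA
    tmb_groups = [[p.tmb_per_mb for p in groups[s]] for s in present]
    if all(len(g) >= 2 for g in tmb_groups):
        tmb_cmp = compare_means(tmb_groups, welch=welch)
        for s, summ in zip(present, tmb_cmp["groups"]):
            report["sites"][s]["tmb"] = summ
        report["tmb"] = {
            k: tmb_cmp[k] for k in ("test_used", "statistic", "p_value")
        }
    else:
        report["tmb"] = {"test_used": None, "note": "a site has <2 patients"}

    # PD-L1: TPS categories compared across sites
    cats = sorted(
        {_pdl1_category(0.0, pdl1_bins), _pdl1_category(pdl1_bins[0], pdl1_bins),
         _pdl1_category(pdl1_bins[1], pdl1_bins)}
    )
    counts = np.zeros((len(present), 3), dtype=int)
    cat_index = {
        _pdl1_category(v, pdl1_bins): j
        for j, v in enumerate([0.0, pdl1_bins[0], pdl1_bins[1]])
    }
    for i, s in enumerate(present):
        for p in groups[s]:
            if p.pdl1_tps is not None:
                counts[i, cat_index[_pdl1_category(p.pdl1_tps, pdl1_bins)]] += 1
    report["pdl1"] = {"categories": list(cat_index), "counts": counts.tolist()}
    nonzero_cols = counts.sum(axis=0) > 0
    trimmed = counts[:, nonzero_cols]
    if trimmed.shape[1] >= 2 and (trimmed.sum(axis=1) > 0).all():
        expected = sps.contingency.expected_freq(trimmed)
        if (expected < 5).any() and trimmed.shape == (2, 2):
            stat, p = sps.fisher_exact(trimmed)
            report["pdl1"].update(
                {"test_used": "fisher", "statistic": float(stat),
                 "p_value": float(p)}
            )
        else:
            chi2, p, _, _ = sps.chi2_contingency(trimmed, correction=False)
            report["pdl1"].update(
                {"test_used": "chi-square", "statistic": float(chi2),
                 "p_value": float(p)}
            )
    else:
        report["pdl1"]["test_used"] = None
    return report


def comparisons_to_frame(comparisons: Sequence[CohortComparison]) -> pd.DataFrame:
    """Flatten CohortComparison records to a report table."""
    return pd.DataFrame(
        [
            {
                "gene": c.gene,
                "group_a": c.group_a,
                "group_b": c.group_b,
                "a_mut": c.a_mut,
                "a_total": c.a_total,
                "b_mut": c.b_mut,
                "b_total": c.b_total,
                "freq_a": c.freq_a,
                "freq_b": c.freq_b,
                "p_value": c.p_value,
                "p_adjusted": c.p_adjusted,
                "test_used": c.test_used,
            }
            for c in comparisons
        ]
    )


def plot_frequency_bars(freq: pd.DataFrame, path: str) -> None:
    """Basic per-gene mutation-frequency barplot (PNG/SVG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(freq)), 3.5))
    ax.bar(freq["gene"], freq["percentage"], color="#4c72b0")
    ax.set_ylabel("patients mutated (%)")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
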