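"""Per-gene translational efficiencies and range-narrowing diagnostics.

TE for a gene is the ratio of its summarized intensity in a polysomal pool
(HP, or LP) to its intensity in total RNA, per biological project.  Two
pooled summaries are maintained:

* mode A ("pooled"): mean TE per strain over all projects' worth of data —
  by default the ratio of mean intensities (switchable to the mean of
  per-project TEs);
* mode B ("ratio"): the mutant/wild-type TE ratio computed separately per
  project, then averaged, with its SEM and a two-tailed pooled-variance
  Student t-test of the per-project TE triples.

Diagnostics quantify genome-wide narrowing of the TE range in the mutant:
MA-plot M variances, the log-log regression slope of wild-type on mutant
TEs, counts of genes beyond fixed TE thresholds, and the fraction of
high-TE genes whose efficiency drops in the mutant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from polyte.normalize import ExpressionMatrix

__all__ = [
    "MAStats",
    "RegressionFit",
    "ThresholdCounts",
    "GeneClassification",
    "compute_te",
    "gene_ttest",
    "classify_genes",
    "tabulate_thresholds",
    "dependency_fractions",
    "ma_stats",
    "te_regression",
    "group_mean_ratio",
]


@dataclass
class MAStats:
    """Per-gene M (log2 ratio) and A (mean log2 intensity) for one array
    pair, with the sample variance of M."""

    m: np.ndarray
    a: np.ndarray
    variance_m: float


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    n_genes: int


@dataclass
class ThresholdCounts:
    """Numbers of genes with pooled mean TE beyond fixed cutoffs
    (inclusive comparisons)."""

    ge_high: int
    ge_higher: int
    le_low: int
    le_lower: int
    thresholds: tuple[float, float, float, float] = (1.5, 2.0, 0.67, 0.5)

    def __post_init__(self) -> None:
        assert self.ge_higher <= self.ge_high
        assert self.le_lower <= self.le_low


@dataclass
class GeneClassification:
    """Genes whose mutant/WT TE ratio passes a fold-change + p-value rule."""

    down_set: list = field(default_factory=list)
    up_set: list = field(default_factory=list)
    down_threshold: float = 0.71
    up_threshold: float = 1.4
    alpha: float = 0.1

    def __post_init__(self) -> None:
        if set(self.down_set) & set(self.up_set):
            raise ValueError("down_set and up_set overlap")


def compute_te(
    expr: ExpressionMatrix,
    numerator_fraction: str = "HP",
    mean_mode: str = "ratio_of_means",
) -> pd.DataFrame:
    """Build the per-gene TE table from a group-summarized matrix.

    ``expr`` must be gene-level and linear-scale with MultiIndex columns
    (strain, fraction, project) as produced by
    :func:`polyte.normalize.summarize_tech_reps`, containing the
    ``numerator_fraction`` and ``T`` columns for both strains.

    Returns a DataFrame indexed by gene with per-project TE columns
    (``te_wt_<proj>``, ``te_mut_<proj>``), pooled means (``mean_te_wt``,
    ``mean_te_mut``; mode A), the averaged per-project mutant/WT ratio
    (``mean_ratio``; mode B) with ``ratio_sem``, the t-test ``p_value``
    with a Benjamini-Hochberg column ``p_bh`` (informational), and a
    ``degenerate_t`` flag.
    """
    if expr.scale != "linear":
        expr = expr.to_linear()
    cols = expr.data.columns
    if not isinstance(cols, pd.MultiIndex):
        raise ValueError("expected a group-summarized matrix with (strain, fraction, project) columns")
    strains = {"WT": "wt", "mutant": "mut"}
    projects = sorted(cols.get_level_values("project").unique())

    te = {}
    for strain, tag in strains.items():
        for proj in projects:
            num_key = (strain, numerator_fraction, proj)
            den_key = (strain, "T", proj)
            for key in (num_key, den_key):
                if key not in cols:
                    raise ValueError(f"missing summarized column {key}")
            num = expr.data[num_key].to_numpy()
            den = expr.data[den_key].to_numpy()
            if (den <= 0).any() or (num <= 0).any():
                raise ValueError("non-positive intensity encountered in TE computation")
            te[f"te_{tag}_{proj}"] = num / den

    out = pd.DataFrame(te, index=expr.data.index)
    wt_cols = [f"te_wt_{p}" for p in projects]
    mut_cols = [f"te_mut_{p}" for p in projects]

    if mean_mode == "ratio_of_means":
        for strain, tag in strains.items():
            num = expr.data[[(strain, numerator_fraction, p) for p in projects]].mean(axis=1)
            den = expr.data[[(strain, "T", p) for p in projects]].mean(axis=1)
            out[f"mean_te_{tag}"] = num / den
    elif mean_mode == "mean_of_ratios":
        out["mean_te_wt"] = out[wt_cols].mean(axis=1)
        out["mean_te_mut"] = out[mut_cols].mean(axis=1)
    else:
        raise ValueError(f"unknown mean_mode {mean_mode!r}")

    ratios = out[mut_cols].to_numpy() / out[wt_cols].to_numpy()
    out["mean_ratio"] = ratios.mean(axis=1)
    k = ratios.shape[1]
    out["ratio_sem"] = ratios.std(axis=1, ddof=1) / np.sqrt(k) if k > 1 else 0.0

    if k < 2:
        out["p_value"] = np.nan
        out["degenerate_t"] = True
        out["p_bh"] = np.nan
        return out
    a = out[wt_cols].to_numpy()
    b = out[mut_cols].to_numpy()
    n1 = n2 = k
    s2 = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    diff = a.mean(axis=1) - b.mean(axis=1)
    degenerate = s2 == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n1 + n2 - 2)
    p[degenerate] = np.where(diff[degenerate] == 0.0, 1.0, 0.0)
    out["p_value"] = p
    out["degenerate_t"] = degenerate
    out["p_bh"] = _benjamini_hochberg(out["p_value"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(p, method="bh")


def gene_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """Two-sample pooled-variance Student t-test, two-tailed.

    Returns ``(p_value, degenerate)``.  When both samples have zero
    variance the statistic is undefined; the test then reports p = 1 for
    equal means and p = 0 otherwise, flagged as degenerate so callers can
    tell the convention from a real p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("t-test requires at least two values per sample")
    s2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if s2 == 0.0:
        return (1.0 if a.mean() == b.mean() else 0.0), True
    t = (a.mean() - b.mean()) / np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df=n1 + n2 - 2)
    return float(p), False


def classify_genes(
    te_table: pd.DataFrame,
    down: float = 0.71,
    up: float = 1.4,
    alpha: float = 0.1,
) -> GeneClassification:
    """Select genes whose mean mutant/WT TE ratio passes the fold +
    significance rule (ratio <= ``down`` or >= ``up``, with t-test
    p <= ``alpha``)."""
    if down >= up:
        raise ValueError(f"down threshold ({down}) must be < up threshold ({up})")
    sig = te_table["p_value"] <= alpha
    down_set = te_table.index[(te_table["mean_ratio"] <= down) & sig].tolist()
    up_set = te_table.index[(te_table["mean_ratio"] >= up) & sig].tolist()
    return GeneClassification(down_set, up_set, down, up, alpha)


def tabulate_thresholds(
    mean_te: pd.Series,
    high: float = 1.5,
    higher: float = 2.0,
    low: float = 0.67,
    lower: float = 0.5,
) -> ThresholdCounts:
    """Count genes with mean TE >= high / >= higher / <= low / <= lower
    (all comparisons inclusive)."""
    v = mean_te.to_numpy(dtype=float)
    return ThresholdCounts(
        int((v >= high).sum()),
        int((v >= higher).sum()),
        int((v <= low).sum()),
        int((v <= lower).sum()),
        thresholds=(high, higher, low, lower),
    )


def dependency_fractions(
    te_table: pd.DataFrame, high: float = 1.5, low: float = 0.67
) -> dict[str, float]:
    """Among genes with high (low) wild-type TE, the fraction whose TE is
    strictly lower (higher) in the mutant.

    Keys: ``high_wt_gt_mut`` (TE_wt >= high and TE_wt > TE_mut),
    ``low_wt_gt_mut`` and ``low_wt_lt_mut`` (both orientations are
    reported for the low-TE group), plus the group sizes ``n_high``,
    ``n_low``.  A group with no members yields ``nan`` fractions.
    """
    wt = te_table["mean_te_wt"]
    mut = te_table["mean_te_mut"]
    hi = wt >= high
    lo = wt <= low
    n_hi, n_lo = int(hi.sum()), int(lo.sum())
    return {
        "high_wt_gt_mut": float((hi & (wt > mut)).sum() / n_hi) if n_hi else float("nan"),
        "low_wt_gt_mut": float((lo & (wt > mut)).sum() / n_lo) if n_lo else float("nan"),
        "low_wt_lt_mut": float((lo & (wt < mut)).sum() / n_lo) if n_lo else float("nan"),
        "n_high": n_hi,
        "n_low": n_lo,
    }


def ma_stats(values_1: np.ndarray, values_2: np.ndarray) -> MAStats:
    """M and A values for two intensity vectors.

    M = log2(I1) - log2(I2); A = 0.5 (log2(I1) + log2(I2)).  The variance
    of M (sample variance, n-1 denominator) summarizes the genome-wide
    spread of intensity ratios between the two arrays.
    """
    v1 = np.asarray(values_1, dtype=float)
    v2 = np.asarray(values_2, dtype=float)
    if v1.shape != v2.shape or v1.size < 2:
        raise ValueError("need two equal-length intensity vectors of size >= 2")
    if (v1 <= 0).any() or (v2 <= 0).any():
        raise ValueError("intensities must be strictly positive")
    l1, l2 = np.log2(v1), np.log2(v2)
    m = l1 - l2
    a = 0.5 * (l1 + l2)
    return MAStats(m=m, a=a, variance_m=float(m.var(ddof=1)))


def te_regression(te_table: pd.DataFrame, response: str = "wt") -> RegressionFit:
    """OLS fit of log2 pooled TE, wild type on mutant by default.

    With the wild type as response, a slope above 1 indicates a narrower
    TE range in the mutant (genes above the genome-average TE in WT sit
    closer to the average in the mutant, and vice versa).  Set
    ``response="mut"`` for the transposed orientation.
    """
    wt = np.log2(te_table["mean_te_wt"].to_numpy(dtype=float))
    mut = np.log2(te_table["mean_te_mut"].to_numpy(dtype=float))
    y, x = (wt, mut) if response == "wt" else (mut, wt)
    if len(y) < 2:
        raise ValueError("regression requires at least two genes")
    fit = stats.linregress(x, y)
    return RegressionFit(slope=float(fit.slope), intercept=float(fit.intercept), n_genes=len(y))


def group_mean_ratio(te_table: pd.DataFrame, selector: str = "above") -> float:
    """Mean wild-type/mutant TE ratio over the genes whose pooled WT TE is
    above (below) the genome-average WT TE.

    Per gene, the per-project TE_wt/TE_mut ratios are averaged over
    projects; the group value is the arithmetic mean over the selected
    genes.  The genome average is the arithmetic mean of pooled WT TEs.
    """
    wt_cols = [c for c in te_table.columns if c.startswith("te_wt_")]
    mut_cols = [c.replace("wt", "mut") for c in wt_cols]
    per_gene = (te_table[wt_cols].to_numpy() / te_table[mut_cols].to_numpy()).mean(axis=1)
    genome_mean = te_table["mean_te_wt"].mean()
    if selector == "above":
        mask = te_table["mean_te_wt"].to_numpy() > genome_mean
    elif selector == "below":
        mask = te_table["mean_te_wt"].to_numpy() < genome_mean
    else:
        raise ValueError(f"selector must be 'above' or 'below', got {selector!r}")
    if not mask.any():
        raise ValueError("empty gene selection")
    return float(per_gene[mask].mean())
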