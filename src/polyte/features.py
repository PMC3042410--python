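"""Associating gene sets with structural features, essentiality and
functional categories.

The feature table carries per-gene annotations — 5'UTR/ORF/3'UTR lengths,
uORF counts, a precomputed secondary-structure (MFE) significance flag,
essentiality, functional categories, and optional ribosome-density columns
— with missing values permitted and excluded pairwise from every statistic.
Gene sets typically come from the TE classification (translationally up- or
down-responsive genes) but any id list works.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "group_feature_stats",
    "uorf_stats",
    "category_enrichment",
    "essential_fraction",
    "candidate_gene_report",
    "density_crossref",
]


@dataclass
class EnrichmentResult:
    category: str
    set_count: int
    universe_count: int
    set_size: int
    universe_size: int
    log2_fold_enrichment: float
    fisher_p: float
    bonferroni_p: float
    direction: str  # "enriched" | "underrepresented"


def _usable(features: pd.DataFrame, genes, fieldname: str) -> np.ndarray:
    vals = features.loc[features.index.intersection(genes), fieldname].dropna()
    return vals.to_numpy(dtype=float)


def group_feature_stats(
    gene_set,
    features: pd.DataFrame,
    fieldname: str,
    reference=None,
    test: str = "welch",
) -> tuple[float, float, float]:
    """Mean +/- SEM of a feature over a gene set, with a two-tailed p-value
    versus a reference set (all annotated genes by default).

    ``test`` selects the comparison: ``"welch"`` (default, unequal-variance
    t), ``"student"`` (pooled-variance t) or ``"mann-whitney"``.  Genes
    missing the feature are dropped pairwise.
    """
    x = _usable(features, gene_set, fieldname)
    if len(x) < 2:
        raise ValueError(f"need >=2 genes with non-missing {fieldname!r}, got {len(x)}")
    ref_genes = features.index if reference is None else reference
    y = _usable(features, ref_genes, fieldname)
    mean = float(x.mean())
    sem = float(x.std(ddof=1) / np.sqrt(len(x)))
    if test == "welch":
        p = stats.ttest_ind(x, y, equal_var=False).pvalue
    elif test == "student":
        p = stats.ttest_ind(x, y, equal_var=True).pvalue
    elif test == "mann-whitney":
        p = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
    else:
        raise ValueError(f"unknown test {test!r}")
    return mean, sem, float(p)


def uorf_stats(gene_set, features: pd.DataFrame) -> tuple[float, float]:
    """Mean uORFs per transcript +/- SEM over a gene set."""
    x = _usable(features, gene_set, "n_uorfs")
    if len(x) < 2:
        raise ValueError("need >=2 genes with uORF annotations")
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(len(x)))


def _gene_categories(features: pd.DataFrame, genes) -> dict[str, set]:
    out: dict[str, set] = {}
    cats = features.loc[features.index.intersection(genes), "categories"]
    for gene, c in cats.items():
        if isinstance(c, str):
            c = {s for s in c.split(";") if s}
        out[gene] = set(c) if c is not None else set()
    return out


def category_enrichment(
    gene_set, features: pd.DataFrame, universe=None, min_members: int = 2
) -> list[EnrichmentResult]:
    """Per-category two-sided Fisher exact tests of a gene set against a
    universe, Bonferroni-corrected over the tested categories.

    Enrichment is ``log2((k/n) / (K/N))`` for k of n set genes and K of N
    universe genes in the category.  Categories with fewer than
    ``min_members`` universe members are skipped.
    """
    if universe is None:
        universe = features.index
    universe = pd.Index(universe)
    gene_set = [g for g in gene_set if g in universe]
    uni_cats = _gene_categories(features, universe)
    set_cats = {g: uni_cats[g] for g in gene_set}
    n, n_universe = len(gene_set), len(universe)

    counts_uni: dict[str, int] = {}
    for cats in uni_cats.values():
        for c in cats:
            counts_uni[c] = counts_uni.get(c, 0) + 1
    counts_set: dict[str, int] = {}
    for cats in set_cats.values():
        for c in cats:
            counts_set[c] = counts_set.get(c, 0) + 1
    for c in counts_set:
        if c not in counts_uni:  # pragma: no cover - set is a subset of universe
            warnings.warn(f"category {c!r} absent from universe; skipped")

    tested = [c for c, k in sorted(counts_uni.items()) if k >= min_members]
    results = []
    for cat in tested:
        big_k = counts_uni[cat]
        k = counts_set.get(cat, 0)
        table = [[k, n - k], [big_k - k, (n_universe - n) - (big_k - k)]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        set_rate = k / n if n else 0.0
        uni_rate = big_k / n_universe
        with np.errstate(divide="ignore"):
            log2_fold = float(np.log2(set_rate / uni_rate)) if set_rate > 0 else -np.inf
        results.append(
            EnrichmentResult(
                category=cat,
                set_count=k,
                universe_count=big_k,
                set_size=n,
                universe_size=n_universe,
                log2_fold_enrichment=log2_fold,
                fisher_p=p,
                bonferroni_p=min(1.0, p * len(tested)),
                direction="enriched" if set_rate >= uni_rate else "underrepresented",
            )
        )
    return results


def essential_fraction(
    gene_set, features: pd.DataFrame, universe=None
) -> tuple[float, float]:
    """Fraction of essential genes in a set and the Fisher exact p versus
    the universe frequency."""
    if universe is None:
        universe = features.index
    flags = features["essential"]
    if flags.isna().all():
        raise ValueError("no essentiality flags present")
    in_set = flags.loc[features.index.intersection(gene_set)].dropna().astype(bool)
    uni = flags.loc[features.index.intersection(universe)].dropna().astype(bool)
    rest = uni.drop(index=in_set.index, errors="ignore")
    table = [
        [int(in_set.sum()), int((~in_set).sum())],
        [int(rest.sum()), int((~rest).sum())],
    ]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return float(in_set.mean()), p


def candidate_gene_report(
    gene_ids,
    te_table: pd.DataFrame,
    synonyms: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-gene mean mutant/WT TE ratio +/- SEM and t-test p for a named
    list of candidate genes (e.g. putative IRES-containing mRNAs).

    ``synonyms`` maps aliases to systematic ids.  Unresolvable ids appear
    in the output with NaN statistics and ``found=False`` rather than
    aborting the report.
    """
    rows = []
    for name in gene_ids:
        gid = synonyms.get(name, name) if synonyms else name
        if gid in te_table.index:
            rec = te_table.loc[gid]
            rows.append(
                {
                    "gene": name,
                    "gene_id": gid,
                    "mean_ratio": rec["mean_ratio"],
                    "ratio_sem": rec["ratio_sem"],
                    "p_value": rec["p_value"],
                    "found": True,
                }
            )
        else:
            rows.append(
                {
                    "gene": name,
                    "gene_id": gid,
                    "mean_ratio": np.nan,
                    "ratio_sem": np.nan,
                    "p_value": np.nan,
                    "found": False,
                }
            )
    return pd.DataFrame(rows).set_index("gene")


def density_crossref(
    te_table_lp: pd.DataFrame,
    features: pd.DataFrame,
    density_max: float | None = None,
    orf_max: int | None = None,
    peak_ribosome_range: tuple[int, int] = (1, 3),
) -> dict:
    """Mean LP-based TE per strain for genes in a low-ribosome-load class.

    Genes are retained when their peak ribosome count lies in
    ``peak_ribosome_range`` and they satisfy the density ceiling
    (``ribosome_density <= density_max``, ribosomes/100 nt) or the
    ORF-length ceiling (``orf_len < orf_max``), whichever is given.
    """
    if density_max is None and orf_max is None:
        raise ValueError("provide density_max or orf_max")
    common = te_table_lp.index.intersection(features.index)
    feats = features.loc[common]
    lo, hi = peak_ribosome_range
    mask = feats["peak_ribosomes"].between(lo, hi)
    if density_max is not None:
        mask &= feats["ribosome_density"] <= density_max
    if orf_max is not None:
        mask &= feats["orf_len"] < orf_max
    kept = common[mask.to_numpy(dtype=bool)]
    if len(kept) == 0:
        raise ValueError("filter retained no genes")
    sub = te_table_lp.loc[kept]
    out = {"n_genes": int(len(kept))}
    for tag in ("wt", "mut"):
        vals = sub[f"mean_te_{tag}"].to_numpy(dtype=float)
        out[f"mean_te_{tag}"] = float(vals.mean())
        out[f"sem_te_{tag}"] = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return out
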