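"""End-to-end pipeline: probe matrix -> normalized summaries -> TE table ->
narrowing diagnostics -> classification -> feature association, with a JSON
report capturing every computed number and the input hashes that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from polyte import io as pio
from polyte.normalize import (
    ExpressionMatrix,
    quantile_normalize,
    median_polish_summarize,
    scale_arrays,
    summarize_tech_reps,
)
from polyte import te as te_mod
from polyte import features as feat_mod

log = logging.getLogger("polyte")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and switches for one pipeline run."""

    matrix_path: str | None = None
    sheet_path: str | None = None
    features_path: str | None = None
    output_dir: str = "polyte_out"
    numerator_fraction: str = "HP"
    te_high: float = 1.5
    te_higher: float = 2.0
    te_low: float = 0.67
    te_lower: float = 0.5
    ratio_up: float = 1.4
    ratio_down: float = 0.71
    alpha: float = 0.1
    mean_mode: str = "ratio_of_means"
    regression_response: str = "wt"
    tech_rep_scale_linear: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not (self.te_lower <= self.te_low < 1.0 < self.te_high <= self.te_higher):
            raise ValueError("TE thresholds are not consistently ordered")
        if self.ratio_down >= self.ratio_up:
            raise ValueError("ratio_down must be < ratio_up")


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def normalize_chain(
    matrix: ExpressionMatrix,
    sheet: pd.DataFrame,
    linear_tech_reps: bool = True,
    qn_groups: str = "strain_fraction",
) -> ExpressionMatrix:
    """quantile normalize -> array scaling -> log2 -> median polish ->
    tech-rep averaging.

    By default quantile normalization is applied within each
    (strain, fraction) array group: arrays probing the same RNA pool are
    forced to a common intensity distribution (removing per-array scale
    factors), while pools whose distributions genuinely differ — polysomal
    versus total RNA — are not cross-equalized, which would flatten part of
    the HP/T ratio signal.  All arrays are then scaled to a common average
    log2 intensity, removing residual between-group scale offsets.
    ``qn_groups="all"`` quantile-normalizes the whole cohort together
    instead.
    """
    if qn_groups == "strain_fraction":
        from dataclasses import replace

        parts = []
        for _, grp in sheet.groupby(["strain", "fraction"], sort=False):
            sub = replace(matrix, data=matrix.data[grp["array_id"].tolist()], gene_map=None)
            parts.append(quantile_normalize(sub).data)
        data = pd.concat(parts, axis=1)[matrix.data.columns]
        qn = ExpressionMatrix(data, scale=matrix.scale, gene_map=matrix.gene_map)
    elif qn_groups == "all":
        qn = quantile_normalize(matrix)
    else:
        raise ValueError(f"unknown qn_groups {qn_groups!r}")
    gene_level = median_polish_summarize(scale_arrays(qn).to_log2(), matrix.gene_map)
    return summarize_tech_reps(gene_level, sheet, linear=linear_tech_reps).to_linear()


def run_pipeline(
    config: PipelineConfig,
    matrix: ExpressionMatrix | None = None,
    sheet: pd.DataFrame | None = None,
    features: pd.DataFrame | None = None,
) -> dict:
    """Run the analysis and write tables, a MANIFEST, and report.json to
    ``config.output_dir``.  Inputs may be passed in memory or read from the
    configured paths."""
    config.validate()
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    provenance: dict[str, str] = {}

    def _stage(name: str) -> None:
        log.info("stage %-12s t=%.1fs", name, time.time() - t0)
        manifest.append(name)
        (outdir / "MANIFEST").write_text("\n".join(manifest) + "\n")

    if matrix is None:
        if config.matrix_path is None:
            raise ValueError("no matrix provided")
        provenance["matrix"] = _hash_file(config.matrix_path)
        matrix = pio.read_matrix(config.matrix_path)
    if sheet is None:
        if config.sheet_path is None:
            raise ValueError("no sample sheet provided")
        provenance["sheet"] = _hash_file(config.sheet_path)
        sheet = pio.read_sheet(config.sheet_path)
    if features is None and config.features_path is not None:
        provenance["features"] = _hash_file(config.features_path)
        features = pio.read_features(config.features_path)

    missing_cols = set(sheet["array_id"]) - set(matrix.data.columns)
    if missing_cols:
        raise ValueError(
            f"sample sheet references missing array columns: {sorted(missing_cols)}"
        )
    _stage("load")

    summarized = normalize_chain(matrix, sheet, config.tech_rep_scale_linear)
    pio.write_matrix(summarized, outdir / "summarized.tsv")
    _stage("normalize")

    te_table = te_mod.compute_te(
        summarized, config.numerator_fraction, mean_mode=config.mean_mode
    )
    pio.write_te_table(te_table, outdir / "te_table.tsv")
    _stage("te")

    # MA variance of the HP:T comparison per strain, averaged over projects
    ma_var = {}
    for strain, tag in (("WT", "wt"), ("mutant", "mut")):
        variances = []
        for proj in sorted({c[2] for c in summarized.data.columns}):
            v1 = summarized.data[(strain, config.numerator_fraction, proj)].to_numpy()
            v2 = summarized.data[(strain, "T", proj)].to_numpy()
            variances.append(te_mod.ma_stats(v1, v2).variance_m)
        ma_var[tag] = float(np.mean(variances))
    _stage("ma")

    fit = te_mod.te_regression(te_table, response=config.regression_response)
    counts = {
        tag: te_mod.tabulate_thresholds(
            te_table[f"mean_te_{tag}"],
            config.te_high,
            config.te_higher,
            config.te_low,
            config.te_lower,
        )
        for tag in ("wt", "mut")
    }
    deps = te_mod.dependency_fractions(te_table, config.te_high, config.te_low)
    classification = te_mod.classify_genes(
        te_table, config.ratio_down, config.ratio_up, config.alpha
    )
    pd.DataFrame(
        {
            "gene_id": classification.down_set + classification.up_set,
            "direction": ["down"] * len(classification.down_set)
            + ["up"] * len(classification.up_set),
        }
    ).to_csv(outdir / "classification.tsv", sep="\t", index=False)
    _stage("classify")

    report: dict = {
        "provenance": provenance,
        "config": asdict(config),
        "n_genes": int(len(te_table)),
        "genome_mean_te_wt": float(te_table["mean_te_wt"].mean()),
        "genome_mean_te_mut": float(te_table["mean_te_mut"].mean()),
        "regression": asdict(fit),
        "ma_variance": ma_var,
        "ma_variance_ratio_wt_mut": ma_var["wt"] / ma_var["mut"],
        "threshold_counts": {k: asdict(v) for k, v in counts.items()},
        "dependency_fractions": deps,
        "classification": {
            "n_down": len(classification.down_set),
            "n_up": len(classification.up_set),
            "down_threshold": classification.down_threshold,
            "up_threshold": classification.up_threshold,
            "alpha": classification.alpha,
        },
    }

    if features is not None:
        assoc: dict = {}
        for name, genes in (
            ("down_set", classification.down_set),
            ("up_set", classification.up_set),
        ):
            if len(genes) >= 2:
                m, s, p = feat_mod.group_feature_stats(genes, features, "utr5_len")
                frac, fp = feat_mod.essential_fraction(genes, features)
                um, us = feat_mod.uorf_stats(genes, features)
                assoc[name] = {
                    "utr5_mean": m, "utr5_sem": s, "utr5_p": p,
                    "essential_fraction": frac, "essential_p": fp,
                    "uorf_mean": um, "uorf_sem": us,
                }
            else:
                assoc[name] = {"note": f"only {len(genes)} genes; skipped"}
        um, us = feat_mod.uorf_stats(features.index, features)
        assoc["genome"] = {
            "utr5_mean": float(features["utr5_len"].mean()),
            "uorf_mean": um,
            "uorf_sem": us,
        }
        report["feature_association"] = assoc
        _stage("features")

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _stage("done")
    return report
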