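"""Fraction-weighted 2^-ddCt quantification of mRNA polysome distributions
and the qPCR TE-ratio cross-validation.

Relative mRNA levels are computed from qPCR cycle thresholds normalized to
18S rRNA (the reference transcript) and to the total-RNA sample:

    ddCt = (Ct(fraction)_GOI - Ct(fraction)_18S)
         - (Ct(total)_GOI   - Ct(total)_18S)

and the relative quantity is 2^-ddCt (perfect-doubling amplification
assumed).  Scaling each fraction's quantity by the proportion of total
A280 units in that gradient pool and renormalizing yields the mRNA's
distribution over {Mono, LP, HP}.  The TE ratio between strains is the
ratio of strain-wise 2^-ddCt(HP-T) values times the ratio of HP A280
weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CtRecord",
    "FractionWeights",
    "DEFAULT_WEIGHTS",
    "load_weights",
    "average_ct",
    "delta_delta_ct",
    "polysome_distribution",
    "qpcr_te_ratio",
    "distribution_from_table",
]

GRADIENT_FRACTIONS = ("Mono", "LP", "HP")


@dataclass(frozen=True)
class CtRecord:
    """Averaged cycle thresholds for one (gene, strain, fraction) sample:
    the gene of interest and the 18S rRNA reference."""

    gene_id: str
    strain: str
    fraction: str
    ct_goi: float
    ct_18s: float

    def normalized(self) -> float:
        return self.ct_goi - self.ct_18s


@dataclass(frozen=True)
class FractionWeights:
    """Per-strain proportions of total gradient A280 units in the Mono,
    LP and HP pools.  Proportions must lie in (0, 1] and sum to 1 within
    +/- 0.01 per strain (measured weight sets need not close exactly)."""

    weights: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for strain, w in self.weights.items():
            missing = set(GRADIENT_FRACTIONS) - set(w)
            if missing:
                raise ValueError(f"strain {strain!r} missing fractions {sorted(missing)}")
            for frac, v in w.items():
                if not (0.0 < v <= 1.0):
                    raise ValueError(f"weight {strain}/{frac} = {v} outside (0, 1]")
            total = sum(w[f] for f in GRADIENT_FRACTIONS)
            if abs(total - 1.0) > 0.01:
                raise ValueError(
                    f"strain {strain!r} weights sum to {total:.3f}, expected 1 +/- 0.01"
                )

    def for_strain(self, strain: str) -> Mapping[str, float]:
        if strain not in self.weights:
            raise KeyError(f"no A280 weights for strain {strain!r}")
        return self.weights[strain]


def load_weights(path=None) -> FractionWeights:
    """Load fraction weights from a YAML file (the packaged defaults when
    no path is given)."""
    if path is None:
        text = resources.files("polyte").joinpath("data/a280_weights.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return FractionWeights(yaml.safe_load(text))


DEFAULT_WEIGHTS = load_weights()


def average_ct(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Average replicate Ct values in Ct (cycle) space.

    Input is the tidy table (gene_id, strain, fraction, target, replicate,
    ct); output has one row per (gene_id, strain, fraction) with ct_goi
    and ct_18s columns.  Averaging cycles, not quantities, matches how
    triplicate qPCR reactions are reduced to a single Ct.
    """
    mean = (
        ct_table.groupby(["gene_id", "strain", "fraction", "target"])["ct"]
        .mean()
        .unstack("target")
    )
    if "GOI" not in mean.columns or "18S" not in mean.columns:
        raise ValueError("Ct table must contain GOI and 18S targets")
    out = mean.rename(columns={"GOI": "ct_goi", "18S": "ct_18s"}).reset_index()
    if out[["ct_goi", "ct_18s"]].isna().any().any():
        raise ValueError("missing GOI or 18S Ct for some (gene, strain, fraction)")
    return out


def delta_delta_ct(rec: CtRecord, total: CtRecord) -> float:
    """Relative quantity 2^-ddCt of a fraction sample versus the total-RNA
    sample of the same gene and strain."""
    if rec.gene_id != total.gene_id or rec.strain != total.strain:
        raise ValueError(
            f"mismatched pairing: {rec.gene_id}/{rec.strain} vs {total.gene_id}/{total.strain}"
        )
    ddct = rec.normalized() - total.normalized()
    return float(2.0**-ddct)


def polysome_distribution(
    quantities: Mapping[str, float], weights: FractionWeights, strain: str
) -> pd.Series:
    """Distribution of an mRNA over {Mono, LP, HP}.

    ``quantities`` are the per-fraction relative quantities (2^-ddCt);
    each is multiplied by the strain's A280 weight for its pool and the
    products are normalized to sum to exactly 1.
    """
    w = weights.for_strain(strain)
    missing = set(GRADIENT_FRACTIONS) - set(quantities)
    if missing:
        raise ValueError(f"missing fraction quantities: {sorted(missing)}")
    weighted = np.array([quantities[f] * w[f] for f in GRADIENT_FRACTIONS], dtype=float)
    if (weighted < 0).any():
        raise ValueError("quantities must be non-negative")
    total = weighted.sum()
    if total == 0:
        raise ValueError("all weighted quantities are zero")
    return pd.Series(weighted / total, index=list(GRADIENT_FRACTIONS), name=strain)


def qpcr_te_ratio(
    ct_hp_mut: CtRecord,
    ct_t_mut: CtRecord,
    ct_hp_wt: CtRecord,
    ct_t_wt: CtRecord,
    weights: FractionWeights = DEFAULT_WEIGHTS,
    mutant_strain: str = "mutant",
    wt_strain: str = "WT",
) -> float:
    """Mutant/WT TE ratio from HP and total Ct quadruples.

    Computed as (2^-ddCt(HP-T)_mut / 2^-ddCt(HP-T)_wt) x (w_HP_mut /
    w_HP_wt), where the A280 weight ratio accounts for the different
    proportions of ribosomal RNA found in heavy polysomes in the two
    strains.  With default weights the Ct-identical baseline is
    0.114/0.308 ~= 0.37.
    """
    rel_mut = delta_delta_ct(ct_hp_mut, ct_t_mut)
    rel_wt = delta_delta_ct(ct_hp_wt, ct_t_wt)
    w_mut = weights.for_strain(mutant_strain)["HP"]
    w_wt = weights.for_strain(wt_strain)["HP"]
    return float((rel_mut / rel_wt) * (w_mut / w_wt))


def distribution_from_table(
    ct_table: pd.DataFrame, weights: FractionWeights = DEFAULT_WEIGHTS
) -> pd.DataFrame:
    """Full pipeline from a tidy replicate Ct table to per-(gene, strain)
    polysome distributions (one row each; Mono/LP/HP columns)."""
    avg = average_ct(ct_table)
    rows = []
    for (gene, strain), grp in avg.groupby(["gene_id", "strain"]):
        recs = {
            r.fraction: CtRecord(gene, strain, r.fraction, r.ct_goi, r.ct_18s)
            for r in grp.itertuples(index=False)
        }
        if "Total" not in recs:
            raise ValueError(f"no Total sample for {gene}/{strain}")
        quantities = {
            f: delta_delta_ct(recs[f], recs["Total"]) for f in GRADIENT_FRACTIONS if f in recs
        }
        dist = polysome_distribution(quantities, weights, strain)
        rows.append({"gene_id": gene, "strain": strain, **dist.to_dict()})
    return pd.DataFrame(rows).set_index(["gene_id", "strain"])
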