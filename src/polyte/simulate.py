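"""Synthetic polysome-profiling datasets with known ground truth.

Emulates the study design the downstream pipeline expects: two strains
(wild type and an initiation-factor-depleted mutant), HP / T (optionally LP)
RNA pools, three biological projects each hybridized to three technical
replicate arrays, multiple probes per gene with multiplicative affinities,
and log-normal noise at the biological, technical and per-array-scale
levels.  The mutant's true log2 TEs are the wild-type values compressed
toward the genome mean by a factor ``beta`` — the "narrowing" effect the
pipeline is built to detect.  Gene features (5'UTR/ORF/3'UTR lengths, uORF
counts, essentiality, categories, ribosome densities) are drawn with
genome-wide statistics matching published yeast compilations: mean 5'UTR
length ~89 nt, ~0.36 uORFs per transcript, and a negative coupling between
TE and ORF length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from polyte.normalize import ExpressionMatrix

__all__ = ["SimulationConfig", "simulate_features", "simulate_true_te",
           "simulate_probe_intensities", "simulate_ct_table", "simulate_dataset"]

STRAINS = ("WT", "mutant")
PROJECTS = ("I", "II", "III")

#: default functional-category labels and sampling probabilities
DEFAULT_CATEGORIES: tuple[tuple[str, float], ...] = (
    ("transcription", 0.10),
    ("rna_processing", 0.08),
    ("dna_processing", 0.07),
    ("protein_synthesis", 0.12),
    ("metabolism", 0.22),
    ("stress_response", 0.08),
    ("transport", 0.13),
    ("unclassified", 0.20),
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Attributes
    ----------
    beta
        Compression factor on log2 TE in the mutant relative to wild type
        (``log2 TE_mut = beta * log2 TE_wt``).  ``beta < 1`` narrows the TE
        range; the default 1/1.30 reproduces a wild-type-on-mutant
        regression slope of 1.30.
    sigma_te
        SD of the gene-to-gene log2 true TE spread in wild type, before the
        ORF-length coupling term is added.
    sigma_bio, sigma_tech, sigma_probe, sigma_scale
        Log2 SDs of biological (per gene x strain x fraction x project),
        technical (per probe x array), probe-affinity (per probe, shared
        across arrays) and per-array scale-factor noise.
    orf_te_coupling
        Slope of log2 TE_wt on centered log2 ORF length (negative: long
        ORFs are translated less efficiently).
    """

    n_genes: int = 6000
    probes_per_gene: int = 4
    n_projects: int = 3
    n_tech_reps: int = 3
    beta: float = 1.0 / 1.30
    sigma_te: float = 0.45
    sigma_bio: float = 0.06
    sigma_tech: float = 0.08
    sigma_probe: float = 0.25
    sigma_scale: float = 0.08
    abundance_mean_log2: float = 9.0
    abundance_sd_log2: float = 1.2
    orf_te_coupling: float = -0.20
    include_lp: bool = False
    lp_te_scale: float = 0.5
    sigma_ct: float = 0.1
    # feature-distribution parameters
    utr5_mean: float = 89.0
    utr5_sdlog: float = 1.0
    orf_mean: float = 1385.0
    orf_sdlog: float = 0.65
    utr3_mean: float = 120.0
    utr3_sdlog: float = 0.70
    uorf_rate: float = 0.36
    essential_fraction: float = 0.18
    mfe_significant_fraction: float = 0.005
    mean_ribosome_density: float = 0.64
    categories: tuple[tuple[str, float], ...] = field(default=DEFAULT_CATEGORIES)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "probes_per_gene", "n_projects", "n_tech_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("sigma_te", "sigma_bio", "sigma_tech", "sigma_probe",
                     "sigma_scale", "sigma_ct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        probs = [p for _, p in self.categories]
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("category probabilities must sum to 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["categories"] = [list(c) for c in self.categories]
        return d

    @property
    def projects(self) -> tuple[str, ...]:
        return PROJECTS[: self.n_projects] if self.n_projects <= 3 else tuple(
            f"P{i + 1}" for i in range(self.n_projects)
        )


def _lognormal_lengths(rng, n, mean, sdlog):
    """Integer lengths >= 1 from a log-normal with the given arithmetic mean."""
    mu = np.log(mean) - 0.5 * sdlog**2
    vals = np.rint(rng.lognormal(mu, sdlog, size=n)).astype(int)
    return np.maximum(vals, 1)


def simulate_features(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a per-gene feature table (lengths, uORFs, flags, categories,
    ribosome densities)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_id = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")

    utr5 = _lognormal_lengths(rng, n, config.utr5_mean, config.utr5_sdlog)
    orf = _lognormal_lengths(rng, n, config.orf_mean, config.orf_sdlog)
    utr3 = _lognormal_lengths(rng, n, config.utr3_mean, config.utr3_sdlog)
    uorfs = rng.poisson(config.uorf_rate, size=n)
    mfe = rng.random(n) < config.mfe_significant_fraction
    essential = rng.random(n) < config.essential_fraction

    labels = [c for c, _ in config.categories]
    probs = [p for _, p in config.categories]
    primary = rng.choice(labels, size=n, p=probs)
    secondary = rng.choice(labels, size=n, p=probs)
    has_second = rng.random(n) < 0.25
    cats = [
        {a} | ({b} if extra else set())
        for a, b, extra in zip(primary, secondary, has_second)
    ]

    # ribosome loading: short ORFs run at higher per-nt density (genome
    # average ~0.64 ribosomes / 100 nt), and the peak ribosome count scales
    # with density x ORF length
    rel_len = np.log(orf / config.orf_mean)
    density = config.mean_ribosome_density * np.exp(-0.4 * rel_len + rng.normal(0, 0.3, n))
    peak = np.maximum(1, np.rint(density * orf / 100.0)).astype(int)

    return pd.DataFrame(
        {
            "utr5_len": utr5,
            "orf_len": orf,
            "utr3_len": utr3,
            "n_uorfs": uorfs,
            "mfe_significant": mfe,
            "essential": essential,
            "categories": cats,
            "ribosome_density": density,
            "peak_ribosomes": peak,
        },
        index=gene_id,
    )


def simulate_true_te(
    config: SimulationConfig,
    features: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw true per-gene log2 TEs and abundances.

    log2 TE_wt = sigma_te * z + coupling * centered log2 ORF length, then
    mean-centered so the genome-average log2 TE is 0 (array scaling makes
    TE values relative, with genome mean ~1).  log2 TE_mut is exactly
    ``beta * log2 TE_wt``.  LP-pool TEs are a damped version of the HP TEs.
    """
    config.validate()
    if len(features) != config.n_genes:
        raise ValueError(
            f"feature table has {len(features)} rows, config expects {config.n_genes}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = config.n_genes
    log2_orf = np.log2(features["orf_len"].to_numpy(dtype=float))
    coupling = config.orf_te_coupling * (log2_orf - log2_orf.mean())
    te_wt = config.sigma_te * rng.standard_normal(n) + coupling
    te_wt -= te_wt.mean()
    te_mut = config.beta * te_wt

    te_lp_wt = config.lp_te_scale * te_wt
    te_lp_mut = config.beta * te_lp_wt

    abundance = 2.0 ** (
        config.abundance_mean_log2 + config.abundance_sd_log2 * rng.standard_normal(n)
    )
    truth = pd.DataFrame(
        {
            "true_log2_te_wt": te_wt,
            "true_log2_te_mut": te_mut,
            "true_log2_te_lp_wt": te_lp_wt,
            "true_log2_te_lp_mut": te_lp_mut,
            "true_abundance": abundance,
        },
        index=features.index,
    )
    return truth.join(features)


def _array_layout(config: SimulationConfig) -> pd.DataFrame:
    fractions = ("HP", "LP", "T") if config.include_lp else ("HP", "T")
    rows = []
    for strain in STRAINS:
        for fraction in fractions:
            for project in config.projects:
                for rep in range(1, config.n_tech_reps + 1):
                    rows.append(
                        {
                            "array_id": f"{strain}_{fraction}_{project}_r{rep}",
                            "strain": strain,
                            "fraction": fraction,
                            "project": project,
                            "tech_rep": rep,
                        }
                    )
    return pd.DataFrame(rows)


def simulate_probe_intensities(
    config: SimulationConfig,
    truth: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate a linear-scale probe-by-array intensity matrix plus its
    sample sheet.

    Expected intensity on a T array is proportional to the gene's
    abundance; on an HP (LP) array it is abundance x TE (x LP TE) for the
    array's strain.  Each probe multiplies in a fixed affinity; each array
    has a scale factor; biological noise is shared by the technical
    replicates of a (strain, fraction, project) RNA sample; technical
    noise is per probe x array.  All noise is log-normal, i.e. additive on
    the log2 scale.
    """
    config.validate()
    if len(truth) != config.n_genes:
        raise ValueError(
            f"truth table has {len(truth)} rows, config expects {config.n_genes}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    sheet = _array_layout(config)
    n_genes, ppg = config.n_genes, config.probes_per_gene
    n_probes, n_arrays = n_genes * ppg, len(sheet)

    gene_ids = truth.index.to_numpy()
    probe_gene = np.repeat(gene_ids, ppg)
    probe_ids = np.array(
        [f"{g}_p{j + 1}" for g in gene_ids for j in range(ppg)]
    )

    log2_abund = np.log2(truth["true_abundance"].to_numpy())
    te = {
        ("WT", "HP"): truth["true_log2_te_wt"].to_numpy(),
        ("mutant", "HP"): truth["true_log2_te_mut"].to_numpy(),
        ("WT", "LP"): truth["true_log2_te_lp_wt"].to_numpy(),
        ("mutant", "LP"): truth["true_log2_te_lp_mut"].to_numpy(),
        ("WT", "T"): np.zeros(n_genes),
        ("mutant", "T"): np.zeros(n_genes),
    }

    affinity = rng.normal(0.0, config.sigma_probe, size=n_probes)
    scale = rng.normal(0.0, config.sigma_scale, size=n_arrays)
    bio_keys = sheet[["strain", "fraction", "project"]].drop_duplicates()
    bio = {
        tuple(k): rng.normal(0.0, config.sigma_bio, size=n_genes)
        for k in bio_keys.itertuples(index=False)
    }

    log2_x = np.empty((n_probes, n_arrays))
    for a, row in enumerate(sheet.itertuples(index=False)):
        gene_level = (
            log2_abund
            + te[(row.strain, row.fraction)]
            + bio[(row.strain, row.fraction, row.project)]
        )
        log2_x[:, a] = (
            np.repeat(gene_level, ppg)
            + affinity
            + scale[a]
            + rng.normal(0.0, config.sigma_tech, size=n_probes)
        )

    data = pd.DataFrame(
        2.0**log2_x, index=pd.Index(probe_ids, name="probe_id"),
        columns=sheet["array_id"].tolist(),
    )
    gene_map = pd.Series(probe_gene, index=data.index, name="gene_id")
    return ExpressionMatrix(data, scale="linear", gene_map=gene_map), sheet


def simulate_ct_table(
    config: SimulationConfig,
    proportions: dict[str, dict[str, float]],
    weights,
    genes: list[str] | None = None,
    n_replicates: int = 3,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate a tidy qPCR Ct table whose fraction-weighted 2^-ddCt
    analysis recovers ``proportions`` exactly at zero Ct noise.

    ``proportions`` maps strain -> {Mono, LP, HP} -> proportion of the
    gradient-wide mRNA.  The construction inverts the quantification: the
    relative quantity to recover for fraction f is q_f = p_f / w_f (w_f the
    A280 weight), so Ct(fraction)_GOI is placed log2(q_f) cycles below the
    value that would give ddCt = 0.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    if genes is None:
        genes = ["gene1"]
    ct_18s, ct_total_goi = 12.0, 20.0
    rows = []
    for strain, props in proportions.items():
        w = weights.for_strain(strain)
        for gene in genes:
            for fraction in ("Mono", "LP", "HP", "Total"):
                if fraction == "Total":
                    goi = ct_total_goi
                else:
                    q = props[fraction] / w[fraction]
                    goi = ct_18s + (ct_total_goi - ct_18s) - np.log2(q)
                for target, base in (("GOI", goi), ("18S", ct_18s)):
                    for rep in range(1, n_replicates + 1):
                        rows.append(
                            {
                                "gene_id": gene,
                                "strain": strain,
                                "fraction": fraction,
                                "target": target,
                                "replicate": rep,
                                "ct": base + rng.normal(0.0, config.sigma_ct),
                            }
                        )
    return pd.DataFrame(rows)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: features + truth + probe matrix in one call.

    Returns ``(probe_matrix, sample_sheet, truth_table)``; the truth table
    carries the feature columns.  All randomness derives from
    ``config.seed`` so identical configs give identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    features = simulate_features(config, rng)
    truth = simulate_true_te(config, features, rng)
    matrix, sheet = simulate_probe_intensities(config, truth, rng)
    return matrix, sheet, truth
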