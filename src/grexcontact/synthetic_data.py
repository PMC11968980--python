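"""Synthetic data generation for the GReX → chromatin-contact analysis.

Everything downstream of this module (elastic-net cis models, pair-dataset
assembly, contact-frequency networks, association bookkeeping) is exercised
on data produced here, so the generator reproduces the statistical structure
the analysis assumes:

* cohort genotypes as binomial dosages with realistic minor-allele
  frequencies;
* transcript annotations in which enhancer RNAs (eRNAs) are short
  (median ~550 bp, >90% under 2 kb) and canonical genes are long;
* a sparse cis-genetic architecture of expression, with eRNAs receiving
  more, smaller-effect variants than genes and a known per-transcript
  heritability;
* symmetric binned contact matrices with exponential distance decay plus a
  planted, smooth, non-linear dependence of contact frequency on the mean
  GReX of the transcripts overlapping each bin pair;
* toy strand-signal tracks and the plain-text fixture files (BED, bedGraph,
  BEDPE, cooler-dump dialect, TSV) the loaders consume.

All randomness flows through one integer seed; identical configurations
yield byte-identical fixture sets.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .grex import ExpressionMatrix, GenotypeMatrix
from .contact_pairs import ContactMatrix, PairDataset, TranscriptAnnotation

DEFAULT_CHROM = "chrS"

# Planted link families: smooth, bounded, genuinely non-linear functions of
# the upstream/downstream mean GReX. The default saturating product is a
# pure interaction — odd in each argument, zero conditional mean given
# either feature alone — so an additive linear model has no leverage on it.


def _softsign(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x / (1.0 + np.abs(x))


def saturating_product(g_up, g_down) -> np.ndarray:
    return _softsign(g_up) * _softsign(g_down)


def bilinear(g_up, g_down) -> np.ndarray:
    return np.asarray(g_up, dtype=float) * np.asarray(g_down, dtype=float)


def radial_bump(g_up, g_down, center: float = 0.0, width: float = 0.5) -> np.ndarray:
    g_up = np.asarray(g_up, dtype=float)
    g_down = np.asarray(g_down, dtype=float)
    return np.exp(-((g_up - center) ** 2 + (g_down - center) ** 2) / (2.0 * width**2))


LINK_FUNCTIONS: Dict[str, Callable] = {
    "saturating_product": saturating_product,
    "bilinear": bilinear,
    "radial_bump": radial_bump,
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    ``erna_snps_per_transcript_mean`` / ``gene_snps_per_transcript_mean``
    control the sparse causal architecture: eRNAs receive roughly twice as
    many, individually smaller, cis effects as canonical genes, mirroring
    the ~2:1 SNPs-per-transcript ratio seen in trained expression models.
    ``contact_scale`` sets the magnitude of the distance-decay term; the
    absolute scale of normalized contact values is a free parameter of the
    generator and is chosen so typical filtered contacts land in the
    single-digit range.
    """

    n_samples: int = 500
    n_variants_per_window: int = 30  # per 100 kb of genome
    maf_range: Tuple[float, float] = (0.05, 0.5)
    n_ernas: int = 60
    n_genes: int = 40
    genome_length: int = 2_000_000
    bin_resolution: int = 10_000
    heritability_range: Tuple[float, float] = (0.2, 0.8)
    erna_snps_per_transcript_mean: float = 8.0
    gene_snps_per_transcript_mean: float = 4.0
    contact_noise_sd: float = 0.5
    distance_decay_rate: float = 3.0e-5  # per bp
    planted_link_strength: float = 4.0
    contact_scale: float = 5.0
    link_function: str = "saturating_product"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        h_lo, h_hi = self.heritability_range
        if not (0.0 <= h_lo <= h_hi <= 1.0):
            raise ConfigurationError(
                f"heritability_range must lie in [0, 1], got {self.heritability_range}"
            )
        for name in ("n_samples", "n_variants_per_window", "n_ernas", "n_genes",
                     "genome_length", "bin_resolution"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        if self.contact_noise_sd < 0:
            raise ConfigurationError("contact_noise_sd must be nonnegative")
        if self.distance_decay_rate <= 0:
            raise ConfigurationError("distance_decay_rate must be positive")
        if self.link_function not in LINK_FUNCTIONS:
            raise ConfigurationError(
                f"unknown link_function {self.link_function!r}; "
                f"choose from {sorted(LINK_FUNCTIONS)}"
            )


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a simulation."""

    effects: Dict[str, Tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    heritability: Dict[str, float] = field(default_factory=dict)
    covariate_coefficients: Optional[np.ndarray] = None
    untrainable: List[str] = field(default_factory=list)
    link_function: Optional[str] = None
    link_params: Dict[str, float] = field(default_factory=dict)
    noiseless_contact: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# Genotypes


def simulate_genotypes(config: SimConfig, rng: Optional[np.random.Generator] = None) -> GenotypeMatrix:
    """Draw a dosage matrix of independent biallelic variants.

    Dosages are binomial(2, MAF) per variant; positions are uniform over the
    synthetic chromosome with a density of ``n_variants_per_window`` per
    100 kb.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_windows = max(1, config.genome_length // 100_000)
    n_variants = int(config.n_variants_per_window * n_windows)
    positions = np.sort(rng.integers(1, config.genome_length + 1, size=n_variants))
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=n_variants)
    dosage = rng.binomial(2, mafs[None, :], size=(config.n_samples, n_variants)).astype(float)
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{i:06d}" for i in range(n_variants)],
            "chrom": DEFAULT_CHROM,
            "pos": positions,
            "maf": mafs,
        }
    )
    sample_ids = [f"S{i:05d}" for i in range(config.n_samples)]
    return GenotypeMatrix(dosage=dosage, variants=variants, sample_ids=sample_ids)


# ---------------------------------------------------------------------------
# Annotations

_ERNA_LOG_SD = 0.7  # lognormal sigma: median 550 bp, ~97% below 2 kb
_GENE_MEDIAN_BP = 20_000.0
_GENE_LOG_SD = 1.0


def simulate_annotations(config: SimConfig, rng: Optional[np.random.Generator] = None
                         ) -> List[TranscriptAnnotation]:
    """Place eRNA and canonical-gene intervals on the synthetic chromosome.

    eRNA lengths are lognormal with median 550 bp so that >90% fall under
    2 kb; gene lengths are lognormal with median 20 kb. Intervals are
    0-based half-open; the TSS is the strand-aware 5' end.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    annotations: List[TranscriptAnnotation] = []
    erna_lengths = np.rint(rng.lognormal(np.log(550.0), _ERNA_LOG_SD, config.n_ernas))
    gene_lengths = np.rint(rng.lognormal(np.log(_GENE_MEDIAN_BP), _GENE_LOG_SD, config.n_genes))
    erna_lengths = np.clip(erna_lengths, 50, None)
    gene_lengths = np.clip(gene_lengths, 200, None)
    max_len = max(erna_lengths.max(initial=0), gene_lengths.max(initial=0))
    if max_len >= config.genome_length:
        raise ConfigurationError(
            f"genome_length {config.genome_length} cannot accommodate a transcript of "
            f"length {int(max_len)}"
        )
    specs = [("ERNA", int(l)) for l in erna_lengths] + [("GENE", int(l)) for l in gene_lengths]
    counters = {"ERNA": 0, "GENE": 0}
    for kind, length in specs:
        start = int(rng.integers(0, config.genome_length - length))
        strand = "+" if rng.random() < 0.5 else "-"
        idx = counters[kind]
        counters[kind] += 1
        annotations.append(
            TranscriptAnnotation(
                id=f"{kind}{idx:05d}",
                tclass="eRNA" if kind == "ERNA" else "canonical",
                chrom=DEFAULT_CHROM,
                start=start,
                end=start + length,
                strand=strand,
            )
        )
    return annotations


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(
    genotypes: GenotypeMatrix,
    annotations: Sequence[TranscriptAnnotation],
    config: SimConfig,
    cis_window_bp: int = 50_000,
    n_covariates: int = 2,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate expression = G·β + covariates·γ + ε with known heritability.

    Per transcript, a sparse causal effect vector β over cis variants is
    drawn (eRNAs: more, smaller effects; genes: fewer, larger) and scaled so
    the empirical var(G·β) / var(expression) matches a heritability sampled
    from ``heritability_range``. Transcripts with an empty cis window are
    flagged in the returned truth and receive pure noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n = genotypes.n_samples
    pos = genotypes.variants["pos"].to_numpy()
    truth = SyntheticTruth()
    values = np.empty((n, len(annotations)))
    covariates = None
    cov_contrib = 0.0
    if n_covariates > 0:
        covariates = np.column_stack(
            [rng.normal(size=n) for _ in range(max(0, n_covariates - 1))]
            + [rng.integers(0, 2, size=n).astype(float)]  # a sex analogue
        )
        truth.covariate_coefficients = rng.normal(0.0, 0.5, size=(n_covariates, len(annotations)))

    for j, ann in enumerate(annotations):
        lo, hi = ann.tss - cis_window_bp, ann.tss + cis_window_bp
        cis_idx = np.flatnonzero((pos >= lo) & (pos <= hi))
        h2 = rng.uniform(*config.heritability_range)
        noise = rng.normal(size=n)
        if cis_idx.size == 0:
            truth.untrainable.append(ann.id)
            truth.heritability[ann.id] = 0.0
            expr = noise
        else:
            mean_k = (config.erna_snps_per_transcript_mean if ann.tclass == "eRNA"
                      else config.gene_snps_per_transcript_mean)
            k = min(cis_idx.size, max(1, rng.poisson(mean_k)))
            causal = rng.choice(cis_idx, size=k, replace=False)
            beta = rng.normal(0.0, 1.0 / np.sqrt(k), size=k)
            g = genotypes.dosage[:, causal] @ beta
            g_var = g.var()
            if g_var > 0 and h2 > 0:
                scale = np.sqrt(h2 / g_var)
                g = g * scale
                beta = beta * scale
                expr = g + np.sqrt(max(0.0, 1.0 - h2)) * noise
            else:
                h2 = 0.0
                expr = noise
            truth.effects[ann.id] = (causal, beta)
            truth.heritability[ann.id] = h2
        values[:, j] = expr

    if covariates is not None:
        cov_contrib = covariates @ truth.covariate_coefficients
        values = values + cov_contrib

    expr_matrix = ExpressionMatrix(
        values=values,
        transcript_ids=[a.id for a in annotations],
        sample_ids=list(genotypes.sample_ids),
        covariates=covariates,
    )
    return expr_matrix, truth


# ---------------------------------------------------------------------------
# Contact matrices


def simulate_contact_matrix(
    annotations: Sequence[TranscriptAnnotation],
    grex_means: Dict[str, float],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[ContactMatrix, SyntheticTruth]:
    """Build a symmetric binned contact matrix with a planted GReX link.

    Entry (i, j) is ``contact_scale · exp(−decay · d_ij)`` plus
    ``planted_link_strength · f(ḡ_i, ḡ_j)`` where f is the configured link
    family applied to the mean GReX of transcripts overlapping each bin
    (bins without transcripts contribute no link term), plus Gaussian noise.
    Both the noiseless value and the noisy observation are truncated at
    zero, since normalized contact frequencies are nonnegative. The
    noiseless matrix is stored in the returned truth.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    res = config.bin_resolution
    if config.genome_length % res != 0:
        warnings.warn(
            f"bin_resolution {res} does not divide genome_length "
            f"{config.genome_length}; last bin is partial"
        )
    n_bins = int(np.ceil(config.genome_length / res))
    starts = np.arange(n_bins) * res
    ends = np.minimum(starts + res, config.genome_length)
    bins = pd.DataFrame({"chrom": DEFAULT_CHROM, "start": starts, "end": ends,
                         "bin_id": np.arange(n_bins)})

    # mean GReX per bin over overlapping transcripts with a GReX value
    bin_grex = np.full(n_bins, np.nan)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for ann in annotations:
        g = grex_means.get(ann.id)
        if g is None:
            continue
        b0 = ann.start // res
        b1 = min((ann.end - 1) // res, n_bins - 1)
        sums[b0:b1 + 1] += g
        counts[b0:b1 + 1] += 1
    has = counts > 0
    bin_grex[has] = sums[has] / counts[has]

    link = LINK_FUNCTIONS[config.link_function]
    ii, jj = np.triu_indices(n_bins)
    d = (jj - ii) * res
    noiseless = config.contact_scale * np.exp(-config.distance_decay_rate * d)
    g_i, g_j = bin_grex[ii], bin_grex[jj]
    both = ~np.isnan(g_i) & ~np.isnan(g_j)
    link_term = np.zeros_like(noiseless)
    link_term[both] = config.planted_link_strength * link(g_i[both], g_j[both])
    noiseless = np.maximum(noiseless + link_term, 0.0)
    noise = rng.normal(0.0, config.contact_noise_sd, size=noiseless.shape) \
        if config.contact_noise_sd > 0 else 0.0
    values = np.maximum(noiseless + noise, 0.0)

    dense_truth = np.zeros((n_bins, n_bins))
    dense_truth[ii, jj] = noiseless
    dense_truth[jj, ii] = noiseless

    pixels = pd.DataFrame({"bin1_id": ii, "bin2_id": jj, "value": values})
    pixels = pixels[pixels["value"] > 0].reset_index(drop=True)
    matrix = ContactMatrix(resolution=res, bins=bins, pixels=pixels, normalized=True)
    truth = SyntheticTruth(
        link_function=config.link_function,
        link_params={"strength": config.planted_link_strength,
                     "decay": config.distance_decay_rate,
                     "scale": config.contact_scale},
        noiseless_contact=dense_truth,
    )
    return matrix, truth


def planted_link_dataset(
    n_pairs: int,
    link_strength: float = 3.0,
    noise_sd: float = 0.7,
    baseline: float = 4.0,
    link_function: str = "saturating_product",
    seed: int = 0,
) -> Tuple[PairDataset, np.ndarray]:
    """Directly simulate a pair-level regression benchmark.

    GReX features are standard normal; contact = baseline +
    strength · f(g_up, g_down) + ε, truncated at zero. Returns the dataset
    and the noiseless contact vector, whose variance ratio gives the
    attainable R² ceiling for any regressor on these two features.
    """
    rng = np.random.default_rng(seed)
    g_up = rng.normal(size=n_pairs)
    g_down = rng.normal(size=n_pairs)
    f = LINK_FUNCTIONS[link_function](g_up, g_down)
    noiseless = baseline + link_strength * f
    y = noiseless + (rng.normal(0.0, noise_sd, size=n_pairs) if noise_sd > 0 else 0.0)
    y = np.maximum(y, 0.0)
    classes = rng.choice(["enhancer-gene", "gene-enhancer", "enhancer-enhancer"],
                         size=n_pairs, p=[0.47, 0.50, 0.03])
    dist = rng.integers(1, 200, size=n_pairs) * 10_000
    df = pd.DataFrame(
        {
            "upstream_id": [f"U{i:06d}" for i in range(n_pairs)],
            "downstream_id": [f"D{i:06d}" for i in range(n_pairs)],
            "pair_class": classes,
            "grex_up": g_up,
            "grex_down": g_down,
            "distance_bp": dist,
            "log1p_distance": np.log1p(dist),
            "contact": y,
        }
    )
    return PairDataset(df, provenance={"source": "planted_link", "link": link_function}), noiseless


# ---------------------------------------------------------------------------
# Strand signal (nuclear run-on analogue)


def simulate_strand_signal(
    annotations: Sequence[TranscriptAnnotation],
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Uniform per-transcript coverage on the annotated strand, as bedGraph
    records (chrom, start, end, value) for plus and minus strands."""
    if rng is None:
        rng = np.random.default_rng(seed)
    plus, minus = [], []
    for ann in sorted(annotations, key=lambda a: (a.chrom, a.start)):
        value = float(rng.lognormal(0.0, 1.0))
        rec = (ann.chrom, ann.start, ann.end, value)
        (plus if ann.strand == "+" else minus).append(rec)
    cols = ["chrom", "start", "end", "value"]
    return (pd.DataFrame(plus, columns=cols), pd.DataFrame(minus, columns=cols))


# ---------------------------------------------------------------------------
# Fixture writing


def write_fixtures(outputs: Dict[str, object], directory: str) -> Dict[str, str]:
    """Write generated objects to plain-text fixture files.

    Recognized keys: ``annotations`` (BED6), ``genotypes`` (dosage TSV +
    variant TSV), ``expression`` (TSV), ``contacts`` (BEDPE + cooler-dump
    style bin/pixel tables), ``signal_plus``/``signal_minus`` (bedGraph).
    Returns a map of logical name → path. Values round-trip to 6 decimals.
    """
    os.makedirs(directory, exist_ok=True)
    written: Dict[str, str] = {}

    def path(name: str) -> str:
        return os.path.join(directory, name)

    if "annotations" in outputs:
        anns: Sequence[TranscriptAnnotation] = outputs["annotations"]  # type: ignore[assignment]
        p = path("annotations.bed")
        with open(p, "w") as fh:
            for a in sorted(anns, key=lambda x: (x.chrom, x.start, x.end)):
                fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.id}\t{a.tclass}\t{a.strand}\n")
        written["annotations"] = p

    if "genotypes" in outputs:
        genos: GenotypeMatrix = outputs["genotypes"]  # type: ignore[assignment]
        p = path("dosages.tsv")
        pd.DataFrame(genos.dosage, index=genos.sample_ids,
                     columns=genos.variants["variant_id"]).to_csv(p, sep="\t", float_format="%.6f")
        written["dosages"] = p
        p2 = path("variants.tsv")
        genos.variants.to_csv(p2, sep="\t", index=False, float_format="%.6f")
        written["variants"] = p2

    if "expression" in outputs:
        expr: ExpressionMatrix = outputs["expression"]  # type: ignore[assignment]
        p = path("expression.tsv")
        pd.DataFrame(expr.values, index=expr.sample_ids,
                     columns=expr.transcript_ids).to_csv(p, sep="\t", float_format="%.6f")
        written["expression"] = p
        if expr.covariates is not None:
            p2 = path("covariates.tsv")
            pd.DataFrame(expr.covariates, index=expr.sample_ids).to_csv(
                p2, sep="\t", float_format="%.6f")
            written["covariates"] = p2

    if "contacts" in outputs:
        m: ContactMatrix = outputs["contacts"]  # type: ignore[assignment]
        bins_p, pixels_p = path("bins.tsv"), path("pixels.tsv")
        m.bins.to_csv(bins_p, sep="\t", index=False)
        m.pixels.to_csv(pixels_p, sep="\t", index=False, float_format="%.6f")
        written["bins"], written["pixels"] = bins_p, pixels_p
        p = path("contacts.bedpe")
        bin_lookup = m.bins.set_index("bin_id")
        with open(p, "w") as fh:
            for row in m.pixels.itertuples(index=False):
                b1 = bin_lookup.loc[row.bin1_id]
                b2 = bin_lookup.loc[row.bin2_id]
                fh.write(
                    f"{b1['chrom']}\t{b1['start']}\t{b1['end']}"
                    f"\t{b2['chrom']}\t{b2['start']}\t{b2['end']}\t{row.value:.6f}\n"
                )
        written["bedpe"] = p

    for key, fname in (("signal_plus", "signal_plus.bedGraph"),
                       ("signal_minus", "signal_minus.bedGraph")):
        if key in outputs:
            df: pd.DataFrame = outputs[key]  # type: ignore[assignment]
            p = path(fname)
            df.to_csv(p, sep="\t", index=False, header=False, float_format="%.6f")
            written[key] = p

    return written


def simulate_study(config: SimConfig) -> Dict[str, object]:
    """Run the whole generator: genotypes → annotations → expression →
    per-transcript mean genetic values → contact matrix → strand signal.

    The "GReX means" fed to the contact simulator are the true per-cohort
    mean genetic values, i.e. what imputation into a large cohort estimates.
    """
    rng = np.random.default_rng(config.seed)
    genos = simulate_genotypes(config, rng)
    anns = simulate_annotations(config, rng)
    expr, truth = simulate_expression(genos, anns, config, rng=rng)
    grex_means: Dict[str, float] = {}
    for tid, (idx, beta) in truth.effects.items():
        grex_means[tid] = float(np.mean(genos.dosage[:, idx] @ beta))
    # center/scale cohort means so the link sees O(1) inputs
    if grex_means:
        vals = np.array(list(grex_means.values()))
        mu, sd = vals.mean(), vals.std() or 1.0
        grex_means = {k: (v - mu) / sd for k, v in grex_means.items()}
    contacts, contact_truth = simulate_contact_matrix(anns, grex_means, config, rng)
    plus, minus = simulate_strand_signal(anns, rng)
    truth.link_function = contact_truth.link_function
    truth.link_params = contact_truth.link_params
    truth.noiseless_contact = contact_truth.noiseless_contact
    return {
        "config": config,
        "genotypes": genos,
        "annotations": anns,
        "expression": expr,
        "grex_means": grex_means,
        "contacts": contacts,
        "signal_plus": plus,
        "signal_minus": minus,
        "truth": truth,
    }
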