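"""Per-transcript cis models of genetically regulated expression (GReX).

The workflow follows the PrediXcan family of methods: expression is first
residualized on technical/biological covariates, then an elastic-net
regression (mixing parameter 0.5, penalty chosen by inner cross-validation)
is fit on cis dosages within ±1 Mb of the transcription start site. Model
quality (cv_r2) is the squared Pearson correlation between out-of-fold
predictions and observed expression, computed with nested cross-validation
so the reported performance is not optimistic. A transcript is "imputable"
when cv_r2 > 0 and the correlation-test p-value is below 0.05; only
imputable models are used to impute GReX into a cohort.

Also here: a cis-eQTL scan (per variant-transcript simple linear
regression with Benjamini-Hochberg FDR across all tests in a run) and
summaries comparing eRNA-based and canonical-gene-based model sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

DEFAULT_CIS_WINDOW_BP = 1_000_000


@dataclass
class GenotypeMatrix:
    """Dosage matrix (samples × variants) with variant metadata.

    ``variants`` columns: variant_id, chrom, pos (1-based), maf.
    Missing dosages are mean-imputed per variant on construction.
    """

    dosage: np.ndarray
    variants: pd.DataFrame
    sample_ids: List[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape[1] != len(self.variants):
            raise ValueError("dosage columns must match variant metadata rows")
        if np.isnan(self.dosage).any():
            col_means = np.nanmean(self.dosage, axis=0)
            nan_r, nan_c = np.where(np.isnan(self.dosage))
            self.dosage[nan_r, nan_c] = col_means[nan_c]
        maf = self.variants["maf"].to_numpy()
        if ((maf <= 0) | (maf > 0.5)).any():
            raise ValueError("MAF must lie in (0, 0.5]")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]


@dataclass
class ExpressionMatrix:
    """Expression values (samples × transcripts) plus optional covariates."""

    values: np.ndarray
    transcript_ids: List[str]
    sample_ids: List[str]
    covariates: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.transcript_ids)):
            raise ValueError("expression shape inconsistent with sample/transcript ids")

    def column(self, transcript_id: str) -> np.ndarray:
        return self.values[:, self.transcript_ids.index(transcript_id)]


@dataclass
class GrexModel:
    """Elastic-net cis model of one transcript's expression."""

    transcript_id: str
    snp_ids: List[str]
    weights: np.ndarray
    cv_r2: float
    cv_pvalue: float
    imputable: bool
    trainable: bool = True

    @property
    def n_snps(self) -> int:
        return int(np.count_nonzero(self.weights))


@dataclass
class EqtlSet:
    """Significant cis-eQTLs: one row per retained (variant, transcript)."""

    table: pd.DataFrame  # transcript_id, variant_id, beta, p, fdr
    fdr_threshold: float

    def variants_for(self, transcript_id: str) -> Set[str]:
        sub = self.table[self.table["transcript_id"] == transcript_id]
        return set(sub["variant_id"])

    @property
    def variant_ids(self) -> Set[str]:
        return set(self.table["variant_id"])


@dataclass
class ModelSetSummary:
    proportion_imputable: float
    mean_cv_r2: float
    mean_maf: float
    mean_snps_per_transcript: float
    n_models: int
    snp_count_comparison_p: Optional[float] = None


# ---------------------------------------------------------------------------


def residualize_expression(expr: ExpressionMatrix,
                           covariates: Optional[np.ndarray] = None) -> ExpressionMatrix:
    """OLS-residualize each transcript's expression on covariates.

    An intercept is always included, so residuals are mean-centered.
    Rank-deficient covariate matrices have collinear columns dropped with a
    warning. Residuals are orthogonal to the retained covariate columns.
    """
    X = covariates if covariates is not None else expr.covariates
    n = expr.values.shape[0]
    design = np.ones((n, 1))
    if X is not None:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        design = np.hstack([design, X])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            # greedy drop of columns that do not increase rank
            keep = [0]
            for j in range(1, design.shape[1]):
                cand = design[:, keep + [j]]
                if np.linalg.matrix_rank(cand) > len(keep):
                    keep.append(j)
            warnings.warn(
                f"covariate matrix is rank-deficient; dropped "
                f"{design.shape[1] - len(keep)} collinear column(s)"
            )
            design = design[:, keep]
    coef, *_ = np.linalg.lstsq(design, expr.values, rcond=None)
    resid = expr.values - design @ coef
    return ExpressionMatrix(
        values=resid,
        transcript_ids=list(expr.transcript_ids),
        sample_ids=list(expr.sample_ids),
        covariates=None,
    )


def _cis_variant_indices(genos: GenotypeMatrix, chrom: str, tss: int, window_bp: int
                         ) -> np.ndarray:
    v = genos.variants
    mask = (v["chrom"] == chrom) & (v["pos"] >= tss - window_bp) & (v["pos"] <= tss + window_bp)
    return np.flatnonzero(mask.to_numpy())


def train_cis_elastic_net(
    genos: GenotypeMatrix,
    expr: ExpressionMatrix,
    annotation,
    window_bp: int = DEFAULT_CIS_WINDOW_BP,
    cv_folds: int = 5,
    seed: int = 0,
) -> GrexModel:
    """Nested-CV elastic net of residualized expression on cis dosages.

    Outer folds provide out-of-fold predictions for cv_r2/cv_pvalue; the
    penalty is chosen by inner 5-fold CV within each outer training fold.
    The returned weights come from a final fit on all samples. Transcripts
    with an empty cis window are returned untrainable and non-imputable.
    """
    y = expr.column(annotation.id)
    cis = _cis_variant_indices(genos, annotation.chrom, annotation.tss, window_bp)
    if cis.size == 0:
        return GrexModel(annotation.id, [], np.zeros(0), np.nan, np.nan,
                         imputable=False, trainable=False)
    X = genos.dosage[:, cis]
    n = X.shape[0]
    oof = np.full(n, np.nan)
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)

    def _fit(Xtr, ytr):
        enet = ElasticNetCV(l1_ratio=0.5, cv=5, alphas=30, random_state=seed,
                            max_iter=5000, tol=1e-3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            enet.fit(Xtr, ytr)
        return enet

    for tr, te in kf.split(X):
        enet = _fit(X[tr], y[tr])
        oof[te] = enet.predict(X[te])

    if np.std(oof) == 0 or np.std(y) == 0:
        cv_r2, cv_p = 0.0, 1.0
    else:
        r, cv_p = stats.pearsonr(oof, y)
        # signed squared correlation: an anti-correlated predictor is not predictive
        cv_r2 = float(r * r) if r > 0 else float(-(r * r))
    imputable = bool(cv_r2 > 0 and cv_p < 0.05)

    final = _fit(X, y)
    nz = np.flatnonzero(final.coef_)
    snp_ids = [genos.variants["variant_id"].iloc[cis[i]] for i in nz]
    return GrexModel(annotation.id, snp_ids, final.coef_[nz], float(cv_r2),
                     float(cv_p), imputable=imputable)


def impute_grex(model: GrexModel, genos: GenotypeMatrix) -> Tuple[np.ndarray, float]:
    """GReX = dosage · weights; returns per-sample values and the cohort mean.

    Model SNPs absent from the genotype panel contribute zero, with a
    warning, matching how PrediXcan-style weights are applied to partially
    overlapping panels.
    """
    grex = np.zeros(genos.n_samples)
    idx_by_id = {v: i for i, v in enumerate(genos.variants["variant_id"])}
    missing = []
    for snp, w in zip(model.snp_ids, model.weights):
        j = idx_by_id.get(snp)
        if j is None:
            missing.append(snp)
            continue
        grex += genos.dosage[:, j] * w
    if missing:
        warnings.warn(f"{len(missing)} model SNP(s) missing from genotypes; contributed 0")
    return grex, float(grex.mean())


def map_cis_eqtls(
    genos: GenotypeMatrix,
    expr: ExpressionMatrix,
    annotations: Sequence,
    window_bp: int = DEFAULT_CIS_WINDOW_BP,
    fdr_threshold: float = 0.1,
) -> EqtlSet:
    """Per-variant cis scan: simple linear regression of expression on dosage.

    Slopes, t statistics and p-values follow the additive single-variant
    model; Benjamini-Hochberg FDR is applied across all cis tests in the
    run and pairs with FDR below the threshold are retained. Zero-variance
    variants are skipped.
    """
    rows = []
    var_ids = genos.variants["variant_id"].to_numpy()
    for ann in annotations:
        cis = _cis_variant_indices(genos, ann.chrom, ann.tss, window_bp)
        if cis.size == 0:
            continue
        y = expr.column(ann.id)
        n = y.size
        yc = y - y.mean()
        sy = yc.std()
        if sy == 0:
            continue
        X = genos.dosage[:, cis]
        sx = X.std(axis=0)
        ok = sx > 0
        if not ok.all():
            warnings.warn(f"{(~ok).sum()} zero-variance variant(s) skipped for {ann.id}")
        Xc = X[:, ok] - X[:, ok].mean(axis=0)
        r = (Xc * yc[:, None]).sum(axis=0) / (n * sx[ok] * sy)
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r * r))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        beta = r * sy / sx[ok]
        for vid, b, pv in zip(var_ids[cis[ok]], beta, p):
            rows.append((ann.id, vid, b, pv))
    table = pd.DataFrame(rows, columns=["transcript_id", "variant_id", "beta", "p"])
    if len(table):
        _, fdr, *_ = multipletests(table["p"], method="fdr_bh")
        table["fdr"] = fdr
        table = table[table["fdr"] < fdr_threshold].reset_index(drop=True)
    else:
        table["fdr"] = pd.Series(dtype=float)
    return EqtlSet(table=table, fdr_threshold=fdr_threshold)


def summarize_model_set(
    models: Sequence[GrexModel],
    genos: Optional[GenotypeMatrix] = None,
    other: Optional[Sequence[GrexModel]] = None,
) -> ModelSetSummary:
    """Summary statistics of a trained model set.

    Untrainable transcripts count in the denominator of the imputable
    proportion. When ``other`` is given, SNPs-per-transcript counts of the
    two sets are compared with a two-sided Mann-Whitney U test.
    """
    if not models:
        raise ValueError("at least one model required")
    imputable = [m for m in models if m.imputable]
    prop = len(imputable) / len(models)
    mean_r2 = float(np.mean([m.cv_r2 for m in imputable])) if imputable else float("nan")
    mean_snps = float(np.mean([m.n_snps for m in models]))
    mean_maf = float("nan")
    if genos is not None:
        maf_by_id = dict(zip(genos.variants["variant_id"], genos.variants["maf"]))
        mafs = [maf_by_id[s] for m in models for s in m.snp_ids if s in maf_by_id]
        mean_maf = float(np.mean(mafs)) if mafs else float("nan")
    p_cmp = None
    if other is not None:
        a = [m.n_snps for m in models]
        b = [m.n_snps for m in other]
        p_cmp = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return ModelSetSummary(prop, mean_r2, mean_maf, mean_snps, len(models), p_cmp)
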