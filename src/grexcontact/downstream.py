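"""Association-layer bookkeeping.

These operations sit downstream of the expression and contact models:
Bonferroni significance thresholds for TWAS (optionally divided further
across traits), an individual-level GReX-trait association scan, GWAS
locus classification by eRNA/gene hit content, Mendelian-randomization
causal tallies and the intersection of causal transcripts with contact
pairs, epigenomic peak-overlap fractions, comparison of eRNA vs canonical
gene eQTL sets (Jaccard index and distance to the nearest TSS), the
colocalization tallying rule (posterior probability ≥ 0.7 in at least one
tissue), and the short/long transcript-length split.

Raw counts and fractions are always retained; rounded percentages are for
display only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .contact_pairs import PairDataset, TranscriptAnnotation
from .grex import EqtlSet


# ---------------------------------------------------------------------------
# Thresholds


@dataclass
class ThresholdSpec:
    alpha: float
    n_tests: int
    n_traits: Optional[int]
    threshold: float

    @property
    def display(self) -> str:
        """3-significant-digit scientific display, e.g. '1.23e-06'."""
        return f"{self.threshold:.2e}"


def bonferroni_thresholds(alpha: float, n_tests: int,
                          n_traits: Optional[int] = None) -> ThresholdSpec:
    """Bonferroni-corrected significance threshold: α / n_tests, divided
    further by n_traits for phenome-wide scans."""
    if n_tests <= 0 or (n_traits is not None and n_traits <= 0):
        raise ValueError("test and trait counts must be positive")
    thr = alpha / n_tests
    if n_traits is not None:
        thr /= n_traits
    return ThresholdSpec(alpha, n_tests, n_traits, thr)


# ---------------------------------------------------------------------------
# GReX-trait association (individual-level analogue of summary-based TWAS)


def associate_grex_with_trait(
    grex: pd.DataFrame,
    phenotype: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    binary: Optional[bool] = None,
) -> pd.DataFrame:
    """Per-transcript regression of phenotype on GReX with covariates.

    ``grex``: samples × transcripts. Quantitative phenotypes use OLS,
    binary ones logistic regression; Wald z and p are reported. Transcripts
    with constant GReX are skipped with a flag.
    """
    y = np.asarray(phenotype, dtype=float)
    if binary is None:
        binary = set(np.unique(y)) <= {0.0, 1.0}
    n = y.size
    base = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        base = np.hstack([base, C])
    rows = []
    for tid in grex.columns:
        g = grex[tid].to_numpy(dtype=float)
        if g.std() == 0:
            rows.append((tid, np.nan, np.nan, True))
            continue
        X = np.hstack([base, g[:, None]])
        try:
            if binary:
                fit = sm.Logit(y, X).fit(disp=0)
            else:
                fit = sm.OLS(y, X).fit()
            z = float(fit.tvalues[-1])
            p = float(fit.pvalues[-1])
        except Exception:
            rows.append((tid, np.nan, np.nan, True))
            continue
        rows.append((tid, z, p, False))
    return pd.DataFrame(rows, columns=["transcript_id", "zscore", "p", "skipped"])


# ---------------------------------------------------------------------------
# GWAS locus classification


def classify_gwas_loci(
    loci: pd.DataFrame,
    erna_hits: pd.DataFrame,
    gene_hits: pd.DataFrame,
    erna_threshold: float,
    gene_threshold: float,
    exclude_mhc: bool = True,
) -> pd.DataFrame:
    """Label each locus eRNA-only / gene-only / both / neither.

    ``loci``: locus_id, chrom, start, end [, mhc]. Hits: transcript_id,
    chrom, start, end, p (any tissue). A hit belongs to a locus when its
    transcript interval intersects the locus interval (half-open, ≥1 bp)
    and its p-value beats the class threshold.
    """
    loci = loci.copy()
    if "mhc" not in loci.columns:
        loci["mhc"] = False
    if exclude_mhc:
        loci = loci[~loci["mhc"]].reset_index(drop=True)

    def _has_hit(locus, hits, thr) -> bool:
        if hits.empty:
            return False
        sig = hits[(hits["p"] < thr) & (hits["chrom"] == locus["chrom"])]
        if sig.empty:
            return False
        ov = (sig["start"] < locus["end"]) & (sig["end"] > locus["start"])
        return bool(ov.any())

    labels = []
    for _, locus in loci.iterrows():
        e = _has_hit(locus, erna_hits, erna_threshold)
        g = _has_hit(locus, gene_hits, gene_threshold)
        labels.append("both" if e and g else "eRNA-only" if e
                      else "gene-only" if g else "neither")
    out = loci[["locus_id"]].copy()
    out["label"] = labels
    return out


# ---------------------------------------------------------------------------
# MR tallies and causal-contact intersection


def tally_causal_fraction(mr_pass_flags: Sequence[bool],
                          transcript_ids: Optional[Sequence[str]] = None
                          ) -> Dict[str, float]:
    """Count and percentage of associations with MR causal evidence."""
    flags = np.asarray(mr_pass_flags, dtype=bool)
    n = flags.size
    count = int(flags.sum())
    fraction = 100.0 * count / n if n else 0.0
    out = {"n_total": n, "n_causal": count, "fraction_pct": fraction,
           "fraction_pct_display": round(fraction, 2)}
    if transcript_ids is not None:
        tids = np.asarray(list(transcript_ids))
        out["n_unique_causal_transcripts"] = int(pd.unique(tids[flags]).size)
    return out


def intersect_causal_contacts(
    causal_ernas: Set[str],
    causal_genes: Set[str],
    pairs: PairDataset,
) -> Dict[str, object]:
    """Partition causal transcripts by physical contact.

    A causal eRNA and causal gene are "in contact" when some pair-dataset
    row joins them (in either orientation). Returns the in-contact pairs
    plus the contact-free members of each causal set.
    """
    t = pairs.table
    in_contact: Set[Tuple[str, str]] = set()
    for up, down in zip(t["upstream_id"], t["downstream_id"]):
        if up in causal_ernas and down in causal_genes:
            in_contact.add((up, down))
        elif up in causal_genes and down in causal_ernas:
            in_contact.add((down, up))
    ernas_in = {e for e, _ in in_contact}
    genes_in = {g for _, g in in_contact}
    return {
        "in_contact_pairs": sorted(in_contact),
        "n_in_contact_pairs": len(in_contact),
        "contact_free_ernas": sorted(causal_ernas - ernas_in),
        "contact_free_genes": sorted(causal_genes - genes_in),
        "n_ernas_in_contact": len(ernas_in),
        "n_genes_in_contact": len(genes_in),
    }


# ---------------------------------------------------------------------------
# Peak overlap


def _any_overlap(region: Tuple[str, int, int], peaks: pd.DataFrame) -> bool:
    chrom, start, end = region
    sub = peaks[peaks["chrom"] == chrom]
    if sub.empty:
        return False
    return bool(((sub["start"] < end) & (sub["end"] > start)).any())


def peak_overlap_fractions(
    regions: pd.DataFrame,
    peak_sets: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Per-mark count and fraction of regions overlapping ≥1 peak.

    ``regions`` and each peak set are BED-like frames (chrom, start, end;
    half-open). A composite 'any' row reports regions overlapping at least
    one mark.
    """
    rows = []
    n = len(regions)
    any_hit = np.zeros(n, dtype=bool)
    region_tuples = list(zip(regions["chrom"], regions["start"], regions["end"]))
    for mark, peaks in peak_sets.items():
        hits = np.array([_any_overlap(r, peaks) for r in region_tuples])
        any_hit |= hits
        rows.append((mark, int(hits.sum()), hits.sum() / n if n else 0.0))
    rows.append(("any", int(any_hit.sum()), any_hit.sum() / n if n else 0.0))
    return pd.DataFrame(rows, columns=["mark", "n_overlapping", "fraction"])


# ---------------------------------------------------------------------------
# eQTL set comparison


@dataclass
class EqtlComparison:
    jaccard: float
    median_tss_distance_a: float
    median_tss_distance_b: float
    mannwhitney_p: float
    distances_a: np.ndarray
    distances_b: np.ndarray


def jaccard_index(a: Set[str], b: Set[str]) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def nearest_tss_distances(
    variants: pd.DataFrame,
    tss_table: pd.DataFrame,
) -> np.ndarray:
    """Absolute distance from each variant to the closest TSS on its
    chromosome, via sorted binary search. Variants on chromosomes with no
    TSS get +inf."""
    out = np.full(len(variants), np.inf)
    tss_by_chrom = {c: np.sort(g["tss"].to_numpy()) for c, g in tss_table.groupby("chrom")}
    for i, (chrom, pos) in enumerate(zip(variants["chrom"], variants["pos"])):
        tss = tss_by_chrom.get(chrom)
        if tss is None or tss.size == 0:
            continue
        j = np.searchsorted(tss, pos)
        cands = []
        if j < tss.size:
            cands.append(abs(int(tss[j]) - pos))
        if j > 0:
            cands.append(abs(int(tss[j - 1]) - pos))
        out[i] = min(cands)
    return out


def eqtl_set_comparison(
    erna_eqtls: EqtlSet,
    gene_eqtls: EqtlSet,
    variant_positions: pd.DataFrame,
    tss_table: pd.DataFrame,
) -> EqtlComparison:
    """Compare eRNA vs canonical-gene eQTL sets.

    Jaccard index over variant-id sets; per-class distances to the nearest
    TSS (restricted to variants exclusive to each class, mirroring the
    eQTL-specificity contrast); two-sided Mann-Whitney U on the distance
    distributions. ``variant_positions``: variant_id, chrom, pos.
    ``tss_table``: chrom, tss.
    """
    a = erna_eqtls.variant_ids
    b = gene_eqtls.variant_ids
    j = jaccard_index(a, b)
    vp = variant_positions.set_index("variant_id")
    only_a = sorted(a - b)
    only_b = sorted(b - a)

    def dists(ids: List[str]) -> np.ndarray:
        if not ids:
            return np.array([])
        sub = vp.loc[ids].reset_index()
        return nearest_tss_distances(sub, tss_table)

    da, db = dists(only_a), dists(only_b)
    if da.size and db.size:
        p = float(stats.mannwhitneyu(da, db, alternative="two-sided").pvalue)
    else:
        p = float("nan")
    return EqtlComparison(
        jaccard=j,
        median_tss_distance_a=float(np.median(da)) if da.size else float("nan"),
        median_tss_distance_b=float(np.median(db)) if db.size else float("nan"),
        mannwhitney_p=p,
        distances_a=da,
        distances_b=db,
    )


# ---------------------------------------------------------------------------
# Colocalization tallies


@dataclass
class ColocSummary:
    n_erna_any: int
    n_gene_any: int
    n_both: int
    n_either: int
    n_exclusive_erna: int
    n_exclusive_gene: int
    percent_increase_over_gene: float
    per_signal: pd.DataFrame

    def __post_init__(self) -> None:
        assert self.n_either == self.n_erna_any + self.n_gene_any - self.n_both
        assert self.n_exclusive_erna + self.n_exclusive_gene + self.n_both == self.n_either


def coloc_tally(records: pd.DataFrame, pp_threshold: float = 0.7) -> ColocSummary:
    """Tally GWAS signals colocalizing with eRNA and/or gene eQTLs.

    A signal colocalizes with a class when its posterior probability is ≥
    ``pp_threshold`` (inclusive) in at least one tissue. ``records``
    columns: signal_id, tissue, eqtl_class ('eRNA'|'canonical'), pp.
    The percent increase is exclusive-eRNA / gene-any × 100: the gain in
    explained GWAS signals from adding eRNA eQTLs to gene eQTLs alone.
    """
    if not records["pp"].between(0, 1).all():
        raise ValueError("posterior probabilities must lie in [0, 1]")
    hit = records[records["pp"] >= pp_threshold]
    erna = set(hit.loc[hit["eqtl_class"] == "eRNA", "signal_id"])
    gene = set(hit.loc[hit["eqtl_class"] == "canonical", "signal_id"])
    both = erna & gene
    either = erna | gene
    per_signal = pd.DataFrame(
        {
            "signal_id": sorted(either),
            "erna": [s in erna for s in sorted(either)],
            "gene": [s in gene for s in sorted(either)],
        }
    )
    increase = 100.0 * len(erna - gene) / len(gene) if gene else float("inf")
    return ColocSummary(
        n_erna_any=len(erna),
        n_gene_any=len(gene),
        n_both=len(both),
        n_either=len(either),
        n_exclusive_erna=len(erna - gene),
        n_exclusive_gene=len(gene - erna),
        percent_increase_over_gene=increase,
        per_signal=per_signal,
    )


def coloc_identities_from_counts(n_erna_any: int, n_gene_any: int, n_both: int
                                 ) -> Dict[str, float]:
    """Derive the exclusive/shared accounting from class-level counts."""
    either = n_erna_any + n_gene_any - n_both
    excl_erna = n_erna_any - n_both
    excl_gene = n_gene_any - n_both
    return {
        "n_either": either,
        "n_exclusive_erna": excl_erna,
        "n_exclusive_gene": excl_gene,
        "percent_increase_over_gene": 100.0 * excl_erna / n_gene_any,
        "shared_fraction_pct": 100.0 * n_both / either,
    }


# ---------------------------------------------------------------------------
# Transcript length classification


def classify_transcript_lengths(
    annotations: Sequence[TranscriptAnnotation],
    cutoff_bp: int = 2000,
) -> Dict[str, float]:
    """Split transcripts into short (< cutoff) vs long (≥ cutoff).

    Short eRNAs (< 2 kb) fit the profile of unstable bidirectional ("2D")
    enhancer transcripts; longer ones resemble spliced, polyadenylated
    ("1D") transcripts.
    """
    if not annotations:
        raise ValueError("no annotations provided")
    lengths = np.array([a.length for a in annotations])
    n_short = int((lengths < cutoff_bp).sum())
    n_long = int(lengths.size - n_short)
    return {
        "n_short": n_short,
        "n_long": n_long,
        "pct_short": 100.0 * n_short / lengths.size,
        "pct_long": 100.0 * n_long / lengths.size,
        "pct_short_display": round(100.0 * n_short / lengths.size, 2),
        "pct_long_display": round(100.0 * n_long / lengths.size, 2),
        "median_length": float(np.median(lengths)),
    }
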