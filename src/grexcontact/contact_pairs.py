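"""Binned Hi-C contact handling and pair-dataset assembly.

Contacts arrive as a text "cooler dump" (bin table + pixel table), BEDPE,
or a dense matrix at fixed resolution. They are stored sparsely in upper
triangle canonical form, optionally balanced with iterative correction
(ICE), intersected with transcript annotations (eRNA vs canonical gene),
and turned into the pair-level training table: for every bin pair with at
least one normalized contact, every transcript pair whose classes are
{eRNA, eRNA} or {eRNA, canonical gene} contributes a row carrying the two
mean GReX features, the genomic distance (log1p-transformed), the pair
class by genomic order (enhancer-gene / gene-enhancer / enhancer-enhancer)
and the normalized contact frequency as the regression target.

The nuclear run-on path aggregates stranded bedGraph signal over the same
annotations into log1p expression values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd


@dataclass
class TranscriptAnnotation:
    """Genomic interval of a transcript, 0-based half-open.

    ``tclass`` distinguishes enhancer RNAs from canonical genes; the TSS is
    the strand-aware 5' end (start for '+', end for '-').
    """

    id: str
    tclass: str  # "eRNA" | "canonical"
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.id}: start must be < end ({self.start} >= {self.end})")
        if self.tclass not in ("eRNA", "canonical"):
            raise ValueError(f"{self.id}: class must be 'eRNA' or 'canonical'")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def length(self) -> int:
        return self.end - self.start


def read_bed_annotations(path: str) -> List[TranscriptAnnotation]:
    """Read annotations from BED6 where column 5 holds the class."""
    anns = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, tclass, strand = line.rstrip("\n").split("\t")[:6]
            anns.append(TranscriptAnnotation(name, tclass, chrom, int(start), int(end), strand))
    return anns


@dataclass
class ContactMatrix:
    """Sparse symmetric binned contact matrix.

    ``bins``: chrom, start, end, bin_id (bins tile each chromosome at
    ``resolution``; the last bin may be partial). ``pixels``: bin1_id ≤
    bin2_id, value ≥ 0, one row per unordered bin pair.
    """

    resolution: int
    bins: pd.DataFrame
    pixels: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        px = self.pixels.copy()
        b1 = px["bin1_id"].to_numpy()
        b2 = px["bin2_id"].to_numpy()
        lo, hi = np.minimum(b1, b2), np.maximum(b1, b2)
        px["bin1_id"], px["bin2_id"] = lo, hi
        px = px.groupby(["bin1_id", "bin2_id"], as_index=False)["value"].sum()
        if (px["value"] < 0).any():
            raise ValueError("contact values must be nonnegative")
        self.pixels = px.reset_index(drop=True)
        self.bins = self.bins.reset_index(drop=True)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def to_dense(self) -> np.ndarray:
        m = np.zeros((self.n_bins, self.n_bins))
        i = self.pixels["bin1_id"].to_numpy()
        j = self.pixels["bin2_id"].to_numpy()
        v = self.pixels["value"].to_numpy()
        m[i, j] = v
        m[j, i] = v
        return m


@dataclass
class PairDataset:
    """Pair-level training table with provenance.

    Columns: upstream_id, downstream_id, pair_class, grex_up, grex_down,
    distance_bp, log1p_distance, contact. Pair classes partition the rows;
    (upstream_id, downstream_id) rows are unique.
    """

    table: pd.DataFrame
    provenance: Dict[str, object] = field(default_factory=dict)

    COLUMNS = ["upstream_id", "downstream_id", "pair_class", "grex_up", "grex_down",
               "distance_bp", "log1p_distance", "contact"]
    CLASSES = ("enhancer-gene", "gene-enhancer", "enhancer-enhancer")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"pair table missing columns: {missing}")
        if self.table.duplicated(["upstream_id", "downstream_id"]).any():
            raise ValueError("duplicate (upstream_id, downstream_id) rows")
        bad = set(self.table["pair_class"]) - set(self.CLASSES)
        if bad:
            raise ValueError(f"unknown pair classes: {bad}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def class_counts(self) -> Dict[str, int]:
        vc = self.table["pair_class"].value_counts()
        return {c: int(vc.get(c, 0)) for c in self.CLASSES}

    def features(self, with_distance: bool = False) -> np.ndarray:
        cols = ["grex_up", "grex_down"] + (["log1p_distance"] if with_distance else [])
        return self.table[cols].to_numpy(dtype=float)

    @property
    def contact(self) -> np.ndarray:
        return self.table["contact"].to_numpy(dtype=float)

    def to_tsv(self, path: str) -> None:
        self.table[self.COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str, **provenance) -> "PairDataset":
        return cls(pd.read_csv(path, sep="\t"), provenance=dict(provenance))


# ---------------------------------------------------------------------------
# Loading


def _bins_from_intervals(intervals: pd.DataFrame, resolution: int) -> pd.DataFrame:
    """Construct a tiling bin table covering all observed intervals."""
    rows = []
    bin_id = 0
    for chrom, grp in intervals.groupby("chrom", sort=True):
        extent = int(grp["end"].max())
        n = int(np.ceil(extent / resolution))
        for k in range(n):
            rows.append((chrom, k * resolution, min((k + 1) * resolution, extent), bin_id))
            bin_id += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "bin_id"])


def load_contacts(
    path,
    dialect: str = "cooler-dump",
    resolution: Optional[int] = None,
    bins_path: Optional[str] = None,
    normalized: bool = False,
) -> ContactMatrix:
    """Read contacts in one of three text dialects.

    ``cooler-dump``: two files — a bin table (chrom/start/end/bin_id, pass
    as ``bins_path``) and a pixel table (bin1_id/bin2_id/count). ``bedpe``:
    chrom1 start1 end1 chrom2 start2 end2 value; anchors must align to the
    declared resolution. ``dense``: a square TSV matrix, symmetric, one
    chromosome tiled at ``resolution``.
    """
    if dialect == "cooler-dump":
        if bins_path is None:
            raise ValueError("cooler-dump dialect requires bins_path")
        bins = pd.read_csv(bins_path, sep="\t")
        bins.columns = [c.lower() for c in bins.columns]
        pixels = pd.read_csv(path, sep="\t")
        pixels.columns = [c.lower() for c in pixels.columns]
        pixels = pixels.rename(columns={"count": "value"})
        res = resolution or int((bins["end"] - bins["start"]).max())
        return ContactMatrix(res, bins[["chrom", "start", "end", "bin_id"]],
                             pixels[["bin1_id", "bin2_id", "value"]], normalized=normalized)

    if dialect == "bedpe":
        if resolution is None:
            raise ValueError("bedpe dialect requires resolution")
        df = pd.read_csv(path, sep="\t", header=None)
        df = df.iloc[:, :7]
        df.columns = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "value"]
        for side in ("1", "2"):
            if (df[f"start{side}"] >= df[f"end{side}"]).any():
                bad = df.index[df[f"start{side}"] >= df[f"end{side}"]][0]
                raise ValueError(f"BEDPE row {bad}: start >= end on side {side}")
            misaligned = df[f"start{side}"].to_numpy() % resolution != 0
            if misaligned.any():
                bad = df.index[misaligned][0]
                raise ValueError(
                    f"BEDPE row {bad}: start{side}={df[f'start{side}'][bad]} not aligned "
                    f"to resolution {resolution}"
                )
        intervals = pd.concat([
            df[["chrom1", "start1", "end1"]].rename(
                columns={"chrom1": "chrom", "start1": "start", "end1": "end"}),
            df[["chrom2", "start2", "end2"]].rename(
                columns={"chrom2": "chrom", "start2": "start", "end2": "end"}),
        ])
        bins = _bins_from_intervals(intervals, resolution)
        key = {(c, s): b for c, s, b in zip(bins["chrom"], bins["start"], bins["bin_id"])}
        b1 = [key[(c, s)] for c, s in zip(df["chrom1"], df["start1"])]
        b2 = [key[(c, s)] for c, s in zip(df["chrom2"], df["start2"])]
        pixels = pd.DataFrame({"bin1_id": b1, "bin2_id": b2, "value": df["value"]})
        return ContactMatrix(resolution, bins, pixels, normalized=normalized)

    if dialect == "dense":
        if resolution is None:
            raise ValueError("dense dialect requires resolution")
        m = np.loadtxt(path, delimiter="\t") if isinstance(path, str) else np.asarray(path, float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("dense matrix must be square")
        if not np.allclose(m, m.T):
            raise ValueError("dense matrix must be symmetric")
        n = m.shape[0]
        bins = pd.DataFrame({"chrom": "chrS", "start": np.arange(n) * resolution,
                             "end": (np.arange(n) + 1) * resolution, "bin_id": np.arange(n)})
        i, j = np.triu_indices(n)
        keep = m[i, j] != 0
        pixels = pd.DataFrame({"bin1_id": i[keep], "bin2_id": j[keep], "value": m[i, j][keep]})
        return ContactMatrix(resolution, bins, pixels, normalized=normalized)

    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# ICE normalization


def ice_normalize(m: ContactMatrix, max_iter: int = 500, tol: float = 1e-8) -> ContactMatrix:
    """Iterative correction: balance the matrix so unmasked row sums equalize.

    Zero-coverage bins are masked. Each iteration divides by the current
    row-bias estimate (row sum / mean row sum); convergence when the
    coefficient of variation of unmasked row sums drops below ``tol``. The
    output is rescaled so the total contact sum is preserved. Idempotent on
    already-balanced input.
    """
    if m.normalized:
        warnings.warn("matrix already flagged normalized; re-balancing anyway")
    dense = m.to_dense()
    coverage = dense.sum(axis=1)
    mask = coverage > 0
    W = dense[np.ix_(mask, mask)].astype(float)
    total = W.sum()
    converged = W.size == 0
    for _ in range(max_iter):
        s = W.sum(axis=1)
        mean_s = s.mean()
        cv = s.std() / mean_s if mean_s > 0 else 0.0
        if cv < tol:
            converged = True
            break
        b = s / mean_s
        W = W / np.outer(b, b)
    if not converged:
        raise RuntimeError(
            f"ICE did not converge in {max_iter} iterations "
            f"(row-sum CV = {cv:.3e}, tol = {tol:.1e})"
        )
    if W.sum() > 0:
        W = W * (total / W.sum())
    out = np.zeros_like(dense)
    out[np.ix_(mask, mask)] = W
    i, j = np.triu_indices(m.n_bins)
    keep = out[i, j] != 0
    pixels = pd.DataFrame({"bin1_id": i[keep], "bin2_id": j[keep], "value": out[i, j][keep]})
    return ContactMatrix(m.resolution, m.bins.copy(), pixels, normalized=True)


# ---------------------------------------------------------------------------
# Annotation overlap and pair assembly


def overlap_bins_with_transcripts(
    m: ContactMatrix, annotations: Sequence[TranscriptAnnotation]
) -> Dict[int, Set[str]]:
    """Map bin_id → transcript ids overlapping the bin by ≥1 bp.

    Half-open interval semantics (bedtools-style); strand is ignored.
    Annotations extending past the chromosome extent are clipped with a
    warning.
    """
    bin_map: Dict[int, Set[str]] = {}
    by_chrom = {chrom: grp.sort_values("start") for chrom, grp in m.bins.groupby("chrom")}
    for ann in annotations:
        grp = by_chrom.get(ann.chrom)
        if grp is None:
            continue
        extent = int(grp["end"].max())
        start, end = ann.start, ann.end
        if end > extent:
            warnings.warn(f"{ann.id} extends past {ann.chrom} extent {extent}; clipped")
            end = extent
            if start >= end:
                continue
        res = m.resolution
        first = start // res
        last = (end - 1) // res
        base = int(grp["bin_id"].iloc[0])
        n = len(grp)
        for k in range(first, min(last, n - 1) + 1):
            bin_map.setdefault(base + k, set()).add(ann.id)
    return bin_map


def build_pair_dataset(
    m: ContactMatrix,
    bin_map: Mapping[int, Set[str]],
    grex_means: Mapping[str, float],
    annotations: Sequence[TranscriptAnnotation],
    min_contact: float = 1.0,
    provenance: Optional[Dict[str, object]] = None,
) -> PairDataset:
    """Assemble the pair-level training table from a normalized matrix.

    For every cis pixel with contact ≥ ``min_contact`` and distinct bins,
    emit all transcript pairs (one from each bin) whose classes are
    {eRNA, eRNA} or {eRNA, canonical}; both members must have a GReX value.
    The bin1-side member is upstream (bins are in genomic order); distance
    is downstream bin start − upstream bin start. A transcript pair seen in
    several pixels keeps the pixel with the maximum contact.
    """
    if not m.normalized:
        raise ValueError("build_pair_dataset requires an ICE-normalized matrix")
    ann_by_id = {a.id: a for a in annotations}
    bins = m.bins.set_index("bin_id")
    best: Dict[Tuple[str, str], Tuple[float, int]] = {}  # -> (contact, distance)
    px = m.pixels
    px = px[(px["value"] >= min_contact) & (px["bin1_id"] != px["bin2_id"])]
    for b1, b2, value in px.itertuples(index=False):
        t1s = bin_map.get(b1)
        t2s = bin_map.get(b2)
        if not t1s or not t2s:
            continue
        r1, r2 = bins.loc[b1], bins.loc[b2]
        if r1["chrom"] != r2["chrom"]:
            continue  # trans pixels excluded; distance undefined
        distance = int(r2["start"] - r1["start"])
        for ta in t1s:
            ca = ann_by_id[ta].tclass
            for tb in t2s:
                if ta == tb:
                    continue
                cb = ann_by_id[tb].tclass
                if ca == "canonical" and cb == "canonical":
                    continue
                if ta not in grex_means or tb not in grex_means:
                    continue
                key = (ta, tb)
                prev = best.get(key)
                if prev is None or value > prev[0]:
                    best[key] = (float(value), distance)
    rows = []
    for (up, down), (value, distance) in best.items():
        cu, cd = ann_by_id[up].tclass, ann_by_id[down].tclass
        if cu == "eRNA" and cd == "eRNA":
            pc = "enhancer-enhancer"
        elif cu == "eRNA":
            pc = "enhancer-gene"
        else:
            pc = "gene-enhancer"
        rows.append((up, down, pc, grex_means[up], grex_means[down],
                     distance, float(np.log1p(distance)), value))
    table = pd.DataFrame(rows, columns=PairDataset.COLUMNS)
    prov = dict(provenance or {})
    prov.setdefault("resolution", m.resolution)
    prov.setdefault("min_contact", min_contact)
    return PairDataset(table.sort_values(["upstream_id", "downstream_id"]).reset_index(drop=True),
                       provenance=prov)


def split_train_test(d: PairDataset, fraction: float = 0.8, seed: int = 0
                     ) -> Tuple[PairDataset, PairDataset]:
    """Uniform random split; train size = floor(n · fraction)."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    n = len(d)
    n_train = int(np.floor(n * fraction))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    tr = d.table.iloc[np.sort(perm[:n_train])].reset_index(drop=True)
    te = d.table.iloc[np.sort(perm[n_train:])].reset_index(drop=True)
    prov = dict(d.provenance)
    return (PairDataset(tr, {**prov, "split": "train", "fraction": fraction}),
            PairDataset(te, {**prov, "split": "test", "fraction": fraction}))


def split_sizes(n: int, fraction: float = 0.8) -> Tuple[int, int]:
    """Deterministic (train, test) sizes under the floor rule."""
    n_train = int(np.floor(n * fraction))
    return n_train, n - n_train


# ---------------------------------------------------------------------------
# Stranded run-on signal aggregation


def read_bedgraph(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    return df


def aggregate_strand_signal(
    plus: pd.DataFrame,
    minus: pd.DataFrame,
    annotations: Sequence[TranscriptAnnotation],
) -> Dict[str, float]:
    """Combine plus- and minus-strand bedGraph signal per transcript.

    For each transcript, signal × overlapped-bp is summed over both strands
    across the transcript interval, then log1p-transformed — the nuclear
    run-on expression used by the baseline contact model.
    """
    for name, df in (("plus", plus), ("minus", minus)):
        if (df["value"] < 0).any():
            raise ValueError(f"negative signal values on {name} strand")
    combined = pd.concat([plus, minus], ignore_index=True)
    out: Dict[str, float] = {}
    by_chrom = {c: g.sort_values("start").reset_index(drop=True)
                for c, g in combined.groupby("chrom")}
    for ann in annotations:
        grp = by_chrom.get(ann.chrom)
        total = 0.0
        if grp is not None:
            s = grp["start"].to_numpy()
            e = grp["end"].to_numpy()
            v = grp["value"].to_numpy()
            ov = np.minimum(e, ann.end) - np.maximum(s, ann.start)
            sel = ov > 0
            total = float((v[sel] * ov[sel]).sum())
        out[ann.id] = float(np.log1p(total))
    return out
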