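"""scRNA-seq preprocessing, QC, differential expression and signatures.

The pipeline runs in a fixed order on a two-condition UMI count matrix:

1. ``downsample_to_match`` — subsample the deeper-sequenced condition
   without replacement so both conditions have the same population-level
   library size.
2. ``remove_invalid_genes`` — drop genes undetected in all cells of
   either condition, and all rows whose gene symbol maps to more than one
   stable gene ID.
3. ``remove_outlier_cells`` — drop cells whose log library size or log
   detected-gene count is >= 5 MADs below the population median, or whose
   mitochondrial expression percentage is >= 5 MADs above it (MAD scaled
   by 1.4826 for normal consistency; metrics computed once, no iterative
   re-filtering).
4. ``log_normalize`` — per-cell scaling to a fixed total (10,000) and
   log1p, i.e. ln(1 + count / cell_total * scale).
5. ``wilcoxon_deg`` — two-sided Wilcoxon rank-sum per gene with a
   detection-fraction (min.pct) and average-logFC prefilter, Bonferroni
   adjusted over the whole matrix.

``intersect_signatures`` intersects the up- and down-regulated
significant sets of two DEG tables (e.g. escapee vs. non-escapee and
escapee vs. untreated-proliferative) and ``overlap_test`` scores a
signature against a published gene set by one-sided Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.io import mmread, mmwrite

__all__ = [
    "CountMatrix",
    "QCReport",
    "downsample_to_match",
    "remove_invalid_genes",
    "remove_outlier_cells",
    "log_normalize",
    "wilcoxon_deg",
    "intersect_signatures",
    "overlap_test",
    "read_gmt",
    "MAD_SCALE",
]

MAD_SCALE = 1.4826  # normal-consistency factor


@dataclass
class CountMatrix:
    """Genes x cells UMI counts with gene symbols, stable IDs and
    per-cell condition labels."""

    counts: np.ndarray
    gene_ids: list[str]
    symbols: list[str]
    cell_ids: list[str]
    condition: np.ndarray

    def __post_init__(self) -> None:
        if sparse.issparse(self.counts):
            self.counts = np.asarray(self.counts.todense())
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x cells)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = self.counts.astype(np.int64)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.symbols) != n_genes:
            raise ValueError("gene annotation length mismatch")
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length mismatch")
        self.condition = np.asarray(self.condition)
        if self.condition.size != n_cells:
            raise ValueError("condition length mismatch")
        if len(set(zip(self.gene_ids, self.symbols))) != n_genes:
            raise ValueError("(gene_id, symbol) rows must be unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.condition:
            seen.setdefault(str(c))
        return list(seen)

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        gm = np.ones(self.shape[0], bool) if gene_mask is None else np.asarray(gene_mask)
        cm = np.ones(self.shape[1], bool) if cell_mask is None else np.asarray(cell_mask)
        return CountMatrix(
            self.counts[np.ix_(gm, cm)],
            [g for g, k in zip(self.gene_ids, gm) if k],
            [s for s, k in zip(self.symbols, gm) if k],
            [c for c, k in zip(self.cell_ids, cm) if k],
            self.condition[cm],
        )

    # --- IO -------------------------------------------------------------
    def to_mtx_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mmwrite(outdir / "matrix.mtx", sparse.coo_matrix(self.counts))
        pd.DataFrame({"gene_id": self.gene_ids, "symbol": self.symbols}).to_csv(
            outdir / "genes.tsv", sep="\t", header=False, index=False)
        pd.Series(self.cell_ids).to_csv(
            outdir / "barcodes.tsv", sep="\t", header=False, index=False)
        pd.DataFrame({"cell_id": self.cell_ids, "condition": self.condition}).to_csv(
            outdir / "conditions.tsv", sep="\t", index=False)

    @classmethod
    def from_mtx_dir(cls, indir) -> "CountMatrix":
        indir = Path(indir)
        counts = np.asarray(mmread(indir / "matrix.mtx").todense())
        genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None,
                            names=["gene_id", "symbol"])
        barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
        cond = pd.read_csv(indir / "conditions.tsv", sep="\t")
        cond = cond.set_index("cell_id").loc[barcodes, "condition"].to_numpy()
        return cls(counts, genes.gene_id.tolist(), genes.symbol.tolist(),
                   barcodes.astype(str).tolist(), cond)

    @classmethod
    def from_csv(cls, path) -> "CountMatrix":
        """CSV with gene_id and symbol columns followed by one column per cell;
        first row of cell columns after the header is read from a companion
        long header 'cell@condition'."""
        df = pd.read_csv(path)
        meta = df[["gene_id", "symbol"]]
        data = df.drop(columns=["gene_id", "symbol"])
        cells, conds = zip(*(c.split("@", 1) for c in data.columns))
        return cls(data.to_numpy(), meta.gene_id.tolist(), meta.symbol.tolist(),
                   list(cells), np.asarray(conds))

    def to_csv(self, path) -> None:
        cols = [f"{c}@{k}" for c, k in zip(self.cell_ids, self.condition)]
        df = pd.DataFrame(self.counts, columns=cols)
        df.insert(0, "symbol", self.symbols)
        df.insert(0, "gene_id", self.gene_ids)
        df.to_csv(path, index=False)


@dataclass
class QCReport:
    removed_genes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene_id", "symbol", "reason"]))
    removed_cells: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["cell_id", "reason"]))
    cell_metrics: pd.DataFrame | None = None


def downsample_to_match(cm: CountMatrix, rng) -> CountMatrix:
    """Subsample the deeper condition's UMIs so both condition totals match.

    Every UMI of the deeper condition is an equally likely unit and the
    draw is without replacement (multivariate hypergeometric over the
    nonzero count entries), so the retained grand total exactly equals the
    shallower condition's.  The shallower condition is unchanged.
    """
    rng = np.random.default_rng(rng)
    conds = cm.conditions()
    if len(conds) != 2:
        raise ValueError("downsampling requires exactly two conditions")
    totals = {c: int(cm.counts[:, cm.condition == c].sum()) for c in conds}
    if min(totals.values()) == 0:
        raise ValueError("one condition has no counts")
    deep = max(conds, key=lambda c: totals[c])
    shallow = min(conds, key=lambda c: totals[c])
    if totals[deep] == totals[shallow]:
        return replace(cm, counts=cm.counts.copy())
    mask = cm.condition == deep
    block = cm.counts[:, mask]
    flat = block.ravel()
    nz = np.flatnonzero(flat)
    kept = rng.multivariate_hypergeometric(flat[nz], totals[shallow])
    new_flat = np.zeros_like(flat)
    new_flat[nz] = kept
    counts = cm.counts.copy()
    counts[:, mask] = new_flat.reshape(block.shape)
    return replace(cm, counts=counts)


def remove_invalid_genes(cm: CountMatrix) -> tuple[CountMatrix, QCReport]:
    """Drop genes not detected in at least one cell of *both* conditions,
    and every row whose symbol corresponds to multiple gene IDs."""
    detected = cm.counts > 0
    ok = np.ones(cm.shape[0], dtype=bool)
    for c in cm.conditions():
        ok &= detected[:, cm.condition == c].any(axis=1)
    reasons = np.where(ok, "", "undetected-in-a-condition").astype(object)

    sym = pd.DataFrame({"symbol": cm.symbols, "gene_id": cm.gene_ids})
    multi = sym.groupby("symbol")["gene_id"].nunique()
    bad_sym = set(multi.index[multi > 1])
    for i, s in enumerate(cm.symbols):
        if s in bad_sym:
            reasons[i] = "multi-ID-symbol"  # takes precedence in the report
            ok[i] = False

    report = QCReport(removed_genes=pd.DataFrame({
        "gene_id": [g for g, k in zip(cm.gene_ids, ok) if not k],
        "symbol": [s for s, k in zip(cm.symbols, ok) if not k],
        "reason": [r for r, k in zip(reasons, ok) if not k],
    }))
    return cm.subset(gene_mask=ok), report


def _mad(x: np.ndarray) -> float:
    return MAD_SCALE * float(np.median(np.abs(x - np.median(x))))


def remove_outlier_cells(
    cm: CountMatrix, mito_gene_ids, n_mads: float = 5.0
) -> tuple[CountMatrix, QCReport]:
    """Remove cells failing any of the three MAD-based outlier rules.

    A cell is an outlier if its log library size or log detected-gene
    count is at least ``n_mads`` MADs *below* the population median, or
    its mitochondrial percentage at least ``n_mads`` MADs *above* it.
    All three metrics are computed once on the incoming matrix.
    """
    if cm.shape[1] < 3:
        raise ValueError("need >= 3 cells for MAD-based QC")
    lib = cm.counts.sum(axis=0).astype(float)
    n_genes = (cm.counts > 0).sum(axis=0).astype(float)
    with np.errstate(divide="ignore"):
        log_lib = np.log(lib)
        log_genes = np.log(n_genes)
    mito_set = set(mito_gene_ids)
    mito_rows = np.array([g in mito_set for g in cm.gene_ids])
    mito_counts = cm.counts[mito_rows, :].sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(lib > 0, 100.0 * mito_counts / lib, 0.0)

    # strict deviation from the median is additionally required so that a
    # zero-MAD metric (e.g. no mitochondrial genes at all) flags nobody
    def _low(x):
        return (x <= np.median(x) - n_mads * _mad(x)) & (x < np.median(x))

    def _high(x):
        return (x >= np.median(x) + n_mads * _mad(x)) & (x > np.median(x))

    fail_lib = _low(log_lib)
    fail_genes = _low(log_genes)
    fail_mito = _high(mito_pct)

    reasons = []
    for fl, fg, fm in zip(fail_lib, fail_genes, fail_mito):
        r = [name for flag, name in
             ((fl, "low-library"), (fg, "low-genes"), (fm, "high-mito")) if flag]
        reasons.append(";".join(r))
    keep = ~(fail_lib | fail_genes | fail_mito)
    if not keep.any():
        raise ValueError("all cells removed by outlier QC")
    metrics = pd.DataFrame({
        "cell_id": cm.cell_ids, "log_library": log_lib,
        "log_n_genes": log_genes, "mito_pct": mito_pct,
    })
    report = QCReport(
        removed_cells=pd.DataFrame({
            "cell_id": [c for c, k in zip(cm.cell_ids, keep) if not k],
            "reason": [r for r, k in zip(reasons, keep) if not k],
        }),
        cell_metrics=metrics,
    )
    return cm.subset(cell_mask=keep), report


def log_normalize(cm: CountMatrix, scale: float = 1e4) -> np.ndarray:
    """ln(1 + count / cell_total * scale) per entry; genes x cells floats."""
    totals = cm.counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        raise ValueError("zero-total cell; run QC first")
    return np.log1p(cm.counts / totals[None, :] * scale)


def _avg_logfc(norm_a: np.ndarray, norm_b: np.ndarray) -> np.ndarray:
    # difference of ln(mean(back-transformed) + 1) between groups
    return (np.log(np.expm1(norm_a).mean(axis=1) + 1.0)
            - np.log(np.expm1(norm_b).mean(axis=1) + 1.0))


def wilcoxon_deg(
    norm: np.ndarray,
    genes: list[str],
    group_a: np.ndarray,
    group_b: np.ndarray,
    logfc_threshold: float = 0.25,
    min_pct: float = 0.01,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression between two cell groups.

    Genes are tested only when detected in at least ``min_pct`` of cells
    in either group and when the absolute average logFC is at least
    ``logfc_threshold``; p values use the two-sided normal approximation
    with tie correction and are Bonferroni-adjusted over *all* genes in
    the matrix.  ``group_a``/``group_b`` are disjoint boolean masks or
    index arrays over cells; positive logFC means higher in group A.
    """
    norm = np.asarray(norm, dtype=float)
    a_idx = np.flatnonzero(group_a) if np.asarray(group_a).dtype == bool else np.asarray(group_a)
    b_idx = np.flatnonzero(group_b) if np.asarray(group_b).dtype == bool else np.asarray(group_b)
    if np.intersect1d(a_idx, b_idx).size:
        raise ValueError("groups overlap")
    if a_idx.size < 3 or b_idx.size < 3:
        raise ValueError("both groups need >= 3 cells")
    A, B = norm[:, a_idx], norm[:, b_idx]
    pct1 = (A > 0).mean(axis=1)
    pct2 = (B > 0).mean(axis=1)
    logfc = _avg_logfc(A, B)
    tested = (np.maximum(pct1, pct2) >= min_pct) & (np.abs(logfc) >= logfc_threshold)

    n_total = norm.shape[0]
    pvals = np.full(n_total, np.nan)
    if tested.any():
        res = stats.mannwhitneyu(A[tested], B[tested], axis=1,
                                 alternative="two-sided", method="asymptotic")
        pvals[tested] = res.pvalue
    padj = np.minimum(pvals * n_total, 1.0)
    out = pd.DataFrame({
        "gene": genes,
        "avg_logFC": logfc,
        "pct_1": pct1,
        "pct_2": pct2,
        "p_val": pvals,
        "p_val_adj": padj,
    })
    out["significant"] = (out.p_val_adj < alpha).fillna(False)
    out["direction"] = np.where(logfc > 0, "up", np.where(logfc < 0, "down", "none"))
    return out


def intersect_signatures(
    deg_a: pd.DataFrame, deg_b: pd.DataFrame
) -> tuple[list[str], list[str]]:
    """Intersect significant up- and down-regulated genes of two DEG tables.

    Both tables must be oriented so positive logFC means up in the focal
    group (e.g. escapees); returns (up list, down list), sorted.
    """

    def sig(df: pd.DataFrame, direction: str) -> set[str]:
        return set(df.loc[df.significant & (df.direction == direction), "gene"])

    up = sorted(sig(deg_a, "up") & sig(deg_b, "up"))
    down = sorted(sig(deg_a, "down") & sig(deg_b, "down"))
    return up, down


def overlap_test(list_a, list_b, universe_size: int) -> tuple[float, float]:
    """One-sided Fisher's exact enrichment test for two gene lists.

    Returns (odds ratio, p).  The universe must contain the union of the
    two lists.
    """
    sa, sb = set(list_a), set(list_b)
    if universe_size < len(sa | sb):
        raise ValueError("universe smaller than union of lists")
    k = len(sa & sb)
    table = [[k, len(sa) - k],
             [len(sb) - k, universe_size - len(sa) - len(sb) + k]]
    odds, p = stats.fisher_exact(table, alternative="greater")
    return float(odds), float(p)


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
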