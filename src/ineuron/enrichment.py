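"""Count-matrix QC, differential expression and gene-set enrichment.

The count matrix is an :class:`anndata.AnnData` (cells x genes, raw integer
counts in ``X``) with cell annotations in ``obs`` (species, line, day, batch,
cluster) and a boolean ``mito`` column in ``var``.

The analysis chain mirrors a standard single-cell comparison of neuronal
cells against progenitors: cell QC (genes detected in [500, 6000],
mitochondrial fraction <= 5 %), gene QC (mean count > 0.1 in at least one
batch), two-sided Wilcoxon rank-sum differential expression on
counts-per-10k log1p values with Benjamini-Hochberg adjustment
(DEG: adjusted p < 0.05 and log2 fold change > 0.25, higher in the first
group), one-sided exact-binomial enrichment of DEGs in gene-set terms
against a background, one-sided Fisher enrichment with BH FDR, and Pearson
correlation of per-term enrichment profiles with the 0.7 reporting
threshold.
"""
from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "qc_cells",
    "qc_genes",
    "normalize_cp10k_log1p",
    "find_degs",
    "binomial_enrichment",
    "fisher_enrichment_fdr",
    "enrichment_correlation",
    "read_gmt",
    "write_gmt",
    "mito_flag_from_symbols",
]

MIN_GENES_DETECTED = 500
MAX_GENES_DETECTED = 6000
MAX_MITO_FRACTION = 0.05
MIN_BATCH_MEAN = 0.1
DEG_ALPHA = 0.05
DEG_LFC = 0.25


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense() if hasattr(x, "todense") else x,
                      dtype=float)


def mito_flag_from_symbols(genes: Sequence[str],
                           prefix: str = "MT-") -> np.ndarray:
    """Default mitochondrial annotation: symbols starting with ``MT-``."""
    return np.array([g.upper().startswith(prefix) for g in genes])


def qc_cells(adata: ad.AnnData,
             min_genes: int = MIN_GENES_DETECTED,
             max_genes: int = MAX_GENES_DETECTED,
             max_mito: float = MAX_MITO_FRACTION,
             mito_col: str = "mito") -> ad.AnnData:
    """Retain cells with min_genes <= genes detected <= max_genes and a
    mitochondrial transcript fraction of at most ``max_mito``."""
    if mito_col not in adata.var:
        raise ValueError(f"var[{mito_col!r}] (mitochondrial flag) is required")
    x = _dense(adata.X)
    detected = (x > 0).sum(axis=1)
    totals = x.sum(axis=1)
    mito = np.asarray(adata.var[mito_col], dtype=bool)
    frac = np.divide(x[:, mito].sum(axis=1), totals,
                     out=np.zeros(len(totals)), where=totals > 0)
    keep = (detected >= min_genes) & (detected <= max_genes) & (
        frac <= max_mito)
    log.info("cell QC: retained %d / %d cells", int(keep.sum()), adata.n_obs)
    return adata[keep].copy()


def qc_genes(adata: ad.AnnData, batch_col: str = "batch") -> ad.AnnData:
    """Keep a gene iff its mean count exceeds 0.1 in at least one batch."""
    if batch_col not in adata.obs:
        raise ValueError(f"obs[{batch_col!r}] is required")
    x = _dense(adata.X)
    batches = adata.obs[batch_col].to_numpy()
    best = np.zeros(adata.n_vars)
    for b in pd.unique(batches):
        mask = batches == b
        if not mask.any():
            raise ValueError(f"batch {b!r} is empty")
        best = np.maximum(best, x[mask].mean(axis=0))
    keep = best > MIN_BATCH_MEAN
    log.info("gene QC: retained %d / %d genes", int(keep.sum()), adata.n_vars)
    return adata[:, keep].copy()


def normalize_cp10k_log1p(x: np.ndarray) -> np.ndarray:
    """Counts-per-10k depth normalisation followed by log1p."""
    totals = x.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(x / totals * 1e4)


def find_degs(adata: ad.AnnData, group_a: np.ndarray, group_b: np.ndarray,
              alpha: float = DEG_ALPHA, lfc_cutoff: float = DEG_LFC,
              pseudo: float = 1e-9) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum DE between two cell groups.

    ``group_a``/``group_b`` are boolean masks over cells; direction is
    "higher in group_a" (the neuronal cells in the study design). Returns a
    frame with log2_fold_change, p_value, adjusted_p (BH) and deg_flag.
    """
    group_a = np.asarray(group_a, dtype=bool)
    group_b = np.asarray(group_b, dtype=bool)
    if group_a.sum() < 3 or group_b.sum() < 3:
        raise ValueError("both groups need at least 3 cells")
    x = _dense(adata.X)
    norm = normalize_cp10k_log1p(x)
    xa, xb = norm[group_a], norm[group_b]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant genes give p = 1
        res = stats.mannwhitneyu(xa, xb, axis=0, alternative="two-sided",
                                 method="auto")
    pvals = np.nan_to_num(res.pvalue, nan=1.0)
    cp10k = np.expm1(norm)
    lfc = np.log2(cp10k[group_a].mean(axis=0) + pseudo) - np.log2(
        cp10k[group_b].mean(axis=0) + pseudo)
    adj = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame({
        "gene": adata.var_names,
        "log2_fold_change": lfc,
        "p_value": pvals,
        "adjusted_p": adj,
    })
    out["deg_flag"] = (out["adjusted_p"] < alpha) & (
        out["log2_fold_change"] > lfc_cutoff)
    return out


def _contingency(degs: set, members: Iterable[str],
                 background: set) -> tuple[int, int, int, int]:
    term = set(members) & background
    k = len(term & degs)
    return k, len(degs), len(term), len(background)


def binomial_enrichment(degs: Sequence[str],
                        sets: Mapping[str, tuple[str, Sequence[str]]],
                        background: Sequence[str],
                        alpha: float = 0.05) -> pd.DataFrame:
    """One-sided exact binomial enrichment per term.

    With n DEGs of which k fall in a term covering K of the N background
    genes, p = P(X >= k), X ~ Binomial(n, K/N). Terms absent from the
    background are skipped with a warning. ``enriched_flag`` uses the raw
    p < alpha rule; a BH column is provided alongside.
    """
    bg = set(background)
    dg = set(degs) & bg
    if set(degs) - bg:
        raise ValueError("DEGs must be a subset of the background")
    rows = []
    for term_id, (name, members) in sets.items():
        k, n, K, N = _contingency(dg, members, bg)
        if K == 0:
            log.warning("term %s has no background genes; skipped", term_id)
            continue
        p = stats.binomtest(k, n, K / N, alternative="greater").pvalue
        rows.append({"term_id": term_id, "term_name": name,
                     "k": k, "n": n, "K": K, "N": N, "p_value": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["enriched_flag"] = out["p_value"] < alpha
    return out


def fisher_enrichment_fdr(degs: Sequence[str],
                          sets: Mapping[str, tuple[str, Sequence[str]]],
                          background: Sequence[str],
                          alpha: float = 0.05) -> pd.DataFrame:
    """One-sided Fisher exact test per term with BH FDR; a term is enriched
    when its FDR is below ``alpha``."""
    bg = set(background)
    dg = set(degs) & bg
    if set(degs) - bg:
        raise ValueError("DEGs must be a subset of the background")
    rows = []
    for term_id, (name, members) in sets.items():
        k, n, K, N = _contingency(dg, members, bg)
        if K == 0:
            log.warning("term %s has no background genes; skipped", term_id)
            continue
        # hypergeometric upper tail: P(X >= k) drawing n from N with K marked
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term_id, "term_name": name,
                     "k": k, "n": n, "K": K, "N": N, "p_value": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["enriched_flag"] = out["fdr"] < alpha
    return out


def enrichment_correlation(profiles: pd.DataFrame,
                           transform: str = "neglog10",
                           threshold: float = 0.7
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation of per-term enrichment profiles.

    ``profiles`` is terms x groups of p-values (or already-transformed
    scores with ``transform='none'``). Returns (r matrix, boolean mask of
    r > threshold, diagonal excluded). Zero-variance profiles yield NaN.
    """
    if profiles.shape[1] < 2 or profiles.shape[0] < 3:
        raise ValueError("need >= 2 profiles of length >= 3")
    vals = profiles.to_numpy(dtype=float)
    if transform == "neglog10":
        vals = -np.log10(np.clip(vals, 1e-300, None))
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(vals, rowvar=False)
    cols = profiles.columns
    rmat = pd.DataFrame(r, index=cols, columns=cols)
    mask = rmat > threshold
    np.fill_diagonal(mask.values, False)
    return rmat, mask


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT gene-set file: term, description, members (tab-separated)."""
    sets = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
        members = [g for g in fields[2:] if g]
        if len(set(members)) != len(members):
            raise ValueError(f"{path}:{lineno}: duplicate genes in term")
        sets[fields[0]] = (fields[1], members)
    return sets


def write_gmt(sets: Mapping[str, tuple[str, Sequence[str]]],
              path: str | Path) -> None:
    lines = ["\t".join([tid, name, *members])
             for tid, (name, members) in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")
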