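"""Fold-internal marker selection and SNP–SV linkage scanning.

Two tools used by the marker-input strategies: a single-marker regression
scan whose pooled p-value ranking picks the most trait-associated markers
(the "10k most associated" strategy, applied to training rows only so no
test-fold phenotype ever influences selection), and a dosage-correlation
LD scan that finds SNPs tagging structural variants at r² ≥ 0.8, the
linked-SNPs strategy. Binary traits enter the scan as {0, 1} class codes
under the same linear-regression ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SV_CLASSES, GenotypeMatrix


@dataclass
class AssociationScan:
    """Per-marker single-regression results for one training fold."""

    table: pd.DataFrame  # id, cls, slope, t_stat, p_value, monomorphic
    trait: str = ""
    fold_id: str = ""


@dataclass
class LinkedSet:
    """SNPs tagging at least one structural variant."""

    pairs: pd.DataFrame  # snp_id, sv_id, sv_class, chrom_snp, pos_snp, chrom_sv, pos_sv, r2
    threshold: float

    @property
    def snp_ids(self) -> list[str]:
        return sorted(set(self.pairs["snp_id"])) if len(self.pairs) else []


def gwas_scan(G_train: GenotypeMatrix, y_train: np.ndarray,
              trait: str = "", fold_id: str = "") -> AssociationScan:
    """Simple linear regression of the phenotype on each marker.

    Vectorized least squares per column: slope, t-statistic and two-sided
    p-value with n-2 residual df. Markers monomorphic in this fold get
    p = 1 and a flag (they carry no information here).
    """
    y = np.asarray(y_train, dtype=float)
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 training accessions (no residual df)")
    if y.shape[0] != G_train.n_accessions:
        raise ValueError("phenotype length does not match genotypes")
    X = G_train.dosages
    if np.isnan(X).any():
        raise ValueError("impute missing dosages before the scan")

    xm = X.mean(axis=0)
    ym = y.mean()
    xc = X - xm
    yc = y - ym
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = yc @ xc
    mono = sxx == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(mono, 0.0, sxy / np.where(mono, 1.0, sxx))
        rss = (yc @ yc) - slope * sxy
        rss = np.clip(rss, 0.0, None)
        se = np.sqrt(rss / (n - 2) / np.where(mono, 1.0, sxx))
        t = np.where((se == 0) | mono, np.where(mono, 0.0, np.inf), slope / np.where(se == 0, 1.0, se))
    pvals = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pvals = np.where(mono, 1.0, np.clip(pvals, np.finfo(float).tiny, 1.0))
    table = pd.DataFrame({
        "id": G_train.markers["id"].to_numpy(),
        "cls": G_train.markers["cls"].to_numpy(),
        "slope": slope, "t_stat": t, "p_value": pvals, "monomorphic": mono,
    })
    return AssociationScan(table, trait=trait, fold_id=fold_id)


def select_top_k(scan: AssociationScan, k: int = 10_000, classes=None) -> list[str]:
    """The k most associated marker ids by pooled ascending p-value.

    ``classes`` restricts the pool (e.g. SNP only); ties break by |t| then
    marker id, so the selection is deterministic and stable under column
    permutation. Monomorphic-in-fold markers are excluded. Returns
    min(k, available) ids.
    """
    tab = scan.table
    if len(tab) == 0:
        raise ValueError("empty association scan")
    if classes is not None:
        if isinstance(classes, str):
            classes = [classes]
        tab = tab[tab["cls"].isin(list(classes))]
    tab = tab[~tab["monomorphic"]].copy()
    if len(tab) == 0:
        raise ValueError("no polymorphic markers to select from")
    if k > len(tab):
        warnings.warn(f"requested top {k} but only {len(tab)} markers available")
    tab["abs_t"] = tab["t_stat"].abs()
    tab = tab.sort_values(["p_value", "abs_t", "id"], ascending=[True, False, True],
                          kind="mergesort")
    return tab["id"].head(k).tolist()


def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors.

    Returns NaN (flagged missing) when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.shape[0] < 3:
        raise ValueError("vectors must share length >= 3")
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def linked_snps(G_train: GenotypeMatrix, threshold: float = 0.8,
                window: int | None = None) -> LinkedSet:
    """All SNP–SV pairs with dosage r² >= ``threshold``.

    The correlation matrix between SNP and SV columns is computed in one
    standardized matrix product. ``window`` (bp) optionally restricts pairs
    to the same chromosome within that distance, bounding the scan cost on
    dense panels. SVs absent -> empty set with a warning.
    """
    snp_mask = G_train.class_columns("SNP")
    sv_mask = G_train.class_columns(list(SV_CLASSES))
    if not sv_mask.any():
        warnings.warn("no structural variants present; linked set is empty")
        return LinkedSet(_empty_pairs(), threshold)
    if not snp_mask.any():
        raise ValueError("no SNPs present")
    X = G_train.dosages
    if np.isnan(X).any():
        raise ValueError("impute missing dosages before the LD scan")

    def _standardize(cols):
        M = X[:, cols]
        sd = M.std(axis=0)
        ok = sd > 0
        Z = np.zeros_like(M)
        Z[:, ok] = (M[:, ok] - M[:, ok].mean(axis=0)) / sd[ok]
        return Z, ok

    snp_cols = np.flatnonzero(snp_mask)
    sv_cols = np.flatnonzero(sv_mask)
    Zs, snp_ok = _standardize(snp_cols)
    Zv, sv_ok = _standardize(sv_cols)
    n = X.shape[0]
    R2 = (Zs.T @ Zv / n) ** 2
    R2[~snp_ok, :] = 0.0
    R2[:, ~sv_ok] = 0.0

    mk = G_train.markers
    if window is not None:
        chrom_s = mk["chrom"].to_numpy()[snp_cols]
        chrom_v = mk["chrom"].to_numpy()[sv_cols]
        pos_s = mk["pos"].to_numpy()[snp_cols].astype(np.int64)
        pos_v = mk["pos"].to_numpy()[sv_cols].astype(np.int64)
        same = chrom_s[:, None] == chrom_v[None, :]
        near = np.abs(pos_s[:, None] - pos_v[None, :]) <= window
        R2 = np.where(same & near, R2, 0.0)

    ii, jj = np.nonzero(R2 >= threshold)
    pairs = pd.DataFrame({
        "snp_id": mk["id"].to_numpy()[snp_cols[ii]],
        "sv_id": mk["id"].to_numpy()[sv_cols[jj]],
        "sv_class": mk["cls"].to_numpy()[sv_cols[jj]],
        "chrom_snp": mk["chrom"].to_numpy()[snp_cols[ii]],
        "pos_snp": mk["pos"].to_numpy()[snp_cols[ii]],
        "chrom_sv": mk["chrom"].to_numpy()[sv_cols[jj]],
        "pos_sv": mk["pos"].to_numpy()[sv_cols[jj]],
        "r2": R2[ii, jj],
    }).drop_duplicates(["snp_id", "sv_id"]).reset_index(drop=True)
    return LinkedSet(pairs, threshold)


def _empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(columns=["snp_id", "sv_id", "sv_class", "chrom_snp",
                                 "pos_snp", "chrom_sv", "pos_sv", "r2"])
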