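"""Genomic relationship matrices (GRMs) and their principal components.

Three kernels are available: the VanRaden additive GRM
``K = ZZᵀ / (2 Σ p_j(1-p_j))`` with ``Z`` the dosage matrix centered by
``2p``; the Vitezica dominance GRM built from dominance-deviation
covariates ``(-2p², 2pq, -2q²)`` for genotypes (0, 1, 2); and the
additive×additive epistatic kernel, the Hadamard product ``A⊙A``.

Presence/absence SV columns go through the same VanRaden formula as
dosages on {0, 1}: centered by 2p with a 2p(1-p) denominator term, so one
formula covers all six marker classes. Allele frequencies may be supplied
from training rows and reused for test rows, keeping cross-validation
leakage-free.
"""

from __future__ import annotations

import numpy as np

from .containers import SV_CLASSES, GenotypeMatrix, KernelMatrix, PCFeatures


def allele_frequencies(G: GenotypeMatrix, rows: np.ndarray | None = None) -> np.ndarray:
    """Per-marker allele frequency: mean dosage / 2 for SNPs, presence
    frequency for SVs. Computed on ``rows`` (training accessions) if given."""
    dos = G.dosages if rows is None else G.dosages[rows]
    if np.isnan(dos).any():
        raise ValueError("impute missing dosages before computing frequencies")
    f = dos.mean(axis=0)
    is_snp = ~G.markers["cls"].isin(SV_CLASSES).to_numpy()
    return np.where(is_snp, f / 2.0, f)


def additive_grm(G: GenotypeMatrix, classes=None, freqs: np.ndarray | None = None,
                 rows: np.ndarray | None = None) -> KernelMatrix:
    """VanRaden additive GRM over the selected marker classes.

    ``freqs`` (or ``rows`` to estimate them on) fixes the centering and
    scaling to training statistics; by default all rows are used.
    """
    mask = np.ones(G.n_markers, bool) if classes is None else G.class_columns(classes)
    sub = G.subset(cols=mask)
    if sub.n_markers == 0:
        raise ValueError("no markers in the selected classes")
    if np.isnan(sub.dosages).any():
        raise ValueError("impute missing dosages before building kernels")
    p = allele_frequencies(sub, rows) if freqs is None else np.asarray(freqs)[mask]
    het = p * (1.0 - p)
    denom = 2.0 * het.sum()
    if denom <= 0:
        raise ValueError("all selected markers monomorphic: zero VanRaden denominator")
    Z = sub.dosages - 2.0 * p
    K = (Z @ Z.T) / denom
    cls = tuple(sorted(set(sub.markers["cls"])))
    return KernelMatrix(K, "additive", cls, sub.n_markers, list(G.accession_ids))


def dominance_grm(G: GenotypeMatrix, freqs: np.ndarray | None = None,
                  rows: np.ndarray | None = None) -> KernelMatrix:
    """Vitezica dominance GRM; defined for diploid SNP dosages only."""
    cls = set(G.markers["cls"])
    if cls & set(SV_CLASSES):
        raise ValueError("dominance GRM undefined for presence/absence SV classes")
    if np.isnan(G.dosages).any():
        raise ValueError("impute missing dosages before building kernels")
    p = allele_frequencies(G, rows) if freqs is None else np.asarray(freqs, dtype=float)
    q = 1.0 - p
    M = G.dosages
    H = np.where(M == 0, -2.0 * p**2, np.where(M == 1, 2.0 * p * q, -2.0 * q**2))
    denom = np.sum((2.0 * p * q) ** 2)
    if denom <= 0:
        raise ValueError("all markers monomorphic: zero dominance denominator")
    D = (H @ H.T) / denom
    return KernelMatrix(D, "dominance", ("SNP",), G.n_markers, list(G.accession_ids))


def epistatic_grm(A: KernelMatrix, normalize: bool = False) -> KernelMatrix:
    """Additive×additive kernel: the Hadamard product A⊙A.

    Left unnormalized by default; ``normalize`` divides by the mean
    diagonal. PSD-ness is inherited from A by the Schur product theorem.
    """
    if A.kind != "additive":
        raise ValueError("epistatic kernel is built from an additive GRM")
    E = A.values * A.values
    if normalize:
        E = E / np.mean(np.diag(E))
    return KernelMatrix(E, "epistatic", A.source_classes, A.n_markers,
                        list(A.accession_ids) if A.accession_ids else None)


def grm_pcs(K: KernelMatrix, n_components: int | None = None,
            explained: float = 0.95) -> PCFeatures:
    """Principal components of a kernel: eigenvectors scaled by √eigenvalue.

    With ``n_components=None`` the smallest count explaining ``explained``
    of the trace is kept. Numerical negative eigenvalues are clamped to 0
    and components are ordered by non-increasing eigenvalue.
    """
    if n_components is not None and n_components <= 0:
        raise ValueError("n_components must be positive")
    w, U = np.linalg.eigh(K.values)
    order = np.argsort(w)[::-1]
    w, U = np.clip(w[order], 0.0, None), U[:, order]
    rank = int(np.sum(w > 1e-12 * max(w[0], 1.0)))
    if n_components is None:
        total = w.sum()
        cum = np.cumsum(w) / total if total > 0 else np.ones_like(w)
        n_components = int(np.searchsorted(cum, explained) + 1)
    c = min(n_components, max(rank, 1))
    scores = U[:, :c] * np.sqrt(w[:c])
    return PCFeatures(scores, w[:c], source_kernel=K.kind)
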