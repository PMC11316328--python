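"""Core data containers shared across the pipeline.

A :class:`GenotypeMatrix` carries accession-by-marker dosages together with
per-marker metadata (id, chromosome, 1-based position, marker class). Marker
classes follow the six-way split used throughout: biallelic SNPs plus five
structural-variant (SV) classes — MITE/DTX and RLX/RIX transposon insertion
polymorphisms, deletions, duplications and inversions. SNP dosages live on
{0, 1, 2} (alternate-allele count), SV dosages on {0, 1} (absence/presence);
missing entries are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical marker-class labels, SNPs first.
MARKER_CLASSES = ("SNP", "MITE-DTX", "RLX-RIX", "DEL", "DUP", "INV")

#: The five structural-variant classes (everything except SNP).
SV_CLASSES = MARKER_CLASSES[1:]

MARKER_COLUMNS = ["id", "chrom", "pos", "cls"]


@dataclass
class GenotypeMatrix:
    """Accessions x markers dosage matrix with per-marker metadata.

    Parameters
    ----------
    dosages
        Float array of shape ``(n_accessions, n_markers)``. NaN marks missing.
    accession_ids
        Ordered, unique accession identifiers.
    markers
        DataFrame with columns ``id``, ``chrom``, ``pos`` (1-based int) and
        ``cls`` (one of :data:`MARKER_CLASSES`), one row per dosage column.
    """

    dosages: np.ndarray
    accession_ids: list[str]
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.accession_ids = [str(a) for a in self.accession_ids]
        self.markers = self.markers.reset_index(drop=True)
        n, p = self.dosages.shape
        if n != len(self.accession_ids):
            raise ValueError("row count does not match accession ids")
        if p != len(self.markers):
            raise ValueError("column count does not match marker metadata")
        if len(set(self.accession_ids)) != n:
            raise ValueError("duplicate accession ids")
        ids = self.markers["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        bad = set(self.markers["cls"]) - set(MARKER_CLASSES)
        if bad:
            raise ValueError(f"unknown marker class(es): {sorted(bad)}")
        self._check_ranges()

    def _check_ranges(self) -> None:
        is_sv = self.markers["cls"].isin(SV_CLASSES).to_numpy()
        with np.errstate(invalid="ignore"):
            if is_sv.any():
                sv = self.dosages[:, is_sv]
                if np.nanmax(sv, initial=0) > 1 or np.nanmin(sv, initial=0) < 0:
                    raise ValueError("SV dosages must lie in {0, 1}")
            snp = self.dosages[:, ~is_sv]
            if snp.size and (np.nanmax(snp, initial=0) > 2 or np.nanmin(snp, initial=0) < 0):
                raise ValueError("SNP dosages must lie in [0, 2]")

    @property
    def n_accessions(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def class_columns(self, classes) -> np.ndarray:
        """Boolean mask over columns for the requested class names."""
        if isinstance(classes, str):
            classes = [classes]
        bad = set(classes) - set(MARKER_CLASSES)
        if bad:
            raise ValueError(f"unknown marker class(es): {sorted(bad)}")
        return self.markers["cls"].isin(list(classes)).to_numpy()

    def subset(self, rows=None, cols=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given row / column indexers."""
        rows = np.arange(self.n_accessions) if rows is None else np.asarray(rows)
        if cols is None:
            cols = np.arange(self.n_markers)
        else:
            cols = np.asarray(cols)
            if cols.dtype == bool:
                cols = np.flatnonzero(cols)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(rows, cols)].copy(),
            accession_ids=[self.accession_ids[i] for i in rows],
            markers=self.markers.iloc[cols].reset_index(drop=True),
        )

    def concat_markers(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        if self.accession_ids != other.accession_ids:
            mine, theirs = set(self.accession_ids), set(other.accession_ids)
            offenders = sorted(mine ^ theirs)
            if offenders:
                raise ValueError(f"accession sets differ; offenders: {offenders[:10]}")
            raise ValueError("accession order differs between genotype sources")
        return GenotypeMatrix(
            dosages=np.hstack([self.dosages, other.dosages]),
            accession_ids=list(self.accession_ids),
            markers=pd.concat([self.markers, other.markers], ignore_index=True),
        )


@dataclass
class PhenotypeTable:
    """Per-accession trait values with population-group labels.

    ``data`` holds one row per accession with columns ``accession_id``,
    ``group`` and one column per trait; ``trait_kinds`` maps trait name to
    ``"quantitative"`` or ``"binary"``. Binary traits are stored on the
    {1, 2} class scale and mapped to {0, 1} (class 1 -> 0, class 2 -> 1)
    only when a loss or likelihood needs it.
    """

    data: pd.DataFrame
    trait_kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        if "accession_id" not in self.data.columns:
            raise ValueError("phenotype table needs an accession_id column")
        if self.data["accession_id"].duplicated().any():
            raise ValueError("duplicate accession ids in phenotypes")
        for trait, kind in self.trait_kinds.items():
            if kind not in ("quantitative", "binary"):
                raise ValueError(f"unknown trait kind {kind!r} for {trait!r}")
            if trait not in self.data.columns:
                raise ValueError(f"trait column {trait!r} missing")
            if kind == "binary":
                levels = set(pd.unique(self.data[trait].dropna()))
                if not levels <= {1, 2, 1.0, 2.0}:
                    raise ValueError(f"binary trait {trait!r} must use classes {{1, 2}}")

    @property
    def traits(self) -> list[str]:
        return list(self.trait_kinds)

    @property
    def accession_ids(self) -> list[str]:
        return [str(a) for a in self.data["accession_id"]]

    @property
    def groups(self) -> np.ndarray:
        return self.data["group"].to_numpy()

    def values(self, trait: str) -> np.ndarray:
        """Trait values as floats; binary traits mapped {1,2} -> {0,1}."""
        y = self.data[trait].to_numpy(dtype=float)
        if self.trait_kinds.get(trait) == "binary":
            y = y - 1.0
        return y

    def aligned_to(self, accession_ids: list[str]) -> "PhenotypeTable":
        """Reorder rows to match a genotype matrix's accession order."""
        idx = self.data.set_index("accession_id")
        missing = [a for a in accession_ids if a not in idx.index]
        if missing:
            raise ValueError(f"accessions without phenotypes: {missing[:10]}")
        return PhenotypeTable(idx.loc[accession_ids].reset_index(), dict(self.trait_kinds))


@dataclass
class KernelMatrix:
    """Symmetric PSD accession x accession relationship matrix."""

    values: np.ndarray
    kind: str
    source_classes: tuple[str, ...] = ()
    n_markers: int = 0
    accession_ids: list[str] | None = None

    #: Relative tolerance on the most negative eigenvalue.
    PSD_RTOL = 1e-8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kernel must be square")
        if self.kind not in ("additive", "dominance", "epistatic"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kernel not symmetric within 1e-10")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def check_psd(self) -> None:
        w = np.linalg.eigvalsh(self.values)
        if w[0] < -self.PSD_RTOL * max(w[-1], 1.0):
            raise ValueError(f"kernel not PSD: min eigenvalue {w[0]:.3e}")


@dataclass
class PCFeatures:
    """Principal-component scores extracted from a relationship kernel.

    ``scores[:, j]`` is eigenvector j scaled by sqrt(eigenvalue_j); columns
    are mutually orthogonal and ordered by non-increasing eigenvalue.
    """

    scores: np.ndarray
    explained_variance: np.ndarray
    source_kernel: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        if self.scores.shape[1] != self.explained_variance.shape[0]:
            raise ValueError("component count mismatch")
        if np.any(np.diff(self.explained_variance) > 1e-10):
            raise ValueError("eigenvalues must be non-increasing")

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]
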