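"""Genotype, structural-variant and phenotype file handling.

Readers accept SNPs from PLINK BED/BIM/FAM or VCF and structural variants
from a wide TSV (``marker_id  chrom  pos  class`` then one column per
accession, values 0/1 or NA). Filtering follows the study design: markers
with folded minor allele frequency <= 0.01 or missing rate > 1% are dropped.
Missing genotypes are imputed with per-marker training means (rounded to
{0,1} for presence/absence SVs) instead of haplotype-based imputation, which
keeps the fold discipline explicit: statistics always come from the rows a
caller passes in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _plink
from .containers import MARKER_CLASSES, SV_CLASSES, GenotypeMatrix, PhenotypeTable

SV_META_COLUMNS = ["marker_id", "chrom", "pos", "class"]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_snp_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK fileset; dosage counts the .bim A1 (alternate) allele."""
    dosages, bim, fam = _plink.read_bed(prefix)
    markers = pd.DataFrame({
        "id": bim["id"].astype(str),
        "chrom": bim["chrom"].astype(str),
        "pos": bim["pos"].astype(int),
        "cls": "SNP",
    })
    return GenotypeMatrix(dosages, list(fam["iid"].astype(str)), markers)


def write_snp_plink(prefix: str | Path, G: GenotypeMatrix) -> None:
    mask = G.class_columns("SNP")
    sub = G.subset(cols=mask)
    bim = pd.DataFrame({
        "chrom": sub.markers["chrom"], "id": sub.markers["id"], "cm": 0,
        "pos": sub.markers["pos"], "a1": "A", "a2": "G",
    })
    fam = pd.DataFrame({
        "fid": sub.accession_ids, "iid": sub.accession_ids,
        "father": 0, "mother": 0, "sex": 0, "phenotype": -9,
    })
    _plink.write_bed(prefix, sub.dosages, bim, fam)


def read_snp_vcf(path: str | Path) -> GenotypeMatrix:
    """Read hard-called biallelic SNP genotypes from a VCF (GT field)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, ids, chroms, poss = [], [], [], []
    for var in vcf:
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=missing
        gt = np.asarray(var.gt_types, dtype=float)
        dos = np.where(gt == 3, np.nan, gt)
        rows.append(dos)
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
    markers = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss, "cls": "SNP"})
    return GenotypeMatrix(np.array(rows).T, samples, markers)


def read_sv_tsv(path: str | Path) -> GenotypeMatrix:
    """Read a structural-variant presence/absence matrix."""
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str})
    missing_cols = [c for c in SV_META_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"SV TSV lacks columns {missing_cols}")
    bad = set(df["class"]) - set(SV_CLASSES)
    if bad:
        raise ValueError(f"malformed SV class label(s): {sorted(bad)}")
    accession_cols = [c for c in df.columns if c not in SV_META_COLUMNS]
    markers = pd.DataFrame({
        "id": df["marker_id"], "chrom": df["chrom"],
        "pos": df["pos"].astype(int), "cls": df["class"],
    })
    dosages = df[accession_cols].to_numpy(dtype=float).T
    return GenotypeMatrix(dosages, accession_cols, markers)


def write_sv_tsv(path: str | Path, G: GenotypeMatrix) -> None:
    mask = G.class_columns(list(SV_CLASSES))
    sub = G.subset(cols=mask)
    out = pd.DataFrame({
        "marker_id": sub.markers["id"], "chrom": sub.markers["chrom"],
        "pos": sub.markers["pos"], "class": sub.markers["cls"],
    })
    body = pd.DataFrame(sub.dosages.T, columns=sub.accession_ids)
    pd.concat([out, body], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotypes(snp_path: str | Path, sv_path: str | Path | None = None,
                   snp_format: str = "plink") -> GenotypeMatrix:
    """Read SNPs (PLINK prefix or VCF) and optionally concatenate SVs.

    Raises if the two sources do not genotype the same accessions.
    """
    if snp_format == "plink":
        snp = read_snp_plink(snp_path)
    elif snp_format == "vcf":
        snp = read_snp_vcf(snp_path)
    else:
        raise ValueError(f"unknown SNP format {snp_format!r}")
    if sv_path is None:
        return snp
    sv = read_sv_tsv(sv_path)
    if set(sv.accession_ids) != set(snp.accession_ids):
        offenders = sorted(set(sv.accession_ids) ^ set(snp.accession_ids))
        raise ValueError(f"SNP/SV accession mismatch: {offenders[:10]}")
    order = [sv.accession_ids.index(a) for a in snp.accession_ids]
    return snp.concat_markers(sv.subset(rows=np.array(order)))


def write_phenotypes(path: str | Path, P: PhenotypeTable) -> None:
    """Write the trait table as TSV plus a ``.kinds.json`` sidecar."""
    path = Path(path)
    P.data.to_csv(path, sep="\t", index=False, na_rep="NA")
    path.with_suffix(path.suffix + ".kinds.json").write_text(json.dumps(P.trait_kinds))


def read_phenotypes(path: str | Path, trait_kinds: dict[str, str] | None = None) -> PhenotypeTable:
    path = Path(path)
    if trait_kinds is None:
        sidecar = path.with_suffix(path.suffix + ".kinds.json")
        trait_kinds = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    df = pd.read_csv(path, sep="\t", dtype={"accession_id": str}, na_values=["NA"])
    return PhenotypeTable(df, trait_kinds)


# ---------------------------------------------------------------------------
# marker filtering / imputation
# ---------------------------------------------------------------------------

def folded_maf(G: GenotypeMatrix, rows: np.ndarray | None = None) -> np.ndarray:
    """Per-marker folded minor allele frequency min(f, 1-f).

    SNP allele frequency is mean dosage / 2; SV frequency is the presence
    frequency. Computed on the given rows (default: all), ignoring missing.
    """
    dos = G.dosages if rows is None else G.dosages[rows]
    with np.errstate(invalid="ignore"):
        f = np.nanmean(dos, axis=0)
    is_snp = ~G.markers["cls"].isin(SV_CLASSES).to_numpy()
    f = np.where(is_snp, f / 2.0, f)
    f = np.nan_to_num(f, nan=0.0)
    return np.minimum(f, 1.0 - f)


@dataclass
class FilterLog:
    removed: pd.DataFrame  # columns: id, cls, reason

    def counts(self) -> dict[str, int]:
        return self.removed["reason"].value_counts().to_dict()


def filter_markers(G: GenotypeMatrix, maf_min: float = 0.01,
                   max_missing: float = 0.01) -> tuple[GenotypeMatrix, FilterLog]:
    """Drop markers with folded MAF <= ``maf_min`` or missing rate > ``max_missing``.

    The MAF rule is a strict removal at the boundary (MAF equal to the
    threshold is removed). Returns the filtered matrix and a log naming each
    removed marker with its reason; raises if nothing survives.
    """
    maf = folded_maf(G)
    miss = np.mean(np.isnan(G.dosages), axis=0)
    drop_maf = maf <= maf_min
    drop_miss = miss > max_missing
    keep = ~(drop_maf | drop_miss)
    if not keep.any():
        raise ValueError("all markers removed by filtering (empty panel)")
    reasons = np.where(drop_maf, "MAF", "missing_rate")
    log = FilterLog(pd.DataFrame({
        "id": G.markers.loc[~keep, "id"].to_numpy(),
        "cls": G.markers.loc[~keep, "cls"].to_numpy(),
        "reason": reasons[~keep],
    }))
    return G.subset(cols=keep), log


def impute_missing(G: GenotypeMatrix, means: np.ndarray | None = None) -> GenotypeMatrix:
    """Mean-impute missing dosages; SV imputations are rounded to {0, 1}.

    ``means`` allows supplying per-marker means estimated on training rows
    so that test rows are imputed without leakage.
    """
    dos = G.dosages.copy()
    isnan = np.isnan(dos)
    if not isnan.any():
        return G.subset() if means is None else _fill(G, dos, isnan, means)
    if means is None:
        fully_missing = isnan.all(axis=0)
        if fully_missing.any():
            off = G.markers.loc[fully_missing, "id"].iloc[0]
            raise ValueError(f"marker {off!r} fully missing; filter before imputing")
        with np.errstate(invalid="ignore"):
            means = np.nanmean(dos, axis=0)
    return _fill(G, dos, isnan, means)


def _fill(G: GenotypeMatrix, dos, isnan, means) -> GenotypeMatrix:
    means = np.asarray(means, dtype=float)
    if np.isnan(means[isnan.any(axis=0)]).any():
        raise ValueError("imputation means missing for a column with gaps")
    is_sv = G.markers["cls"].isin(SV_CLASSES).to_numpy()
    fill = np.where(is_sv, np.round(means), means)
    dos[isnan] = np.broadcast_to(fill, dos.shape)[isnan]
    return GenotypeMatrix(dos, list(G.accession_ids), G.markers.copy())


# ---------------------------------------------------------------------------
# phenotype transforms
# ---------------------------------------------------------------------------

def transform_phenotypes(P: PhenotypeTable, ordinal_to_binary: list[str] = (),
                         log_transform: list[str] = (),
                         log_base: float | None = None) -> PhenotypeTable:
    """Apply the study's trait transforms, keeping originals alongside.

    Ordinal scores are binned to two classes: value 1 -> class 1, anything
    else -> class 2 (new column ``<trait>_binary``, kind binary). Designated
    quantitative traits are log-transformed (natural log by default; pass
    ``log_base`` to change), producing ``<trait>_log``.
    """
    df = P.data.copy()
    kinds = dict(P.trait_kinds)
    for trait in ordinal_to_binary:
        if trait not in df.columns:
            raise KeyError(f"trait {trait!r} not present")
        v = df[trait]
        df[f"{trait}_binary"] = np.where(v.isna(), np.nan, np.where(v == 1, 1.0, 2.0))
        kinds[f"{trait}_binary"] = "binary"
        kinds.pop(trait, None)
    for trait in log_transform:
        if trait not in df.columns:
            raise KeyError(f"trait {trait!r} not present")
        v = df[trait].to_numpy(dtype=float)
        nonpos = (v <= 0) & ~np.isnan(v)
        if nonpos.any():
            acc = df.loc[nonpos, "accession_id"].iloc[0]
            raise ValueError(f"non-positive value for {trait!r} at accession {acc!r}")
        logged = np.log(v)
        if log_base is not None:
            logged = logged / np.log(log_base)
        df[f"{trait}_log"] = logged
        kinds[f"{trait}_log"] = "quantitative"
        kinds.pop(trait, None)
    return PhenotypeTable(df, kinds)
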