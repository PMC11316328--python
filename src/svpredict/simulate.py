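"""Synthetic rice-like panels with SNPs, structural variants and known truth.

The generator emulates the study system: a diversity panel of inbred rice
accessions from five population groups (three large groups used for
training, two small and more diverged groups — aromatic and admixed
stand-ins — held out for across-population prediction), genotyped for six
marker classes: SNPs plus five structural-variant (SV) classes (MITE-DTX
and RLX-RIX transposon insertion polymorphisms, deletions, duplications,
inversions).

Population structure uses the Balding–Nichols model: each marker has an
ancestral frequency p drawn uniformly from ``base_freq_range`` and each
group draws its own frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), so a
single Fst parameter controls divergence. Holdout groups get an inflated
Fst (default 2x) to reproduce the "not phylogenetically close" difficulty
of the across-population scenario. SNP genotypes are binomial(2, p_group)
dosages, SVs are Bernoulli presence/absence.

SV–SNP linkage is planted directly: a designated SV column is a noisy copy
of a (homozygous-coded) partner SNP column, with the flip-noise rate
calibrated by bisection so the realized dosage r² hits a requested target.
This gives the linked-SNPs input strategy a knowable ground truth.

Phenotypes follow an additive (+ optional dominance and additive×additive
epistasis) model with per-class causal variance shares, scaled to a target
narrow-sense heritability on the realized genotypes; binary traits arise by
thresholding the latent liability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MARKER_CLASSES, SV_CLASSES, GenotypeMatrix, PhenotypeTable

#: Group sizes of the real 738-accession panel the generator mimics.
PANEL_GROUP_SIZES = {"IND": 451, "JAP": 166, "AUS": 75, "ARO": 17, "ADM": 29}

#: Marker counts proportional to the real six-class panel at ~1/205 scale.
DESK_MARKER_COUNTS = {
    "SNP": 1117, "MITE-DTX": 254, "RLX-RIX": 105,
    "DEL": 362, "DUP": 125, "INV": 37,
}

#: Planted SV–SNP pairs: roughly 5% of SNPs end up linked to an SV at high
#: r², spread over classes in proportion to their size.
DESK_LINKED_PAIRS = [
    ("DEL", 0.9, 20), ("MITE-DTX", 0.9, 15), ("RLX-RIX", 0.9, 10),
    ("DUP", 0.9, 8), ("INV", 0.9, 3),
]

N_CHROMOSOMES = 12
CHROM_LENGTH = 43_000_000  # rice chromosome scale, bp


@dataclass
class PopulationConfig:
    """Settings for :func:`simulate_population`."""

    n_per_group: dict[str, int] | int = field(default_factory=lambda: dict(PANEL_GROUP_SIZES))
    group_labels: tuple[str, ...] = ("IND", "JAP", "AUS", "ARO", "ADM")
    fst: float = 0.15
    holdout_labels: tuple[str, ...] = ("ARO", "ADM")
    holdout_fst_multiplier: float = 2.0
    base_freq_range: tuple[float, float] = (0.05, 0.95)
    marker_counts: dict[str, int] = field(default_factory=lambda: dict(DESK_MARKER_COUNTS))
    linked_pairs: list[tuple[str, float, int]] = field(default_factory=lambda: list(DESK_LINKED_PAIRS))
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_per_group, int):
            self.n_per_group = {g: self.n_per_group for g in self.group_labels}
        if set(self.n_per_group) != set(self.group_labels):
            raise ValueError("n_per_group labels must match group_labels")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be >= 0")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must lie in [0, 1)")
        lo, hi = self.base_freq_range
        if not (0.01 < lo < hi < 0.99):
            raise ValueError("base_freq_range must be inside (0.01, 0.99)")
        bad = set(self.marker_counts) - set(MARKER_CLASSES)
        if bad:
            raise ValueError(f"unknown marker class(es): {sorted(bad)}")
        if any(c < 0 for c in self.marker_counts.values()):
            raise ValueError("marker counts must be >= 0")
        for cls, r2, count in self.linked_pairs:
            if cls not in SV_CLASSES:
                raise ValueError(f"linked pairs must target an SV class, got {cls!r}")
            if not (0.0 < r2 <= 1.0):
                raise ValueError("target r² must lie in (0, 1]")
            if count > self.marker_counts.get(cls, 0):
                raise ValueError(f"more linked pairs than {cls} markers")


@dataclass
class SimulatedPopulation:
    genotypes: GenotypeMatrix
    groups: np.ndarray  # group label per accession
    linked_pairs: pd.DataFrame  # snp_id, sv_id, target_r2, realized_r2
    holdout_labels: tuple[str, ...] = ("ARO", "ADM")

    @property
    def holdout_mask(self) -> np.ndarray:
        return np.isin(self.groups, list(self.holdout_labels))


@dataclass
class TraitSpec:
    """Settings for :func:`simulate_phenotypes`."""

    kind: str = "quantitative"
    h2: float = 0.5
    class_variance_shares: dict[str, float] = field(
        default_factory=lambda: {"SNP": 0.4, "MITE-DTX": 0.15, "RLX-RIX": 0.1,
                                 "DEL": 0.2, "DUP": 0.1, "INV": 0.05})
    n_causal_per_class: int | dict[str, int] = 20
    dominance_share: float = 0.0
    epistasis_share: float = 0.0
    liability_threshold: float = 0.0
    name: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 must lie in [0, 1]")
        active = {c: s for c, s in self.class_variance_shares.items() if s > 0}
        if abs(sum(active.values()) - 1.0) > 1e-9:
            raise ValueError("class variance shares must sum to 1")
        if self.dominance_share < 0 or self.epistasis_share < 0:
            raise ValueError("dominance/epistasis shares must be >= 0")
        if self.dominance_share + self.epistasis_share >= 1.0:
            raise ValueError("non-additive shares must leave additive variance")

    def causal_count(self, cls: str) -> int:
        if isinstance(self.n_causal_per_class, dict):
            return self.n_causal_per_class.get(cls, 0)
        return self.n_causal_per_class


@dataclass
class TraitTruth:
    """Ground truth returned alongside simulated phenotypes."""

    causal_indices: dict[str, np.ndarray]
    additive_effects: dict[str, np.ndarray]
    genetic_values: np.ndarray
    component_variances: dict[str, float]  # per-class additive + dominance/epistasis
    sigma_e2: float
    h2_realized: float
    liabilities: np.ndarray | None = None
    threshold: float | None = None


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------

def _group_freqs(rng, p_anc: np.ndarray, fst: float) -> np.ndarray:
    if fst == 0.0:
        return p_anc.copy()
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    return rng.beta(a, b)


def simulate_population(config: PopulationConfig) -> SimulatedPopulation:
    """Draw a structured panel across the six marker classes.

    Deterministic given ``config.seed``. Returns the genotype matrix, the
    per-accession group labels, and the planted SV–SNP pair table with
    realized r² values.
    """
    rng = np.random.default_rng(config.seed)
    labels = [g for g in config.group_labels for _ in range(config.n_per_group[g])]
    groups = np.array(labels)
    n = len(groups)

    blocks, meta = [], []
    lo, hi = config.base_freq_range
    for cls in MARKER_CLASSES:
        m = config.marker_counts.get(cls, 0)
        if m == 0:
            continue
        p_anc = rng.uniform(lo, hi, size=m)
        dos = np.empty((n, m))
        for g in config.group_labels:
            rows = groups == g
            if not rows.any():
                continue
            fst = config.fst * (config.holdout_fst_multiplier
                                if g in config.holdout_labels else 1.0)
            fst = min(fst, 0.999)
            pg = _group_freqs(rng, p_anc, fst)
            if cls == "SNP":
                dos[rows] = rng.binomial(2, pg, size=(int(rows.sum()), m))
            else:
                dos[rows] = rng.binomial(1, pg, size=(int(rows.sum()), m))
        blocks.append(dos)
        meta.append(pd.DataFrame({
            "id": [f"{cls}_{j:05d}" for j in range(m)],
            "chrom": rng.integers(1, N_CHROMOSOMES + 1, size=m).astype(str),
            "pos": rng.integers(1, CHROM_LENGTH, size=m),
            "cls": cls,
        }))
    if not blocks:
        raise ValueError("no markers requested")
    dosages = np.hstack(blocks)
    markers = pd.concat(meta, ignore_index=True)

    pairs = _plant_linked_pairs(rng, dosages, markers, config)
    G = GenotypeMatrix(dosages, [f"ACC{i:05d}" for i in range(n)], markers)
    return SimulatedPopulation(G, groups, pairs, tuple(config.holdout_labels))


def _plant_linked_pairs(rng, dosages, markers, config) -> pd.DataFrame:
    """Overwrite selected SV columns with noisy copies of partner SNPs.

    The partner SNP is recoded homozygous (0/2) — inbred-line style — so a
    clean copy reaches dosage r² of exactly 1; flip noise is then tuned by
    bisection until the realized r² lands within ±0.05 of the target.
    """
    snp_cols = np.flatnonzero(markers["cls"] == "SNP")
    records = []
    used_snps: set[int] = set()
    for cls, target, count in config.linked_pairs:
        sv_cols = np.flatnonzero(markers["cls"] == cls)
        chosen_sv = rng.choice(sv_cols, size=count, replace=False)
        for sv_j in chosen_sv:
            ok = False
            for _ in range(50):
                snp_j = int(rng.choice(snp_cols))
                if snp_j in used_snps:
                    continue
                b = (dosages[:, snp_j] >= 1).astype(float)
                if b.std() == 0:
                    continue  # monomorphic partner: pick another
                sv, realized = _calibrated_copy(rng, b, target)
                if sv is not None:
                    dosages[:, snp_j] = 2.0 * b
                    dosages[:, sv_j] = sv
                    used_snps.add(snp_j)
                    records.append({
                        "snp_id": markers.at[snp_j, "id"],
                        "sv_id": markers.at[sv_j, "id"],
                        "target_r2": target, "realized_r2": realized,
                    })
                    ok = True
                    break
            if not ok:
                raise ValueError(
                    f"could not plant {cls} pair at r²={target}: no usable partner")
    return pd.DataFrame(records, columns=["snp_id", "sv_id", "target_r2", "realized_r2"])


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def _calibrated_copy(rng, b: np.ndarray, target: float, tol: float = 0.05):
    """Flip-noise copy of binary vector ``b`` with dosage r² near ``target``."""
    if target >= 1.0 - 1e-12:
        return b.copy(), 1.0
    lo_eps, hi_eps = 0.0, 0.5
    for _ in range(60):
        eps = 0.5 * (lo_eps + hi_eps)
        flips = rng.random(b.shape[0]) < eps
        sv = np.where(flips, 1.0 - b, b)
        r2 = _r2(sv, b)
        if np.isnan(r2):
            continue
        if abs(r2 - target) <= tol:
            return sv, r2
        if r2 > target:
            lo_eps = eps
        else:
            hi_eps = eps
    return None, np.nan


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------

def simulate_phenotypes(G: GenotypeMatrix, spec: TraitSpec,
                        groups: np.ndarray | None = None
                        ) -> tuple[PhenotypeTable, TraitTruth]:
    """Simulate one trait on realized genotypes with known architecture.

    Additive effects are drawn per class and rescaled so each class's
    realized genetic-variance share matches the requested share exactly on
    these genotypes; environmental noise is scaled to hit the target h² on the
    realized genetic variance. Binary traits threshold the latent liability
    (class 1 above the threshold, class 2 below). Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = G.n_accessions
    active = {c: s for c, s in spec.class_variance_shares.items()
              if s > 0 and spec.causal_count(c) > 0}
    for cls in active:
        avail = int(G.class_columns(cls).sum())
        if spec.causal_count(cls) > avail:
            raise ValueError(f"{cls}: {spec.causal_count(cls)} causal > {avail} markers")

    additive_total = 1.0 - spec.dominance_share - spec.epistasis_share
    share_sum = sum(active.values())
    g = np.zeros(n)
    causal, effects, comp_var = {}, {}, {}
    all_causal_cols: list[np.ndarray] = []
    for cls, share in active.items():
        cols = np.flatnonzero(G.class_columns(cls))
        idx = rng.choice(cols, size=spec.causal_count(cls), replace=False)
        X = G.dosages[:, idx]
        Xc = X - X.mean(axis=0)
        beta = rng.normal(size=len(idx))
        g_cls = Xc @ beta
        v = g_cls.var()
        if v <= 0:
            raise ValueError(f"{cls}: causal markers carry no variance")
        target_v = additive_total * share / share_sum
        scale = np.sqrt(target_v / v)
        beta *= scale
        g_cls *= scale
        g += g_cls
        causal[cls], effects[cls] = idx, beta
        comp_var[cls] = float(g_cls.var())
        all_causal_cols.append(idx)

    if spec.dominance_share > 0:
        snp_causal = causal.get("SNP")
        if snp_causal is None:
            raise ValueError("dominance share requires SNP causal markers")
        H = (G.dosages[:, snp_causal] == 1).astype(float)
        Hc = H - H.mean(axis=0)
        d = Hc @ rng.normal(size=Hc.shape[1])
        if d.var() <= 0:
            raise ValueError("no heterozygosity available for dominance effects")
        d *= np.sqrt(spec.dominance_share / d.var())
        g += d
        comp_var["dominance"] = float(d.var())

    if spec.epistasis_share > 0:
        pool = np.concatenate(all_causal_cols)
        n_pairs = len(pool)
        i = rng.choice(pool, size=n_pairs)
        j = rng.choice(pool, size=n_pairs)
        Xc = G.dosages - G.dosages.mean(axis=0)
        W = Xc[:, i] * Xc[:, j]
        ep = (W - W.mean(axis=0)) @ rng.normal(size=n_pairs)
        if ep.var() <= 0:
            raise ValueError("epistatic products carry no variance")
        ep *= np.sqrt(spec.epistasis_share / ep.var())
        g += ep
        comp_var["epistasis"] = float(ep.var())

    var_g = g.var()
    if spec.h2 == 0.0:
        sigma_e2 = 1.0
        y = rng.normal(0.0, 1.0, size=n)
    elif spec.h2 == 1.0:
        sigma_e2 = 0.0
        y = g.copy()
    else:
        sigma_e2 = var_g * (1.0 - spec.h2) / spec.h2
        y = g + rng.normal(0.0, np.sqrt(sigma_e2), size=n)

    liabilities = None
    threshold = None
    if spec.kind == "binary":
        liabilities = y.copy()
        threshold = spec.liability_threshold
        classes = np.where(liabilities > threshold, 1.0, 2.0)
        if len(np.unique(classes)) < 2:
            raise ValueError("degenerate binary trait: a single class realized")
        y = classes

    if groups is None:
        groups = np.array(["ALL"] * n)
    table = PhenotypeTable(
        pd.DataFrame({"accession_id": G.accession_ids, "group": groups, spec.name: y}),
        {spec.name: spec.kind},
    )
    truth = TraitTruth(
        causal_indices=causal, additive_effects=effects, genetic_values=g,
        component_variances=comp_var, sigma_e2=sigma_e2,
        h2_realized=float(var_g / y.var()) if spec.kind == "quantitative" and y.var() > 0 else
        float(var_g / (var_g + sigma_e2)) if (var_g + sigma_e2) > 0 else 0.0,
        liabilities=liabilities, threshold=threshold,
    )
    return table, truth
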