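"""Synthetic multi-breed genotype panels, QTL architectures and phenotypes.

The generator produces diploid panels with within-chromosome LD (founder
haplotype copying with recombination) and between-breed divergence
(Balding-Nichols drift around a shared ancestral frequency), samples a
three-class QTL architecture, builds phenotypes at a target heritability
with an optional per-breed effect, and perturbs genotypes with
MAF-dependent allele errors.  Everything is deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ANNOTATION_CLASSES = ("NSC", "REG", "HD", "OTHER")

DEFAULT_N_SMALL = 3485
DEFAULT_N_MEDIUM = 500
DEFAULT_N_LARGE = 15
#: per-class effect-variance multipliers of the additive genetic variance
QTL_CLASS_VARIANCE = {"small": 1e-4, "medium": 1e-3, "large": 1e-2}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePanel:
    """Phased binary haplotypes, two rows per individual.

    ``haplotypes`` has shape ``(2 * n_individuals, n_variants)``; rows
    ``2j`` and ``2j + 1`` belong to individual ``j``.
    """

    haplotypes: np.ndarray
    breed: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ancestral_freq: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.breed = np.asarray(self.breed)
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ancestral_freq = np.asarray(self.ancestral_freq, dtype=np.float64)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D array")
        if self.haplotypes.shape[0] % 2 != 0:
            raise ValueError("haplotype rows must come in pairs (two per individual)")
        if self.haplotypes.shape[0] != 2 * self.breed.shape[0]:
            raise ValueError("breed labels must match individuals (haplotype rows / 2)")
        uniq = np.unique(self.haplotypes)
        if uniq.size and not np.isin(uniq, [0, 1]).all():
            raise ValueError("alleles must be 0/1")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if p.size > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions must strictly increase within chromosome {c}")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class GenotypePanel:
    """Dosage matrix (individuals x variants) plus per-variant/individual metadata."""

    dosage: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    variant_id: np.ndarray
    maf: np.ndarray
    annotation: np.ndarray
    breed: np.ndarray
    sex: np.ndarray
    iid: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = self.dosage.shape
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.variant_id = np.asarray(self.variant_id, dtype=object)
        self.maf = np.asarray(self.maf, dtype=np.float64)
        self.annotation = np.asarray(self.annotation, dtype=object)
        self.breed = np.asarray(self.breed)
        self.sex = np.asarray(self.sex)
        self.iid = np.asarray(self.iid, dtype=object)
        for name, arr, size in (
            ("chrom", self.chrom, m), ("pos", self.pos, m),
            ("variant_id", self.variant_id, m), ("maf", self.maf, m),
            ("annotation", self.annotation, m), ("breed", self.breed, n),
            ("sex", self.sex, n), ("iid", self.iid, n),
        ):
            if arr.shape[0] != size:
                raise ValueError(f"{name} has length {arr.shape[0]}, expected {size}")
        bad = set(np.unique(self.annotation)) - set(ANNOTATION_CLASSES)
        if bad:
            raise ValueError(f"unknown annotation class(es): {sorted(bad)}")
        if ((self.dosage < 0) | (self.dosage > 2)).any():
            raise ValueError("dosages must be 0, 1 or 2")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele, from current dosages."""
        return self.dosage.mean(axis=0) / 2.0

    def recompute_maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset_variants(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            dosage=self.dosage[:, idx], chrom=self.chrom[idx], pos=self.pos[idx],
            variant_id=self.variant_id[idx], maf=self.maf[idx],
            annotation=self.annotation[idx], breed=self.breed, sex=self.sex,
            iid=self.iid,
        )

    def subset_individuals(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            dosage=self.dosage[idx], chrom=self.chrom, pos=self.pos,
            variant_id=self.variant_id, maf=self.maf, annotation=self.annotation,
            breed=self.breed[idx], sex=self.sex[idx], iid=self.iid[idx],
        )

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(
            dosage=self.dosage.copy(), chrom=self.chrom.copy(), pos=self.pos.copy(),
            variant_id=self.variant_id.copy(), maf=self.maf.copy(),
            annotation=self.annotation.copy(), breed=self.breed.copy(),
            sex=self.sex.copy(), iid=self.iid.copy(),
        )


@dataclass
class QTLSet:
    """Causal variants with additive effects in three size classes."""

    indices: np.ndarray
    effects: np.ndarray
    size_class: np.ndarray
    sigma_g2: float = 1.0

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.effects = np.asarray(self.effects, dtype=np.float64)
        self.size_class = np.asarray(self.size_class, dtype=object)
        if not (self.indices.shape == self.effects.shape == self.size_class.shape):
            raise ValueError("indices, effects and size_class must align")

    @property
    def n_qtl(self) -> int:
        return self.indices.shape[0]

    def class_counts(self) -> dict:
        return {k: int((self.size_class == k).sum()) for k in ("small", "medium", "large")}

    def to_frame(self, variant_id: np.ndarray | None = None) -> pd.DataFrame:
        vid = (np.asarray(variant_id)[self.indices] if variant_id is not None
               else self.indices.astype(str))
        return pd.DataFrame({
            "variant_id": vid, "index": self.indices,
            "size_class": self.size_class, "effect": self.effects,
        })


@dataclass
class TraitSim:
    """Simulated trait: phenotype = tbv + env + breed_effect, exactly."""

    tbv: np.ndarray
    env: np.ndarray
    breed_effect: np.ndarray
    phenotype: np.ndarray
    h2: float

    def __post_init__(self) -> None:
        for name in ("tbv", "env", "breed_effect", "phenotype"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if not np.allclose(self.phenotype, self.tbv + self.env + self.breed_effect):
            raise ValueError("phenotype decomposition identity violated")

    def to_frame(self, iid: np.ndarray, breed: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame({
            "id": np.asarray(iid, dtype=object), "tbv": self.tbv,
            "phenotype": self.phenotype, "breed": np.asarray(breed, dtype=object),
        })


@dataclass
class ErrorModel:
    """Allele-flip error model with per-variant probability r / sqrt(MAF), capped at 1."""

    r: float
    target: str = "both"

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("error rate parameter r must be >= 0")
        if self.target not in ("reference", "validation", "both"):
            raise ValueError("target must be 'reference', 'validation' or 'both'")

    def error_prob(self, maf: np.ndarray) -> np.ndarray:
        maf = np.asarray(maf, dtype=np.float64)
        if self.r == 0:
            return np.zeros_like(maf)
        if (maf <= 0).any():
            raise ValueError("error probability undefined for MAF = 0; filter first")
        return np.minimum(self.r / np.sqrt(maf), 1.0)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _chromosome_layout(n_variants: int, n_chromosomes: int, chrom_length: int,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Split variants over chromosomes; sorted unique bp positions per chromosome."""
    base, extra = divmod(n_variants, n_chromosomes)
    chroms, positions = [], []
    for c in range(1, n_chromosomes + 1):
        m_c = base + (1 if c <= extra else 0)
        if m_c == 0:
            continue
        pos = np.sort(rng.choice(chrom_length, size=m_c, replace=False)) + 1
        chroms.append(np.full(m_c, c, dtype=np.int64))
        positions.append(pos.astype(np.int64))
    return np.concatenate(chroms), np.concatenate(positions)


def _mosaic(pool: np.ndarray, n_hap: int, chrom: np.ndarray, pos: np.ndarray,
            recomb_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Recombinant mosaics of a haplotype pool, switching source at crossovers."""
    n_pool, m = pool.shape
    out = np.empty((n_hap, m), dtype=np.int8)
    for c in np.unique(chrom):
        mask = chrom == c
        m_c = int(mask.sum())
        gaps = np.diff(pos[mask])
        p_switch = 1.0 - np.exp(-recomb_rate * gaps)
        switch = np.zeros((n_hap, m_c), dtype=np.int32)
        if m_c > 1:
            switch[:, 1:] = (rng.random((n_hap, m_c - 1)) < p_switch).astype(np.int32)
        seg = np.cumsum(switch, axis=1)
        max_seg = int(seg[:, -1].max()) + 1 if m_c else 1
        choice = rng.integers(0, n_pool, size=(n_hap, max_seg))
        path = np.take_along_axis(choice, seg, axis=1)
        out[:, mask] = pool[path, np.nonzero(mask)[0][None, :]]
    return out


def simulate_panel(
    n_per_breed: Mapping[str, int],
    n_variants: int,
    n_chromosomes: int = 2,
    divergence: float = 0.05,
    recomb_rate: float = 1e-8,
    seed: int | np.random.SeedSequence | None = None,
    n_founders: int = 100,
    chrom_length: int = 100_000_000,
    freq_beta: tuple[float, float] = (0.6, 0.6),
    split_scale: float = 50.0,
) -> HaplotypePanel:
    """Simulate a multi-breed haplotype panel with LD and breed divergence.

    A shared ancestral pool of ``n_founders`` haplotypes is drawn site-wise
    from a Beta frequency spectrum.  Each breed passes through a founder
    bottleneck: ``round(1 / divergence)`` breed founders are sampled as
    recombinant mosaics of the ancestral pool (recombination inflated by
    ``split_scale`` to model the time since the split), which yields an
    F_ST between breeds of roughly ``divergence`` while conserving
    short-range LD across breeds.  Individual haplotypes are recombinant
    mosaics of their breed's founders.  ``divergence = 0`` skips the
    bottleneck entirely (all breeds copy the ancestral pool).
    """
    if n_variants <= 0:
        raise ValueError("n_variants must be positive")
    if n_chromosomes <= 0:
        raise ValueError("n_chromosomes must be positive")
    if not (0 <= divergence < 0.5):
        raise ValueError("divergence must lie in [0, 0.5)")
    if not n_per_breed or any(v < 1 for v in n_per_breed.values()):
        raise ValueError("every breed needs a positive individual count")
    if n_founders < 1:
        raise ValueError("n_founders must be positive")

    rng = np.random.default_rng(seed)
    chrom, pos = _chromosome_layout(n_variants, n_chromosomes, chrom_length, rng)
    m = chrom.shape[0]

    p_anc = rng.beta(freq_beta[0], freq_beta[1], size=m)
    p_anc = np.clip(p_anc, 0.01, 0.99)
    ancestral = (rng.random((n_founders, m)) < p_anc).astype(np.int8)

    hap_blocks, breed_labels = [], []
    for breed in sorted(n_per_breed):
        n_ind = n_per_breed[breed]
        if divergence == 0:
            founders = ancestral
        else:
            n_breed_founders = max(2, int(round(1.0 / divergence)))
            founders = _mosaic(ancestral, n_breed_founders, chrom, pos,
                               recomb_rate * split_scale, rng)
        hap = _mosaic(founders, 2 * n_ind, chrom, pos, recomb_rate, rng)
        hap_blocks.append(hap)
        breed_labels.extend([breed] * n_ind)

    return HaplotypePanel(
        haplotypes=np.vstack(hap_blocks), breed=np.asarray(breed_labels, dtype=object),
        chrom=chrom, pos=pos, ancestral_freq=p_anc,
    )


def simulate_coalescent_panel(
    n_per_breed: Mapping[str, int],
    n_chromosomes: int = 5,
    chrom_length: int = 20_000_000,
    divergence: float = 0.08,
    Ne: float = 500.0,
    recomb_rate: float = 1e-8,
    mut_rate: float = 3e-9,
    seed: int | None = None,
) -> HaplotypePanel:
    """Coalescent-backed multi-breed panel (realistic shared LD across breeds).

    Breeds split sequentially from a common ancestor (the i-th listed breed
    joins at time ``2 * Ne * divergence * i``), so between-breed F_ST grows
    with ``divergence`` while short-range LD — which arises from the shared
    genealogy — is conserved across breeds.  Chromosomes are independent
    replicates.  Requires ``msprime``.
    """
    import msprime  # local import: only this generator needs it

    if not (0 <= divergence < 0.5):
        raise ValueError("divergence must lie in [0, 0.5)")
    breeds = sorted(n_per_breed)
    if not breeds or any(n_per_breed[b] < 1 for b in breeds):
        raise ValueError("every breed needs a positive individual count")

    dem = msprime.Demography()
    for b in breeds:
        dem.add_population(name=b, initial_size=Ne)
    merged = breeds[0]
    for i, b in enumerate(breeds[1:], start=1):
        anc = f"anc{i}"
        dem.add_population(name=anc, initial_size=Ne)
        t = max(2.0 * Ne * divergence * i, 1e-9)
        dem.add_population_split(time=t, derived=[merged, b], ancestral=anc)
        merged = anc

    ss = np.random.SeedSequence(seed)
    chrom_seeds = (ss.generate_state(2 * n_chromosomes) % (2**31 - 1)) + 1
    hap_parts, chroms, positions = [], [], []
    for c in range(1, n_chromosomes + 1):
        ts = msprime.sim_ancestry(
            samples={b: n_per_breed[b] for b in breeds}, demography=dem,
            sequence_length=chrom_length, recombination_rate=recomb_rate,
            random_seed=int(chrom_seeds[2 * (c - 1)]))
        ts = msprime.sim_mutations(ts, rate=mut_rate,
                                   random_seed=int(chrom_seeds[2 * c - 1]))
        G = ts.genotype_matrix()  # sites x haplotypes
        pos = np.floor(ts.sites_position).astype(np.int64) + 1
        biallelic = (G <= 1).all(axis=1)
        keep = biallelic.copy()
        keep[1:] &= np.diff(pos) > 0  # unique integer positions
        hap_parts.append(G[keep].T.astype(np.int8))
        chroms.append(np.full(int(keep.sum()), c, dtype=np.int64))
        positions.append(pos[keep])

    haplotypes = np.hstack(hap_parts)
    # msprime orders sample nodes by population in the order given
    breed_per_ind = np.concatenate(
        [np.full(n_per_breed[b], b, dtype=object) for b in breeds])
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)
    return HaplotypePanel(haplotypes=haplotypes, breed=breed_per_ind,
                          chrom=chrom, pos=pos,
                          ancestral_freq=haplotypes.mean(axis=0))


def genotypes_from_haplotypes(panel: HaplotypePanel, sex: np.ndarray | None = None,
                              annotation: np.ndarray | None = None) -> GenotypePanel:
    """Collapse phased haplotypes into 0/1/2 dosages; MAF over all individuals."""
    dosage = (panel.haplotypes[0::2] + panel.haplotypes[1::2]).astype(np.int8)
    p = dosage.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    n, m = dosage.shape
    vid = np.array([f"v{c}_{q}" for c, q in zip(panel.chrom, panel.pos)], dtype=object)
    return GenotypePanel(
        dosage=dosage, chrom=panel.chrom, pos=panel.pos, variant_id=vid, maf=maf,
        annotation=np.full(m, "OTHER", dtype=object), breed=panel.breed,
        sex=sex if sex is not None else np.full(n, "F", dtype=object),
        iid=np.array([f"ind{j:06d}" for j in range(n)], dtype=object),
    )


def assign_annotations(panel: GenotypePanel,
                       proportions: Mapping[str, float],
                       seed: int | None = None,
                       exclude_from: Mapping[str, Sequence[int]] | None = None) -> GenotypePanel:
    """Randomly tag variants with annotation classes at the given proportions.

    ``exclude_from`` maps a class name to variant indices that must not be
    assigned to it (used e.g. to keep causal variants off the HD subset).
    Unassigned variants stay "OTHER".
    """
    rng = np.random.default_rng(seed)
    m = panel.n_variants
    annotation = np.full(m, "OTHER", dtype=object)
    pool = np.arange(m)
    rng.shuffle(pool)
    taken = np.zeros(m, dtype=bool)
    for cls, frac in proportions.items():
        if cls not in ANNOTATION_CLASSES:
            raise ValueError(f"unknown annotation class {cls!r}")
        n_cls = int(round(frac * m))
        banned = np.zeros(m, dtype=bool)
        if exclude_from and cls in exclude_from:
            banned[np.asarray(exclude_from[cls], dtype=np.int64)] = True
        avail = pool[~taken[pool] & ~banned[pool]]
        chosen = avail[:n_cls]
        annotation[chosen] = cls
        taken[chosen] = True
    out = panel.copy()
    out.annotation = annotation
    return out


def sample_qtl(panel: GenotypePanel, n_small: int = DEFAULT_N_SMALL,
               n_medium: int = DEFAULT_N_MEDIUM, n_large: int = DEFAULT_N_LARGE,
               sigma_g2: float = 1.0, seed: int | None = None,
               candidates: np.ndarray | None = None) -> QTLSet:
    """Sample QTL without replacement and draw class-scaled additive effects.

    Class effect variances are 1e-4, 1e-3 and 1e-2 times ``sigma_g2`` for
    small, medium and large QTL.  ``candidates`` restricts the sampling pool
    (defaults to all variants).
    """
    for n in (n_small, n_medium, n_large):
        if n < 0:
            raise ValueError("class counts must be non-negative")
    total = n_small + n_medium + n_large
    pool = np.arange(panel.n_variants) if candidates is None else np.asarray(candidates)
    if total > pool.shape[0]:
        raise ValueError(f"requested {total} QTL but only {pool.shape[0]} candidate variants")
    rng = np.random.default_rng(seed)
    if total == 0:
        return QTLSet(indices=np.empty(0, np.int64), effects=np.empty(0),
                      size_class=np.empty(0, object), sigma_g2=sigma_g2)
    idx = rng.choice(pool, size=total, replace=False)
    size_class = np.concatenate([
        np.full(n_small, "small", dtype=object),
        np.full(n_medium, "medium", dtype=object),
        np.full(n_large, "large", dtype=object),
    ])
    sd = np.sqrt(np.array([QTL_CLASS_VARIANCE[k] for k in size_class]) * sigma_g2)
    effects = rng.normal(0.0, 1.0, size=total) * sd
    order = np.argsort(idx, kind="stable")
    return QTLSet(indices=idx[order], effects=effects[order],
                  size_class=size_class[order], sigma_g2=sigma_g2)


def compute_tbv(panel: GenotypePanel, qtl: QTLSet) -> np.ndarray:
    """True breeding value: dosage-weighted sum of QTL effects per individual."""
    if qtl.n_qtl == 0:
        return np.zeros(panel.n_individuals)
    if qtl.indices.max(initial=-1) >= panel.n_variants or qtl.indices.min(initial=0) < 0:
        raise ValueError("QTL indices out of range for panel")
    return panel.dosage[:, qtl.indices].astype(np.float64) @ qtl.effects


def simulate_phenotype(
    tbv: np.ndarray, h2: float, breeds: np.ndarray,
    breed_effect_spec: Mapping[str, tuple[float, float]] | None = None,
    seed: int | None = None, per_individual_breed_effect: bool = False,
) -> TraitSim:
    """Add environmental noise (to reach heritability ``h2``) and breed effects.

    The environmental variance is ``var_w(tbv) * (1 - h2) / h2`` where
    ``var_w`` is the pooled within-breed TBV variance (TBV centered per
    breed), so the realized within-breed heritability matches the target
    even when breeds have diverged genetically.  By default the breed
    effect is a single draw per breed shared by all its members
    (``per_individual_breed_effect=True`` resamples per individual).
    """
    if not (0 < h2 <= 1):
        raise ValueError("h2 must lie in (0, 1]")
    tbv = np.asarray(tbv, dtype=np.float64)
    breeds = np.asarray(breeds)
    if tbv.shape != breeds.shape:
        raise ValueError("tbv and breeds must align")
    rng = np.random.default_rng(seed)
    centered = tbv.copy()
    for b in np.unique(breeds):
        mask = breeds == b
        centered[mask] -= tbv[mask].mean()
    var_tbv = centered.var()
    env_sd = np.sqrt(var_tbv * (1.0 - h2) / h2)
    env = rng.normal(0.0, env_sd, size=tbv.shape[0]) if env_sd > 0 else np.zeros_like(tbv)
    breed_effect = np.zeros_like(tbv)
    if breed_effect_spec:
        for breed, (mean, sd) in breed_effect_spec.items():
            mask = breeds == breed
            if not mask.any():
                continue
            if per_individual_breed_effect:
                breed_effect[mask] = rng.normal(mean, sd, size=int(mask.sum()))
            else:
                breed_effect[mask] = rng.normal(mean, sd)
    return TraitSim(tbv=tbv, env=env, breed_effect=breed_effect,
                    phenotype=tbv + env + breed_effect, h2=h2)


def inject_errors(panel: GenotypePanel, model: ErrorModel,
                  seed: int | None = None,
                  validation_mask: np.ndarray | None = None) -> GenotypePanel:
    """Flip each of the two alleles of each genotype independently with p = e(MAF).

    ``e`` uses the pre-error MAF stored on the input panel.  Only
    individuals in the targeted population (resolved from ``model.target``
    and ``validation_mask``) are perturbed; the input panel is untouched.
    """
    if model.r == 0:
        return panel.copy()
    e = model.error_prob(panel.maf)
    n = panel.n_individuals
    if validation_mask is None:
        if model.target != "both":
            raise ValueError("validation_mask required when target != 'both'")
        row_mask = np.ones(n, dtype=bool)
    else:
        validation_mask = np.asarray(validation_mask, dtype=bool)
        row_mask = {"both": np.ones(n, dtype=bool),
                    "validation": validation_mask,
                    "reference": ~validation_mask}[model.target]
    rng = np.random.default_rng(seed)
    out = panel.copy()
    d = out.dosage[row_mask].astype(np.int64)
    e_mat = np.broadcast_to(e, d.shape)
    # d alleles carry the counted allele: flips down ~ Bin(d, e), up ~ Bin(2-d, e)
    down = rng.binomial(d, e_mat)
    up = rng.binomial(2 - d, e_mat)
    out.dosage[row_mask] = (d - down + up).astype(np.int8)
    out.maf = out.recompute_maf()
    return out


def maf_filter(panel: GenotypePanel, min_maf: float) -> GenotypePanel:
    """Drop variants whose MAF is strictly below ``min_maf`` (order preserved)."""
    keep = np.nonzero(panel.maf >= min_maf)[0]
    return panel.subset_variants(keep)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)

_DEFAULT_CROSS_RULES = {"REG": ("NSC",), "HD": ("NSC", "REG"), "OTHER": ("NSC",)}


def ld_prune(panel: GenotypePanel, r2_max: float = 0.9,
             tier_order: Sequence[str] = ("NSC", "REG", "HD", "OTHER"),
             window: int = 50, step: int = 5,
             cross_rules: Mapping[str, Sequence[str]] | None = None) -> GenotypePanel:
    """Two-phase annotation-tiered LD pruning on squared dosage correlation.

    Phase 1 prunes greedily within each annotation tier per chromosome with
    a sliding window (the later-positioned variant of an offending pair is
    removed).  Phase 2 removes lower-priority variants exceeding ``r2_max``
    against any retained variant of the tiers listed for their class in
    ``cross_rules`` (default: REG vs NSC; HD vs NSC or REG; OTHER vs NSC).
    """
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must lie in (0, 1]")
    bad = set(np.unique(panel.annotation)) - set(tier_order)
    if bad:
        raise ValueError(f"annotation class(es) {sorted(bad)} missing from tier_order")
    rules = dict(_DEFAULT_CROSS_RULES) if cross_rules is None else dict(cross_rules)

    dosage = panel.dosage.astype(np.float64)
    keep = np.ones(panel.n_variants, dtype=bool)

    # phase 1: within-tier windowed pruning, per chromosome, genome order
    for tier in tier_order:
        for c in np.unique(panel.chrom):
            idx = np.nonzero((panel.annotation == tier) & (panel.chrom == c))[0]
            if idx.size < 2:
                continue
            for start in range(0, idx.size, step):
                win = idx[start:start + window]
                active = [i for i in win if keep[i]]
                for a_pos in range(len(active)):
                    i = active[a_pos]
                    if not keep[i]:
                        continue
                    for j in active[a_pos + 1:]:
                        if keep[j] and _pairwise_r2(dosage[:, i], dosage[:, j]) > r2_max:
                            keep[j] = False
                if start + window >= idx.size:
                    break

    # phase 2: cross-tier removal against retained higher-priority variants
    for tier in tier_order:
        higher = rules.get(tier, ())
        if not higher:
            continue
        for c in np.unique(panel.chrom):
            ref_idx = np.nonzero(np.isin(panel.annotation, higher)
                                 & (panel.chrom == c) & keep)[0]
            if ref_idx.size == 0:
                continue
            cand = np.nonzero((panel.annotation == tier) & (panel.chrom == c) & keep)[0]
            for i in cand:
                for j in ref_idx:
                    if _pairwise_r2(dosage[:, i], dosage[:, j]) > r2_max:
                        keep[i] = False
                        break

    return panel.subset_variants(np.nonzero(keep)[0])
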