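"""Readers and writers: PLINK .bed/.bim/.fam, dosage matrix text, phenotype
and pedigree CSV, annotation tables, structured run configs and manifests."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .pedigree import Pedigree, sort_pedigree
from .simdata import ANNOTATION_CLASSES, GenotypePanel

BED_MAGIC = b"\x6c\x1b"
BED_VARIANT_MAJOR = b"\x01"

_SEX_CODE = {"M": "1", "F": "2"}
_SEX_DECODE = {"1": "M", "2": "F"}


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a variant-major .bed triplet; dosages count the A1 allele.

    The breed label is stored as the family id and sex as 1/2/0.
    """
    prefix = Path(prefix)
    n, m = panel.n_individuals, panel.n_variants
    codes = np.empty_like(panel.dosage, dtype=np.uint8)
    codes[panel.dosage == 2] = 0b00
    codes[panel.dosage == 1] = 0b10
    codes[panel.dosage == 0] = 0b11
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(BED_MAGIC + BED_VARIANT_MAJOR)
        buf = np.zeros((m, n_bytes), dtype=np.uint8)
        for k in range(4):
            sl = codes[k::4, :]  # individuals k, k+4, ...
            buf[:, :sl.shape[0]] |= (sl.T.astype(np.uint8)) << (2 * k)
        fh.write(buf.tobytes())
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(m):
            fh.write(f"{panel.chrom[j]}\t{panel.variant_id[j]}\t0\t{panel.pos[j]}\tA\tG\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i in range(n):
            sex = _SEX_CODE.get(str(panel.sex[i]), "0")
            fh.write(f"{panel.breed[i]}\t{panel.iid[i]}\t0\t0\t{sex}\t-9\n")


def read_plink(prefix: str | Path, max_missing: float = 0.05) -> GenotypePanel:
    """Read a variant-major .bed triplet into a GenotypePanel.

    Missing genotypes are imputed to the rounded per-variant mean dosage;
    variants with a missing fraction above ``max_missing`` are rejected.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype=str)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "vid", "cm", "pos", "a1", "a2"], dtype=str)
    if len(bim) == 0:
        raise ValueError("variant file is empty")
    if len(fam) == 0:
        raise ValueError("sample file is empty")
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:2] != BED_MAGIC:
        raise ValueError("not a .bed file (magic-byte mismatch)")
    if raw[2:3] != BED_VARIANT_MAJOR:
        raise ValueError("only variant-major .bed files are supported")
    n_bytes = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != m * n_bytes:
        raise ValueError(f".bed payload has {body.size} bytes, expected {m * n_bytes}")
    body = body.reshape(m, n_bytes)
    # expand 2-bit codes: individual i is bits 2*(i%4) of byte i//4
    shifts = (2 * (np.arange(n) % 4)).astype(np.uint8)
    codes = (body[:, np.arange(n) // 4] >> shifts) & 0b11
    dosage = np.empty((m, n), dtype=np.float64)
    dosage[codes == 0b00] = 2
    dosage[codes == 0b10] = 1
    dosage[codes == 0b11] = 0
    missing = codes == 0b01
    dosage[missing] = np.nan
    miss_frac = missing.mean(axis=1)
    if (miss_frac > max_missing).any():
        worst = int(np.argmax(miss_frac))
        raise ValueError(f"variant {bim['vid'][worst]} has {miss_frac[worst]:.1%} "
                         f"missing genotypes (cap {max_missing:.1%})")
    n_imputed = int(missing.sum())
    if n_imputed:
        means = np.nanmean(dosage, axis=1)
        for j in np.nonzero(missing.any(axis=1))[0]:
            dosage[j, missing[j]] = np.round(means[j])
    dosage = dosage.T.astype(np.int8)

    def _chrom_code(c: str) -> int:
        if c.upper() == "X":
            return 30
        try:
            return int(c)
        except ValueError:
            raise ValueError(f"unknown chromosome code {c!r}") from None

    chrom = np.array([_chrom_code(c) for c in bim["chrom"]], dtype=np.int64)
    p = dosage.mean(axis=0) / 2.0
    panel = GenotypePanel(
        dosage=dosage, chrom=chrom, pos=bim["pos"].astype(np.int64).to_numpy(),
        variant_id=bim["vid"].to_numpy(dtype=object),
        maf=np.minimum(p, 1.0 - p),
        annotation=np.full(m, "OTHER", dtype=object),
        breed=fam["fid"].to_numpy(dtype=object),
        sex=np.array([_SEX_DECODE.get(s, "U") for s in fam["sex"]], dtype=object),
        iid=fam["iid"].to_numpy(dtype=object))
    panel.n_imputed = n_imputed
    return panel


# ---------------------------------------------------------------------------
# dosage matrix text
# ---------------------------------------------------------------------------

def write_dosage_matrix(panel: GenotypePanel, path: str | Path) -> None:
    """Whitespace matrix: header of variant ids, one row per individual."""
    with open(path, "w") as fh:
        fh.write("IID " + " ".join(map(str, panel.variant_id)) + "\n")
        for i in range(panel.n_individuals):
            fh.write(str(panel.iid[i]) + " "
                     + " ".join(map(str, panel.dosage[i])) + "\n")


def read_dosage_matrix(path: str | Path) -> GenotypePanel:
    df = pd.read_csv(path, sep=r"\s+", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("dosage matrix needs an IID column and at least one variant")
    vids = np.asarray(df.columns[1:], dtype=object)
    dosage = df.iloc[:, 1:].to_numpy()
    if not np.isin(np.unique(dosage), [0, 1, 2]).all():
        raise ValueError("dosage matrix entries must be 0, 1 or 2")
    m = vids.shape[0]
    chrom = np.ones(m, dtype=np.int64)
    pos = np.arange(1, m + 1, dtype=np.int64)
    parsed = [str(v).removeprefix("v").split("_") for v in vids]
    if all(len(p) == 2 and p[0].isdigit() and p[1].isdigit() for p in parsed):
        chrom = np.array([int(p[0]) for p in parsed], dtype=np.int64)
        pos = np.array([int(p[1]) for p in parsed], dtype=np.int64)
    p_freq = dosage.mean(axis=0) / 2.0
    n = dosage.shape[0]
    return GenotypePanel(
        dosage=dosage.astype(np.int8), chrom=chrom, pos=pos, variant_id=vids,
        maf=np.minimum(p_freq, 1.0 - p_freq),
        annotation=np.full(m, "OTHER", dtype=object),
        breed=np.full(n, "unknown", dtype=object),
        sex=np.full(n, "U", dtype=object),
        iid=df.iloc[:, 0].to_numpy(dtype=object))


def read_genotypes(path: str | Path, format: str = "plink_bed",
                   **kwargs) -> GenotypePanel:
    if format == "plink_bed":
        return read_plink(path, **kwargs)
    if format == "dosage_matrix":
        return read_dosage_matrix(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Phenotype CSV with id, value, optional weight and fixed-effect columns."""
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns or "value" not in df.columns:
        raise ValueError("phenotype file needs 'id' and 'value' columns")
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate phenotype id {dup!r}")
    try:
        df["value"] = df["value"].astype(np.float64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric trait value: {exc}") from None
    if "weight" in df.columns:
        df["weight"] = df["weight"].astype(np.float64)
        if (df["weight"] <= 0).any():
            raise ValueError("weights must be positive")
    else:
        df["weight"] = 1.0
    return df


def read_pedigree(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, dtype=str)
    for col in ("id", "sire", "dam"):
        if col not in df.columns:
            raise ValueError("pedigree file needs id, sire and dam columns")
    return sort_pedigree(df[["id", "sire", "dam"]])


def read_annotations(path: str | Path, panel: GenotypePanel) -> GenotypePanel:
    """Apply a variant_id,class table to a panel (unlisted variants -> OTHER)."""
    df = pd.read_csv(path, dtype=str)
    if "variant_id" not in df.columns or "class" not in df.columns:
        raise ValueError("annotation file needs variant_id and class columns")
    bad = set(df["class"]) - set(ANNOTATION_CLASSES)
    if bad:
        raise ValueError(f"unknown annotation class(es): {sorted(bad)}")
    mapping = dict(zip(df["variant_id"], df["class"]))
    out = panel.copy()
    out.annotation = np.array([mapping.get(str(v), "OTHER") for v in panel.variant_id],
                              dtype=object)
    return out


# ---------------------------------------------------------------------------
# run config / manifest
# ---------------------------------------------------------------------------

_CONFIG_SCHEMA = {
    "genotypes": str, "genotype_format": str, "phenotypes": str, "pedigree": str,
    "annotations": str, "validation_ids": list, "validation_file": str,
    "fixed_effects": list, "strategy": str, "drop_proportion": (int, float),
    "drop_point": (int, str), "n_iter": int, "post_drop_iter": int,
    "em_max_iter": int, "em_tol": (int, float), "h2_prior": (int, float),
    "seed": int, "chr_gebv": str, "compensation": str, "prior_from": str,
    "alpha": list, "gamma": list, "min_maf": (int, float),
    "out_prefix": str, "log_level": str,
}

_SIM_SCHEMA = {
    "n_per_breed": dict, "n_variants": int, "n_chromosomes": int,
    "divergence": (int, float), "recomb_rate": (int, float), "n_founders": int,
    "n_small": int, "n_medium": int, "n_large": int, "sigma_g2": (int, float),
    "h2": (int, float), "breed_effect": dict, "min_maf": (int, float),
    "error_r": (int, float), "error_target": str, "annotation_proportions": dict,
    "chrom_length": int,
}


def load_config(path: str | Path, schema: str = "run") -> dict:
    """YAML config with an anti-typo contract: unknown keys are errors."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    allowed = _CONFIG_SCHEMA if schema == "run" else _SIM_SCHEMA
    for key, val in cfg.items():
        if key not in allowed:
            raise ValueError(f"unknown config key {key!r}")
        if val is not None and not isinstance(val, allowed[key]):
            raise ValueError(f"config key {key!r} has wrong type "
                             f"({type(val).__name__})")
    base = Path(path).parent
    for key in ("genotypes", "phenotypes", "pedigree", "annotations",
                "validation_file"):
        if cfg.get(key):
            p = Path(cfg[key])
            if not p.is_absolute():
                p = base / p
            cfg[key] = str(p)
            probe = p.with_suffix(".bed") if key == "genotypes" and cfg.get(
                "genotype_format", "plink_bed") == "plink_bed" else p
            if not probe.exists():
                raise FileNotFoundError(f"config path for {key!r} not found: {probe}")
    return cfg


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, config: Mapping, seeds: Mapping,
                   inputs: Sequence[str | Path] = (),
                   outputs: Sequence[str | Path] = (),
                   stages: Mapping | None = None) -> None:
    manifest = {
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": {k: v for k, v in config.items()},
        "seeds": dict(seeds),
        "inputs": {str(p): file_sha256(p) for p in inputs if Path(p).exists()},
        "outputs": [str(p) for p in outputs],
    }
    if stages:
        manifest["stages"] = dict(stages)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
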