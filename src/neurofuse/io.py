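"""Readers and writers for the on-disk formats the pipeline touches.

A cohort lives in one directory with a JSON manifest listing, per patient,
which modality files exist — the modality-availability mask is explicit on
disk rather than inferred from file presence.

Conventions: VCF positions are 1-based (as in the format itself); voxel
indices are 0-based. Genotypes are stored as the alternate-allele count
(0 = hom-ref, 1 = het, 2 = hom-alt) with -1 for missing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

MISSING_GT = -1

#: value used for a genotype-quality score when the VCF carries no GQ field;
#: treated as passing by every quality filter.
GQ_PASSING = np.inf


class VCFParseError(ValueError):
    """Raised when a VCF record cannot be decoded; carries the record number."""


@dataclass
class GenotypeTable:
    """Biallelic genotype calls for a set of samples.

    Attributes
    ----------
    chrom, pos, ref, alt : per-site arrays (``pos`` is 1-based).
    genotypes : int array (n_sites, n_samples), alt-allele counts, -1 missing.
    quals : float array (n_sites, n_samples), per-genotype GQ
        (``inf`` when the file had no GQ).
    samples : list of sample ids.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    quals: np.ndarray
    samples: list[str]

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_ids(self) -> list[str]:
        return [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)]

    def take_sites(self, idx) -> "GenotypeTable":
        idx = np.asarray(idx)
        return GenotypeTable(
            self.chrom[idx], self.pos[idx], self.ref[idx], self.alt[idx],
            self.genotypes[idx], self.quals[idx], list(self.samples),
        )

    def take_samples(self, sample_ids) -> "GenotypeTable":
        missing = [s for s in sample_ids if s not in self.samples]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        cols = [self.samples.index(s) for s in sample_ids]
        return GenotypeTable(
            self.chrom, self.pos, self.ref, self.alt,
            self.genotypes[:, cols], self.quals[:, cols], list(sample_ids),
        )


@dataclass
class RawEHRTable:
    """Mixed-type clinical table with an explicit missing mask.

    ``schema`` maps each column to one of ``quantitative | binary |
    categorical``; the missing mask is boolean (True = missing) and aligned
    with ``values``.
    """

    values: pd.DataFrame
    schema: dict[str, str]
    missing: pd.DataFrame

    def __post_init__(self):
        if list(self.values.columns) != list(self.missing.columns):
            raise ValueError("values and missing mask must share columns")
        if not self.values.index.is_unique:
            raise ValueError("row ids must be unique")
        unknown = set(self.schema.values()) - {"quantitative", "binary", "categorical"}
        if unknown:
            raise ValueError(f"unknown column types in schema: {sorted(unknown)}")

    @property
    def patient_ids(self) -> list:
        return list(self.values.index)


@dataclass
class VolumeSet:
    """Per-patient 3D intensity volumes on a common grid plus a shared atlas.

    ``atlas`` holds integer region labels on the same grid; ``region_names``
    maps label -> anatomical name and every mapped label must occur in the
    atlas.
    """

    volumes: dict[str, np.ndarray]
    atlas: np.ndarray
    region_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        shape = self.atlas.shape
        for pid, vol in self.volumes.items():
            if vol.shape != shape:
                raise ValueError(
                    f"volume for {pid!r} has shape {vol.shape}, atlas grid is {shape}"
                )
        present = set(np.unique(self.atlas).tolist())
        for label in self.region_names:
            if label not in present:
                raise ValueError(f"region label {label} not present in atlas")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.volumes)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, sample_subset=None, drop_multiallelic=True) -> GenotypeTable:
    """Load a VCF (optionally bgzipped) into a :class:`GenotypeTable`.

    GT is required; GQ is read when present, otherwise every genotype is
    treated as passing quality. Phased and unphased calls are treated
    identically; half-calls and ``./.`` become missing. Multi-allelic
    records are dropped when ``drop_multiallelic`` is true, otherwise split
    into one biallelic record per alternate allele (other alts -> missing).
    """
    vcf = VCF(str(path), gts012=False)
    all_samples = list(vcf.samples)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in all_samples]
        if missing:
            raise KeyError(f"samples not present in VCF: {missing}")
        keep = [all_samples.index(s) for s in sample_subset]
        samples = list(sample_subset)
    else:
        keep = list(range(len(all_samples)))
        samples = all_samples

    chrom, pos, ref, alt, gts, gqs = [], [], [], [], [], []
    for rec_no, var in enumerate(vcf, start=1):
        try:
            alts = var.ALT
            if len(alts) != 1:
                if drop_multiallelic:
                    continue
                split = _split_multiallelic(var, keep)
            else:
                split = [(alts[0], _decode_genotypes(var, keep))]
            gq = _decode_gq(var, keep)
            for alt_allele, calls in split:
                chrom.append(var.CHROM)
                pos.append(var.POS)
                ref.append(var.REF)
                alt.append(alt_allele)
                gts.append(calls)
                gqs.append(gq)
        except VCFParseError:
            raise
        except Exception as exc:  # cyvcf2 raises bare Exceptions on bad records
            raise VCFParseError(f"malformed VCF record #{rec_no} in {path}: {exc}") from exc

    return GenotypeTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        genotypes=np.array(gts, dtype=np.int8).reshape(-1, len(samples)),
        quals=np.array(gqs, dtype=float).reshape(-1, len(samples)),
        samples=samples,
    )


def _decode_genotypes(var, keep):
    out = np.empty(len(keep), dtype=np.int8)
    for j, i in enumerate(keep):
        a0, a1 = var.genotypes[i][0], var.genotypes[i][1]
        if a0 < 0 or a1 < 0:  # ./., half-calls
            out[j] = MISSING_GT
        else:
            out[j] = (a0 > 0) + (a1 > 0)
    return out


def _split_multiallelic(var, keep):
    records = []
    for alt_idx, alt_allele in enumerate(var.ALT, start=1):
        calls = np.empty(len(keep), dtype=np.int8)
        for j, i in enumerate(keep):
            a0, a1 = var.genotypes[i][0], var.genotypes[i][1]
            alleles = (a0, a1)
            if a0 < 0 or a1 < 0 or any(a not in (0, alt_idx) for a in alleles):
                calls[j] = MISSING_GT
            else:
                calls[j] = (a0 == alt_idx) + (a1 == alt_idx)
        records.append((alt_allele, calls))
    return records


def _decode_gq(var, keep):
    gq = var.format("GQ")
    if gq is None:
        return np.full(len(keep), GQ_PASSING)
    gq = np.asarray(gq, dtype=float).reshape(-1)
    out = gq[keep]
    return np.where(np.isfinite(out) & (out >= 0), out, GQ_PASSING)


def write_vcf(table: GenotypeTable, path) -> Path:
    """Write a GenotypeTable as a minimal VCFv4.2 text file with GT:GQ."""
    path = Path(path)
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING_GT: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = sorted(set(table.chrom.tolist()), key=str)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for i in range(table.n_sites):
            cells = []
            for j in range(table.n_samples):
                gq = table.quals[i, j]
                gq_str = "99" if not np.isfinite(gq) else str(int(round(gq)))
                cells.append(f"{gt_strings[int(table.genotypes[i, j])]}:{gq_str}")
            fh.write(f"{table.chrom[i]}\t{table.pos[i]}\t.\t{table.ref[i]}\t"
                     f"{table.alt[i]}\t.\tPASS\t.\tGT:GQ\t" + "\t".join(cells) + "\n")
    return path


# ---------------------------------------------------------------------------
# EHR tables
# ---------------------------------------------------------------------------

def read_ehr(path, schema_path, sep=None) -> RawEHRTable:
    """Read a delimited clinical table with a YAML sidecar schema.

    The schema declares each column's type; values violating the declared
    type raise with the offending row/column named — no silent coercion.
    Empty cells become missing.
    """
    path = Path(path)
    with open(schema_path) as fh:
        schema = yaml.safe_load(fh)["columns"]
    if sep is None:
        sep = "\t" if path.suffix in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=object)
    unknown = [c for c in df.columns if c not in schema]
    if unknown:
        raise ValueError(f"columns missing from schema: {unknown}")

    values = {}
    missing = {}
    for col in df.columns:
        raw = df[col]
        miss = raw.isna() | (raw.astype(str).str.strip() == "")
        kind = schema[col]
        if kind == "quantitative":
            parsed = pd.to_numeric(raw.where(~miss), errors="coerce")
            bad = (~miss) & parsed.isna()
            if bad.any():
                row = bad.idxmax()
                raise ValueError(
                    f"non-numeric value {raw[row]!r} in quantitative column "
                    f"{col!r}, row {row!r}"
                )
            values[col] = parsed
        elif kind == "binary":
            parsed = pd.to_numeric(raw.where(~miss), errors="coerce")
            bad = (~miss) & (~parsed.isin([0, 1]))
            if bad.any():
                row = bad.idxmax()
                raise ValueError(
                    f"non-binary value {raw[row]!r} in binary column {col!r}, row {row!r}"
                )
            values[col] = parsed
        elif kind == "categorical":
            values[col] = raw.where(~miss).astype(object)
        else:
            raise ValueError(f"unknown column type {kind!r} for column {col!r}")
        missing[col] = miss

    return RawEHRTable(
        values=pd.DataFrame(values, index=df.index),
        schema={c: schema[c] for c in df.columns},
        missing=pd.DataFrame(missing, index=df.index),
    )


def write_ehr(table: RawEHRTable, path, schema_path) -> Path:
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".tab"} else ","
    out = table.values.where(~table.missing, other="")
    out.to_csv(path, sep=sep, index=True, index_label="patient_id")
    with open(schema_path, "w") as fh:
        yaml.safe_dump({"columns": table.schema}, fh, sort_keys=False)
    return path


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def read_volumes(paths: dict, atlas_path, region_names=None) -> VolumeSet:
    """Load per-patient NIfTI volumes plus the shared integer-label atlas.

    All volumes must sit on the atlas grid; a shape mismatch is an error.
    """
    atlas = np.asanyarray(nib.load(str(atlas_path)).dataobj).astype(np.int32)
    volumes = {}
    for pid, p in paths.items():
        vol = np.asanyarray(nib.load(str(p)).dataobj).astype(np.float64)
        if vol.shape != atlas.shape:
            raise ValueError(
                f"volume for {pid!r} has grid {vol.shape}, atlas grid is {atlas.shape}"
            )
        volumes[pid] = vol
    return VolumeSet(volumes=volumes, atlas=atlas, region_names=dict(region_names or {}))


def write_volumes(volset: VolumeSet, out_dir) -> dict:
    """Write each volume and the atlas as NIfTI; returns the path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    paths = {}
    for pid, vol in volset.volumes.items():
        p = out_dir / f"{pid}.nii.gz"
        nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(p))
        paths[pid] = p
    atlas_path = out_dir / "atlas.nii.gz"
    nib.save(nib.Nifti1Image(volset.atlas.astype(np.int16), affine), str(atlas_path))
    with open(out_dir / "regions.json", "w") as fh:
        json.dump({str(k): v for k, v in volset.region_names.items()}, fh, indent=1)
    return {"volumes": paths, "atlas": atlas_path}


# ---------------------------------------------------------------------------
# Gene intervals (BED) and manifest
# ---------------------------------------------------------------------------

def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Read a BED file of gene intervals -> (chrom, start0, end, name)."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{parts[1]}-{parts[2]}"
            intervals.append((parts[0], int(parts[1]), int(parts[2]), name))
    return intervals


def write_manifest(out_dir, patient_ids, labels, files: dict) -> Path:
    """Write the cohort manifest: patients, labels and per-modality paths."""
    out_dir = Path(out_dir)
    manifest = {
        "patients": [
            {
                "id": str(pid),
                "label": str(labels[i]),
                "modalities": {
                    mod: str(Path(fmap[pid]).relative_to(out_dir))
                    for mod, fmap in files.items() if pid in fmap
                },
            }
            for i, pid in enumerate(patient_ids)
        ]
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return path


def read_manifest(path) -> dict:
    with open(path) as fh:
        manifest = json.load(fh)
    if "patients" not in manifest:
        raise ValueError("manifest lacks a 'patients' list")
    return manifest
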