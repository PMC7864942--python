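"""Synthetic multimodal cohort generator.

Emulates a study population in which every patient has clinical (EHR) data
while genotyping and structural imaging cover overlapping subsets, the way
large observational dementia cohorts are assembled. Three diagnostic classes
(CN, MCI, AD) carry planted signal in each modality:

* EHR — a subset of quantitative features is drawn from class-shifted
  Gaussians (shift = ``effect_size`` x class index), the rest is noise;
  cells go missing completely at random.
* SNP — causal sites get class-dependent alternate-allele frequencies;
  null sites share one frequency per site and genotypes are sampled
  binomially, i.e. in Hardy-Weinberg proportions. Genotype-quality scores
  are sampled so a configurable fraction falls below a typical filter
  threshold.
* Imaging — per-region smooth base texture plus, in causal regions, a
  class-dependent mean-intensity shift and a bright blob whose size grows
  with disease stage.

Modalities share a per-patient latent severity scalar (weight configurable)
so that combining modalities can genuinely beat any single one; apart from
that scalar the modality noises are independent. All distributions are
stand-ins: no public characterization of the real cohort's feature
distributions exists, so the generator aims at plausible testbeds, not
realism (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import io as nfio

CLASSES = ("CN", "MCI", "AD")

#: region labels/names used for the deep imaging model by default
DEFAULT_REGIONS = {
    1: "left hippocampus",
    2: "right hippocampus",
    3: "right superior temporal",
    4: "right amygdala",
    5: "left amygdala",
}


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``modality_coverage`` gives either per-modality inclusion probabilities
    (floats in [0,1]) or explicit counts (ints; key ``all_three`` fixes the
    size of the fully observed subset). EHR is always present for everyone.
    """

    n_patients: int = 400
    class_proportions: tuple = (0.35, 0.40, 0.25)  # CN, MCI, AD
    modality_coverage: dict = field(default_factory=lambda: {"snp": 0.40, "imaging": 0.25})
    n_ehr_features: int = 60
    n_snp_sites: int = 200
    n_regions: int = 5
    region_shape: tuple = (22, 23, 18)
    n_causal_per_modality: int = 10
    effect_size: float = 1.0
    ehr_missing_rate: float = 0.10
    severity_weight: float = 0.5
    low_gq_rate: float = 0.05
    in_gene_rate: float = 0.85
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        for name in ("n_patients", "n_ehr_features", "n_snp_sites", "n_regions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.ehr_missing_rate < 1:
            raise ValueError("ehr_missing_rate must be in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        n_quant = _n_quantitative(self.n_ehr_features)
        if self.n_causal_per_modality > min(n_quant, self.n_snp_sites):
            raise ValueError(
                "n_causal_per_modality exceeds the quantitative EHR feature "
                "or SNP site count"
            )
        # imaging causal regions are capped at n_regions inside the sampler
        if len(self.region_shape) != 3 or any(s <= 0 for s in self.region_shape):
            raise ValueError("region_shape must be 3 positive integers")


@dataclass
class CohortTruth:
    """Ground-truth planted structure, returned alongside the cohort."""

    causal_ehr: list[str]
    causal_ehr_idx: np.ndarray
    causal_snp_idx: np.ndarray
    causal_regions: list[int]
    severity: np.ndarray


@dataclass
class Cohort:
    patient_ids: list[str]
    labels: np.ndarray                 # per-patient class name
    availability: pd.DataFrame         # bool columns: ehr, snp, imaging
    ehr: nfio.RawEHRTable
    genotypes: nfio.GenotypeTable      # samples = patients with SNP data
    volumes: nfio.VolumeSet            # patients with imaging data
    truth: CohortTruth

    def __post_init__(self):
        if not self.availability["ehr"].all():
            raise ValueError("every patient must have EHR data")
        if set(self.genotypes.samples) != set(
            self.availability.index[self.availability["snp"]]
        ):
            raise ValueError("SNP availability flags disagree with stored genotypes")
        if set(self.volumes.patient_ids) != set(
            self.availability.index[self.availability["imaging"]]
        ):
            raise ValueError("imaging availability flags disagree with stored volumes")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def label_codes(self) -> np.ndarray:
        return np.array([CLASSES.index(l) for l in self.labels])


def _n_quantitative(n_features: int) -> int:
    # 60% quantitative / 20% binary / 20% categorical split of the EHR table
    return n_features - 2 * (n_features // 5)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Sample a full multimodal cohort; bitwise-deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    patient_ids = [f"P{i:04d}" for i in range(n)]

    # labels: deterministic counts closest to the requested proportions
    counts = np.floor(np.asarray(spec.class_proportions) * n).astype(int)
    counts[0] += n - counts.sum()
    classes = np.repeat(np.arange(3), counts)
    rng.shuffle(classes)
    labels = np.array([CLASSES[c] for c in classes], dtype=object)

    severity = classes + rng.normal(0.0, 0.5, size=n)

    availability = _sample_availability(spec, rng, patient_ids)
    ehr, causal_ehr_idx, causal_names = _sample_ehr(spec, rng, patient_ids, classes, severity)

    snp_ids = [pid for pid in patient_ids if availability.loc[pid, "snp"]]
    snp_idx = np.array([patient_ids.index(p) for p in snp_ids], dtype=int)
    genotypes, causal_snp_idx = _sample_genotypes(
        spec, rng, snp_ids, classes[snp_idx], severity[snp_idx]
    )

    img_ids = [pid for pid in patient_ids if availability.loc[pid, "imaging"]]
    img_idx = np.array([patient_ids.index(p) for p in img_ids], dtype=int)
    volumes, causal_regions = _sample_volumes(
        spec, rng, img_ids, classes[img_idx], severity[img_idx]
    )

    truth = CohortTruth(
        causal_ehr=causal_names,
        causal_ehr_idx=causal_ehr_idx,
        causal_snp_idx=causal_snp_idx,
        causal_regions=causal_regions,
        severity=severity,
    )
    return Cohort(patient_ids, labels, availability, ehr, genotypes, volumes, truth)


def _sample_availability(spec, rng, patient_ids) -> pd.DataFrame:
    n = len(patient_ids)
    cov = spec.modality_coverage
    snp = np.zeros(n, dtype=bool)
    img = np.zeros(n, dtype=bool)
    if all(isinstance(v, (int, np.integer)) and not isinstance(v, bool) for v in cov.values()):
        n_snp, n_img = int(cov["snp"]), int(cov["imaging"])
        n_both = int(cov.get("all_three", round(n_snp * n_img / n)))
        if n_both > min(n_snp, n_img) or (n_snp + n_img - n_both) > n:
            raise ValueError("explicit modality counts are inconsistent")
        order = rng.permutation(n)
        both = order[:n_both]
        snp_only = order[n_both:n_snp]
        img_only = order[n_snp:n_snp + n_img - n_both]
        snp[both] = snp[snp_only] = True
        img[both] = img[img_only] = True
    else:
        snp = rng.random(n) < float(cov["snp"])
        img = rng.random(n) < float(cov["imaging"])
    return pd.DataFrame(
        {"ehr": np.ones(n, dtype=bool), "snp": snp, "imaging": img}, index=patient_ids
    )


def _sample_ehr(spec, rng, patient_ids, classes, severity):
    n, m = len(patient_ids), spec.n_ehr_features
    n_cat = n_bin = m // 5
    n_quant = m - n_bin - n_cat
    k = spec.n_causal_per_modality
    w = spec.severity_weight

    causal_idx = np.arange(k)  # first k quantitative columns carry signal
    quant = rng.normal(0.0, 1.0, size=(n, n_quant))
    shift = spec.effect_size * ((1 - w) * classes + w * severity)[:, None]
    quant[:, :k] += shift

    values, schema, order = {}, {}, []
    for j in range(n_quant):
        name = f"clin_q{j:03d}"
        values[name] = quant[:, j]
        schema[name] = "quantitative"
        order.append(name)
    for j in range(n_bin):
        name = f"clin_b{j:03d}"
        values[name] = rng.integers(0, 2, size=n).astype(float)
        schema[name] = "binary"
        order.append(name)
    levels = np.array(["a", "b", "c"], dtype=object)
    for j in range(n_cat):
        name = f"clin_c{j:03d}"
        values[name] = levels[rng.integers(0, 3, size=n)]
        schema[name] = "categorical"
        order.append(name)

    df = pd.DataFrame(values, index=patient_ids)[order]
    missing = pd.DataFrame(
        rng.random((n, m)) < spec.ehr_missing_rate, index=patient_ids, columns=order
    )
    df = df.where(~missing)
    table = nfio.RawEHRTable(values=df, schema=schema, missing=missing)
    return table, causal_idx, [order[i] for i in causal_idx]


def _sample_genotypes(spec, rng, sample_ids, classes, severity):
    n_sites, k = spec.n_snp_sites, spec.n_causal_per_modality
    n = len(sample_ids)
    w = spec.severity_weight

    causal_idx = rng.choice(n_sites, size=k, replace=False)
    causal_mask = np.zeros(n_sites, dtype=bool)
    causal_mask[causal_idx] = True

    # per-site, per-patient alt-allele frequency
    base = rng.uniform(0.02, 0.5, size=n_sites)
    p = np.tile(base, (n, 1))
    stage = (1 - w) * classes + w * severity  # shared latent drives causal AFs
    p[:, causal_mask] = np.clip(
        0.25 + 0.12 * spec.effect_size * stage[:, None], 0.01, 0.95
    )
    geno = rng.binomial(2, p).astype(np.int8)  # (n, n_sites)

    gq = np.where(
        rng.random((n, n_sites)) < spec.low_gq_rate,
        rng.uniform(5, 19, size=(n, n_sites)),
        rng.uniform(30, 99, size=(n, n_sites)),
    )

    chrom, pos = _sample_positions(spec, rng, n_sites)
    bases = np.array(["A", "C", "G", "T"], dtype=object)
    ref = bases[rng.integers(0, 4, size=n_sites)]
    alt = np.array([bases[(list(bases).index(r) + 1) % 4] for r in ref], dtype=object)

    table = nfio.GenotypeTable(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        genotypes=geno.T.copy(), quals=gq.T.copy(), samples=list(sample_ids),
    )
    return table, np.sort(causal_idx)


def _sample_positions(spec, rng, n_sites):
    intervals = nfio.read_bed(default_gene_bed())
    in_gene = rng.random(n_sites) < spec.in_gene_rate
    chrom = np.empty(n_sites, dtype=object)
    pos = np.empty(n_sites, dtype=np.int64)
    for i in range(n_sites):
        c, s, e, _ = intervals[rng.integers(0, len(intervals))]
        if in_gene[i]:
            chrom[i] = c
            pos[i] = rng.integers(s + 1, e + 1)  # 1-based inside [s+1, e]
        else:
            chrom[i] = c
            pos[i] = e + int(rng.integers(50_000, 500_000))  # clear of the gene
    order = np.lexsort((pos, chrom.astype(str)))
    return chrom[order], pos[order]


def default_gene_bed() -> Path:
    """Path to the packaged, editable AD-associated gene interval list."""
    return Path(__file__).parent / "data" / "ad_genes.bed"


def _sample_volumes(spec, rng, img_ids, classes, severity):
    bs = tuple(spec.region_shape)
    n_regions = spec.n_regions
    atlas, region_boxes = _build_atlas(n_regions, bs)
    k = spec.n_causal_per_modality
    causal_regions = list(range(1, min(k, n_regions) + 1))
    w = spec.severity_weight

    names = {
        r: DEFAULT_REGIONS.get(r, f"region {r}") for r in range(1, n_regions + 1)
    }
    volumes = {}
    for i, pid in enumerate(img_ids):
        vol = rng.normal(0.2, 0.05, size=atlas.shape)
        stage = (1 - w) * classes[i] + w * severity[i]
        for r in range(1, n_regions + 1):
            mask = atlas == r
            texture = ndimage.gaussian_filter(
                rng.normal(0.0, 1.0, size=atlas.shape), sigma=2.0
            )
            vol[mask] += 0.5 + 0.15 * texture[mask]
            if r in causal_regions:
                vol[mask] += 0.12 * spec.effect_size * stage
                vol += _blob(atlas.shape, region_boxes[r],
                             radius=1.5 + 0.8 * spec.effect_size * max(stage, 0.0)) * mask
        volumes[pid] = vol
    volset = nfio.VolumeSet(volumes=volumes, atlas=atlas, region_names=names)
    return volset, causal_regions


def _build_atlas(n_regions, block_shape):
    """Regions are inset cuboids stacked along axis 0 with background gaps."""
    b0, b1, b2 = block_shape
    grid = np.zeros((n_regions * (b0 + 2) + 2, b1 + 4, b2 + 4), dtype=np.int32)
    boxes = {}
    for r in range(1, n_regions + 1):
        z0 = 2 + (r - 1) * (b0 + 2)
        # inset so the labelled bounding box is smaller than the crop shape,
        # exercising the symmetric zero-padding path downstream
        i0, i1, i2 = max(b0 // 6, 1), max(b1 // 6, 1), max(b2 // 6, 1)
        grid[z0 + i0:z0 + b0 - i0, 2 + i1:2 + b1 - i1, 2 + i2:2 + b2 - i2] = r
        boxes[r] = (z0 + b0 // 2, 2 + b1 // 2, 2 + b2 // 2)
    return grid, boxes


def _blob(shape, center, radius):
    if radius <= 0:
        return np.zeros(shape)
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    return 0.4 * np.exp(-d2 / (2.0 * radius**2))


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write a cohort in the standard on-disk layout; returns the manifest path.

    The generator doubles as a fixture factory for the I/O layer: EHR as
    CSV + YAML schema, genotypes as VCF, volumes as NIfTI, labels as CSV,
    tied together by a JSON manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ehr_path = nfio.write_ehr(cohort.ehr, out_dir / "ehr.csv", out_dir / "ehr.schema.yaml")
    vcf_path = nfio.write_vcf(cohort.genotypes, out_dir / "genotypes.vcf")
    vol_paths = nfio.write_volumes(cohort.volumes, out_dir / "volumes")

    labels = pd.DataFrame(
        {"label": cohort.labels}, index=pd.Index(cohort.patient_ids, name="patient_id")
    )
    labels.to_csv(out_dir / "labels.csv")

    files = {
        "ehr": {pid: ehr_path for pid in cohort.patient_ids},
        "snp": {pid: vcf_path for pid in cohort.genotypes.samples},
        "imaging": dict(vol_paths["volumes"]),
    }
    labels_by_pos = {i: cohort.labels[i] for i in range(cohort.n_patients)}
    return nfio.write_manifest(out_dir, cohort.patient_ids, labels_by_pos, files)
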