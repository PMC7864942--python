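"""Config-driven end-to-end runs.

A run takes a cohort (synthetic, or loaded from an on-disk manifest),
builds the split plan, and for every internal fold fits the modality
pipelines on the training rows only: EHR normalization + denoising
autoencoder, SNP filtering + mRMR + autoencoder, ROI extraction + 3D CNN.
Per-modality intermediate features are zero-masked where a modality is
absent, concatenated, and classified by the shallow decision layer; fold
metrics aggregate into the evaluation report. A final refit on all
internal patients scores the external test set and feeds interpretation
(perturbation ranking and the raw-vs-intermediate cluster comparison).

Single-modality networks are trained on their own staging tasks — EHR
three-class, SNP CN vs MCI/AD, imaging CN vs AD — and their intermediate
features are reused by whichever fusion task is requested, mirroring the
two-stage (representation first, fusion second) training design.

One global seed fans out to per-stage seeds through a fixed derivation so
a single integer reproduces the entire run.
"""

from __future__ import annotations

import copy
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ehr as ehr_mod
from . import fusion, interpret, io as nfio, snp as snp_mod
from .evaluate import EvalReport, SplitPlan, make_splits, metrics
from .imaging import extract_rois
from .nn import RegionCNNClassifier, StackedDenoisingAutoencoder
from .simulate import Cohort, CohortSpec, default_gene_bed, generate_cohort

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "runs/latest",
    "cohort": {},  # CohortSpec overrides, or {"manifest": <path>}
    "task": {
        "modalities": ["ehr", "snp", "imaging"],
        "classifier": {"kind": "random_forest", "params": {"n_trees": fusion.DEEP_FUSION_TREES}},
    },
    "ehr": {"missing_threshold": 0.70},
    "snp": {
        "min_gq": 20.0, "max_missing_rate": 0.10, "min_maf": 0.05,
        "hwe_alpha": 1e-6, "k_select": 50, "gene_bed": None,
    },
    # autoencoder regularization here is retuned for the desk-scale
    # synthetic cohort (~10^1-10^2 input features): the headline values
    # (corruption 0.6, L2 0.03/0.06) were cross-validated against a much
    # wider clinical feature space where the summed reconstruction term
    # dwarfs the weight penalty. See docs/methods.md.
    "sda_ehr": {
        "layer_sizes": [200, 100, 50], "corruption_p": 0.3,
        "l2_pretrain": 0.003, "l2_finetune": 0.001,
        "pretrain_epochs": 25, "finetune_epochs": 25,
        "batch_size": 3, "learning_rate": 1e-3,
    },
    "sda_snp": {
        "layer_sizes": [200, 100, 50], "corruption_p": 0.3,
        "l2_pretrain": 0.003, "l2_finetune": 0.002,
        "pretrain_epochs": 30, "finetune_epochs": 30,
        "batch_size": 3, "learning_rate": 1e-3,
    },
    "cnn": {
        "n_kernels": 10, "kernel_shape": [5, 5, 5], "pool_shape": [3, 3, 3],
        "fc1_width": 20, "fc2_width": 20, "dropout_p": 0.5, "batch_size": 5,
        "learning_rate": 1e-3, "max_epochs": 12, "patience": 4,
        "val_fraction": 0.2, "layer_order": "methods",
    },
    "evaluation": {"n_folds": 10, "external_fraction": 0.10, "stratify": True},
    "interpretation": {"enabled": True, "kmeans_k": None},
}


def derive_seed(global_seed: int, stage: str) -> int:
    """Fixed fan-out from the single run seed to a per-stage seed (< 2^31)."""
    ss = np.random.SeedSequence([int(global_seed) & 0x7FFFFFFF,
                                 zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def load_config(source) -> dict:
    """Merge a YAML file / dict over the defaults (nested, two levels)."""
    if source is None:
        user = {}
    elif isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = copy.deepcopy(dict(source))
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


class StageError(RuntimeError):
    """Wraps a failure with the pipeline stage it happened in."""

    def __init__(self, stage, exc):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage
        self.cause = exc


# ---------------------------------------------------------------------------
# Cohort sources
# ---------------------------------------------------------------------------

def build_cohort(cfg: dict) -> Cohort:
    cohort_cfg = dict(cfg.get("cohort", {}))
    if "manifest" in cohort_cfg:
        return load_cohort(Path(cohort_cfg["manifest"]).parent)
    cohort_cfg.setdefault("seed", derive_seed(cfg["seed"], "cohort"))
    spec_kwargs = {
        k: (tuple(v) if isinstance(v, list) else v) for k, v in cohort_cfg.items()
    }
    return generate_cohort(CohortSpec(**spec_kwargs))


def load_cohort(cohort_dir) -> Cohort:
    """Reassemble a cohort from the standard on-disk layout."""
    cohort_dir = Path(cohort_dir)
    manifest = nfio.read_manifest(cohort_dir / "manifest.json")
    patient_ids = [p["id"] for p in manifest["patients"]]
    labels = np.array([p["label"] for p in manifest["patients"]], dtype=object)
    avail = pd.DataFrame(
        {
            mod: [mod in p["modalities"] for p in manifest["patients"]]
            for mod in ("ehr", "snp", "imaging")
        },
        index=patient_ids,
    )
    ehr = nfio.read_ehr(cohort_dir / "ehr.csv", cohort_dir / "ehr.schema.yaml")
    snp_ids = [pid for pid, has in zip(patient_ids, avail["snp"]) if has]
    gt = nfio.read_vcf(cohort_dir / "genotypes.vcf", sample_subset=snp_ids)
    with open(cohort_dir / "volumes" / "regions.json") as fh:
        region_names = {int(k): v for k, v in json.load(fh).items()}
    img_paths = {
        p["id"]: cohort_dir / p["modalities"]["imaging"]
        for p in manifest["patients"] if "imaging" in p["modalities"]
    }
    vols = nfio.read_volumes(img_paths, cohort_dir / "volumes" / "atlas.nii.gz",
                             region_names)
    return Cohort(patient_ids, labels, avail, ehr, gt, vols, truth=None)


# ---------------------------------------------------------------------------
# Per-fold modality fitting
# ---------------------------------------------------------------------------

@dataclass
class FoldModels:
    """Everything fitted on one training split."""

    ehr_state: object = None
    ehr_sda: StackedDenoisingAutoencoder | None = None
    ehr_feature_names: list = field(default_factory=list)
    snp_sites: list = field(default_factory=list)
    snp_sda: StackedDenoisingAutoencoder | None = None
    cnn: RegionCNNClassifier | None = None
    filter_log: dict | None = None


def _code_width(cfg_block) -> int:
    return int(cfg_block["layer_sizes"][-1])


class TaskRunner:
    """Runs one modality-combination task over a cohort."""

    def __init__(self, cohort: Cohort, modalities, cfg: dict):
        self.cohort = cohort
        self.modalities = tuple(m for m in fusion.BLOCK_ORDER if m in modalities)
        if not self.modalities:
            raise ValueError("task needs at least one modality")
        self.cfg = cfg
        self.scheme = cfg["task"].get("scheme") or fusion.task_for(self.modalities)
        self.seed = int(cfg["seed"])

        labels = cohort.labels
        collapsed, keep = fusion.collapse_labels(labels, self.scheme)
        has_any = np.zeros(cohort.n_patients, dtype=bool)
        for mod in self.modalities:
            has_any |= cohort.availability[mod].to_numpy()
        self.keep = keep & has_any
        self.ids = [p for p, k in zip(cohort.patient_ids, self.keep) if k]
        self.labels = pd.Series(collapsed[self.keep], index=self.ids)
        self.full_labels = pd.Series(labels[self.keep], index=self.ids)

        # precompute deterministic imaging features once
        if "imaging" in self.modalities:
            self.rois = extract_rois(cohort.volumes)
        else:
            self.rois = None

    # -- fitting on a training split --------------------------------------

    def fit_models(self, train_ids, fold_tag: str) -> FoldModels:
        models = FoldModels()
        cfg = self.cfg
        avail = self.cohort.availability

        if "ehr" in self.modalities:
            models.ehr_state = ehr_mod.fit_ehr_transform(
                self.cohort.ehr, train_ids,
                missing_threshold=cfg["ehr"]["missing_threshold"],
            )
            matrix = ehr_mod.apply_ehr_transform(self.cohort.ehr, models.ehr_state)
            models.ehr_feature_names = matrix.feature_names
            X = ehr_mod.to_unit_interval(matrix.values.loc[train_ids].to_numpy())
            y = self.full_labels.loc[train_ids].to_numpy()  # EHR task: 3-class
            sda = StackedDenoisingAutoencoder(
                **_sda_kwargs(cfg["sda_ehr"]),
                random_state=derive_seed(self.seed, f"sda_ehr/{fold_tag}"),
            )
            models.ehr_sda = sda.fit(X, y)

        if "snp" in self.modalities:
            snp_train = [p for p in train_ids if avail.loc[p, "snp"]]
            if len(snp_train) >= 10:
                gt_train = self.cohort.genotypes.take_samples(snp_train)
                y_snp, _ = fusion.collapse_labels(
                    self.full_labels.loc[snp_train].to_numpy(), "cn_vs_mciad"
                )
                snp_cfg = snp_mod.SNPFilterConfig(
                    min_gq=cfg["snp"]["min_gq"],
                    max_missing_rate=cfg["snp"]["max_missing_rate"],
                    min_maf=cfg["snp"]["min_maf"],
                    hwe_alpha=cfg["snp"]["hwe_alpha"],
                    k_select=cfg["snp"]["k_select"],
                    gene_intervals=nfio.read_bed(
                        cfg["snp"]["gene_bed"] or default_gene_bed()
                    ),
                )
                matrix, log = snp_mod.prepare_snp_features(gt_train, y_snp, snp_cfg)
                models.snp_sites = matrix.site_ids
                models.filter_log = log.as_dict()
                sda = StackedDenoisingAutoencoder(
                    **_sda_kwargs(cfg["sda_snp"]),
                    random_state=derive_seed(self.seed, f"sda_snp/{fold_tag}"),
                )
                models.snp_sda = sda.fit(snp_mod.to_unit_interval(matrix.values), y_snp)

        if "imaging" in self.modalities:
            img_train = [p for p in train_ids if avail.loc[p, "imaging"]]
            y_full = self.full_labels.loc[img_train].to_numpy()
            keep2 = y_full != "MCI"  # imaging network stages CN vs AD
            img_train = [p for p, k in zip(img_train, keep2) if k]
            if len(img_train) >= 2 * cfg["cnn"]["batch_size"]:
                cnn = RegionCNNClassifier(
                    **_cnn_kwargs(cfg["cnn"]),
                    random_state=derive_seed(self.seed, f"cnn/{fold_tag}"),
                )
                X = self.rois.stack(img_train)
                models.cnn = cnn.fit(X, self.full_labels.loc[img_train].to_numpy())
        return models

    # -- codes -------------------------------------------------------------

    def codes_for(self, models: FoldModels, ids) -> tuple[dict, pd.DataFrame]:
        cfg = self.cfg
        avail = self.cohort.availability
        codes = {}
        mask = {}
        n = len(ids)
        pos = {p: i for i, p in enumerate(ids)}

        if "ehr" in self.modalities:
            matrix = ehr_mod.apply_ehr_transform(self.cohort.ehr, models.ehr_state)
            X = ehr_mod.to_unit_interval(matrix.values.loc[ids].to_numpy())
            codes["ehr"] = models.ehr_sda.transform(X)
            mask["ehr"] = avail.loc[ids, "ehr"].to_numpy()

        if "snp" in self.modalities:
            width = _code_width(cfg["sda_snp"])
            block = np.zeros((n, width))
            have = np.zeros(n, dtype=bool)
            if models.snp_sda is not None:
                snp_ids = [p for p in ids if avail.loc[p, "snp"]]
                if snp_ids:
                    gt = self.cohort.genotypes.take_samples(snp_ids)
                    site_pos = {s: i for i, s in enumerate(gt.site_ids())}
                    sel = [site_pos[s] for s in models.snp_sites]
                    enc = snp_mod.encode_genotypes(gt.take_sites(sel))
                    vals = snp_mod.to_unit_interval(enc.values)
                    c = models.snp_sda.transform(vals)
                    for p, row in zip(snp_ids, c):
                        block[pos[p]] = row
                        have[pos[p]] = True
            codes["snp"] = block
            mask["snp"] = have

        if "imaging" in self.modalities:
            width = self.cfg["cnn"]["fc1_width"] * len(self.rois.region_ids)
            block = np.zeros((n, width))
            have = np.zeros(n, dtype=bool)
            if models.cnn is not None:
                img_ids = [p for p in ids if avail.loc[p, "imaging"]]
                if img_ids:
                    c = models.cnn.transform(self.rois.stack(img_ids))
                    for p, row in zip(img_ids, c):
                        block[pos[p]] = row
                        have[pos[p]] = True
            codes["imaging"] = block
            mask["imaging"] = have

        return codes, pd.DataFrame(mask, index=ids)

    # -- one train/evaluate cycle -----------------------------------------

    def _fit_and_predict(self, train_ids, eval_ids, fold_tag: str):
        models = self.fit_models(train_ids, fold_tag)
        all_ids = list(train_ids) + list(eval_ids)
        codes, mask = self.codes_for(models, all_ids)
        if len(self.modalities) == 1:
            preds = self._single_modality_predict(models, codes, mask, all_ids)
            pred_eval = preds.loc[eval_ids].to_numpy()
        else:
            fused, _prov = fusion.concat_intermediate(codes, mask)
            spec = fusion.ClassifierSpec(
                kind=self.cfg["task"]["classifier"]["kind"],
                params=self.cfg["task"]["classifier"].get("params", {}),
            )
            tr = [all_ids.index(p) for p in train_ids]
            ev = [all_ids.index(p) for p in eval_ids]
            clf = fusion.fit_decision_layer(
                fused[tr], self.labels.loc[train_ids].to_numpy(), spec,
                seed=derive_seed(self.seed, f"decision/{fold_tag}"),
            )
            pred_eval = clf.predict(fused[ev])
            models.decision_layer = clf
            models.fused = fused
            models.fused_ids = all_ids
        return models, pred_eval

    def _single_modality_predict(self, models, codes, mask, ids) -> pd.Series:
        mod = self.modalities[0]
        avail = mask[mod].to_numpy()
        out = pd.Series(index=ids, dtype=object)
        if mod == "ehr":
            matrix = ehr_mod.apply_ehr_transform(self.cohort.ehr, models.ehr_state)
            X = ehr_mod.to_unit_interval(matrix.values.loc[ids].to_numpy())
            out[:] = models.ehr_sda.predict(X)
        elif mod == "snp":
            snp_ids = [p for p, a in zip(ids, avail) if a]
            gt = self.cohort.genotypes.take_samples(snp_ids)
            site_pos = {s: i for i, s in enumerate(gt.site_ids())}
            sel = [site_pos[s] for s in models.snp_sites]
            enc = snp_mod.encode_genotypes(gt.take_sites(sel))
            out.loc[snp_ids] = models.snp_sda.predict(
                snp_mod.to_unit_interval(enc.values)
            )
        else:
            img_ids = [p for p, a in zip(ids, avail) if a]
            out.loc[img_ids] = models.cnn.predict(self.rois.stack(img_ids))
        return out

    # -- the full protocol -------------------------------------------------

    def run(self) -> "TaskResult":
        ev = self.cfg["evaluation"]
        plan = make_splits(
            self.labels, seed=derive_seed(self.seed, "splits"),
            n_folds=ev["n_folds"], external_fraction=ev["external_fraction"],
            stratify=ev["stratify"],
        )
        report = EvalReport()
        fold_models = []
        for f in range(plan.n_folds):
            train_ids, val_ids = plan.fold_split(f)
            models, pred = self._fit_and_predict(train_ids, val_ids, f"fold{f}")
            row = metrics(self.labels.loc[val_ids].to_numpy(), pred)
            report.add_fold(row)
            fold_models.append((models, val_ids))

        internal = plan.internal_ids()
        final_models, pred_ext = self._fit_and_predict(
            internal, plan.external_ids, "final"
        )
        report.external = metrics(
            self.labels.loc[plan.external_ids].to_numpy(), pred_ext
        )
        return TaskResult(
            modalities=self.modalities, scheme=self.scheme, ids=self.ids,
            labels=self.labels, plan=plan, report=report,
            fold_models=fold_models, final_models=final_models, runner=self,
        )


@dataclass
class TaskResult:
    modalities: tuple
    scheme: str
    ids: list
    labels: pd.Series
    plan: SplitPlan
    report: EvalReport
    fold_models: list
    final_models: FoldModels
    runner: TaskRunner


def _sda_kwargs(block: dict) -> dict:
    return {
        "layer_sizes": tuple(block["layer_sizes"]),
        "corruption_p": block["corruption_p"],
        "l2_pretrain": block["l2_pretrain"],
        "l2_finetune": block["l2_finetune"],
        "pretrain_epochs": block["pretrain_epochs"],
        "finetune_epochs": block["finetune_epochs"],
        "batch_size": block["batch_size"],
        "learning_rate": block["learning_rate"],
    }


def _cnn_kwargs(block: dict) -> dict:
    return {
        "n_kernels": block["n_kernels"],
        "kernel_shape": tuple(block["kernel_shape"]),
        "pool_shape": tuple(block["pool_shape"]),
        "fc1_width": block["fc1_width"],
        "fc2_width": block["fc2_width"],
        "dropout_p": block["dropout_p"],
        "batch_size": block["batch_size"],
        "learning_rate": block["learning_rate"],
        "max_epochs": block["max_epochs"],
        "patience": block["patience"],
        "val_fraction": block["val_fraction"],
        "layer_order": block["layer_order"],
    }


# ---------------------------------------------------------------------------
# Interpretation on a finished task
# ---------------------------------------------------------------------------

def interpret_task(result: TaskResult, cfg: dict):
    """Perturbation ranking (EHR inputs, validation folds averaged) and the
    raw-vs-intermediate cluster comparison."""
    runner = result.runner
    ranking = None
    cluster = None
    if "ehr" in result.modalities:
        tables = []
        names = None
        for models, val_ids in result.fold_models:
            matrix = ehr_mod.apply_ehr_transform(runner.cohort.ehr, models.ehr_state)
            X = ehr_mod.to_unit_interval(matrix.values.loc[val_ids].to_numpy())
            y = runner.full_labels.loc[val_ids].to_numpy()
            r = interpret.perturb_rank(
                models.ehr_sda, X, y, feature_names=matrix.feature_names,
                evaluation_set="internal validation folds",
            )
            tables.append(r.table.set_index("feature"))
            names = matrix.feature_names
        common = set.intersection(*(set(t.index) for t in tables))
        avg = (
            pd.concat([t.loc[sorted(common)] for t in tables])
            .groupby(level=0)[["baseline", "masked", "drop"]].mean()
        )
        name_order = {nm: i for i, nm in enumerate(names)}
        avg = avg.reset_index().rename(columns={"index": "feature"})
        avg["idx"] = avg["feature"].map(name_order)
        avg = avg.sort_values(["drop", "idx"], ascending=[False, True]).drop(columns="idx")
        ranking = interpret.FeatureRanking(
            table=avg.reset_index(drop=True),
            evaluation_set="internal validation folds (averaged)",
        )

        # cluster comparison: raw EHR vs intermediate codes, final model
        final = result.final_models
        matrix = ehr_mod.apply_ehr_transform(runner.cohort.ehr, final.ehr_state)
        X = ehr_mod.to_unit_interval(matrix.values.loc[result.ids].to_numpy())
        inter = final.ehr_sda.transform(X)
        k = cfg["interpretation"].get("kmeans_k") or len(np.unique(result.labels))
        cluster = interpret.cluster_compare(
            X, inter, k=k, seed=derive_seed(cfg["seed"], "kmeans")
        )
    return ranking, cluster


# ---------------------------------------------------------------------------
# Top-level run
# ---------------------------------------------------------------------------

def run_pipeline(config=None, out_dir=None) -> Path:
    """Execute preprocess -> training -> fusion -> evaluation -> interpretation.

    ``config`` is a YAML path or dict merged over the defaults. Writes the
    evaluation report, feature ranking, cluster comparison, predictions and
    a frozen copy of the resolved config (with its hash) to the run
    directory, which is returned.
    """
    cfg = load_config(config)
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)

    resolved = yaml.safe_dump(cfg, sort_keys=True)
    cfg_hash = hashlib.sha256(resolved.encode()).hexdigest()[:12]
    (out / f"config.{cfg_hash}.yaml").write_text(resolved)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc

    cohort = stage("cohort", build_cohort, cfg)
    runner = stage("setup", TaskRunner, cohort, cfg["task"]["modalities"], cfg)
    result = stage("train+evaluate", runner.run)
    result.report.to_json(out / f"eval_report.{cfg_hash}.json")

    preds_path = out / f"split_plan.{cfg_hash}.json"
    with open(preds_path, "w") as fh:
        json.dump(
            {"external_ids": [str(i) for i in result.plan.external_ids],
             "folds": [[str(i) for i in f] for f in result.plan.folds]},
            fh, indent=1,
        )

    if cfg["interpretation"]["enabled"]:
        ranking, cluster = stage("interpretation", interpret_task, result, cfg)
        if ranking is not None:
            ranking.to_tsv(out / f"feature_ranking.{cfg_hash}.tsv")
        if cluster is not None:
            with open(out / f"cluster_comparison.{cfg_hash}.json", "w") as fh:
                json.dump(cluster.to_dict(), fh, indent=1)

    if result.final_models.filter_log is not None:
        with open(out / f"snp_filter_log.{cfg_hash}.json", "w") as fh:
            json.dump(result.final_models.filter_log, fh, indent=1)

    # training curves of the final refit, one JSON object per line
    with open(out / f"training_curves.{cfg_hash}.jsonl", "w") as fh:
        final = result.final_models
        if final.ehr_sda is not None:
            fh.write(json.dumps({"model": "sda_ehr",
                                 "pretrain": final.ehr_sda.pretrain_curves_,
                                 "finetune": final.ehr_sda.finetune_curve_}) + "\n")
        if final.snp_sda is not None:
            fh.write(json.dumps({"model": "sda_snp",
                                 "pretrain": final.snp_sda.pretrain_curves_,
                                 "finetune": final.snp_sda.finetune_curve_}) + "\n")
        if final.cnn is not None:
            fh.write(json.dumps({"model": "cnn3d", "history": final.cnn.history_}) + "\n")
    return out
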