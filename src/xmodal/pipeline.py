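"""Three-step experiment driver.

Step 1 — supervised single-modality models: the radiograph backbone stays
frozen (in latent mode the generator's feature vectors stand in for the
frozen-backbone output); the histology bag aggregator is trained with
focal loss; baseline diagnosis and grading heads are trained per fold on
the raw embeddings and fold-ensembled on the held-out test split.

Step 2 — cross-modal alignment per fold: modality embedders and projection
heads trained on same-patient pairs with the combined InfoNCE+focal
objective; projection heads are then discarded.

Step 3 — classification on enhanced embeddings: per-fold heads on the
enhanced radiograph set (diagnosis, grading), the enhanced histology set
(grading), and the concatenated (mid-level fused) set (grading), each
fold-ensembled on the test split, with paired DeLong comparisons of the
pre- vs post-alignment grading models.

All randomness derives from one base seed; identical config + seed yields
byte-identical persisted reports. The same split plan is used by every
step, and no test-split patient ever enters a training or early-stopping
computation (audited).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .alignment import (EmbeddingSet, enhance, retrieval_accuracy, train_alignment)
from .classifiers import HeadConfig, fuse, train_head
from .encoders import BagEncoder, ImageEncoder, train_bag_encoder
from .errors import ConfigError, DataError
from .evaluation import (FoldPlan, delong_test, ensemble_predict, evaluate,
                         reports_to_frame, stratified_split)
from .losses import AlignmentConfig, FocalParams
from .synthetic import CohortSpec, PatientRecord, generate_cohort, paired_subset

_CONFIG_KEYS = {"cohort", "focal", "align", "head", "n_folds", "fractions",
                "bag_encoder", "align_train", "seed", "out_dir"}


@dataclass
class RunConfig:
    """Fully serializable description of one experiment run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    focal: FocalParams = field(default_factory=FocalParams)
    align: AlignmentConfig = field(default_factory=AlignmentConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    n_folds: int = 5
    fractions: tuple = (0.64, 0.16, 0.20)
    #: bag-aggregator geometry; the 12-block/8-head configuration is the
    #: reference default, the 2/2 test profile keeps desk runs fast
    bag_encoder: dict = field(default_factory=lambda: {"n_blocks": 2, "n_heads": 2,
                                                       "max_epochs": 30})
    align_train: dict = field(default_factory=lambda: {"max_epochs": 200})
    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _CONFIG_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            for k in d["cohort"]:
                if k not in CohortSpec.__dataclass_fields__:
                    raise ConfigError(f"unknown cohort key: {k}")
            for tup in ("class_probs", "pairing_rule", "bag_size_range"):
                if tup in d["cohort"] and isinstance(d["cohort"][tup], list):
                    d["cohort"][tup] = tuple(d["cohort"][tup])
            d["cohort"] = CohortSpec(**d["cohort"])
        if "focal" in d and isinstance(d["focal"], dict):
            if d["focal"].get("class_weights") is not None:
                d["focal"]["class_weights"] = tuple(d["focal"]["class_weights"])
            d["focal"] = FocalParams(**d["focal"])
        if "align" in d and isinstance(d["align"], dict):
            d["align"] = AlignmentConfig(**d["align"])
        if "head" in d and isinstance(d["head"], dict):
            if "hidden" in d["head"]:
                d["head"]["hidden"] = tuple(d["head"]["hidden"])
            d["head"] = HeadConfig(**d["head"])
        if "fractions" in d:
            d["fractions"] = tuple(d["fractions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where results land is not part of the experiment
        return hashlib.sha256(json.dumps(d, sort_keys=True,
                                         default=str).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Step results
# ---------------------------------------------------------------------------

@dataclass
class Step1Result:
    cohort: list
    plan: FoldPlan
    rad_raw: EmbeddingSet
    hist_raw: EmbeddingSet
    bag_encoder: BagEncoder
    image_encoder: ImageEncoder | None
    diagnosis_labels: dict
    grade_labels: dict
    baseline_reports: dict      # model name -> {metric: EvalReport}
    baseline_test_probs: dict   # model name -> {pid: prob}
    backbone_checksums: dict


@dataclass
class Step2Result:
    embedders: dict             # fold -> (embedder_r, embedder_h)
    reports: dict               # fold -> AlignmentReport
    enhanced_rad: dict          # fold -> EmbeddingSet
    enhanced_hist: dict         # fold -> EmbeddingSet


@dataclass
class Step3Result:
    reports: dict               # model name -> {metric: EvalReport}
    test_probs: dict            # model name -> {pid: prob}
    comparisons: dict           # name -> DelongResult
    fused_coverage: int = 0
    test_retrieval: float | None = None


def _labels(cohort: list[PatientRecord]) -> tuple[dict, dict]:
    diag = {r.patient_id: 1 if r.diagnosis_label == "tumor" else 0 for r in cohort}
    grade = {r.patient_id: 1 if r.grade_label == "high" else 0
             for r in cohort if r.grade_label is not None}
    return diag, grade


def _task_subset(ids, labels) -> list:
    return [i for i in ids if i in labels]


def _cv_heads(embeddings: EmbeddingSet, labels: dict, task: str, plan: FoldPlan,
              cfg: RunConfig, seed_offset: int) -> tuple[list, dict]:
    """Train one head per fold; return (heads, ensembled test probabilities)."""
    heads = []
    for fold in range(1, plan.n_folds + 1):
        trg = _task_subset(plan.train_ids(fold), labels)
        vag = _task_subset(plan.val_ids(fold), labels)
        trg = [i for i in trg if i in embeddings.vectors]
        vag = [i for i in vag if i in embeddings.vectors]
        head, _ = train_head(embeddings, labels, task, trg, vag,
                             focal=cfg.focal, config=cfg.head,
                             seed=cfg.seed * 1000 + seed_offset + fold)
        heads.append(head)
    test = [i for i in _task_subset(plan.test_ids, labels) if i in embeddings.vectors]
    probs = ensemble_predict(heads, embeddings.subset(test))
    return heads, probs


# ---------------------------------------------------------------------------
# Steps
# ---------------------------------------------------------------------------

def run_step1(cfg: RunConfig) -> Step1Result:
    """Generate (or render) the cohort, split it, compute raw embeddings and
    baseline pre-alignment reports."""
    cohort = generate_cohort(cfg.cohort)
    diag, grade = _labels(cohort)
    plan = stratified_split(cohort, cfg.fractions, strat_var="class_name",
                            seed=cfg.seed + 1, n_folds=cfg.n_folds)
    for r in cohort:
        r.split = "test" if r.patient_id in set(plan.test_ids) else "cv"

    image_encoder = None
    if cfg.cohort.render_mode == "latent":
        rad_raw = EmbeddingSet("radiograph", "raw",
                               {r.patient_id: np.asarray(r.radiograph_view, dtype=float)
                                for r in cohort if r.radiograph_view is not None})
        extractor_id, latent_dim = "identity", cfg.cohort.latent_dim_histology
    else:
        image_encoder = ImageEncoder("tiny_cnn", seed=cfg.seed + 7, frozen=True)
        rad_raw = EmbeddingSet("radiograph", "raw",
                               {r.patient_id: image_encoder.encode(r.radiograph_view)
                                for r in cohort if r.radiograph_view is not None})
        extractor_id, latent_dim = "tiny_cnn", cfg.cohort.latent_dim_histology

    paired = paired_subset(cohort)
    bags = {r.patient_id: r.histology_bag for r in paired}
    bag_encoder = BagEncoder(extractor_id, seed=cfg.seed + 8,
                             n_blocks=cfg.bag_encoder.get("n_blocks", 12),
                             n_heads=cfg.bag_encoder.get("n_heads", 8),
                             patch_size=cfg.cohort.patch_size, latent_dim=latent_dim)
    checksums = {"image_encoder_pre": image_encoder.checksum() if image_encoder else None}
    tr1 = [i for i in plan.train_ids(1) if i in bags]
    va1 = [i for i in plan.val_ids(1) if i in bags]
    if len(tr1) >= 2 and len({grade[i] for i in tr1}) == 2:
        train_bag_encoder(bag_encoder, bags, grade, tr1, va1, focal=cfg.focal,
                          max_epochs=cfg.bag_encoder.get("max_epochs", 30),
                          patience=cfg.head.patience, batch_size=cfg.head.batch_size,
                          seed=cfg.seed + 9)
    hist_raw = EmbeddingSet("histology", "raw",
                            {i: bag_encoder.encode_bag(bags[i]) for i in sorted(bags)})
    checksums["image_encoder_post_step1"] = image_encoder.checksum() if image_encoder else None

    reports, test_probs = {}, {}
    _, p = _cv_heads(rad_raw, diag, "diagnosis", plan, cfg, 100)
    reports["diagnosis_radiograph_raw"] = evaluate(p, diag)
    test_probs["diagnosis_radiograph_raw"] = p
    _, p = _cv_heads(rad_raw, grade, "grading", plan, cfg, 200)
    reports["grading_radiograph_raw"] = evaluate(p, grade)
    test_probs["grading_radiograph_raw"] = p
    if len(set(hist_raw.vectors) & set(plan.test_ids)) >= 2:
        _, p = _cv_heads(hist_raw, grade, "grading", plan, cfg, 300)
        if len({grade[i] for i in p}) == 2:
            reports["grading_histology_raw"] = evaluate(p, grade)
            test_probs["grading_histology_raw"] = p
    return Step1Result(cohort, plan, rad_raw, hist_raw, bag_encoder, image_encoder,
                       diag, grade, reports, test_probs, checksums)


def run_step2(cfg: RunConfig, s1: Step1Result) -> Step2Result:
    """Per-fold contrastive alignment; enhanced sets with projections discarded."""
    embedders, reports, enh_r, enh_h = {}, {}, {}, {}
    for fold in range(1, s1.plan.n_folds + 1):
        er, eh, rep = train_alignment(
            s1.rad_raw, s1.hist_raw, s1.grade_labels, cfg=cfg.align, focal=cfg.focal,
            train_ids=s1.plan.train_ids(fold), val_ids=s1.plan.val_ids(fold),
            batch_size=cfg.head.batch_size, patience=cfg.head.patience,
            max_epochs=cfg.align_train.get("max_epochs", 200),
            seed=cfg.seed * 100 + fold)
        embedders[fold] = (er, eh)
        reports[fold] = rep
        enh_r[fold] = enhance(s1.rad_raw, er)
        enh_h[fold] = enhance(s1.hist_raw, eh)
    if s1.image_encoder is not None:
        s1.backbone_checksums["image_encoder_post_step2"] = s1.image_encoder.checksum()
    return Step2Result(embedders, reports, enh_r, enh_h)


def run_step3(cfg: RunConfig, s1: Step1Result, s2: Step2Result) -> Step3Result:
    """Heads on enhanced embeddings, fused model, and pre/post comparisons."""
    plan, diag, grade = s1.plan, s1.diagnosis_labels, s1.grade_labels
    reports, test_probs = {}, {}

    def cv_enhanced(sets_by_fold: dict, labels: dict, task: str, offset: int) -> dict:
        heads_probs = []
        test = None
        for fold in range(1, plan.n_folds + 1):
            emb = sets_by_fold[fold]
            trg = [i for i in _task_subset(plan.train_ids(fold), labels) if i in emb.vectors]
            vag = [i for i in _task_subset(plan.val_ids(fold), labels) if i in emb.vectors]
            head, _ = train_head(emb, labels, task, trg, vag, focal=cfg.focal,
                                 config=cfg.head, seed=cfg.seed * 1000 + offset + fold)
            t = [i for i in _task_subset(plan.test_ids, labels) if i in emb.vectors]
            test = t if test is None else test
            heads_probs.append(head.predict_proba(emb.subset(t)))
        return {i: float(np.mean([d[i] for d in heads_probs])) for i in test}

    p = cv_enhanced(s2.enhanced_rad, diag, "diagnosis", 400)
    reports["diagnosis_radiograph_enhanced"] = evaluate(p, diag)
    test_probs["diagnosis_radiograph_enhanced"] = p
    p = cv_enhanced(s2.enhanced_rad, grade, "grading", 500)
    reports["grading_radiograph_enhanced"] = evaluate(p, grade)
    test_probs["grading_radiograph_enhanced"] = p
    p_hist = None
    test_hist = [i for i in plan.test_ids if i in s1.hist_raw.vectors]
    if len(test_hist) >= 2 and len({grade[i] for i in test_hist}) == 2:
        p_hist = cv_enhanced(s2.enhanced_hist, grade, "grading", 600)
        reports["grading_histology_enhanced"] = evaluate(p_hist, grade)
        test_probs["grading_histology_enhanced"] = p_hist

    # fused (mid-level concatenation), per fold
    fused_by_fold, coverage = {}, 0
    for fold in range(1, plan.n_folds + 1):
        fused_set, _excluded = fuse(s2.enhanced_rad[fold], s2.enhanced_hist[fold])
        fused_by_fold[fold] = fused_set
        coverage = len(fused_set.vectors)
    test_fused = [i for i in plan.test_ids if i in fused_by_fold[1].vectors]
    p_fused = None
    if len(test_fused) >= 2 and len({grade[i] for i in test_fused}) == 2:
        p_fused = cv_enhanced(fused_by_fold, grade, "grading", 700)
        reports["grading_fused"] = evaluate(p_fused, grade)
        test_probs["grading_fused"] = p_fused

    comparisons = {}

    def paired_cmp(name: str, pre: dict | None, post: dict | None, labels: dict):
        if pre is None or post is None:
            return
        ids = sorted(set(pre) & set(post))
        y = [labels[i] for i in ids]
        if len(set(y)) < 2:
            return
        comparisons[name] = delong_test([post[i] for i in ids], y,
                                        scores_b=[pre[i] for i in ids])

    paired_cmp("grading_radiograph_pre_vs_post",
               s1.baseline_test_probs.get("grading_radiograph_raw"),
               test_probs.get("grading_radiograph_enhanced"), grade)
    paired_cmp("grading_histology_pre_vs_post",
               s1.baseline_test_probs.get("grading_histology_raw"),
               test_probs.get("grading_histology_enhanced"), grade)

    test_pairs = [i for i in plan.test_ids if i in s1.hist_raw.vectors]
    test_ret = None
    if len(test_pairs) >= 2:
        test_ret = float(np.mean([
            retrieval_accuracy(s2.enhanced_rad[f].subset(test_pairs),
                               s2.enhanced_hist[f].subset(test_pairs))
            for f in range(1, plan.n_folds + 1)]))
    if s1.image_encoder is not None:
        s1.backbone_checksums["image_encoder_post_step3"] = s1.image_encoder.checksum()
    return Step3Result(reports, test_probs, comparisons, coverage, test_ret)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def audit_no_leakage(plan: FoldPlan, s1: Step1Result, s3: Step3Result) -> None:
    """Test-split patients must never enter training; their predictions must
    exist for every evaluated model."""
    plan.audit()
    test = set(plan.test_ids)
    for fold in range(1, plan.n_folds + 1):
        if test & set(plan.train_ids(fold)) or test & set(plan.val_ids(fold)):
            raise DataError("leakage: test patient present in a CV fold")
    for name, probs in {**s1.baseline_test_probs, **s3.test_probs}.items():
        extra = set(probs) - test
        if extra:
            raise DataError(f"{name}: prediction for non-test patient {sorted(extra)[:3]}")


def run_experiment(cfg: RunConfig) -> dict:
    """Run steps 1-3, audit, and persist reports; returns the result bundle."""
    s1 = run_step1(cfg)
    s2 = run_step2(cfg, s1)
    s3 = run_step3(cfg, s1, s2)
    audit_no_leakage(s1.plan, s1, s3)
    checks = s1.backbone_checksums
    if checks.get("image_encoder_pre") is not None:
        frozen_ok = len({v for k, v in checks.items() if v is not None}) == 1
        if not frozen_ok:
            raise DataError("frozen radiograph backbone changed during training")
    bundle = {"config": cfg, "step1": s1, "step2": s2, "step3": s3}
    if cfg.out_dir:
        write_reports(cfg, bundle)
    return bundle


def summarize(bundle: dict) -> dict:
    """JSON-ready summary of an experiment bundle."""
    cfg: RunConfig = bundle["config"]
    s1, s2, s3 = bundle["step1"], bundle["step2"], bundle["step3"]
    named = {**s1.baseline_reports, **s3.reports}
    return {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_patients": len(s1.cohort),
        "n_paired": len(s1.hist_raw.vectors),
        "fused_coverage": s3.fused_coverage,
        "test_retrieval_accuracy": s3.test_retrieval,
        "models": {name: {m: r.to_dict() for m, r in reps.items()}
                   for name, reps in named.items()},
        "comparisons": {k: v.to_dict() for k, v in s3.comparisons.items()},
        "alignment": {f: r.to_dict() for f, r in s2.reports.items()},
        "backbone_checksums": s1.backbone_checksums,
    }


def write_reports(cfg: RunConfig, bundle: dict) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = summarize(bundle)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True,
                                                 default=float) + "\n")
    cfg_echo = cfg.to_dict()
    cfg_echo.pop("out_dir", None)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg_echo, sort_keys=True))
    s1, s2 = bundle["step1"], bundle["step2"]
    named = {**s1.baseline_reports, **bundle["step3"].reports}
    reports_to_frame(named).to_csv(out / "metrics.csv", index=False, float_format="%.6g")
    s1.plan.to_frame().to_csv(out / "splits.csv", index=False)
    s1.rad_raw.to_frame().to_csv(out / "radiograph_raw.csv", index=False,
                                 float_format="%.10g")
    s1.hist_raw.to_frame().to_csv(out / "histology_raw.csv", index=False,
                                  float_format="%.10g")
    s2.enhanced_rad[1].to_frame().to_csv(out / "radiograph_enhanced_fold1.csv",
                                         index=False, float_format="%.10g")
    s2.enhanced_hist[1].to_frame().to_csv(out / "histology_enhanced_fold1.csv",
                                          index=False, float_format="%.10g")
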