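"""Reference desk-scale experiments built on the pipeline.

The knowledge-transfer experiment probes the framework's central
mechanism: with histology carrying a stronger class signal than
radiographs, does a grading classifier on contrastively enhanced
radiograph embeddings match or beat the same classifier on raw radiograph
embeddings, and does cross-modal retrieval of the true patient beat
chance? Held-out performance is measured on an independently generated
evaluation cohort from the same specification (disjoint seed), which
estimates generalization far more precisely than the small internal test
split.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .alignment import EmbeddingSet, enhance, retrieval_accuracy, train_alignment
from .classifiers import HeadConfig, train_head
from .encoders import BagEncoder, train_bag_encoder
from .evaluation import auc, stratified_split
from .losses import AlignmentConfig, FocalParams
from .synthetic import CohortSpec, generate_cohort, paired_subset

#: study conditions of the transfer experiment
TRANSFER_SPEC = CohortSpec(n_patients=400, signal_strength_radiograph=0.5,
                           signal_strength_histology=1.5)


@dataclass
class TransferResult:
    seed: int
    auc_raw: float
    auc_enhanced: float
    retrieval: float
    retrieval_chance: float

    @property
    def transfer_win(self) -> bool:
        return self.auc_enhanced >= self.auc_raw

    @property
    def retrieval_win(self) -> bool:
        return self.retrieval > self.retrieval_chance


def knowledge_transfer_run(seed: int, spec: CohortSpec | None = None,
                           align: AlignmentConfig | None = None,
                           focal: FocalParams | None = None,
                           head: HeadConfig | None = None,
                           eval_n: int = 1000, n_folds: int = 5,
                           bag_epochs: int = 30, align_epochs: int = 200) -> TransferResult:
    """One seeded replicate of the knowledge-transfer experiment.

    Trains the full stack (bag aggregator, per-fold alignment, per-fold
    raw and enhanced grading heads) on a cohort generated at ``seed`` and
    evaluates the fold-ensembled heads on an independent cohort generated
    at a derived seed. Retrieval is measured on the evaluation cohort's
    paired subset, averaged over fold embedders.
    """
    spec = replace(spec or TRANSFER_SPEC, seed=seed)
    align = align or AlignmentConfig()
    focal = focal or FocalParams()
    head = head or HeadConfig()

    cohort = generate_cohort(spec)
    plan = stratified_split(cohort, strat_var="class_name", seed=seed + 1000,
                            n_folds=n_folds)
    rad_raw = EmbeddingSet("radiograph", "raw",
                           {r.patient_id: r.radiograph_view for r in cohort})
    bags = {r.patient_id: r.histology_bag for r in paired_subset(cohort)}
    grade = {r.patient_id: 1 if r.grade_label == "high" else 0
             for r in cohort if r.grade_label}

    be = BagEncoder("identity", n_blocks=2, n_heads=2, seed=seed,
                    latent_dim=spec.latent_dim_histology)
    tr1 = [i for i in plan.train_ids(1) if i in bags]
    va1 = [i for i in plan.val_ids(1) if i in bags]
    train_bag_encoder(be, bags, grade, tr1, va1, focal=focal,
                      max_epochs=bag_epochs, patience=head.patience,
                      batch_size=head.batch_size, seed=seed)
    hist_raw = EmbeddingSet("histology", "raw",
                            {i: be.encode_bag(bags[i]) for i in sorted(bags)})

    eval_spec = replace(spec, n_patients=eval_n, seed=seed + 5000)
    evc = generate_cohort(eval_spec)
    erad = EmbeddingSet("radiograph", "raw",
                        {"E" + r.patient_id: r.radiograph_view for r in evc})
    ebags = {"E" + r.patient_id: r.histology_bag for r in paired_subset(evc)}
    egrade = {"E" + r.patient_id: 1 if r.grade_label == "high" else 0
              for r in evc if r.grade_label}
    etum = sorted(egrade)
    ey = [egrade[i] for i in etum]
    epairs = sorted(ebags)
    ehist = EmbeddingSet("histology", "raw",
                         {i: be.encode_bag(ebags[i]) for i in epairs})

    raw_probs, enh_probs, rets = [], [], []
    for fold in range(1, n_folds + 1):
        tr, va = plan.train_ids(fold), plan.val_ids(fold)
        er, eh, _ = train_alignment(rad_raw, hist_raw, grade, cfg=align, focal=focal,
                                    train_ids=tr, val_ids=va,
                                    batch_size=head.batch_size, patience=head.patience,
                                    max_epochs=align_epochs, seed=seed * 10 + fold)
        enh_tr = enhance(rad_raw, er)
        enh_ev = enhance(erad, er)
        enh_hev = enhance(ehist, eh)
        trg = [i for i in tr if i in grade]
        vag = [i for i in va if i in grade]
        h_raw, _ = train_head(rad_raw, grade, "grading", trg, vag, focal=focal,
                              config=head, seed=seed * 10 + fold)
        h_enh, _ = train_head(enh_tr, grade, "grading", trg, vag, focal=focal,
                              config=head, seed=seed * 10 + fold)
        raw_probs.append(h_raw.predict_proba(erad.subset(etum)))
        enh_probs.append(h_enh.predict_proba(enh_ev.subset(etum)))
        rets.append(retrieval_accuracy(enh_ev.subset(epairs), enh_hev.subset(epairs)))

    mean = lambda ds: [float(np.mean([d[i] for d in ds])) for i in etum]
    return TransferResult(seed=seed,
                          auc_raw=auc(mean(raw_probs), ey),
                          auc_enhanced=auc(mean(enh_probs), ey),
                          retrieval=float(np.mean(rets)),
                          retrieval_chance=1.0 / len(epairs))


def knowledge_transfer_study(base_seed: int, n_seeds: int = 5, **kwargs) -> list[TransferResult]:
    """n_seeds seeded replicates with seeds derived from base_seed."""
    return [knowledge_transfer_run(base_seed + k, **kwargs) for k in range(1, n_seeds + 1)]
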