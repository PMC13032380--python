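"""Synthetic paired-cohort generator.

Emulates the statistical skeleton of a two-modality bone-lesion cohort:
each patient has a latent diagnosis class (high-grade chondroid tumor,
low-grade chondroid tumor, or a radiographic mimic such as avascular
necrosis / fibrous dysplasia), a radiograph view, and — for chondroid
tumor patients only — a bag of histology patches. The two views share the
latent class but differ in informativeness: by default histology carries
the stronger class signal, which is the regime in which cross-modal
knowledge transfer is measurable.

Class counts follow a deterministic largest-remainder apportionment of
the class probability vector, so fixture counts are exact: the default
188-patient cohort has 13 high-grade, 68 low-grade, and 107 mimic
patients.

Two render modes:

``latent``
    Views are Gaussian feature vectors ``z = mu_class * s + noise`` whose
    class-mean structure lives on dedicated axes: a diagnosis axis, a
    grade-severity axis, and a shared non-diagnostic morphology axis. The
    severity and morphology coordinates are continuous per-patient traits
    drawn once and seen by BOTH views (the same lesion drives both
    images), so same-patient pairs carry structure beyond the class label
    — the substrate cross-modal alignment can transfer. Fast; used for
    unit tests and the desk-scale experiments.
``raster``
    Views are rendered images carrying the same latent class: a grayscale
    lesion ellipse whose margin roughness and contrast depend on class for
    the radiograph arm, and RGB spot textures whose density and size
    variance depend on grade for histology patches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError

CLASSES = ("chondroid_high", "chondroid_low", "mimic")

#: Table-style default composition: 13 high-grade, 68 low-grade, 107 mimics of 188.
DEFAULT_CLASS_PROBS = (13 / 188, 68 / 188, 107 / 188)


def largest_remainder(probs: np.ndarray, n: int) -> np.ndarray:
    """Apportion n items to classes by largest remainder (deterministic).

    Ties in the fractional remainders are broken by class order.
    """
    probs = np.asarray(probs, dtype=float)
    quotas = probs * n
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    # stable sort => earlier classes win exact ties
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    return counts


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic paired cohort.

    signal_strength_* are standardized mean shifts: the class-mean
    directions have unit norm per active axis and are scaled by the signal
    strength, against per-feature Gaussian noise of sd ``noise_sd``.
    """

    n_patients: int = 188
    class_probs: tuple = DEFAULT_CLASS_PROBS
    pairing_rule: tuple = ("chondroid_high", "chondroid_low")
    signal_strength_radiograph: float = 0.5
    signal_strength_histology: float = 1.5
    noise_sd: float = 1.0
    #: within-class spread of the continuous per-patient severity shared by
    #: both views (the same tumor drives both images); 0 collapses severity
    #: to the binary grade.
    within_class_spread: float = 0.5
    #: loading of a non-diagnostic per-patient morphology axis shared by
    #: both views (same anatomy/texture seen twice); gives same-patient
    #: pairs structure beyond the class label.
    shared_axis_weight: float = 1.0
    #: optional modality-private nuisance factors: low-rank variation
    #: private to each view (positioning/exposure artifacts on radiographs,
    #: staining variation on histology), carrying no diagnostic signal.
    #: Off by default: latent mode emulates embeddings of preprocessed
    #: images, and the preprocessing stage (intensity standardization,
    #: stain normalization) exists to remove exactly this variation.
    n_nuisance_factors: int = 0
    nuisance_strength: float = 2.0
    bag_size_range: tuple = (4, 12)
    render_mode: str = "latent"
    seed: int = 0
    #: radiograph latent width emulates a pooled CNN-backbone feature vector
    #: (high-dimensional, class signal diffuse); histology patch latents are
    #: compact, mirroring the asymmetry of backbone output sizes.
    latent_dim_radiograph: int = 64
    latent_dim_histology: int = 16
    radiograph_size: int = 64
    patch_size: int = 32

    def validate(self) -> None:
        probs = np.asarray(self.class_probs, dtype=float)
        if probs.shape != (len(CLASSES),):
            raise ConfigError(f"class_probs must have {len(CLASSES)} entries")
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigError("class_probs must be nonnegative and sum to 1 within 1e-9")
        n_active = int((probs > 0).sum())
        if self.n_patients < n_active:
            raise ConfigError(
                f"n_patients={self.n_patients} smaller than the {n_active} classes "
                "with nonzero probability")
        if self.render_mode not in ("latent", "raster"):
            raise ConfigError(f"unknown render_mode {self.render_mode!r}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        lo, hi = self.bag_size_range
        if not (1 <= lo <= hi):
            raise ConfigError("bag_size_range must satisfy 1 <= lo <= hi")
        if min(self.latent_dim_radiograph, self.latent_dim_histology) < 3:
            raise ConfigError("latent dims must be >= 3 (diagnosis, grade, morphology axes)")
        for c in self.pairing_rule:
            if c not in CLASSES:
                raise ConfigError(f"unknown class {c!r} in pairing_rule")

    def class_counts(self) -> dict[str, int]:
        self.validate()
        counts = largest_remainder(np.asarray(self.class_probs), self.n_patients)
        return dict(zip(CLASSES, (int(c) for c in counts)))


@dataclass
class PatientRecord:
    """One subject: labels plus the available views."""

    patient_id: str
    class_name: str
    diagnosis_label: str            # "tumor" | "mimic"
    grade_label: str | None         # "high" | "low" | None (mimics)
    radiograph_view: np.ndarray | None = None
    histology_bag: list | None = None
    split: str = "unassigned"

    @property
    def has_both_views(self) -> bool:
        return self.radiograph_view is not None and self.histology_bag is not None


_DIAG_COORD = {"mimic": -1.0, "chondroid_low": 1.0, "chondroid_high": 1.0}
_GRADE_COORD = {"mimic": 0.0, "chondroid_low": -1.0, "chondroid_high": 1.0}


def _latent_view(class_name: str, severity: float, morphology: float,
                 signal: float, spec: "CohortSpec", dim: int,
                 rng: np.random.Generator) -> np.ndarray:
    """One view's latent vector.

    Axis 0 carries the diagnosis signal (tumor +1 vs mimic -1), axis 1 the
    continuous grade severity, axis 2 the shared non-diagnostic morphology
    axis; remaining axes are noise. ``severity`` and ``morphology`` are
    per-patient values shared by both views, so same-patient pairs are
    linked beyond their class label.
    """
    z = spec.noise_sd * rng.standard_normal(dim)
    z[0] += signal * _DIAG_COORD[class_name]
    z[1] += signal * severity
    z[2] += spec.shared_axis_weight * morphology
    return z


# --------------------------------------------------------------------------
# Raster rendering
# --------------------------------------------------------------------------

_ROUGHNESS = {"mimic": 0.02, "chondroid_low": 0.12, "chondroid_high": 0.30}
_SPOT_COUNT = {"chondroid_low": 10, "chondroid_high": 22, "mimic": 10}
_SPOT_R_SD = {"chondroid_low": 0.3, "chondroid_high": 1.4, "mimic": 0.3}


def render_radiograph(class_name: str, rng: np.random.Generator, size: int = 64,
                      signal: float = 1.0, noise_sd: float = 1.0) -> np.ndarray:
    """Grayscale lesion raster: ellipse with class-dependent margin roughness.

    Tumors are brighter than mimics and high-grade margins are rougher;
    the class-vs-noise contrast scales with ``signal``/``noise_sd``.
    """
    img = 0.25 + 0.08 * rng.standard_normal((size, size))
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    theta = np.arctan2(yy - cy, xx - cx)
    r = np.hypot(yy - cy, xx - cx)
    base_r = size * 0.28
    rough = _ROUGHNESS[class_name] * min(signal, 2.0)
    # low-order angular harmonics produce a lobulated margin
    phases = rng.uniform(0, 2 * np.pi, size=3)
    margin = base_r * (1.0 + rough * (np.sin(3 * theta + phases[0])
                                      + 0.6 * np.sin(5 * theta + phases[1])
                                      + 0.4 * np.sin(7 * theta + phases[2])))
    lesion = r <= margin
    contrast = (0.5 if class_name != "mimic" else 0.2) * min(signal, 2.0) / max(noise_sd, 1e-6)
    img[lesion] += min(contrast, 0.6)
    img += 0.05 * noise_sd * rng.standard_normal((size, size))
    return np.clip(img, 0.0, 1.0)


def render_patch(class_name: str, rng: np.random.Generator, size: int = 32,
                 signal: float = 1.0) -> np.ndarray:
    """RGB histology-like patch: hematoxylin-ish spots on an eosin-ish field.

    Spot density and spot-size variance increase with grade; the strength
    of that dependence scales with ``signal``.
    """
    w = min(signal, 2.0) / 2.0
    n_spots = int(round((1 - w) * 10 + w * _SPOT_COUNT[class_name]))
    r_sd = (1 - w) * 0.3 + w * _SPOT_R_SD[class_name]
    img = np.ones((size, size, 3))
    img[..., 0] *= 0.92
    img[..., 1] *= 0.78
    img[..., 2] *= 0.85
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(n_spots):
        cy, cx = rng.uniform(2, size - 2, size=2)
        radius = max(0.8, rng.normal(2.0, r_sd))
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
        img[mask] = (0.35, 0.2, 0.5)
    img += 0.03 * rng.standard_normal(img.shape)
    return np.clip(img, 0.0, 1.0)


def render_slide(class_name: str, rng: np.random.Generator, size: int = 512,
                 patch_size: int = 32, tissue_margin: int = 96,
                 signal: float = 1.0) -> np.ndarray:
    """Synthetic whole-slide raster: white background with a central tissue block.

    Used to exercise tissue masking and tiling; the tissue block is tiled
    from :func:`render_patch` textures of the given class.
    """
    slide = np.ones((size, size, 3))
    lo, hi = tissue_margin, size - tissue_margin
    for y in range(lo, hi, patch_size):
        for x in range(lo, hi, patch_size):
            ph = min(patch_size, hi - y)
            pw = min(patch_size, hi - x)
            slide[y:y + ph, x:x + pw] = render_patch(class_name, rng, patch_size, signal)[:ph, :pw]
    return slide


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Generate the cohort described by ``spec``; deterministic in (spec, seed)."""
    spec.validate()
    counts = spec.class_counts()
    rng = np.random.default_rng(spec.seed)

    labels = [c for c in CLASSES for _ in range(counts[c])]
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]

    width = max(4, len(str(spec.n_patients)))
    # fixed nuisance loading matrices, one per modality (drawn once per
    # cohort): columns are random directions scaled by nuisance_strength
    k = spec.n_nuisance_factors
    def loadings(dim: int) -> np.ndarray:
        b = rng.standard_normal((dim, k)) if k else np.zeros((dim, 0))
        if k:
            b /= np.linalg.norm(b, axis=0, keepdims=True)
        return spec.nuisance_strength * b
    b_rad = loadings(spec.latent_dim_radiograph)
    b_hist = loadings(spec.latent_dim_histology)
    records: list[PatientRecord] = []
    for i, class_name in enumerate(labels):
        pid = f"P{i:0{width}d}"
        diagnosis = "mimic" if class_name == "mimic" else "tumor"
        grade = None if diagnosis == "mimic" else ("high" if class_name == "chondroid_high" else "low")
        paired = class_name in spec.pairing_rule

        # per-patient traits shared across views: continuous severity around
        # the grade coordinate, plus a non-diagnostic morphology trait
        severity = _GRADE_COORD[class_name] + spec.within_class_spread * rng.standard_normal()
        morphology = rng.standard_normal()

        if spec.render_mode == "latent":
            rad = _latent_view(class_name, severity, morphology,
                               spec.signal_strength_radiograph, spec,
                               spec.latent_dim_radiograph, rng)
            rad += b_rad @ rng.standard_normal(k) if k else 0.0
            bag = None
            if paired:
                core = _latent_view(class_name, severity, morphology,
                                    spec.signal_strength_histology, spec,
                                    spec.latent_dim_histology, rng)
                core += b_hist @ rng.standard_normal(k) if k else 0.0
                n_patches = int(rng.integers(spec.bag_size_range[0], spec.bag_size_range[1] + 1))
                bag = [core + 0.5 * spec.noise_sd * rng.standard_normal(spec.latent_dim_histology)
                       for _ in range(n_patches)]
        else:
            rad = render_radiograph(class_name, rng, spec.radiograph_size,
                                    spec.signal_strength_radiograph, spec.noise_sd)
            bag = None
            if paired:
                n_patches = int(rng.integers(spec.bag_size_range[0], spec.bag_size_range[1] + 1))
                bag = [render_patch(class_name, rng, spec.patch_size,
                                    spec.signal_strength_histology)
                       for _ in range(n_patches)]

        records.append(PatientRecord(patient_id=pid, class_name=class_name,
                                     diagnosis_label=diagnosis, grade_label=grade,
                                     radiograph_view=rad, histology_bag=bag))
    return records


def paired_subset(cohort: list[PatientRecord]) -> list[PatientRecord]:
    """Records carrying both views, in stable patient_id order."""
    return sorted((r for r in cohort if r.has_both_views), key=lambda r: r.patient_id)


def cohort_summary(cohort: list[PatientRecord]) -> dict:
    """Headline composition numbers, percentages rounded as printed in reports."""
    n = len(cohort)
    n_tumor = sum(r.diagnosis_label == "tumor" for r in cohort)
    n_high = sum(r.grade_label == "high" for r in cohort)
    n_low = sum(r.grade_label == "low" for r in cohort)
    n_mimic = n - n_tumor
    return {
        "n_patients": n,
        "n_tumor": n_tumor,
        "n_high": n_high,
        "n_low": n_low,
        "n_mimic": n_mimic,
        "n_paired": sum(r.has_both_views for r in cohort),
        "pct_tumor": int(round(100.0 * n_tumor / n)) if n else 0,
        "pct_high_of_tumor": int(round(100.0 * n_high / n_tumor)) if n_tumor else 0,
    }


# --------------------------------------------------------------------------
# Disk round-trip
# --------------------------------------------------------------------------

def write_cohort(cohort: list[PatientRecord], out_dir, render_mode: str) -> None:
    """Persist a cohort as a directory tree plus a manifest CSV.

    Raster cohorts write one PNG per radiograph and a PNG directory per
    histology bag; latent cohorts write the feature vectors as CSV tables.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    if render_mode == "raster":
        from PIL import Image

        (out / "radiographs").mkdir(exist_ok=True)
        (out / "histology").mkdir(exist_ok=True)
        for r in cohort:
            rad_path = ""
            bag_path = ""
            if r.radiograph_view is not None:
                rad_path = f"radiographs/{r.patient_id}.png"
                arr = np.clip(r.radiograph_view * 255, 0, 255).astype(np.uint8)
                Image.fromarray(arr, mode="L").save(out / rad_path)
            if r.histology_bag is not None:
                bag_path = f"histology/{r.patient_id}"
                (out / bag_path).mkdir(exist_ok=True)
                for j, patch in enumerate(r.histology_bag):
                    arr = np.clip(patch * 255, 0, 255).astype(np.uint8)
                    Image.fromarray(arr, mode="RGB").save(out / bag_path / f"patch_{j:03d}.png")
            rows.append((r.patient_id, r.diagnosis_label, r.grade_label or "",
                         rad_path, bag_path, r.split))
    else:
        rad_rows, patch_rows = [], []
        for r in cohort:
            if r.radiograph_view is not None:
                rad_rows.append([r.patient_id] + list(r.radiograph_view))
            if r.histology_bag is not None:
                for j, p in enumerate(r.histology_bag):
                    patch_rows.append([r.patient_id, j] + list(p))
            rows.append((r.patient_id, r.diagnosis_label, r.grade_label or "",
                         "radiograph_latents.csv", "histology_patch_latents.csv", r.split))
        rad_dim = len(rad_rows[0]) - 1 if rad_rows else 0
        cols = ["patient_id"] + [f"f{i}" for i in range(rad_dim)]
        pd.DataFrame(rad_rows, columns=cols).to_csv(out / "radiograph_latents.csv", index=False)
        patch_dim = len(patch_rows[0]) - 2 if patch_rows else 0
        pcols = ["patient_id", "patch_idx"] + [f"f{i}" for i in range(patch_dim)]
        pd.DataFrame(patch_rows, columns=pcols).to_csv(out / "histology_patch_latents.csv",
                                                       index=False)
    manifest = pd.DataFrame(rows, columns=["patient_id", "diagnosis_label", "grade_label",
                                           "radiograph_path", "histology_path", "split"])
    manifest.to_csv(out / "manifest.csv", index=False)
    (out / "summary.json").write_text(json.dumps(cohort_summary(cohort), indent=2,
                                                 sort_keys=True) + "\n")


def table1_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The default 188-patient fixture spec (13 high / 68 low / 107 mimic)."""
    return replace(CohortSpec(seed=seed), **overrides)
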