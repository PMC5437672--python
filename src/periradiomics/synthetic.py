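"""Synthetic DCE-MRI phantoms, cohorts, and planted-effect feature tables.

The undeposited patient cohort is replaced by deterministic digital
phantoms: an ellipsoidal tumor in a uniform background, enhancing according
to class-specific Tofts kinetics, with the class-linked texture contrasts
reported for responders and non-responders planted explicitly:

* peritumoral speckle — high-frequency multiplicative noise in the ring
  (non-pCR phantoms carry larger amplitude), driving Laws spot/ripple
  responses and ring intensity SD;
* gradient disorder — the spatial pattern of enhancement is a mix of an
  ordered radial ramp and a smooth random field, mixed by a disorder
  parameter in [0, 1] (non-pCR phantoms are more disordered), driving
  CoLlAGe orientation-entropy contrasts;
* enhancement heterogeneity — the amplitude of that spatial modulation of
  the voxel-wise transfer constant.

All randomness flows through a single per-phantom seed; identical
configurations produce bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import DceSeries
from .features import FeatureTable
from .tofts import tofts_forward_biexp

#: Acquisition times (minutes post-injection): precontrast then five
#: postcontrast phases at 90-second intervals starting 2 minutes in.
DEFAULT_PHASE_TIMES_MIN = (0.0, 2.0, 3.5, 5.0, 6.5, 8.0)

#: Class-mean Tofts kinetics (proxy units/min) and texture effects.  When a
#: phantom's texture_effect / kinetics are left unset, per-patient values
#: are drawn around these means with the SDs below, so the two classes
#: overlap the way real responder cohorts do (kinetics overlap strongly —
#: PK parameters are weak response discriminators — while the planted
#: texture contrasts separate only partially).
CLASS_KINETICS = {"pCR": (0.30, 0.65), "non_pCR": (0.40, 0.85)}
KINETICS_PATIENT_SD = (0.10, 0.20)  # (ktrans, kep)
CLASS_TEXTURE_EFFECTS = {
    "pCR": dict(peritumoral_speckle_amplitude=0.05, gradient_disorder=0.2, enhancement_heterogeneity=0.25),
    "non_pCR": dict(peritumoral_speckle_amplitude=0.25, gradient_disorder=0.8, enhancement_heterogeneity=0.45),
}
TEXTURE_EFFECT_PATIENT_SD = dict(
    peritumoral_speckle_amplitude=0.10, gradient_disorder=0.30, enhancement_heterogeneity=0.15
)

TUMOR_BASELINE = 300.0
BACKGROUND_BASELINE = 200.0
RING_ENHANCEMENT_FRACTION = 0.3


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class TextureEffect:
    """Planted class-linked texture contrast magnitudes."""

    peritumoral_speckle_amplitude: float = 0.0
    gradient_disorder: float = 0.0
    enhancement_heterogeneity: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gradient_disorder <= 1.0:
            raise ValueError("gradient_disorder must be in [0, 1]")
        if self.enhancement_heterogeneity < 0:
            raise ValueError("enhancement_heterogeneity must be >= 0")


@dataclass(frozen=True)
class PhantomConfig:
    seed: int = 0
    grid_shape: tuple[int, int, int] = (5, 48, 48)
    pixel_spacing_mm: tuple[float, float] = (0.75, 0.75)
    slice_thickness_mm: float = 1.5
    phase_times_min: tuple[float, ...] = DEFAULT_PHASE_TIMES_MIN
    tumor_radius_mm: float = 6.0
    class_label: str = "pCR"
    texture_effect: TextureEffect | None = None  # None -> class distribution
    kinetics: tuple[float, float] | None = None  # (ktrans, kep); None -> class distribution
    noise_sd: float = 2.0
    lobulation: float = 0.0

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.phase_times_min)
        if len(times) < 2 or np.any(np.diff(times) <= 0):
            raise ValueError("phase times must be strictly increasing (precontrast first)")
        if self.class_label not in CLASS_KINETICS:
            raise ValueError(f"unknown class label {self.class_label!r}")

    def resolved_effect(self, jitter=(0.0, 0.0, 0.0)) -> TextureEffect:
        if self.texture_effect is not None:
            return self.texture_effect
        means = CLASS_TEXTURE_EFFECTS[self.class_label]
        sds = TEXTURE_EFFECT_PATIENT_SD
        return TextureEffect(
            peritumoral_speckle_amplitude=max(
                0.0,
                means["peritumoral_speckle_amplitude"]
                + sds["peritumoral_speckle_amplitude"] * jitter[0],
            ),
            gradient_disorder=float(
                np.clip(means["gradient_disorder"] + sds["gradient_disorder"] * jitter[1], 0.0, 1.0)
            ),
            enhancement_heterogeneity=max(
                0.0,
                means["enhancement_heterogeneity"]
                + sds["enhancement_heterogeneity"] * jitter[2],
            ),
        )

    def resolved_kinetics(self, jitter=(0.0, 0.0)) -> tuple[float, float]:
        if self.kinetics is not None:
            return self.kinetics
        kt, ke = CLASS_KINETICS[self.class_label]
        kt = max(0.05, kt + KINETICS_PATIENT_SD[0] * jitter[0])
        ke = max(0.10, ke + KINETICS_PATIENT_SD[1] * jitter[1])
        return kt, ke


@dataclass(frozen=True)
class CohortSpec:
    n_pcr: int = 24
    n_non_pcr: int = 54
    group: str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pcr < 0 or self.n_non_pcr < 0:
            raise ValueError("cohort counts must be >= 0")


@dataclass
class PhantomPatient:
    patient_id: str
    series: DceSeries
    tumor_mask: np.ndarray
    label: str
    group: str


def _smooth_standardized_field(rng: np.random.Generator, shape, mask, sigma=1.5) -> np.ndarray:
    """Gaussian-smoothed noise field standardized over ``mask`` voxels."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma)
    sel = smooth[mask]
    sd = sel.std()
    if sd == 0:
        return np.zeros(shape)
    return (smooth - sel.mean()) / sd


def generate_phantom(config: PhantomConfig) -> tuple[DceSeries, np.ndarray]:
    """Deterministic phantom series and tumor mask for one patient.

    Tumor voxels follow S(t) = S0 (1 + C_t(t)) with voxel-wise transfer
    constants modulated by the planted spatial pattern; ring-adjacent tissue
    enhances at a fixed fraction of the tumor kinetics and carries the
    multiplicative speckle field.  With all texture effects and noise at
    zero every tumor voxel is identical within a phase.
    """
    nz, ny, nx = config.grid_shape
    ry = config.tumor_radius_mm / config.pixel_spacing_mm[0]
    rx = config.tumor_radius_mm / config.pixel_spacing_mm[1]
    rz = max(config.tumor_radius_mm / config.slice_thickness_mm / 2.0, 1.0)
    if 2 * ry >= ny or 2 * rx >= nx or 2 * rz >= nz:
        raise GeometryError("tumor does not fit inside the grid")

    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(float)
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    phi = np.arctan2(yy - cy, xx - cx)
    lob = 1.0 + config.lobulation * np.cos(3.0 * phi)
    r2 = (
        ((zz - cz) / rz) ** 2
        + ((yy - cy) / (ry * lob)) ** 2
        + ((xx - cx) / (rx * lob)) ** 2
    )
    tumor = r2 <= 1.0
    if not tumor.any():
        raise GeometryError("tumor mask is empty at this geometry")

    # ring used only for planting the speckle field; the analysis pipeline
    # re-derives it with region_geometry at extraction time
    from .regions import peritumoral_ring

    ring = peritumoral_ring(tumor, config.pixel_spacing_mm).peritumoral_mask

    rng = np.random.default_rng(config.seed)
    # fixed draw order so fields are comparable across configs at one seed
    effect_jitter = rng.standard_normal(3)
    kinetics_jitter = rng.standard_normal(2)
    disorder_field = _smooth_standardized_field(rng, config.grid_shape, tumor)
    speckle_noise = rng.standard_normal(config.grid_shape)
    acq_noise = rng.standard_normal((len(config.phase_times_min),) + config.grid_shape)

    effect = config.resolved_effect(effect_jitter)
    ktrans0, kep = config.resolved_kinetics(kinetics_jitter)

    # ordered radial ramp (standardized over tumor voxels) vs random field
    radial = -np.sqrt(r2)
    sel = radial[tumor]
    radial = (radial - sel.mean()) / (sel.std() if sel.std() > 0 else 1.0)
    mix = (1.0 - effect.gradient_disorder) * radial + effect.gradient_disorder * disorder_field
    ktrans_map = ktrans0 * np.clip(1.0 + effect.enhancement_heterogeneity * mix, 0.1, None)

    times = np.asarray(config.phase_times_min)
    post = times[1:]
    basis = np.atleast_2d(tofts_forward_biexp(1.0, kep, post))  # (1, n_post)

    data = np.full((len(times), nz, ny, nx), BACKGROUND_BASELINE)
    # tumor enhancement
    ct_tumor = ktrans_map[tumor][:, None] * basis  # (n_tumor, n_post)
    data[0][tumor] = TUMOR_BASELINE
    for p in range(1, len(times)):
        vol = data[p]
        vol[tumor] = TUMOR_BASELINE * (1.0 + ct_tumor[:, p - 1])
    # ring enhancement + multiplicative speckle on all phases
    ct_ring = RING_ENHANCEMENT_FRACTION * ktrans0 * basis[0]  # (n_post,)
    # multiplicative speckle floored at 5% signal: intensity stays physical
    speckle = np.clip(1.0 + effect.peritumoral_speckle_amplitude * speckle_noise, 0.05, None)
    for p in range(len(times)):
        vol = data[p]
        enh = ct_ring[p - 1] if p >= 1 else 0.0
        vol[ring] = BACKGROUND_BASELINE * (1.0 + enh) * speckle[ring]
    if config.noise_sd > 0:
        data = data + config.noise_sd * acq_noise

    series = DceSeries(
        data=data,
        phase_times_min=times,
        pixel_spacing_mm=config.pixel_spacing_mm,
        slice_thickness_mm=config.slice_thickness_mm,
    )
    return series, tumor


def generate_cohort(
    spec: CohortSpec, phantom_defaults: PhantomConfig | None = None
) -> list[PhantomPatient]:
    """A list of phantom patients with per-patient seeds spec.seed + i.

    pCR patients come first, then non-pCR; labels and receptor group are
    attached to each record.
    """
    defaults = phantom_defaults or PhantomConfig()
    patients: list[PhantomPatient] = []
    labels = ["pCR"] * spec.n_pcr + ["non_pCR"] * spec.n_non_pcr
    for i, label in enumerate(labels):
        cfg = replace(defaults, seed=spec.seed + i, class_label=label)
        series, tumor = generate_phantom(cfg)
        patients.append(
            PhantomPatient(
                patient_id=f"{spec.group}-{i:03d}",
                series=series,
                tumor_mask=tumor,
                label=label,
                group=spec.group,
            )
        )
    return patients


def generate_feature_table(
    n_samples: int,
    n_features: int,
    n_informative: int,
    effect_size: float,
    seed: int,
    positive_fraction: float = 0.5,
) -> tuple[FeatureTable, np.ndarray]:
    """Gaussian feature table with planted class differences.

    Informative columns differ between classes by ``effect_size`` standard
    deviations; the rest are pure noise.  Ground-truth informative column
    indices are recorded in ``table.attrs["informative_indices"]``.  Labels
    are 1 for the positive (pCR) class.
    """
    if n_informative > n_features:
        raise ValueError("n_informative must be <= n_features")
    rng = np.random.default_rng(seed)
    n_pos = int(round(n_samples * positive_fraction))
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_samples - n_pos, dtype=int)])
    X = rng.standard_normal((n_samples, n_features))
    informative = rng.choice(n_features, size=n_informative, replace=False)
    if n_informative:
        X[np.ix_(labels == 1, informative)] += effect_size
    cols = [f"feat_{j:04d}" for j in range(n_features)]
    df = pd.DataFrame(X, columns=cols, index=[f"s{i:04d}" for i in range(n_samples)])
    table = FeatureTable(df, labels=labels, attrs={"informative_indices": sorted(int(j) for j in informative)})
    return table, labels


def generate_patterned_groups(
    n_per_group: int,
    n_features: int,
    effect_size: float,
    seed: int,
    noise_sd: float = 1.0,
) -> tuple[FeatureTable, np.ndarray]:
    """Two groups with opposite feature *patterns* (for clustering tests).

    Group 1 has mean ``+effect_size * s_j`` on feature j and group 0 the
    negated pattern, with signs ``s_j`` alternating across features.  Unlike
    a uniform shift, a sign-alternating pattern survives the per-patient
    centering implied by the Pearson correlation distance, which is what
    separates enhancement *profiles* rather than overall intensity levels.
    """
    rng = np.random.default_rng(seed)
    signs = np.where(np.arange(n_features) % 2 == 0, 1.0, -1.0)
    labels = np.concatenate([np.ones(n_per_group, dtype=int), np.zeros(n_per_group, dtype=int)])
    means = np.where(labels[:, None] == 1, 1.0, -1.0) * effect_size * signs[None, :]
    X = means + noise_sd * rng.standard_normal((2 * n_per_group, n_features))
    df = pd.DataFrame(
        X,
        columns=[f"feat_{j:04d}" for j in range(n_features)],
        index=[f"s{i:04d}" for i in range(2 * n_per_group)],
    )
    return FeatureTable(df, labels=labels), labels


def write_cohort(
    patients: list[PhantomPatient], out_dir: str | Path, manifest_name: str = "manifest.csv"
) -> Path:
    """Write phantoms + masks as NIfTI and a CSV manifest; returns its path."""
    from .core import save_mask_nifti, save_series_nifti

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in patients:
        series_path = out / f"{p.patient_id}_series.nii.gz"
        mask_path = out / f"{p.patient_id}_mask.nii.gz"
        save_series_nifti(p.series, series_path)
        save_mask_nifti(
            p.tumor_mask, mask_path, p.series.pixel_spacing_mm, p.series.slice_thickness_mm
        )
        rows.append(
            {
                "patient_id": p.patient_id,
                "label": p.label,
                "group": p.group,
                "series_path": series_path.name,
                "mask_path": mask_path.name,
                "phase_times_min": ";".join(str(t) for t in p.series.phase_times_min),
                "pixel_spacing_mm": ";".join(str(s) for s in p.series.pixel_spacing_mm),
            }
        )
    manifest = out / manifest_name
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
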