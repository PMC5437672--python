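"""Per-patient feature aggregation and the radiomic feature table.

Each of the 99 texture descriptor maps is summarized by five first-order
statistics (mean, median, SD, skewness, kurtosis) over each region
(intratumoral, peritumoral) at each of two phases (initial = first
postcontrast, peak = postcontrast phase of maximal mean tumor enhancement):
99 x 5 = 495 statistical features per region-phase, 990 per region, and
1980 radiomic features per scan.  The three Tofts parameter maps add
3 x 5 = 15 PK statistical features computed over the intratumoral region.
Feature values are normalized column-wise to [-1, 1] against a reference
(training) table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import textures
from .regions import RegionPair

STATISTICS = ("mean", "median", "SD", "skewness", "kurtosis")
REGIONS = ("intratumoral", "peritumoral")
PHASES = ("initial", "peak")
PK_PARAMETERS = ("ktrans", "kep", "ve")

FAMILIES = ("Laws", "Gabor", "Haralick", "CoLlAGe", "PK")


@dataclass(frozen=True)
class FeatureId:
    """Identity of one feature-table column."""

    family: str
    descriptor: str
    region: str
    phase: str  # "initial" / "peak"; "all" for phase-pooled PK features
    statistic: str

    @property
    def name(self) -> str:
        return "|".join((self.family, self.descriptor, self.region, self.phase, self.statistic))

    @classmethod
    def from_name(cls, name: str) -> "FeatureId":
        parts = name.split("|")
        if len(parts) != 5:
            raise ValueError(f"not a feature id: {name!r}")
        return cls(*parts)


def radiomic_feature_ids(thetas=textures.GABOR_THETAS_UNIFORM) -> list[FeatureId]:
    """The 1980 radiomic column ids in canonical order:
    region-major, then phase, then descriptor (bank order), then statistic."""
    descriptors = textures.descriptor_names(thetas)
    out = []
    for region in REGIONS:
        for phase in PHASES:
            for family, descriptor in descriptors:
                for stat in STATISTICS:
                    out.append(FeatureId(family, descriptor, region, phase, stat))
    return out


def pk_feature_ids() -> list[FeatureId]:
    """The 15 PK column ids (3 parameters x 5 statistics, intratumoral)."""
    return [
        FeatureId("PK", param, "intratumoral", "all", stat)
        for param in PK_PARAMETERS
        for stat in STATISTICS
    ]


def all_feature_ids() -> list[FeatureId]:
    return radiomic_feature_ids() + pk_feature_ids()


@dataclass
class FeatureTable:
    """Patients x features matrix with per-column identity and metadata."""

    df: pd.DataFrame
    labels: pd.Series | None = None
    groups: pd.Series | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.labels is not None:
            self.labels = pd.Series(np.asarray(self.labels), index=self.df.index)
        if self.groups is not None:
            self.groups = pd.Series(np.asarray(self.groups), index=self.df.index)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_patients(self) -> int:
        return len(self.df)

    @property
    def n_features(self) -> int:
        return self.df.shape[1]

    def subset_features(self, names) -> "FeatureTable":
        return FeatureTable(self.df[list(names)].copy(), self.labels, self.groups, dict(self.attrs))

    def subset_patients(self, index) -> "FeatureTable":
        df = self.df.loc[index]
        return FeatureTable(
            df.copy(),
            None if self.labels is None else self.labels.loc[index].copy(),
            None if self.groups is None else self.groups.loc[index].copy(),
            dict(self.attrs),
        )

    def to_csv(self, path: str | Path) -> None:
        out = self.df.copy()
        if self.labels is not None:
            out.insert(0, "__label__", self.labels)
        if self.groups is not None:
            out.insert(0, "__group__", self.groups)
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, index_col=0)
        labels = df.pop("__label__") if "__label__" in df else None
        groups = df.pop("__group__") if "__group__" in df else None
        return cls(df, labels, groups)


# ---------------------------------------------------------------------------
# Phase selection and first-order statistics
# ---------------------------------------------------------------------------

def select_phases(series, tumor_mask: np.ndarray) -> tuple[int, int]:
    """Absolute phase indices of the initial and peak postcontrast phases.

    Initial is always the first postcontrast phase; peak is the postcontrast
    phase with maximal mean intensity inside the tumor mask.
    """
    if series.n_postcontrast < 2:
        raise ValueError("need at least 2 postcontrast phases")
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    means = [series.data[p][tumor_mask].mean() for p in range(1, series.data.shape[0])]
    return 1, 1 + int(np.argmax(means))


def aggregate_stats(map_values: np.ndarray, region_mask: np.ndarray | None = None) -> dict:
    """Five first-order statistics of a descriptor map over a region.

    SD uses the n-1 denominator; skewness and kurtosis are moment-based
    with the non-excess kurtosis convention (Gaussian -> 3).  A constant
    region returns skewness 0 and kurtosis 0 (flagged via the "degenerate"
    entry) since the standardized moments are undefined there.
    """
    if region_mask is not None:
        vals = np.asarray(map_values)[np.asarray(region_mask, dtype=bool)]
    else:
        vals = np.asarray(map_values).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty region")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    degenerate = sd == 0.0
    if degenerate:
        skew = kurt = 0.0
    else:
        d = vals - mean
        m2 = float(np.mean(d**2))
        skew = float(np.mean(d**3)) / m2**1.5
        kurt = float(np.mean(d**4)) / m2**2
    return {
        "mean": mean,
        "median": float(np.median(vals)),
        "SD": sd,
        "skewness": skew,
        "kurtosis": kurt,
        "degenerate": degenerate,
    }


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

class AssemblyError(KeyError):
    pass


def compute_texture_volumes(
    series,
    region: RegionPair,
    phase_index: int,
    haralick_spec: textures.HaralickSpec | None = None,
    collage_spec: textures.CollageSpec | None = None,
) -> dict[str, np.ndarray]:
    """All 99 descriptor maps of one phase, stacked per-slice into volumes.

    The windowed families are evaluated only at tumor + ring voxels; slices
    without any region voxels are left NaN.
    """
    union = region.union
    vol = series.data[phase_index]
    out = {
        f"{fam} {desc}": np.full(vol.shape, np.nan)
        for fam, desc in textures.descriptor_names()
    }
    for z in range(vol.shape[0]):
        m = union[z]
        if not m.any():
            continue
        bank = textures.texture_bank(vol[z], haralick_spec, collage_spec, mask=m, quantization_mask=m)
        for name, arr in bank.maps.items():
            out[name][z] = arr
    return out


def assemble_features(
    texture_volumes_by_phase: dict[str, dict[str, np.ndarray]],
    pk_volumes: dict[str, np.ndarray],
    region: RegionPair,
) -> pd.Series:
    """One patient's 1980 + 15 feature row in canonical column order.

    ``texture_volumes_by_phase`` maps "initial"/"peak" to the 99 named
    descriptor volumes of that phase; ``pk_volumes`` holds the three Tofts
    maps.  A missing map raises ``AssemblyError`` naming the FeatureId.
    """
    masks = {"intratumoral": region.tumor_mask, "peritumoral": region.peritumoral_mask}
    values, names = [], []
    cache: dict[tuple, dict] = {}
    for fid in radiomic_feature_ids():
        key = (fid.family, fid.descriptor, fid.region, fid.phase)
        if key not in cache:
            phase_maps = texture_volumes_by_phase.get(fid.phase)
            map_name = f"{fid.family} {fid.descriptor}"
            if phase_maps is None or map_name not in phase_maps:
                raise AssemblyError(f"missing texture map for {fid.name}")
            cache[key] = aggregate_stats(phase_maps[map_name], masks[fid.region])
        values.append(cache[key][fid.statistic])
        names.append(fid.name)
    for fid in pk_feature_ids():
        if fid.descriptor not in pk_volumes:
            raise AssemblyError(f"missing PK map for {fid.name}")
        key = ("PK", fid.descriptor)
        if key not in cache:
            cache[key] = aggregate_stats(pk_volumes[fid.descriptor], masks["intratumoral"])
        values.append(cache[key][fid.statistic])
        names.append(fid.name)
    return pd.Series(values, index=names, dtype=float)


def extract_patient_features(
    series,
    region: RegionPair,
    haralick_spec: textures.HaralickSpec | None = None,
    collage_spec: textures.CollageSpec | None = None,
    include_pk: bool = True,
) -> pd.Series:
    """End-to-end per-patient feature extraction (texture + PK)."""
    from . import tofts as _tofts

    initial, peak = select_phases(series, region.tumor_mask)
    tex = {
        "initial": compute_texture_volumes(series, region, initial, haralick_spec, collage_spec),
        "peak": compute_texture_volumes(series, region, peak, haralick_spec, collage_spec),
    }
    if include_pk:
        pk = _tofts.pk_maps(series, region)
    else:
        pk = {k: np.zeros(series.grid_shape) for k in PK_PARAMETERS}
    return assemble_features(tex, pk, region)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_features(
    table: FeatureTable, reference: FeatureTable | None = None
) -> FeatureTable:
    """Affine per-column normalization to [-1, 1].

    The reference table (default: the table itself) supplies column min/max;
    the reference min maps to -1 and max to +1, values outside the reference
    range are clipped, and constant reference columns map to 0.  Freezing
    the training table as reference keeps holdout patients from influencing
    the scaling.
    """
    ref = reference if reference is not None else table
    if list(ref.columns) != list(table.columns):
        raise ValueError("reference columns do not match")
    lo = ref.df.min(axis=0)
    hi = ref.df.max(axis=0)
    span = hi - lo
    safe = span.replace(0.0, 1.0)
    scaled = (table.df - lo) / safe * 2.0 - 1.0
    scaled = scaled.clip(-1.0, 1.0)
    scaled.loc[:, span == 0.0] = 0.0
    return FeatureTable(scaled, table.labels, table.groups, dict(table.attrs))
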