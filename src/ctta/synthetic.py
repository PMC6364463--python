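"""Synthetic two-phase CT phantom cohorts with controllable lesion heterogeneity.

Each subject gets one volume + mask pair per contrast phase
(corticomedullary, nephrographic).  A lesion is an ellipsoid with mildly
jittered semi-axes on a uniform background, filled with:

* the group- and phase-specific mean enhancement (HU);
* a correlated Gaussian texture field: white noise smoothed with a Gaussian
  kernel of the group's correlation length, then rescaled so the texture
  standard deviation inside the mask hits the target exactly (amplitude and
  correlation length are therefore independent knobs — amplitude drives the
  SD feature, correlation length the fine-vs-coarse LoG response);
* a subject-level heavy-tail modulation: the field is multiplied by
  ``exp(g * m)`` with ``m`` a smooth unit-variance field and ``g`` drawn per
  subject from the group's ``texture_tail`` (mean, sd), truncated at zero.
  This is the generator's model of *texture heterogeneity*: larger ``g``
  concentrates intensity variation into focal hot/cold spots, which lowers
  min-max-binned histogram entropy while leaving the masked SD pinned by the
  rescaling.  (With purely Gaussian fields, per-ROI min-max entropy is
  affine-invariant, so no amplitude knob could move it.)
* an optional central necrotic core: a concentric ellipsoid covering the
  group's ``necrosis_fraction`` of the lesion volume, set uniformly to
  ``mean - necrosis_drop_hu`` before noise — liquefied necrosis is far more
  homogeneous than viable tumor, which is what depresses entropy;
* i.i.d. Gaussian acquisition noise over the whole grid.

The two phases share all texture parameters and the subject's tail draw and
differ only in mean enhancement; each phase gets its own field realization.
Generation is reproducible: every subject draws from a child generator
seeded by (cohort seed, CRC-32 of the subject id), so adding subjects never
reshuffles existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from ctta.io import (
    GROUPS,
    MIN_LESION_SLICES,
    PHASES,
    ImageVolume,
    ROIMask,
    save_mask,
    save_volume,
    write_manifest,
)


class PhantomError(ValueError):
    """Invalid phantom specification or a generated lesion violating invariants."""


def _per_group(value) -> dict[str, object]:
    """Broadcast a shared value (or per-phase dict) to both groups."""
    if isinstance(value, dict) and set(GROUPS) <= set(value):
        return {g: value[g] for g in GROUPS}
    return {g: value for g in GROUPS}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a phantom cohort.

    Group sizes default to the 77 low / 54 high split of a typical
    retrospective grading cohort; any sizes >= 2 are allowed.  Slice
    thickness defaults to 3 mm and the minimum lesion radius guarantees
    every lesion spans at least seven axial slices.
    """

    n_low: int = 77
    n_high: int = 54
    volume_shape: tuple[int, int, int] = (64, 64, 24)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    lesion_radius_range: tuple[float, float] = (12.0, 20.0)  # mm, semi-axes
    background_hu: float = 35.0
    #: group -> phase -> lesion mean enhancement (HU)
    lesion_mean_hu: dict = field(
        default_factory=lambda: {
            "low": {"corticomedullary": 94.0, "nephrographic": 84.0},
            "high": {"corticomedullary": 82.0, "nephrographic": 76.0},
        }
    )
    texture_field_sd: dict = field(default_factory=lambda: {"low": 35.0, "high": 30.0})
    texture_correlation_length: dict = field(
        default_factory=lambda: {"low": 1.5, "high": 1.5}
    )  # mm
    #: subject-level tail-modulation strength (mean, sd), truncated normal >= 0
    texture_tail: dict = field(
        default_factory=lambda: {"low": (0.2, 0.1), "high": (0.8, 0.3)}
    )
    tail_modulation_length: float = 6.0  # mm
    necrosis_fraction: dict = field(default_factory=lambda: {"low": 0.05, "high": 0.25})
    necrosis_drop_hu: float = 45.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_low < 2 or self.n_high < 2:
            raise PhantomError("each group needs at least 2 subjects")
        r_lo, r_hi = self.lesion_radius_range
        if r_lo <= 0 or r_hi < r_lo:
            raise PhantomError(
                f"degenerate lesion radius range {self.lesion_radius_range}"
            )
        sp = self.voxel_spacing
        if any(s <= 0 for s in sp):
            raise PhantomError(f"voxel spacing must be positive, got {sp}")
        # seven-slice inclusion rule must be satisfiable by construction
        if 2.0 * r_lo / sp[2] < MIN_LESION_SLICES + 1:
            raise PhantomError(
                f"minimum lesion radius {r_lo} mm cannot guarantee "
                f"{MIN_LESION_SLICES} axial slices at {sp[2]} mm thickness"
            )
        extents = [n * s for n, s in zip(self.volume_shape, sp)]
        if 2.0 * r_hi + 8.0 > min(extents):
            raise PhantomError(
                f"maximum lesion radius {r_hi} mm does not fit the "
                f"{extents} mm volume"
            )
        for name in ("texture_field_sd", "texture_correlation_length",
                     "texture_tail", "necrosis_fraction", "lesion_mean_hu"):
            object.__setattr__(self, name, _per_group(getattr(self, name)))
        for g in GROUPS:
            frac = self.necrosis_fraction[g]
            if not 0.0 <= frac <= 1.0:
                raise PhantomError(f"necrosis_fraction[{g}]={frac} outside [0, 1]")
            if self.texture_field_sd[g] < 0:
                raise PhantomError("texture_field_sd must be >= 0")
        if self.noise_sd < 0:
            raise PhantomError("noise_sd must be >= 0")

    def as_null(self) -> "PhantomSpec":
        """Same cohort with every group-dependent parameter forced to the
        low-group value; labels are retained."""
        return replace(
            self,
            lesion_mean_hu={g: dict(self.lesion_mean_hu["low"]) for g in GROUPS},
            texture_field_sd={g: self.texture_field_sd["low"] for g in GROUPS},
            texture_correlation_length={
                g: self.texture_correlation_length["low"] for g in GROUPS
            },
            texture_tail={g: tuple(self.texture_tail["low"]) for g in GROUPS},
            necrosis_fraction={g: self.necrosis_fraction["low"] for g in GROUPS},
        )

    @property
    def affine(self) -> np.ndarray:
        return np.diag([*self.voxel_spacing, 1.0])


def heterogeneity_contrast_spec(
    n_low: int = 40, n_high: int = 40, seed: int = 0, **overrides
) -> PhantomSpec:
    """A cohort whose groups differ *only* in texture heterogeneity.

    Enhancement means, texture amplitude, correlation length and necrosis are
    identical across groups; only the subject-level tail-modulation strength
    differs.  Entropy is the feature designed to respond; the moment features
    see matched means and SDs.
    """
    params = dict(
        n_low=n_low,
        n_high=n_high,
        seed=seed,
        lesion_mean_hu={"corticomedullary": 94.0, "nephrographic": 84.0},
        texture_field_sd=35.0,
        texture_correlation_length=1.5,
        texture_tail={"low": (0.2, 0.1), "high": (0.8, 0.3)},
        necrosis_fraction=0.0,
    )
    params.update(overrides)
    return PhantomSpec(**params)


def null_spec(n_low: int = 40, n_high: int = 40, seed: int = 0, **overrides) -> PhantomSpec:
    """A cohort with no group difference at all (global null)."""
    return heterogeneity_contrast_spec(n_low, n_high, seed, **overrides).as_null()


def subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    """Child generator for one subject, stable under cohort-size changes."""
    return np.random.default_rng([seed, zlib.crc32(subject_id.encode())])


def _smooth_unit_field(
    rng: np.random.Generator, shape, sigma_vox
) -> np.ndarray:
    f = ndimage.gaussian_filter(
        rng.standard_normal(shape).astype(np.float32), sigma=sigma_vox, mode="reflect"
    )
    sd = f.std()
    return f / sd if sd > 0 else f


def _ellipsoid_dist2(shape, spacing, center, semi_mm) -> np.ndarray:
    """Squared normalized distance to the ellipsoid surface, by broadcasting."""
    axes = []
    for k in range(3):
        x = (np.arange(shape[k], dtype=np.float32) - center[k]) * spacing[k] / semi_mm[k]
        axes.append((x * x).reshape([-1 if i == k else 1 for i in range(3)]))
    return axes[0] + axes[1] + axes[2]


def simulate_lesion(
    spec: PhantomSpec,
    group: str,
    phase: str,
    rng: np.random.Generator,
    tail_g: float | None = None,
    necrosis_fraction: float | None = None,
) -> tuple[ImageVolume, ROIMask]:
    """One phase image of one subject: (volume, mask).

    ``tail_g`` and ``necrosis_fraction`` default to the group's spec values
    (``tail_g`` is normally drawn once per subject by :func:`generate_cohort`
    and shared across phases).
    """
    shape = spec.volume_shape
    sp = np.asarray(spec.voxel_spacing, dtype=np.float64)
    if tail_g is None:
        mean_g, sd_g = spec.texture_tail[group]
        tail_g = max(0.0, rng.normal(mean_g, sd_g)) if sd_g > 0 else float(mean_g)
    if necrosis_fraction is None:
        necrosis_fraction = spec.necrosis_fraction[group]

    center = np.asarray(shape) / 2.0 + rng.uniform(-3.0, 3.0, 3) / sp
    semi_mm = rng.uniform(*spec.lesion_radius_range, 3)
    mask = _ellipsoid_dist2(shape, sp, center, semi_mm) <= 1.0

    vol = np.full(shape, spec.background_hu, dtype=np.float32)
    mean_hu = spec.lesion_mean_hu[group][phase]
    vol[mask] = mean_hu

    tex_sd = spec.texture_field_sd[group]
    if tex_sd > 0:
        corr_vox = spec.texture_correlation_length[group] / sp
        tex = _smooth_unit_field(rng, shape, corr_vox)
        if tail_g > 0:
            mod = _smooth_unit_field(rng, shape, spec.tail_modulation_length / sp)
            tex = tex * np.exp(tail_g * mod)
        masked_sd = tex[mask].std()
        if masked_sd > 0:
            vol[mask] += tex[mask] / masked_sd * tex_sd

    if necrosis_fraction > 0:
        scale = necrosis_fraction ** (1.0 / 3.0)
        core2 = _ellipsoid_dist2(shape, sp, center, semi_mm * scale)
        vol[(core2 <= 1.0) & mask] = mean_hu - spec.necrosis_drop_hu

    if spec.noise_sd > 0:
        vol += rng.standard_normal(shape).astype(np.float32) * spec.noise_sd

    roi = ROIMask(mask, spec.affine)
    if roi.n_voxels == 0:
        raise PhantomError(f"generated an empty lesion ({group}/{phase})")
    if roi.n_slices() < MIN_LESION_SLICES:
        raise PhantomError(
            f"generated lesion spans {roi.n_slices()} axial slices "
            f"(< {MIN_LESION_SLICES}); spec violates the inclusion rule"
        )
    return ImageVolume(vol.astype(np.float32), spec.affine), roi


def _subject_ids(spec: PhantomSpec):
    for group, n in (("low", spec.n_low), ("high", spec.n_high)):
        for i in range(n):
            yield f"{group}-{i + 1:03d}", group


def generate_cohort(spec: PhantomSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write the phantom cohort to ``out_dir`` and return its manifest.

    One volume + mask NIfTI pair per subject per phase, plus
    ``manifest.csv``.  The returned manifest carries absolute paths; the CSV
    stores them relative to ``out_dir``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write-probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    rows = []
    for subject_id, group in _subject_ids(spec):
        rng = subject_rng(spec.seed, subject_id)
        mean_g, sd_g = spec.texture_tail[group]
        tail_g = max(0.0, rng.normal(mean_g, sd_g)) if sd_g > 0 else float(mean_g)
        for phase in PHASES:
            volume, mask = simulate_lesion(spec, group, phase, rng, tail_g=tail_g)
            vol_name = f"{subject_id}_{phase}_vol.nii"
            mask_name = f"{subject_id}_{phase}_mask.nii"
            save_volume(volume, out_dir / vol_name)
            save_mask(mask, out_dir / mask_name)
            rows.append(
                {
                    "subject_id": subject_id,
                    "group": group,
                    "phase": phase,
                    "volume": vol_name,
                    "mask": mask_name,
                }
            )
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out_dir / "manifest.csv")
    resolved = manifest.copy()
    for col in ("volume", "mask"):
        resolved[col] = [str(out_dir / p) for p in resolved[col]]
    return resolved


def generate_null_cohort(spec: PhantomSpec, out_dir: str | Path) -> pd.DataFrame:
    """As :func:`generate_cohort` with all group differences removed."""
    return generate_cohort(spec.as_null(), out_dir)
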