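"""Synthetic subjects for testing the whole pipeline without patient data.

A synthetic subject consists of a gamma-variate arterial input, a delayed
and dispersed portal-vein input generated by the unit-gain dispersion
compartment, a liver curve produced by one of the kinetic models plus the
blood-volume mixture, and a spleen curve produced by a 1TCM of the aorta.
All clean curves live on the 1-s grid; the observable data are their frame
averages on the acquisition schedule, with multiplicative Gaussian noise
whose standard deviation shrinks with the square root of the frame duration
(longer frames average more counts).

Default ground-truth kinetic parameters sit at the cohort-mean estimates of
the measured-PV dual-input model (f_A = 0.299, f_P = 0.930 mL/min/mL,
k = 1.603 /min, V_B = 0.095, dt1 = 18 s, dt2 = 23 s), so recovery
experiments exercise the physiologically relevant regime.

:func:`generate_phantom_image` additionally paints the four VOIs as
non-overlapping boxes into a small 4-D image, the portal-vein box carrying
an optional cold rim, so the extraction module (largest component,
percentile TAC) can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .curves import FrameSchedule, FrameTAC, SampledCurve, frame_average
from .kinetics import (
    ModelParams,
    NewModelParams,
    OneTissueParams,
    RijzewijkParams,
    TaniguchiParams,
    blend_blood,
    blood_input,
    simulate_1tcm,
    simulate_new_model,
    simulate_pv_compartment,
    simulate_rijzewijk,
    simulate_taniguchi,
)
from .voi import ImageGeometry, VoiMask

__all__ = [
    "LayoutError",
    "AifSpec",
    "SubjectSpec",
    "SyntheticSubject",
    "PhantomLayout",
    "generate_aif",
    "generate_subject",
    "generate_phantom_image",
]

VOI_ORDER = ("aorta", "portal_vein", "liver", "spleen")


class LayoutError(ValueError):
    """Raised when phantom VOI boxes overlap or leave the image."""


@dataclass(frozen=True)
class AifSpec:
    """Gamma-variate arterial input A (t - t0)^alpha exp(-(t - t0)/beta).

    ``amplitude`` is the leading coefficient A in Bq/mL; with the default
    shape (alpha = 3, beta = 6 s, onset 8 s) the curve peaks near 26 s, as a
    first-minute arterial bolus should.  An optional recirculation shoulder
    adds ``recirc_fraction`` of the peak height, rising with time constant
    ``recirc_tau_s``, so the tail stays elevated the way recirculating water
    keeps arterial activity from returning to zero.
    """

    amplitude: float = 170.0
    onset_s: float = 8.0
    shape: float = 3.0
    scale_s: float = 6.0
    recirc_fraction: float = 0.15
    recirc_tau_s: float = 40.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.shape <= 0 or self.scale_s <= 0 or self.onset_s < 0:
            raise ValueError("need shape > 0, scale > 0, onset >= 0")
        if self.recirc_fraction < 0 or self.recirc_tau_s <= 0:
            raise ValueError("recirculation shoulder needs fraction >= 0, tau > 0")

    @property
    def peak_height(self) -> float:
        """Peak of the gamma-variate term, at t = onset + shape * scale."""
        return float(
            self.amplitude
            * (self.shape * self.scale_s) ** self.shape
            * np.exp(-self.shape)
        )

    @classmethod
    def with_peak(cls, peak_bq_ml: float, **kwargs) -> "AifSpec":
        """Build a spec whose gamma-variate term peaks at ``peak_bq_ml``."""
        probe = cls(amplitude=1.0, **kwargs)
        return cls(amplitude=peak_bq_ml / probe.peak_height, **kwargs)


def generate_aif(spec: AifSpec, grid_end: int = 280) -> SampledCurve:
    """Evaluate the gamma-variate input on the 1-s grid t = 1..``grid_end``."""
    t = np.arange(1, grid_end + 1, dtype=float)
    d = t - spec.onset_s
    values = np.zeros_like(t)
    pos = d > 0
    values[pos] = spec.amplitude * d[pos] ** spec.shape * np.exp(-d[pos] / spec.scale_s)
    if spec.recirc_fraction > 0:
        values[pos] += (
            spec.recirc_fraction
            * spec.peak_height
            * (1.0 - np.exp(-d[pos] / spec.recirc_tau_s))
        )
    return SampledCurve(values, label="aorta")


@dataclass(eq=False)
class SubjectSpec:
    """Ground truth for one synthetic subject.

    ``params`` drives the liver curve (any of the four models); the
    measured-style portal input is always generated by the dispersion
    compartment with ``pv_rate`` (/min) and ``pv_delay`` (s), and the spleen
    by a 1TCM of the aorta.  ``noise_fraction`` is the multiplicative
    Gaussian noise level at the reference frame duration.
    """

    aif: AifSpec = field(default_factory=AifSpec)
    params: ModelParams = field(
        default_factory=lambda: NewModelParams(
            f_A=0.299, f_P=0.930, k=1.603, V_B=0.095, dt1=18, dt2=23
        )
    )
    pv_rate: float = 1.25
    pv_delay: int = 5
    spleen: OneTissueParams = field(
        default_factory=lambda: OneTissueParams(f=1.0, k=1.1, V_B=0.2, dt1=22)
    )
    noise_fraction: float = 0.05
    frame_duration_ref_s: float = 5.0
    seed: int = 0
    schedule: FrameSchedule = field(default_factory=FrameSchedule.default)

    def __post_init__(self) -> None:
        if self.noise_fraction < 0:
            raise ValueError("noise fraction must be non-negative")
        if self.pv_rate <= 0:
            raise ValueError("portal dispersion rate must be positive")


@dataclass(eq=False)
class SyntheticSubject:
    """A generated subject: spec, clean 1-s curves and noisy frame TACs.

    ``curves`` holds the clean curves by role ('aorta', 'portal_vein',
    'liver' for the blood-blended PET signal, 'liver_tissue', 'spleen');
    ``clean_tacs`` and ``noisy_tacs`` hold the frame-averaged versions for
    the four observable VOIs.  Regenerating from the stored spec (same seed)
    reproduces the noisy TACs bit-identically.
    """

    spec: SubjectSpec
    curves: dict
    clean_tacs: dict
    noisy_tacs: dict


def _liver_curves(
    params: ModelParams, aorta: SampledCurve, pv_measured: SampledCurve
) -> tuple[SampledCurve, SampledCurve]:
    """Tissue and blood-blended liver curves for any generating model."""
    if isinstance(params, NewModelParams):
        c_t = simulate_new_model(params, aorta, pv_measured)
        blood = blood_input(params, aorta, pv_measured)
    elif isinstance(params, TaniguchiParams):
        c_t, c_pv = simulate_taniguchi(params, aorta)
        blood = blood_input(params, aorta, c_pv)
    elif isinstance(params, RijzewijkParams):
        c_t, c_pv = simulate_rijzewijk(params, aorta)
        blood = blood_input(params, aorta, c_pv)
    elif isinstance(params, OneTissueParams):
        c_t = simulate_1tcm(params, aorta)
        blood = blood_input(params, aorta)
    else:
        raise TypeError(f"unknown parameter type {type(params).__name__}")
    return c_t, blend_blood(c_t, blood, params.V_B)


def generate_subject(spec: SubjectSpec) -> SyntheticSubject:
    """Generate one subject's clean curves and noisy frame TACs."""
    grid_end = int(round(spec.schedule.span))
    aorta = generate_aif(spec.aif, grid_end)
    pv = simulate_pv_compartment(spec.pv_rate, spec.pv_delay, aorta)
    liver_tissue, liver_pet = _liver_curves(spec.params, aorta, pv)
    spleen_tissue = simulate_1tcm(spec.spleen, aorta)
    spleen_pet = blend_blood(spleen_tissue, aorta, spec.spleen.V_B)

    curves = {
        "aorta": aorta,
        "portal_vein": SampledCurve(pv.values, label="portal_vein"),
        "liver_tissue": SampledCurve(liver_tissue.values, label="liver"),
        "liver": SampledCurve(liver_pet.values, label="liver"),
        "spleen": SampledCurve(spleen_pet.values, label="spleen"),
    }
    clean_tacs = {
        name: frame_average(curves[name], spec.schedule) for name in VOI_ORDER
    }

    rng = np.random.default_rng(spec.seed)
    durations = spec.schedule.durations
    scale = spec.noise_fraction / np.sqrt(durations / spec.frame_duration_ref_s)
    noisy_tacs = {}
    for name in VOI_ORDER:  # fixed draw order keeps generation reproducible
        z = rng.standard_normal(spec.schedule.n_frames)
        values = clean_tacs[name].values * (1.0 + scale * z)
        noisy_tacs[name] = FrameTAC(
            spec.schedule, values, label=name, allow_negative=True
        )
    return SyntheticSubject(
        spec=spec, curves=curves, clean_tacs=clean_tacs, noisy_tacs=noisy_tacs
    )


@dataclass(eq=False)
class PhantomLayout:
    """Axis-aligned VOI boxes inside a small image grid.

    ``boxes`` maps each VOI label to ``((x0, x1), (y0, y1), (z0, z1))``
    half-open voxel ranges.  Boxes must be disjoint and inside the image.
    """

    shape: tuple = (40, 40, 20)
    voxel_size: tuple = (1.65, 1.65, 2.80)
    boxes: dict = field(
        default_factory=lambda: {
            "liver": ((2, 18), (2, 18), (4, 16)),
            "aorta": ((24, 28), (4, 8), (2, 18)),
            "portal_vein": ((22, 30), (12, 18), (8, 12)),
            "spleen": ((32, 38), (4, 10), (6, 14)),
        }
    )

    def __post_init__(self) -> None:
        occupancy = np.zeros(self.shape, dtype=np.uint8)
        for label, box in self.boxes.items():
            sl = self.slices(label)
            for (lo, hi), n in zip(box, self.shape):
                if not 0 <= lo < hi <= n:
                    raise LayoutError(f"box '{label}' leaves the {self.shape} image")
            occupancy[sl] += 1
        if occupancy.max() > 1:
            raise LayoutError("phantom VOI boxes overlap")

    def slices(self, label: str) -> tuple:
        (x0, x1), (y0, y1), (z0, z1) = self.boxes[label]
        return (slice(x0, x1), slice(y0, y1), slice(z0, z1))

    @property
    def geometry(self) -> ImageGeometry:
        return ImageGeometry.axis_aligned(self.shape, self.voxel_size)


def _rim_split(box_shape: tuple, core_fraction: float) -> np.ndarray:
    """Boolean core (True) / rim (False) split of a box by centre distance.

    The core is the ``core_fraction`` of voxels nearest the box centre in
    normalised Chebyshev distance, so the rim forms an outer shell.
    """
    grids = np.meshgrid(
        *[(np.arange(n) - (n - 1) / 2.0) / max(n, 2) for n in box_shape],
        indexing="ij",
    )
    dist = np.maximum.reduce([np.abs(g) for g in grids])
    cutoff = np.quantile(dist, core_fraction)
    return dist <= cutoff


def generate_phantom_image(
    subject: SyntheticSubject,
    layout: Optional[PhantomLayout] = None,
    voxel_noise_fraction: float = 0.0,
    pv_rim_fraction: float = 0.0,
    rim_intensity: float = 0.5,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, dict, ImageGeometry]:
    """Paint the subject's clean frame TACs into a small 4-D phantom.

    Every voxel of a VOI box carries that VOI's clean per-frame value, times
    ``(1 + voxel_noise_fraction * z)`` voxel-level Gaussian noise.  With
    ``pv_rim_fraction`` > 0 the outer ``pv_rim_fraction`` of the portal-vein
    box is scaled by ``rim_intensity``, emulating the partial-volume-dimmed
    shell of a thin vessel; the hottest core then justifies the percentile
    TAC over the plain mean.  Returns the 4-D image, a dict of label ->
    :class:`~hepaflow.voi.VoiMask` and the grid geometry.
    """
    layout = layout or PhantomLayout()
    geometry = layout.geometry
    n_frames = subject.spec.schedule.n_frames
    rng = np.random.default_rng(subject.spec.seed if seed is None else seed)
    pet4d = np.zeros((*layout.shape, n_frames))
    masks = {}
    for label in VOI_ORDER:
        sl = layout.slices(label)
        box_shape = tuple(s.stop - s.start for s in sl)
        values = subject.clean_tacs[label].values  # (n_frames,)
        block = np.broadcast_to(values, (*box_shape, n_frames)).copy()
        if label == "portal_vein" and pv_rim_fraction > 0:
            core = _rim_split(box_shape, 1.0 - pv_rim_fraction)
            block[~core] *= rim_intensity
        if voxel_noise_fraction > 0:
            z = rng.standard_normal(block.shape)
            block *= 1.0 + voxel_noise_fraction * z
        pet4d[sl] = block
        mask = np.zeros(layout.shape, dtype=bool)
        mask[sl] = True
        masks[label] = VoiMask(mask, geometry, label)
    return pet4d, masks, geometry
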