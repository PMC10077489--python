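"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: two-channel ring
images of a capillary loop (membrane ring plus a luminally displaced
glycocalyx ring, PSF-blurred, optionally noisy), multi-subject cohorts with
group effects, electron-microscopy grid-intersection annotation tables, and
one-compartment tracer-washout decay traces.

All generators are pure functions of their parameter record including the
seed: identical inputs reproduce identical outputs bit for bit.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import i0e

from .permeability import DecayTrace
from .profiles import ChannelImagePair
from .tem import TEMAnnotation
from .tiffio import write_image_pair

log = logging.getLogger(__name__)

__all__ = [
    "LoopTruth",
    "GroupSpec",
    "CohortSpec",
    "TEMTruth",
    "DecayTruth",
    "TEMAnnotation",
    "render_ring_image",
    "ring_radial_profile",
    "make_loop_image",
    "make_cohort",
    "make_tem_annotation",
    "make_decay_trace",
]

NOISE_MODELS = ("none", "gaussian", "poisson")


@dataclass(frozen=True)
class LoopTruth:
    """Ground-truth parameters of one synthetic capillary-loop image.

    ``glx_offset`` is the luminal inward displacement of the glycocalyx ring
    relative to the membrane ring — the true value of the peak-to-peak index
    the pipeline estimates.
    """

    radius_membrane: float = 5.0
    glx_offset: float = 0.3
    psf_sigma: float = 0.1
    pixel_size: float = 0.05
    peak_intensity: tuple[float, float] = (10000.0, 12000.0)  # (glx, membrane)
    background: tuple[float, float] = (100.0, 100.0)
    noise_model: str = "none"
    noise_magnitude: float = 0.0  # gaussian: SD as fraction of peak intensity
    ring_width: float = 0.0  # intrinsic Gaussian cross-section sigma, um
    glx_side: str = "luminal"  # "abluminal" flips the ring outside (controls)
    center: tuple[float, float] | None = None  # um; None -> field-of-view centre
    fov_um: float | None = None  # None -> auto-sized
    margin_um: float = 1.2  # extra margin so centred 2-um lines stay in frame
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.radius_membrane > self.glx_offset >= 0:
            raise ValueError("require radius_membrane > glx_offset >= 0")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if self.psf_sigma < 0 or self.ring_width < 0:
            raise ValueError("psf_sigma and ring_width must be >= 0")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {NOISE_MODELS}")
        if self.glx_side not in ("luminal", "abluminal"):
            raise ValueError("glx_side must be 'luminal' or 'abluminal'")

    @property
    def sigma_eff(self) -> float:
        """PSF and intrinsic ring width combined in quadrature."""
        return float(np.hypot(self.psf_sigma, self.ring_width))

    @property
    def glx_radius(self) -> float:
        if self.glx_side == "luminal":
            return self.radius_membrane - self.glx_offset
        return self.radius_membrane + self.glx_offset


@dataclass(frozen=True)
class GroupSpec:
    label: str
    mean_offset: float
    between_subject_sd: float
    n_subjects: int

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.between_subject_sd < 0:
            raise ValueError("between_subject_sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Multi-group cohort layout: subjects -> glomeruli -> loops."""

    groups: tuple[GroupSpec, ...]
    glomeruli_per_subject: int = 3
    loops_per_glomerulus: int = 3
    loop_defaults: LoopTruth = field(default_factory=LoopTruth)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        if self.glomeruli_per_subject < 1 or self.loops_per_glomerulus < 1:
            raise ValueError("all counts must be >= 1")
        object.__setattr__(self, "groups", tuple(self.groups))


@dataclass(frozen=True)
class TEMTruth:
    """Parameters for a synthetic EM grid-intersection annotation table."""

    n_intersections: int = 100
    thickness_mean: float = 200.0  # nm
    thickness_sd: float = 50.0
    fraction_uncovered_target: float | None = None
    uncovered_max: float = 10.0  # nm
    width_specs: tuple = (
        ("gbm", 150.0, 20.0, 10),
        ("foot_process", 250.0, 40.0, 10),
        ("slit", 40.0, 5.0, 10),
    )  # (kind, mean nm, sd nm, n pairs)
    fenestrations: int = 12
    foot_processes: int = 8
    gbm_length_um: float = 6.0
    capillary_id: str = "cap1"
    glomerulus_id: str = "glom1"
    subject_id: str = "subj1"
    seed: int = 0
    achieved_uncovered_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.n_intersections < 1:
            raise ValueError("n_intersections must be >= 1")
        if self.fraction_uncovered_target is not None and not (
            0.0 <= self.fraction_uncovered_target <= 1.0
        ):
            raise ValueError("fraction_uncovered_target must be in [0, 1]")
        if self.thickness_mean < 0 or self.thickness_sd < 0 or self.gbm_length_um <= 0:
            raise ValueError("lengths must be >= 0 and gbm_length_um > 0")


@dataclass(frozen=True)
class DecayTruth:
    """One-compartment washout parameters; k = 2 * ps_true / radius."""

    ps_true: float = 0.025  # um/s
    radius: float = 5.0  # um
    i0: float = 1000.0
    i_inf: float = 0.0
    sampling_rate: float = 1.0  # Hz
    duration: float = 90.0  # s
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ps_true < 0:
            raise ValueError("ps_true must be >= 0")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.duration < 60.0:
            raise ValueError("duration must cover the default 60 s fitting window")
        if self.sampling_rate <= 0 or self.noise_sd < 0:
            raise ValueError("sampling_rate must be > 0 and noise_sd >= 0")

    @property
    def k(self) -> float:
        return 2.0 * self.ps_true / self.radius


def ring_radial_profile(r, radius: float, sigma: float):
    """Radial intensity of a unit-line-density circle convolved with a
    normalised 2D Gaussian of width *sigma* (exact closed form)."""
    r = np.asarray(r, dtype=float)
    a = r * radius / sigma**2
    return (radius / sigma**2) * np.exp(-((r - radius) ** 2) / (2 * sigma**2)) * i0e(a)


def render_ring_image(shape, center, radius, sigma, pixel_size) -> np.ndarray:
    """Render a PSF-blurred zero-width ring at unit line density.

    The pixel sum times the pixel area approximates the ring circumference
    (flux conservation under a unit-sum PSF).
    """
    if sigma <= 0:
        raise ValueError("rendering requires sigma > 0 (psf_sigma or ring_width)")
    nrows, ncols = shape
    x = (np.arange(ncols) + 0.5) * pixel_size
    y = (np.arange(nrows) + 0.5) * pixel_size
    rr = np.hypot(x[None, :] - center[0], y[:, None] - center[1])
    return ring_radial_profile(rr, radius, sigma)


def make_loop_image(truth: LoopTruth) -> tuple[ChannelImagePair, LoopTruth]:
    """Render the two-channel loop image described by *truth*.

    Returns the image pair and the truth record with the resolved field of
    view and centre filled in.
    """
    sigma = truth.sigma_eff
    if sigma <= 0:
        raise ValueError("psf_sigma and ring_width cannot both be zero")
    min_fov = 2.0 * (truth.radius_membrane + 3.0 * sigma)
    fov = truth.fov_um
    if fov is None:
        fov = 2.0 * (truth.radius_membrane + max(3.0 * sigma, truth.margin_um))
    if fov < min_fov:
        raise ValueError(
            f"field of view too small: {fov:.3f} um < required {min_fov:.3f} um "
            "(loop plus 3*psf_sigma margin)"
        )
    n = int(np.ceil(fov / truth.pixel_size))
    extent = n * truth.pixel_size
    center = truth.center if truth.center is not None else (extent / 2, extent / 2)

    rng = np.random.default_rng(truth.seed)
    channels = []
    radii = (truth.glx_radius, truth.radius_membrane)
    for radius, peak, bg in zip(radii, truth.peak_intensity, truth.background):
        base = render_ring_image((n, n), center, radius, sigma, truth.pixel_size)
        r_dense = np.linspace(max(radius - 5 * sigma, 0.0), radius + 5 * sigma, 4001)
        profile_max = ring_radial_profile(r_dense, radius, sigma).max()
        img = bg + peak / profile_max * base
        if truth.noise_model == "gaussian" and truth.noise_magnitude > 0:
            img = img + rng.normal(0.0, truth.noise_magnitude * peak, img.shape)
        elif truth.noise_model == "poisson":
            img = rng.poisson(img).astype(float)
        n_neg = int(np.sum(img < 0))
        if n_neg:
            log.info("clipping %d negative pixels to 0 after noise", n_neg)
            img = np.clip(img, 0.0, None)
        channels.append(img)

    pair = ChannelImagePair(
        glx=channels[0], membrane=channels[1], pixel_size=truth.pixel_size
    )
    resolved = dataclasses.replace(truth, fov_um=extent, center=tuple(center))
    return pair, resolved


MANIFEST_COLUMNS = [
    "subject_id",
    "group",
    "glomerulus_id",
    "loop_id",
    "path",
    "true_offset_um",
    "seed",
    "pixel_size_um",
]


def make_cohort(spec: CohortSpec, out_dir) -> pd.DataFrame:
    """Write a cohort of loop TIFFs plus manifest and seed-point CSVs.

    One image per loop; all loops of a subject share the subject's true
    glycocalyx offset (group mean plus a between-subject normal deviate).
    Returns the manifest, which is also written to ``manifest.csv``; lumen
    seed points for automated contour extraction go to ``seeds.csv``.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "loops"
    img_dir.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    defaults = spec.loop_defaults
    max_offset = 0.8 * defaults.radius_membrane

    rows = []
    seed_rows = []
    loop_counter = 0
    n_loops_total = (
        sum(g.n_subjects for g in spec.groups)
        * spec.glomeruli_per_subject
        * spec.loops_per_glomerulus
    )
    loop_seeds = np.random.SeedSequence(spec.seed + 1).generate_state(n_loops_total)
    for group in spec.groups:
        for si in range(group.n_subjects):
            subject_id = f"{group.label}_s{si}"
            offset = float(
                np.clip(
                    rng.normal(group.mean_offset, group.between_subject_sd),
                    0.0,
                    max_offset,
                )
            )
            for gi in range(spec.glomeruli_per_subject):
                glom_id = f"{subject_id}_g{gi}"
                for li in range(spec.loops_per_glomerulus):
                    loop_id = f"{glom_id}_l{li}"
                    seed = int(loop_seeds[loop_counter])
                    loop_counter += 1
                    truth = dataclasses.replace(
                        defaults, glx_offset=offset, seed=seed
                    )
                    pair, resolved = make_loop_image(truth)
                    path = img_dir / f"{loop_id}.tif"
                    write_image_pair(path, pair)
                    rows.append(
                        {
                            "subject_id": subject_id,
                            "group": group.label,
                            "glomerulus_id": glom_id,
                            "loop_id": loop_id,
                            "path": str(path.relative_to(out_dir)),
                            "true_offset_um": offset,
                            "seed": seed,
                            "pixel_size_um": truth.pixel_size,
                        }
                    )
                    seed_rows.append(
                        {
                            "loop_id": loop_id,
                            "x_um": resolved.center[0],
                            "y_um": resolved.center[1],
                        }
                    )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    pd.DataFrame(seed_rows).to_csv(out_dir / "seeds.csv", index=False)
    return manifest


def make_tem_annotation(truth: TEMTruth) -> tuple[TEMAnnotation, TEMTruth]:
    """Generate an EM annotation table realising the requested thickness
    distribution; the achieved uncovered fraction is recorded in the
    returned truth."""
    rng = np.random.default_rng(truth.seed)
    n = truth.n_intersections
    cutoff = truth.uncovered_max

    if truth.fraction_uncovered_target is None:
        thickness = np.clip(
            rng.normal(truth.thickness_mean, truth.thickness_sd, n), 0.0, None
        )
    else:
        n_unc = int(round(truth.fraction_uncovered_target * n))
        uncovered = rng.uniform(0.0, cutoff, n_unc)
        covered = np.empty(n - n_unc)
        for i in range(covered.size):
            for _ in range(1000):
                draw = rng.normal(truth.thickness_mean, truth.thickness_sd)
                if draw > cutoff:
                    covered[i] = draw
                    break
            else:  # pathological spec: fall back to just above the cutoff
                covered[i] = cutoff + abs(
                    rng.normal(0.0, max(truth.thickness_sd, 1.0))
                )
        thickness = np.concatenate([uncovered, covered])
        rng.shuffle(thickness)

    grid_spacing = 500.0  # nm between successive grid intersections
    x0 = np.arange(n) * grid_spacing
    y0 = np.zeros(n)
    theta = rng.uniform(0.0, 2 * np.pi, n)
    x1 = x0 + thickness * np.cos(theta)
    y1 = y0 + thickness * np.sin(theta)
    intersections = np.column_stack([x0, y0, x1, y1])

    width_rows = []
    for kind, mean, sd, n_pairs in truth.width_specs:
        widths = np.clip(rng.normal(mean, sd, n_pairs), 0.0, None)
        wx = rng.uniform(0.0, 5000.0, n_pairs)
        wy = rng.uniform(0.0, 5000.0, n_pairs)
        phi = rng.uniform(0.0, 2 * np.pi, n_pairs)
        for j in range(n_pairs):
            width_rows.append(
                {
                    "kind": kind,
                    "x0_nm": wx[j],
                    "y0_nm": wy[j],
                    "x1_nm": wx[j] + widths[j] * np.cos(phi[j]),
                    "y1_nm": wy[j] + widths[j] * np.sin(phi[j]),
                }
            )
    width_pairs = pd.DataFrame(
        width_rows, columns=["kind", "x0_nm", "y0_nm", "x1_nm", "y1_nm"]
    )

    annotation = TEMAnnotation(
        intersections=intersections,
        width_pairs=width_pairs,
        counts={
            "fenestrations": truth.fenestrations,
            "foot_processes": truth.foot_processes,
        },
        gbm_length_um=truth.gbm_length_um,
        capillary_id=truth.capillary_id,
        glomerulus_id=truth.glomerulus_id,
        subject_id=truth.subject_id,
    )
    achieved = float(np.mean(thickness <= cutoff))
    return annotation, dataclasses.replace(
        truth, achieved_uncovered_fraction=achieved
    )


def make_decay_trace(truth: DecayTruth) -> DecayTrace:
    """Simulate I(t) = I_inf + (I0 - I_inf) * exp(-k t) with additive noise;
    t = 0 is the perfusate switch."""
    rng = np.random.default_rng(truth.seed)
    times = np.arange(0.0, truth.duration + 1e-9, 1.0 / truth.sampling_rate)
    intensities = truth.i_inf + (truth.i0 - truth.i_inf) * np.exp(-truth.k * times)
    if truth.noise_sd > 0:
        intensities = intensities + rng.normal(0.0, truth.noise_sd, times.shape)
        n_neg = int(np.sum(intensities < 0))
        if n_neg:
            log.info("clipping %d negative intensities to 0", n_neg)
            intensities = np.clip(intensities, 0.0, None)
    return DecayTrace(
        times=times, intensities=intensities, t0=0.0, radius=truth.radius
    )
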