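"""Synthetic oocyte phantoms with analytic ground truth.

A phantom is a nested-ellipse model of a denuded metaphase-II oocyte: an
ooplasm ellipse inside a perivitelline-space (PVS) boundary inside the zona
pellucida (ZP) outer boundary, rasterized into a 4-class label image
(background=0, ooplasm=1, PVS=2, ZP=3) and an 8-bit grayscale image with
per-region intensity bands plus noise.  Boundary irregularity is a low-order
Fourier perturbation of the ellipse radius, which produces realistic
sub-unity circularity without self-intersection.

Default geometry is calibrated so the population means of the dimensionless
inter-region ratios sit where they sit in real MII-oocyte cohorts:
ooplasm-vs-ZP major-axis ratio ~= 0.70 and ooplasm-vs-PVS area ratio ~= 0.81.
There is no absolute size scale (no micron calibration): every downstream
feature is a ratio or dimensionless descriptor, so phantoms are calibrated
on ratios only.

A cohort-structured dataset generator layers clinical structure on top:
patients with one or more retrieval cycles, cohorts of oocytes per cycle,
integer oocyte ages, multi-site clinic labels, and a logistic outcome model
linking a handful of driver features (oocyte age, ooplasm roundness,
ooplasm-vs-PVS area ratio, cohort size) to a binary blastocyst outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .morphometry import (
    REGIONS,
    RegionGeometry,
    polygon_geometry,
    relative_features,
    shape_descriptors,
)

__all__ = [
    "PhantomSpec",
    "PhantomConfigError",
    "OutcomeModel",
    "OutcomeTerm",
    "OocyteRecord",
    "generate_phantom",
    "generate_cohort_dataset",
    "boundary_polygon",
    "render_labels",
    "render_image",
    "render_record",
    "truth_geometry",
    "default_outcome_model",
    "null_outcome_model",
    "recovery_outcome_model",
]

#: Fourier modes perturbing each boundary radius
_FOURIER_MODES = (2, 3, 4, 5)


class PhantomConfigError(ValueError):
    """Phantom specification implies degenerate or non-nested regions."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and appearance of one synthetic oocyte.

    All lengths are in pixels.  ``pvs_outer_scale`` shrinks the ZP inner
    ellipse (ZP outer minus ``zp_thickness``) to give the PVS outer boundary;
    ``ooplasm_scale`` shrinks the PVS outer boundary to give the ooplasm
    boundary — so regions nest by construction.  ``size_jitter`` and
    ``ratio_jitter`` are relative standard deviations applied per oocyte to
    the overall scale and to the nesting scales, giving cohort-level spread
    in the ratio features comparable to real populations.
    """

    image_size: int = 256
    zp_outer_axes: tuple[float, float] = (88.0, 84.0)
    zp_thickness: float = 16.0
    pvs_outer_scale: float = 0.949
    ooplasm_scale: float = 0.90
    center_offset: float = 2.0
    rotation: float | None = None  # None -> sampled uniform on [0, pi)
    elongation_jitter: float = 0.018
    boundary_noise_amplitude: float = 1.2
    size_jitter: float = 0.05
    ratio_jitter: float = 0.012
    axis_jitter: float = 0.025
    boxiness_jitter: float = 0.25
    intensity_levels: dict[str, float] = field(
        default_factory=lambda: {"background": 190.0, "ooplasm": 95.0,
                                 "pvs": 235.0, "zp": 120.0})
    noise_sd: float = 6.0

    def validate(self) -> None:
        a, b = self.zp_outer_axes
        if a <= 0 or b <= 0 or self.zp_thickness <= 0:
            raise PhantomConfigError("axes and ZP thickness must be positive")
        if self.zp_thickness >= min(a, b):
            raise PhantomConfigError("ZP thickness consumes the whole oocyte")
        if not (0.0 < self.pvs_outer_scale < 1.0) or not (0.0 < self.ooplasm_scale < 1.0):
            raise PhantomConfigError("nesting scales must lie strictly in (0, 1)")
        if max(a, b) + self.center_offset + self.boundary_noise_amplitude + 2 \
                > self.image_size / 2:
            raise PhantomConfigError("oocyte does not fit inside the image")
        if set(self.intensity_levels) != {"background", "ooplasm", "pvs", "zp"}:
            raise PhantomConfigError("intensity_levels must name all four classes")


@dataclass(frozen=True)
class OutcomeTerm:
    """One driver of the synthetic outcome, in logit units.

    ``form="linear"`` contributes ``coef * z`` and ``form="quadratic"``
    contributes ``coef * z**2``, where ``z = (x - center) / scale`` is the
    standardized feature.  Quadratic terms with negative coefficients model
    an optimum at ``center`` with a tolerated band of width ``scale`` —
    the "narrow range of acceptable values" pattern seen in developmentally
    competent oocytes, whose feature ranges are tighter than those of
    arrested ones.
    """

    feature: str
    coef: float
    center: float
    scale: float
    form: str = "linear"


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic outcome process P(blastocyst | features).

    With all coefficients zero the outcome prevalence is
    ``sigmoid(intercept)`` exactly.
    """

    intercept: float = -0.45
    terms: tuple[OutcomeTerm, ...] = ()

    def logit(self, features: dict[str, float]) -> float:
        out = self.intercept
        for t in self.terms:
            z = (features[t.feature] - t.center) / t.scale
            if t.form == "quadratic":
                out += t.coef * z * z
            elif t.form == "linear":
                out += t.coef * z
            else:
                raise ValueError(f"unknown term form {t.form!r}")
        return out

    def probability(self, features: dict[str, float]) -> float:
        return 1.0 / (1.0 + math.exp(-self.logit(features)))


def default_outcome_model() -> OutcomeModel:
    """Outcome model used for cohort datasets unless overridden.

    Drivers and signs mirror what matters for developmental competence in
    real cohorts: younger oocytes, rounder ooplasm, larger ooplasm-vs-PVS
    area ratio and larger cohorts are favourable.  Centers/scales are the
    default-phantom population mean and sd of each driver, so coefficients
    are per-standard-deviation log-odds.
    """
    return OutcomeModel(
        intercept=-0.45,
        terms=(
            OutcomeTerm("oocyte_age", -0.50, 36.0, 4.5),
            OutcomeTerm("ooplasm_roundness", +0.60, 0.9337, 0.0387),
            OutcomeTerm("ooplasm_vs_pvs_area_ratio", -0.50, 0.8091, 0.0464),
            OutcomeTerm("cohort_size", +0.30, 6.9, 4.6),
        ),
    )


def null_outcome_model(intercept: float = 0.0) -> OutcomeModel:
    """Outcome independent of every feature: prevalence sigmoid(intercept)."""
    return OutcomeModel(intercept=intercept, terms=())


def recovery_outcome_model() -> OutcomeModel:
    """Outcome model for the driver-recovery study.

    Exactly three drivers — oocyte age (linear, unfavourable), ooplasm
    roundness and ooplasm-vs-PVS area ratio (quadratic optimum-deviation
    penalties) — so that a trained classifier's feature attributions can be
    checked against known ground truth.  The quadratic form encodes the
    narrow-band-of-acceptable-values pattern of developmentally competent
    oocytes, and makes the morphometric drivers identifiable: a linear
    combination of roundness and area ratio is geometrically equivalent to
    a single axis-ratio direction (the ellipse fit ties area to the axis
    product), whereas deviation-from-optimum signals concentrate on the
    named features themselves.
    """
    return OutcomeModel(
        intercept=0.9,
        terms=(
            OutcomeTerm("oocyte_age", -0.80, 36.0, 4.5),
            OutcomeTerm("ooplasm_roundness", -0.70, 0.9337, 0.0387,
                        form="quadratic"),
            OutcomeTerm("ooplasm_vs_pvs_area_ratio", -0.70, 0.8091, 0.0464,
                        form="quadratic"),
        ),
    )


# ---------------------------------------------------------------------------
# geometry sampling and rendering
# ---------------------------------------------------------------------------

def _sample_geometry(spec: PhantomSpec, rng: np.random.Generator) -> dict:
    """Draw one oocyte's analytic boundary parameters.

    Returns a dict region -> {center, semi_axes, rotation, fourier_cos,
    fourier_sin}; with zero jitter and zero boundary noise every boundary is
    an exact ellipse.
    """
    spec.validate()
    a_zp, b_zp = spec.zp_outer_axes
    size = 1.0 + np.clip(spec.size_jitter * rng.standard_normal(), -2.5, 2.5)
    elong = np.clip(spec.elongation_jitter * rng.standard_normal(), -0.12, 0.12)
    a_zp, b_zp = a_zp * size * (1 + elong), b_zp * size / (1 + elong)
    if b_zp > a_zp:
        a_zp, b_zp = b_zp, a_zp
    rot = spec.rotation if spec.rotation is not None else float(rng.uniform(0, np.pi))

    pvs_scale = float(np.clip(
        spec.pvs_outer_scale * (1 + 0.5 * spec.ratio_jitter * rng.standard_normal()),
        0.5, 0.985))
    # per-oocyte ooplasm shape variation has three independent latents: a
    # small isotropic scale jitter (ratio_jitter), an anisotropic jitter on
    # the major axis only (axis_jitter, the ooplasm is not an exactly
    # similar copy of the PVS ellipse), and superellipse boxiness, which
    # moves enclosed area at nearly fixed fitted axes.  Boxiness vanishes
    # in the analytic-ellipse mode (boundary noise and elongation jitter
    # both zero), where every boundary is an exact ellipse.
    common = float(np.clip(
        spec.ooplasm_scale * (1 + spec.ratio_jitter * rng.standard_normal()),
        0.5, 0.97))
    aniso = 1.0 + np.clip(spec.axis_jitter * rng.standard_normal(), -0.1, 0.1)
    exact_ellipses = (spec.boundary_noise_amplitude == 0
                      and spec.elongation_jitter == 0)
    if exact_ellipses:
        n_oop = 2.0
    else:
        n_oop = float(np.clip(2.0 + spec.boxiness_jitter * rng.standard_normal(),
                              1.6, 2.6))
    a_pvs = (a_zp - spec.zp_thickness * size) * pvs_scale
    b_pvs = (b_zp - spec.zp_thickness * size) * pvs_scale
    a_oop, b_oop = a_pvs * common * aniso, b_pvs * common

    c0 = (spec.image_size - 1) / 2.0

    def _offset(radius: float) -> np.ndarray:
        if radius <= 0:
            return np.zeros(2)
        ang = rng.uniform(0, 2 * np.pi)
        r = radius * np.sqrt(rng.uniform())
        return np.array([r * np.sin(ang), r * np.cos(ang)])

    center_zp = np.array([c0, c0]) + _offset(spec.center_offset)
    center_pvs = center_zp + _offset(spec.center_offset / 2)
    center_oop = center_pvs + _offset(spec.center_offset / 2)

    truth: dict = {}
    for region, center, (a, b) in (
            ("zp", center_zp, (a_zp, b_zp)),
            ("pvs", center_pvs, (a_pvs, b_pvs)),
            ("ooplasm", center_oop, (a_oop, b_oop))):
        r_ref = 0.5 * (a + b)
        sd = spec.boundary_noise_amplitude / (2.0 * r_ref) if r_ref > 0 else 0.0
        cos_c = sd * rng.standard_normal(len(_FOURIER_MODES))
        sin_c = sd * rng.standard_normal(len(_FOURIER_MODES))
        if spec.boundary_noise_amplitude == 0:
            cos_c[:] = 0.0
            sin_c[:] = 0.0
        truth[region] = {
            "center": center.astype(float),
            "semi_axes": (float(a), float(b)),
            "rotation": float(rot),
            "exponent": n_oop if region == "ooplasm" else 2.0,
            "fourier_cos": cos_c,
            "fourier_sin": sin_c,
        }
    return truth


def _boundary_radius(region_truth: dict, theta: np.ndarray) -> np.ndarray:
    """Radius of the (possibly perturbed) boundary at polar angles theta,
    measured from the region center; theta is in image (row, col) frame."""
    a, b = region_truth["semi_axes"]
    phi = theta - region_truth["rotation"]
    n = region_truth.get("exponent", 2.0)
    if n == 2.0:
        r_ell = a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
    else:  # superellipse |x/a|^n + |y/b|^n = 1 in polar form
        r_ell = (np.abs(np.cos(phi) / a) ** n
                 + np.abs(np.sin(phi) / b) ** n) ** (-1.0 / n)
    rho = np.ones_like(theta)
    for k, cc, ss in zip(_FOURIER_MODES, region_truth["fourier_cos"],
                         region_truth["fourier_sin"]):
        rho += cc * np.cos(k * theta) + ss * np.sin(k * theta)
    return r_ell * rho


def boundary_polygon(region_truth: dict, n_points: int = 512) -> np.ndarray:
    """Dense (row, col) polygon of one region boundary, for analytic
    measurement of the ground-truth geometry."""
    theta = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    r = _boundary_radius(region_truth, theta)
    cy, cx = region_truth["center"]
    return np.c_[cy + r * np.sin(theta), cx + r * np.cos(theta)]


def render_labels(truth: dict, image_size: int) -> np.ndarray:
    """Rasterize the analytic boundaries into a 4-class label image.

    Regions are painted outer to inner (ZP, PVS, ooplasm) so every pixel has
    exactly one label and nesting is guaranteed.  Pixel centers are at
    integer (row, col) coordinates.
    """
    yy, xx = np.mgrid[0:image_size, 0:image_size].astype(float)
    labels = np.zeros((image_size, image_size), dtype=np.uint8)
    for region, code in (("zp", 3), ("pvs", 2), ("ooplasm", 1)):
        t = truth[region]
        dy, dx = yy - t["center"][0], xx - t["center"][1]
        theta = np.arctan2(dy, dx)
        inside = np.hypot(dy, dx) <= _boundary_radius(t, theta)
        labels[inside] = code
    return labels


def render_image(labels: np.ndarray, spec: PhantomSpec,
                 rng: np.random.Generator) -> np.ndarray:
    """Grayscale 8-bit image: per-region intensity bands plus Gaussian noise."""
    levels = spec.intensity_levels
    lut = np.array([levels["background"], levels["ooplasm"],
                    levels["pvs"], levels["zp"]], dtype=float)
    img = lut[labels]
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_phantom(spec: PhantomSpec, seed: int
                     ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Generate one phantom: (image, label_image, geometry_truth).

    Deterministic for fixed (spec, seed).  ``geometry_truth`` carries the
    analytic center, semi-axes, rotation and Fourier perturbation of every
    region boundary; the label image is its rasterization.
    """
    rng = np.random.default_rng(seed)
    truth = _sample_geometry(spec, rng)
    labels = render_labels(truth, spec.image_size)
    image = render_image(labels, spec, rng)
    return image, labels, truth


def truth_geometry(truth: dict) -> dict[str, RegionGeometry]:
    """Measure the analytic boundaries themselves (no rasterization)."""
    return {r: polygon_geometry(boundary_polygon(truth[r]), region=r)
            for r in REGIONS}


# ---------------------------------------------------------------------------
# cohort-structured datasets
# ---------------------------------------------------------------------------

@dataclass
class OocyteRecord:
    """One oocyte of a cohort dataset, with its analytic ground truth."""

    oocyte_id: str
    patient_id: str
    cycle_id: str
    clinic: str
    oocyte_age: int
    cohort_size: int
    outcome: int
    true_probability: float
    geometry: dict[str, RegionGeometry]
    truth: dict
    phantom_seed: int


def _default_cohort_sizes(rng: np.random.Generator) -> int:
    # 1 + NegBinomial tuned to mean ~6.9, sd ~4.6 oocytes per retrieval cycle
    return 1 + int(rng.negative_binomial(2.434, 0.292))


def _default_ages(rng: np.random.Generator) -> int:
    return int(np.clip(np.rint(rng.normal(36.0, 4.5)), 21, 45))


_CLINICS = ("site_a", "site_b", "site_c", "site_d", "site_e")
#: P(number of retrieval cycles per patient); mean ~1.19
_CYCLE_COUNT_P = (0.84, 0.13, 0.03)


def generate_cohort_dataset(
    n_patients: int,
    seed: int,
    cohort_size_distribution=None,
    age_distribution=None,
    outcome_model: OutcomeModel | None = None,
    spec: PhantomSpec | None = None,
    clinics: tuple[str, ...] = _CLINICS,
) -> list[OocyteRecord]:
    """Generate a patient/cycle/oocyte-structured dataset with outcomes.

    Each patient gets a clinic, an age and one or more retrieval cycles;
    each cycle is a cohort of oocytes whose geometry is sampled from
    ``spec`` and whose blastocyst outcome is drawn Bernoulli from
    ``outcome_model`` evaluated on the oocyte's true features.  Same seed,
    same dataset.  Images are not rasterized here; each record stores its
    ``phantom_seed`` and ``truth`` so :func:`render_labels` /
    :func:`render_image` reproduce them on demand.
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    spec = spec or PhantomSpec()
    spec.validate()
    outcome_model = outcome_model if outcome_model is not None else default_outcome_model()
    cohort_size_distribution = cohort_size_distribution or _default_cohort_sizes
    age_distribution = age_distribution or _default_ages

    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    records: list[OocyteRecord] = []
    oocyte_counter = 0
    for p in range(n_patients):
        patient_id = f"P{p:05d}"
        clinic = clinics[int(rng.integers(len(clinics)))]
        age = int(age_distribution(rng))
        n_cycles = 1 + int(rng.choice(len(_CYCLE_COUNT_P), p=_CYCLE_COUNT_P))
        for c in range(n_cycles):
            cycle_id = f"{patient_id}C{c}"
            n_oocytes = int(cohort_size_distribution(rng))
            if n_oocytes < 1:
                raise ValueError(f"empty cohort generated for cycle {cycle_id}")
            for _ in range(n_oocytes):
                oseed = int(rng.integers(0, 2**31 - 1))
                orng = np.random.default_rng(oseed)
                truth = _sample_geometry(spec, orng)
                geoms = truth_geometry(truth)
                desc = shape_descriptors(geoms["ooplasm"])
                rel = relative_features(geoms)
                drivers = {
                    "oocyte_age": float(age),
                    "cohort_size": float(n_oocytes),
                    "ooplasm_roundness": desc.roundness,
                    "ooplasm_vs_pvs_area_ratio": rel["ooplasm_vs_pvs_area_ratio"],
                }
                p_true = outcome_model.probability(drivers)
                outcome = int(rng.uniform() < p_true)
                records.append(OocyteRecord(
                    oocyte_id=f"O{oocyte_counter:06d}",
                    patient_id=patient_id,
                    cycle_id=cycle_id,
                    clinic=clinic,
                    oocyte_age=age,
                    cohort_size=n_oocytes,
                    outcome=outcome,
                    true_probability=p_true,
                    geometry=geoms,
                    truth=truth,
                    phantom_seed=oseed,
                ))
                oocyte_counter += 1
    return records


def render_record(record: OocyteRecord, spec: PhantomSpec | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one record's stored geometry into (image, label_image).

    Identical to what :func:`generate_phantom` would produce for the
    record's ``phantom_seed`` because geometry draws precede noise draws.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(record.phantom_seed)
    _sample_geometry(spec, rng)  # advance the stream past the geometry draws
    labels = render_labels(record.truth, spec.image_size)
    image = render_image(labels, spec, rng)
    return image, labels
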