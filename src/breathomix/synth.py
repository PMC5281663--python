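"""Synthetic breath-measurement cohorts with the structure the pipeline assumes.

Real metal-oxide sensor conductance traces are smooth in temperature and
drift slowly over cycles; disease classes shift the redox response pattern;
individual devices differ by gain; and noise is multiplicative.  The
generator emulates exactly that statistical structure — a shared smooth
separable baseline surface, a per-class low-multilinear-rank perturbation
with configurable amplitude, per-serial log-normal device gains, and
element-wise log-normal noise — without simulating the chemistry of any
specific volatile compound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import (
    KNOWN_SERIALS,
    N_CYCLES,
    N_SENSORS,
    N_STEPS,
    TENSOR_SHAPE,
    Measurement,
    PatientMetadata,
)

__all__ = [
    "ClassSignature",
    "ClassDemographics",
    "CohortConfig",
    "build_signatures",
    "simulate_measurement",
    "generate_cohort",
    "permute_labels",
]


@dataclass(frozen=True)
class ClassDemographics:
    """Per-class metadata sampling distributions (defaults loosely follow the
    head-and-neck cancer cohort structure)."""

    age_mean: float = 65.0
    age_sd: float = 10.0
    male_fraction: float = 0.7
    food_intake_fraction: float = 0.3
    smoking_fraction: float = 0.5
    pack_years_mean: float = 25.0
    stage_probs: tuple[float, ...] = (0.05, 0.2, 0.2, 0.2, 0.35)


@dataclass
class CohortConfig:
    """Full description of a synthetic cohort; a pure function of this
    object (including ``seed``) determines every generated value."""

    class_sizes: Mapping[str, int]
    effect_amplitude: float = 0.15
    signature_ranks: tuple[int, int, int] = (1, 1, 1)
    device_spread: float = 0.10  # sd of log device gain
    noise_cv: float = 0.05
    serial_proportions: Mapping[int, float] | None = None
    demographics: Mapping[str, ClassDemographics] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.class_sizes:
            raise ValueError("at least one class required")
        for name, n in self.class_sizes.items():
            if int(n) <= 0:
                raise ValueError(f"class size for {name!r} must be a positive integer")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")
        if self.effect_amplitude < 0:
            raise ValueError("effect amplitude must be non-negative")
        if self.serial_proportions is None:
            self.serial_proportions = {s: 1.0 / len(KNOWN_SERIALS) for s in KNOWN_SERIALS}
        props = dict(self.serial_proportions)
        if any(s not in KNOWN_SERIALS for s in props):
            raise ValueError(f"serial proportions must use serials {KNOWN_SERIALS}")
        total = sum(props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"serial proportions must sum to 1, got {total}")
        if self.demographics is None:
            self.demographics = {name: ClassDemographics() for name in self.class_sizes}

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        d = json.loads(text)
        demo = d.pop("demographics", None)
        if demo is not None:
            demo = {
                k: ClassDemographics(**{**v, "stage_probs": tuple(v.get("stage_probs", ClassDemographics().stage_probs))})
                for k, v in demo.items()
            }
        if "signature_ranks" in d:
            d["signature_ranks"] = tuple(d["signature_ranks"])
        if "serial_proportions" in d and d["serial_proportions"] is not None:
            d["serial_proportions"] = {int(k): float(v) for k, v in d["serial_proportions"].items()}
        return cls(demographics=demo, **d)


@dataclass(frozen=True)
class ClassSignature:
    """Mean response surface (64 x 36 x 3 template) for one class."""

    label: str
    template: np.ndarray

    def __post_init__(self) -> None:
        if self.template.shape != TENSOR_SHAPE:
            raise ValueError(f"template shape {self.template.shape} != {TENSOR_SHAPE}")
        if np.any(self.template <= 0):
            raise ValueError(f"class template for {self.label!r} has non-positive entries")


def _baseline_surface() -> np.ndarray:
    """Shared smooth positive baseline: per sensor, a separable product of a
    low-order sinusoid in temperature step and a slow exponential drift in
    cycle, at sensor-specific gain."""
    steps = np.arange(N_STEPS)
    cycles = np.arange(N_CYCLES)
    base = np.empty(TENSOR_SHAPE)
    sensor_gain = (10.0, 14.0, 8.0)  # arbitrary conductance units
    for s in range(N_SENSORS):
        f = 1.0 + 0.3 * np.sin(np.pi * steps / (N_STEPS - 1) + 0.5 * s)
        g = 1.0 + 0.2 * np.exp(-cycles / 12.0) + 0.05 * np.cos(2 * np.pi * cycles / N_CYCLES)
        base[:, :, s] = sensor_gain[s] * np.outer(f, g)
    return base


def build_signatures(config: CohortConfig) -> dict[str, ClassSignature]:
    """One template per class: shared baseline plus a per-class multilinear
    perturbation of the configured ranks.

    One random rank-``signature_ranks`` perturbation pattern is drawn (shared
    factor matrices and core), normalized to unit peak magnitude, and each
    class adds it with a deterministic coefficient evenly spaced on [+1, -1]
    across classes times ``effect_amplitude`` times the baseline mean.
    Deterministic class coefficients make the amplitude a calibrated effect
    size (any two classes differ by at least 2/(K-1) x amplitude x baseline
    mean at the pattern peak), and peak normalization makes template
    positivity independent of the seed: the baseline surface is
    deterministic, so any amplitude below min(baseline)/mean(baseline)
    (about 0.4) is valid.  The difference between two class templates has
    multilinear rank at most ``signature_ranks``; amplitude 0 makes all
    templates identical.  Deterministic given the config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 101]))
    base = _baseline_surface()
    r1, r2, r3 = config.signature_ranks
    # Smooth shared factors (random low-order Fourier combinations).
    u = _smooth_factors(rng, N_STEPS, r1)
    v = _smooth_factors(rng, N_CYCLES, r2)
    w = rng.standard_normal((N_SENSORS, r3))
    core = rng.standard_normal((r1, r2, r3))
    pattern = np.einsum("abc,ia,jb,kc->ijk", core, u, v, w)
    peak = np.max(np.abs(pattern))
    pattern = pattern / peak if peak > 0 else np.zeros(TENSOR_SHAPE)
    scale = config.effect_amplitude * base.mean()

    labels = list(config.class_sizes)
    coeffs = (
        [1.0] if len(labels) == 1
        else [1.0 - 2.0 * k / (len(labels) - 1) for k in range(len(labels))]
    )
    signatures = {}
    for label, c in zip(labels, coeffs):
        template = base + c * scale * pattern
        if np.any(template <= 0):
            raise ValueError(
                f"effect amplitude {config.effect_amplitude} drives the template for "
                f"{label!r} non-positive; reduce the amplitude"
            )
        signatures[label] = ClassSignature(label=label, template=template)
    return signatures


def _smooth_factors(rng: np.random.Generator, n: int, r: int) -> np.ndarray:
    t = np.linspace(0, 1, n)
    cols = []
    for _ in range(r):
        coef = rng.standard_normal(4)
        col = (
            coef[0] * np.sin(np.pi * t)
            + coef[1] * np.cos(np.pi * t)
            + coef[2] * np.sin(2 * np.pi * t)
            + coef[3] * t
        )
        cols.append(col)
    return np.column_stack(cols)


def simulate_measurement(
    signature: ClassSignature,
    device_factor: float,
    noise_cv: float,
    seed: int | np.random.SeedSequence,
) -> np.ndarray:
    """Draw one measurement tensor: template x device gain x log-normal noise.

    The log-normal noise has unit mean (mu = -sigma^2/2 with
    sigma^2 = ln(1 + CV^2)), so the expected tensor equals
    template x device_factor at any CV.
    """
    if device_factor <= 0:
        raise ValueError("device factor must be positive")
    if noise_cv < 0:
        raise ValueError("noise CV must be non-negative")
    rng = np.random.default_rng(seed)
    tensor = signature.template * device_factor
    if noise_cv > 0:
        sigma2 = np.log1p(noise_cv**2)
        noise = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=TENSOR_SHAPE)
        tensor = tensor * noise
    return tensor


def _allocate_serials(n: int, proportions: Mapping[int, float]) -> list[int]:
    """Deterministic largest-remainder allocation of n patients to serials."""
    serials = sorted(proportions)
    quotas = [n * proportions[s] for s in serials]
    counts = [int(np.floor(q)) for q in quotas]
    leftover = n - sum(counts)
    remainders = sorted(
        range(len(serials)), key=lambda i: (-(quotas[i] - counts[i]), serials[i])
    )
    for i in remainders[:leftover]:
        counts[i] += 1
    out: list[int] = []
    for s, c in zip(serials, counts):
        out.extend([s] * c)
    return out


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[Measurement], list[PatientMetadata]]:
    """Generate a full cohort of measurements plus metadata.

    Patient ids are ``P0001``.. in class order; device serials are allocated
    deterministically by the configured proportions (largest remainder);
    per-device gains are a single log-normal draw per serial; metadata fields
    are sampled from the per-class demographic distributions.  The whole
    cohort is a pure function of the config, including its seed.
    """
    signatures = build_signatures(config)
    root = np.random.SeedSequence([int(config.seed), 202])
    device_ss, meta_ss, noise_ss = root.spawn(3)

    dev_rng = np.random.default_rng(device_ss)
    device_gain = {
        s: float(dev_rng.lognormal(mean=0.0, sigma=config.device_spread))
        for s in sorted(KNOWN_SERIALS)
    }
    meta_rng = np.random.default_rng(meta_ss)

    measurements: list[Measurement] = []
    metadata: list[PatientMetadata] = []
    counter = 0
    noise_children = iter(noise_ss.spawn(sum(int(n) for n in config.class_sizes.values())))
    for label, size in config.class_sizes.items():
        size = int(size)
        serials = _allocate_serials(size, config.serial_proportions)
        demo = config.demographics[label]
        for i in range(size):
            counter += 1
            pid = f"P{counter:04d}"
            serial = serials[i]
            tensor = simulate_measurement(
                signatures[label], device_gain[serial], config.noise_cv, next(noise_children)
            )
            measurements.append(
                Measurement(patient_id=pid, label=label, device_serial=serial, tensor=tensor)
            )
            stage_p = np.asarray(demo.stage_probs, dtype=float)
            stage_p = stage_p / stage_p.sum()
            metadata.append(
                PatientMetadata(
                    patient_id=pid,
                    label=label,
                    device_serial=serial,
                    age=float(np.round(meta_rng.normal(demo.age_mean, demo.age_sd), 1)),
                    sex="male" if meta_rng.random() < demo.male_fraction else "female",
                    food_intake_lt4h=bool(meta_rng.random() < demo.food_intake_fraction),
                    currently_smoking=bool(meta_rng.random() < demo.smoking_fraction),
                    pack_years=float(np.round(meta_rng.exponential(demo.pack_years_mean), 1)),
                    tumor_stage=int(meta_rng.choice(5, p=stage_p)),
                )
            )
    return measurements, metadata


def permute_labels(
    measurements: Sequence[Measurement],
    metadata: Sequence[PatientMetadata],
    seed: int,
) -> tuple[list[Measurement], list[PatientMetadata]]:
    """Randomly reassign the label multiset across patients (null model);
    tensors are untouched."""
    rng = np.random.default_rng(seed)
    labels = [m.label for m in measurements]
    perm = rng.permutation(len(labels))
    new_labels = [labels[i] for i in perm]
    meta_by_id = {p.patient_id: p for p in metadata}
    out_m, out_p = [], []
    for m, lbl in zip(measurements, new_labels):
        out_m.append(
            Measurement(
                patient_id=m.patient_id,
                label=lbl,
                device_serial=m.device_serial,
                tensor=m.tensor.copy(),
            )
        )
        p = meta_by_id[m.patient_id]
        out_p.append(
            PatientMetadata(
                patient_id=p.patient_id,
                label=lbl,
                device_serial=p.device_serial,
                age=p.age,
                sex=p.sex,
                food_intake_lt4h=p.food_intake_lt4h,
                currently_smoking=p.currently_smoking,
                pack_years=p.pack_years,
                tumor_stage=p.tumor_stage,
            )
        )
    return out_m, out_p
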