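"""Synthetic cohort and phantom generator.

Produces complete simulated studies — per-lesion ground-truth kinetics at
two visits, venous plasma samples, static-scan tissue concentrations, SUV
readings and small voxel phantoms — with the statistical structure the
analysis pipeline assumes, so every downstream stage can be validated
without real data.

Treatment effect is applied through the binding rate ``k3`` so that the
week-8 net clearance equals the baseline value times a drawn multiplier
(log-normal; medians ~1.9 for progressing and ~1.1 for non-progressing
patients).  A disease-burden knob optionally depresses the plasma input
function in proportion to the total skeletal flux, decoupling SUV from net
clearance the way a changing input function does in vivo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterator

import numpy as np
import pandas as pd

from petflux.errors import GeometryError, SpecError
from petflux.input_function import PopulationInputFunction, VenousSample
from petflux.kinetics import (
    RateConstants,
    TimeActivityCurve,
    macro_flux,
    patlak_fit,
    simulate_tissue_curve,
)

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "PatientVisitRecord",
    "Phantom",
    "generate_cohort",
    "generate_phantom",
]

VISITS = ("baseline", "week8")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated two-visit cohort.

    Log-normal distributions are parameterized by (median, log-space sigma);
    a sigma of 0 makes the draw degenerate at the median.
    """

    n_patients: int = 12
    pd_fraction: float = 4.0 / 12.0
    lesions_min: int = 1
    lesions_max: int = 8
    k1_median: float = 0.10
    k1_sigma: float = 0.25
    k2_median: float = 0.30
    k2_sigma: float = 0.20
    k3_median: float = 0.20
    k3_sigma: float = 0.30
    k4: float = 0.0
    pd_multiplier_median: float = 1.9
    pd_multiplier_sigma: float = 0.25
    non_pd_multiplier_median: float = 1.1
    non_pd_multiplier_sigma: float = 0.12
    flare_probability: float = 0.15
    venous_noise_cv: float = 0.05
    scan_noise_cv: float = 0.05
    injected_mean_MBq: float = 228.0
    injected_sd_MBq: float = 15.0
    weight_mean_kg: float = 70.0
    weight_sd_kg: float = 10.0
    burden_depression: float = 0.0
    blood_pool_fraction: float = 0.05
    suv_max_factor_low: float = 1.5
    suv_max_factor_high: float = 2.5
    volume_median_cm3: float = 6.0
    volume_sigma: float = 0.5
    scan_time_min: float = 60.0
    venous_times: tuple[float, float] = (55.0, 85.0)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise SpecError("n_patients must be >= 1")
        if not 0.0 <= self.pd_fraction <= 1.0:
            raise SpecError("pd_fraction must be in [0, 1]")
        if not 1 <= self.lesions_min <= self.lesions_max:
            raise SpecError("need 1 <= lesions_min <= lesions_max")
        for name in (
            "k1_median", "k2_median", "k3_median",
            "pd_multiplier_median", "non_pd_multiplier_median",
            "volume_median_cm3", "injected_mean_MBq", "weight_mean_kg",
        ):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be > 0")
        for name in (
            "k1_sigma", "k2_sigma", "k3_sigma", "k4",
            "pd_multiplier_sigma", "non_pd_multiplier_sigma",
            "venous_noise_cv", "scan_noise_cv", "injected_sd_MBq",
            "weight_sd_kg", "burden_depression", "volume_sigma",
        ):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be >= 0")
        if not 0.0 <= self.flare_probability <= 1.0:
            raise SpecError("flare_probability must be in [0, 1]")
        if not 0.0 <= self.blood_pool_fraction < 1.0:
            raise SpecError("blood_pool_fraction must be in [0, 1)")


@dataclass
class PatientVisitRecord:
    """One patient's data at one visit, as the analysis pipeline receives it."""

    patient_id: str
    visit: str
    injected_activity_MBq: float
    body_weight_kg: float
    venous_samples: list[VenousSample]
    lesions: pd.DataFrame
    reference: str | None = None


@dataclass
class SyntheticCohort:
    """Generated study: measurement tables plus the generating ground truth."""

    spec: CohortSpec
    seed: int
    patients: pd.DataFrame  # patient_id, visit, injected_MBq, weight_kg, reference
    lesions: pd.DataFrame  # patient_id, visit, lesion_id, c_bone, suv, volume
    venous: pd.DataFrame  # patient_id, visit, time_min, kBq_per_mL
    truth: pd.DataFrame  # per lesion-visit kinetic ground truth

    def visit_records(self) -> Iterator[PatientVisitRecord]:
        for (pid, visit), pat in self.patients.groupby(["patient_id", "visit"]):
            ven = self.venous[
                (self.venous["patient_id"] == pid) & (self.venous["visit"] == visit)
            ]
            yield PatientVisitRecord(
                patient_id=pid,
                visit=visit,
                injected_activity_MBq=float(pat["injected_MBq"].iloc[0]),
                body_weight_kg=float(pat["weight_kg"].iloc[0]),
                venous_samples=[
                    VenousSample(float(r.time_min), float(r.kBq_per_mL))
                    for r in ven.itertuples()
                ],
                lesions=self.lesions[
                    (self.lesions["patient_id"] == pid)
                    & (self.lesions["visit"] == visit)
                ].reset_index(drop=True),
                reference=str(pat["reference"].iloc[0]),
            )

    def to_csv(self, out_dir) -> dict[str, str]:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("patients", "lesions", "venous", "truth"):
            path = out / f"{name}.csv"
            frame = getattr(self, name).copy()
            frame.insert(0, "seed", self.seed)
            frame.to_csv(path, index=False)
            paths[name] = str(path)
        return paths


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    if sigma == 0.0:
        return median
    return float(rng.lognormal(math.log(median), sigma))


def _scaled_k3(rc: RateConstants, multiplier: float) -> float:
    """Binding rate giving ``multiplier`` times the baseline net clearance.

    The extraction fraction ``k3/(k2+k3)`` cannot reach 1, so the target is
    capped at 0.95 of the plasma clearance K1.
    """
    f = min(multiplier * macro_flux(rc) / rc.K1, 0.95)
    return rc.k2 * f / (1.0 - f)


def generate_cohort(
    spec: CohortSpec,
    seed: int,
    pop: PopulationInputFunction | None = None,
) -> SyntheticCohort:
    """Generate a deterministic synthetic two-visit cohort.

    The same ``(spec, seed, pop)`` always yields identical tables.  Ground
    truth per lesion-visit includes the rate constants, the true net
    clearance, the graphical intercept ``v0`` obtained by a dynamic fit of
    the noiseless curves, and the input-function scale actually applied.
    """
    rng = np.random.default_rng(seed)
    if pop is None:
        pop = PopulationInputFunction()
    T = spec.scan_time_min
    grid = np.arange(0.0, 90.0 + 1e-9, 0.1)
    pop_values = np.asarray(pop.curve(grid))

    n_pd = int(round(spec.n_patients * spec.pd_fraction))
    patient_rows, lesion_rows, venous_rows, truth_rows = [], [], [], []

    for p in range(spec.n_patients):
        is_pd = p < n_pd
        pid = f"P{p + 1:02d}"
        reference = "PD" if is_pd else "non-PD"
        weight = max(float(rng.normal(spec.weight_mean_kg, spec.weight_sd_kg)), 40.0)
        n_lesions = int(rng.integers(spec.lesions_min, spec.lesions_max + 1))
        base_scale = _lognormal(rng, 1.0, 0.10)

        lesions: list[dict] = []
        for j in range(n_lesions):
            rc0 = RateConstants(
                K1=_lognormal(rng, spec.k1_median, spec.k1_sigma),
                k2=_lognormal(rng, spec.k2_median, spec.k2_sigma),
                k3=_lognormal(rng, spec.k3_median, spec.k3_sigma),
                k4=spec.k4,
            )
            flare = (not is_pd) and (rng.random() < spec.flare_probability)
            if is_pd or flare:
                mult = _lognormal(
                    rng, spec.pd_multiplier_median, spec.pd_multiplier_sigma
                )
            else:
                mult = _lognormal(
                    rng, spec.non_pd_multiplier_median, spec.non_pd_multiplier_sigma
                )
            rc1 = replace(rc0, k3=_scaled_k3(rc0, mult))
            volume = _lognormal(rng, spec.volume_median_cm3, spec.volume_sigma)
            suv_max_factor = float(
                rng.uniform(spec.suv_max_factor_low, spec.suv_max_factor_high)
            )
            lesions.append(
                {
                    "lesion_id": f"{pid}-L{j + 1}",
                    "rc": {"baseline": rc0, "week8": rc1},
                    "multiplier": mult,
                    "flare": flare,
                    "volume": volume,
                    "suv_max_factor": suv_max_factor,
                }
            )

        for visit in VISITS:
            injected = max(
                float(rng.normal(spec.injected_mean_MBq, spec.injected_sd_MBq)), 1.0
            )
            total_flux = sum(macro_flux(l["rc"][visit]) for l in lesions)
            input_scale = base_scale * math.exp(
                -spec.burden_depression * total_flux
            )
            plasma = TimeActivityCurve(times=grid, values=input_scale * pop_values)
            cp_T = float(plasma.interp(T))

            patient_rows.append(
                {
                    "patient_id": pid,
                    "visit": visit,
                    "injected_MBq": injected,
                    "weight_kg": weight,
                    "reference": reference,
                }
            )
            for t_s in spec.venous_times:
                noise = _lognormal(rng, 1.0, spec.venous_noise_cv)
                venous_rows.append(
                    {
                        "patient_id": pid,
                        "visit": visit,
                        "time_min": t_s,
                        "kBq_per_mL": input_scale * float(pop.curve(t_s)) * noise,
                    }
                )
            for lesion in lesions:
                rc = lesion["rc"][visit]
                tissue = simulate_tissue_curve(rc, plasma, grid)
                c_bone_true = float(tissue.interp(T))
                slope, v0 = patlak_fit(tissue, plasma, t_star=10.0)
                c_bone = c_bone_true * _lognormal(rng, 1.0, spec.scan_noise_cv)
                c_image = c_bone + spec.blood_pool_fraction * cp_T
                suv_mean = c_image * weight / injected
                lesion_rows.append(
                    {
                        "patient_id": pid,
                        "visit": visit,
                        "lesion_id": lesion["lesion_id"],
                        "site": "metastasis",
                        "C_bone_T_kBq_mL": c_bone,
                        "suv_max": suv_mean * lesion["suv_max_factor"],
                        "suv_mean": suv_mean,
                        "volume_cm3": lesion["volume"],
                    }
                )
                truth_rows.append(
                    {
                        "patient_id": pid,
                        "visit": visit,
                        "lesion_id": lesion["lesion_id"],
                        "reference": reference,
                        "K1": rc.K1,
                        "k2": rc.k2,
                        "k3": rc.k3,
                        "k4": rc.k4,
                        "true_ki": macro_flux(rc),
                        "dynamic_ki": slope,
                        "v0": v0,
                        "c_bone_true": c_bone_true,
                        "input_scale": input_scale,
                        "multiplier": lesion["multiplier"],
                        "flare": lesion["flare"],
                    }
                )

    return SyntheticCohort(
        spec=spec,
        seed=seed,
        patients=pd.DataFrame(patient_rows),
        lesions=pd.DataFrame(lesion_rows),
        venous=pd.DataFrame(venous_rows),
        truth=pd.DataFrame(truth_rows),
    )


@dataclass
class Phantom:
    """Gaussian-blob voxel phantom with its analytic 40%-threshold level set."""

    image: np.ndarray
    seed_voxel: tuple[int, int, int]
    analytic_mask: np.ndarray
    peak: float
    sigma: float


def generate_phantom(
    peak: float,
    grid_shape: tuple[int, int, int] = (25, 25, 25),
    sigma: float = 3.0,
    background: float = 0.0,
    center: tuple[int, int, int] | None = None,
    threshold_fraction: float = 0.40,
) -> Phantom:
    """Isotropic Gaussian blob phantom on a zero (or constant) background.

    The analytic mask contains exactly the voxels whose blob value is at or
    above ``threshold_fraction`` of the peak, i.e. those within radius
    ``sigma * sqrt(2 * ln(1/threshold_fraction))`` of the center.

    Raises
    ------
    GeometryError
        If the blob (3 sigma radius) does not fit in the grid.
    """
    if peak <= 0:
        raise SpecError("peak must be > 0")
    if sigma <= 0:
        raise SpecError("sigma must be > 0")
    shape = tuple(int(s) for s in grid_shape)
    if center is None:
        center = tuple(s // 2 for s in shape)
    radius_fit = 3.0 * sigma
    for c, s in zip(center, shape):
        if c - radius_fit < 0 or c + radius_fit > s - 1:
            raise GeometryError(
                f"blob of radius {radius_fit:.1f} voxels at {center} exceeds "
                f"grid {shape}"
            )
    zz, yy, xx = np.indices(shape)
    r2 = (
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    ).astype(float)
    blob = peak * np.exp(-r2 / (2.0 * sigma * sigma))
    image = background + blob
    r_thresh = sigma * math.sqrt(2.0 * math.log(1.0 / threshold_fraction))
    analytic_mask = r2 <= r_thresh * r_thresh
    return Phantom(
        image=image,
        seed_voxel=center,
        analytic_mask=analytic_mask,
        peak=peak,
        sigma=sigma,
    )
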