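"""Synthetic study cohorts with the ligation-model structure.

Draws per-animal Doppler metrics around published group means +/- SEM
(four groups: sham/ligated x 1/2 weeks, left and right carotid), builds
per-animal phantom specs whose ligated/sham wall-modulus ratio equals the
prescribed fold change (2x at 1 week, 3x at 2 weeks), and emits
per-artery histology area profiles in which the intima is unmeasurable
(missing) in non-ligated arteries and thick in the ligated left carotid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from vasoelast.histology import SectionAreas
from vasoelast.phantom import IntimaSpec, PhantomSpec

#: Published group-level Doppler metrics, mean and SEM per group
#: (heart rate beats/min, diameters mm, velocities mm/s, gradient mmHg,
#: VTI mm).  Keys: (arm, timepoint, artery).
REFERENCE_METRICS: dict[tuple[str, str, str], dict[str, tuple[float, float]]] = {
    ("sham", "1wk", "LCA"): {
        "heart_rate": (517, 6), "diastolic_diameter": (0.36, 0.02),
        "systolic_diameter": (0.30, 0.01), "edv": (74, 16), "psv": (597, 49),
        "mean_gradient": (0.42, 0.08), "vti": (20.6, 3.0),
    },
    ("ligated", "1wk", "LCA"): {
        "heart_rate": (514, 25), "diastolic_diameter": (0.48, 0.03),
        "systolic_diameter": (0.45, 0.03), "edv": (1, 0.0), "psv": (191, 30),
        "mean_gradient": (0.05, 0.01), "vti": (2.8, 0.3),
    },
    ("sham", "2wk", "LCA"): {
        "heart_rate": (541, 11), "diastolic_diameter": (0.38, 0.01),
        "systolic_diameter": (0.30, 0.0), "edv": (118, 12), "psv": (828, 89),
        "mean_gradient": (0.87, 0.18), "vti": (28.5, 2.7),
    },
    ("ligated", "2wk", "LCA"): {
        "heart_rate": (537, 6), "diastolic_diameter": (0.40, 0.04),
        "systolic_diameter": (0.38, 0.04), "edv": (2, 1), "psv": (216, 44),
        "mean_gradient": (0.06, 0.03), "vti": (4.1, 0.8),
    },
    ("sham", "1wk", "RCA"): {
        "heart_rate": (511, 11), "diastolic_diameter": (0.39, 0.02),
        "systolic_diameter": (0.30, 0.02), "edv": (95, 22), "psv": (807, 62),
        "mean_gradient": (0.78, 0.13), "vti": (26.3, 2.6),
    },
    ("ligated", "1wk", "RCA"): {
        "heart_rate": (528, 16), "diastolic_diameter": (0.51, 0.01),
        "systolic_diameter": (0.40, 0.01), "edv": (108, 16), "psv": (919, 135),
        "mean_gradient": (1.03, 0.27), "vti": (27.6, 2.9),
    },
    ("sham", "2wk", "RCA"): {
        "heart_rate": (546, 8), "diastolic_diameter": (0.43, 0.01),
        "systolic_diameter": (0.33, 0.01), "edv": (90, 12), "psv": (850, 51),
        "mean_gradient": (0.81, 0.10), "vti": (24.2, 1.6),
    },
    ("ligated", "2wk", "RCA"): {
        "heart_rate": (540, 8), "diastolic_diameter": (0.49, 0.03),
        "systolic_diameter": (0.39, 0.03), "edv": (86, 8), "psv": (887, 59),
        "mean_gradient": (0.89, 0.10), "vti": (26.5, 1.3),
    },
}

METRIC_NAMES = [
    "heart_rate", "diastolic_diameter", "systolic_diameter",
    "edv", "psv", "mean_gradient", "vti",
]


@dataclass
class GroupSpec:
    """One experimental arm x timepoint: sample size and per-metric
    per-artery (mean, SEM) generating parameters."""

    arm: str                 # "sham" | "ligated"
    timepoint: str           # "1wk" | "2wk"
    n: int
    metrics: dict[str, dict[str, tuple[float, float]]]  # artery -> metric -> (mean, sem)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        for artery in self.metrics.values():
            for name, (_, sem) in artery.items():
                if sem < 0:
                    raise ValueError(f"SEM of {name} must be >= 0")


@dataclass
class CohortSpec:
    """Generating parameters for a synthetic study.

    ``modulus_fold_change`` maps timepoint -> ligated/sham wall-modulus
    ratio (2x at 1 week, 3x at 2 weeks in the default study).
    ``sham_wall_modulus`` (18 kPa) is deliberately distinct from the
    20 kPa inversion trial solution so recovery never starts at truth.
    """

    groups: list[GroupSpec]
    modulus_fold_change: dict[str, float] = field(
        default_factory=lambda: {"1wk": 2.0, "2wk": 3.0}
    )
    sham_wall_modulus: float = 18.0      # kPa
    modulus_cv: float = 0.05             # animal-level lognormal spread
    noise_sd_fraction: float = 0.01      # displacement noise, fraction of peak
    mesh_density: float = 0.025          # mm
    seed: int = 0

    def __post_init__(self) -> None:
        for f in self.modulus_fold_change.values():
            if not f > 0:
                raise ValueError("fold change must be > 0")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise fraction must be >= 0")


def default_cohort_spec(
    n_override: int | None = None, seed: int = 0, timepoints: tuple[str, ...] = ("1wk", "2wk")
) -> CohortSpec:
    """The published study design: n=5 per arm (n=6 ligated at 2 weeks)."""
    sizes = {("sham", "1wk"): 5, ("ligated", "1wk"): 5,
             ("sham", "2wk"): 5, ("ligated", "2wk"): 6}
    groups = []
    for (arm, tp), n in sizes.items():
        if tp not in timepoints:
            continue
        metrics = {
            art: REFERENCE_METRICS[(arm, tp, art)] for art in ("LCA", "RCA")
        }
        groups.append(GroupSpec(arm, tp, n_override or n, metrics))
    return CohortSpec(groups=groups, seed=seed)


@dataclass
class CohortData:
    """Generated study tables: one metrics row per artery per animal,
    plus per-animal LCA phantom specs and per-artery histology areas."""

    metrics: pd.DataFrame
    phantoms: dict[str, PhantomSpec]          # animal id -> LCA phantom
    areas: dict[tuple[str, str], SectionAreas]  # (animal id, artery) -> profile
    spec: CohortSpec


def _histology_profile(
    rng: np.random.Generator,
    lumen_diameter_mm: float,
    ligated_lca: bool,
    stiffness_scale: float = 1.0,
) -> SectionAreas:
    """Area profile at 200-um stations over 2000 um of carotid length.

    Non-ligated arteries carry a missing (unmeasurable) intima; the
    ligated left carotid gets a thick neointima peaking mid-segment whose
    size scales with the animal's wall-stiffness deviation
    (``stiffness_scale``), reflecting intima-driven stiffening.
    """
    stations = np.arange(0.0, 2001.0, 200.0)
    r_lumen = lumen_diameter_mm * 1000.0 / 2.0  # um
    lumen = np.pi * r_lumen**2 * rng.normal(1.0, 0.05, stations.size).clip(0.7, 1.3)
    media_ring = np.pi * ((r_lumen + 40.0) ** 2 - r_lumen**2)
    media = media_ring * rng.normal(1.0, 0.05, stations.size).clip(0.7, 1.3)
    advent = media * rng.normal(1.3, 0.05, stations.size).clip(0.8, 2.0)
    if ligated_lca:
        bump = np.exp(-0.5 * ((stations - 800.0) / 600.0) ** 2)
        peak = media_ring * stiffness_scale * rng.normal(0.9, 0.05)
        intima = np.clip(peak, 0.05 * media_ring, None) * bump
        lumen = np.clip(lumen - 0.8 * intima, 0.1 * lumen, None)
    else:
        intima = np.full(stations.size, np.nan)
    return SectionAreas(
        stations_um=stations,
        areas_um2={"lumen": lumen, "intima": intima, "media": media, "adventitia": advent},
    )


def generate_cohort(spec: CohortSpec) -> CohortData:
    """Draw a complete synthetic study.

    Per-animal Doppler metrics are Normal(mean, SD) with SD = SEM * sqrt(n)
    of the source group.  Ligated-arm LCA wall moduli are the sham modulus
    times the timepoint's fold change (up to the animal-level lognormal
    spread, which is mean-preserving).  Fully reproducible from the seed.
    """
    root = np.random.SeedSequence(spec.seed)
    rows = []
    phantoms: dict[str, PhantomSpec] = {}
    areas: dict[tuple[str, str], SectionAreas] = {}
    base = PhantomSpec()

    for g_idx, group in enumerate(spec.groups):
        g_seed = np.random.SeedSequence(entropy=root.entropy, spawn_key=(g_idx,))
        rng = np.random.default_rng(g_seed)
        fold = spec.modulus_fold_change[group.timepoint]
        for i in range(group.n):
            animal = f"{group.arm}-{group.timepoint}-{i + 1:02d}"
            ligated = group.arm == "ligated"
            # mean-preserving lognormal animal spread
            sigma = np.sqrt(np.log1p(spec.modulus_cv**2))
            jitter = rng.lognormal(-0.5 * sigma**2, sigma)
            e_wall = spec.sham_wall_modulus * (fold if ligated else 1.0) * jitter
            phantom_seed = int(rng.integers(0, 2**31 - 1))
            phantoms[animal] = replace(
                base,
                region_moduli={"wall": float(e_wall)},
                mesh_density=spec.mesh_density,
                seed=phantom_seed,
            )
            for artery in ("LCA", "RCA"):
                draws = {}
                for name in METRIC_NAMES:
                    mean, sem = group.metrics[artery][name]
                    sd = sem * np.sqrt(group.n)
                    draws[name] = rng.normal(mean, sd)
                draws["psv"] = max(draws["psv"], 1.0)
                draws["edv"] = float(np.clip(draws["edv"], 0.0, draws["psv"]))
                for d in ("diastolic_diameter", "systolic_diameter"):
                    draws[d] = max(draws[d], 0.05)
                draws["vti"] = max(draws["vti"], 0.1)
                draws["heart_rate"] = max(draws["heart_rate"], 300.0)
                # per-beat VTI and heart rate imply the cycle-averaged velocity
                draws["ta_mean_velocity"] = draws["vti"] * draws["heart_rate"] / 60.0
                rows.append(
                    {
                        "animal": animal,
                        "arm": group.arm,
                        "timepoint": group.timepoint,
                        "artery": artery,
                        "group": f"{group.arm}-{group.timepoint}",
                        "wall_modulus_true_kpa": float(e_wall) if artery == "LCA" else np.nan,
                        **draws,
                    }
                )
                areas[(animal, artery)] = _histology_profile(
                    rng,
                    draws["diastolic_diameter"],
                    ligated and artery == "LCA",
                    stiffness_scale=float(e_wall / (spec.sham_wall_modulus * fold)),
                )
    metrics = pd.DataFrame(rows)
    dup = metrics.duplicated(subset=["animal", "artery", "timepoint"])
    if dup.any():
        raise ValueError("duplicated animal-artery-timepoint keys")
    return CohortData(metrics=metrics, phantoms=phantoms, areas=areas, spec=spec)
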