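"""Synthetic per-cell intensity cohorts.

No raw per-cell intensities from the original imaging study are publicly
available, so every downstream stage is developed and tested against
synthetic cohorts that reproduce the statistical structure the analysis
assumes:

* channel intensities are right-skewed on a 12-bit (0–4095) scale and are
  modelled as multivariate log-normal within each (pathological class,
  tissue compartment) stratum;
* cancer-like cells differ from benign cells in a fixed direction per marker
  (Panel I: DAPI and AMACR up, 5mC and 5hmC down; Panel II: H3K9me3 and
  nuclear AR up, SAFB and H3K27me3 down), with the effect strongest in pure
  epithelium and absent in pure stroma;
* cohorts are organised as patients x specimen phases x cells, mirroring a
  longitudinal biopsy/prostatectomy design.

Effect magnitudes are package defaults (documented in docs/methods.md), not
measured values: the source study reports directions and significance, not
per-class channel means.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    CellTable,
    ConfigurationError,
    DefinitionError,
    GLEASON_GROUPS,
    PANEL_I,
    PANEL_II,
    PATH_CATEGORIES,
    COMPARTMENTS,
)

__all__ = [
    "ClassProfile",
    "CohortConfig",
    "profile_from_effects",
    "generate_cohort",
    "default_profiles",
    "default_cohort_config",
    "null_cohort_config",
    "culture_cohort_config",
    "generate_logistic_table",
    "largest_remainder_counts",
    "PANEL_I_BASELINE_LOG_MEAN",
    "PANEL_I_CANCER_EFFECT",
    "PANEL_II_BASELINE_LOG_MEAN",
    "PANEL_II_CANCER_EFFECT",
    "CLASS_SEVERITY",
    "COMPARTMENT_ATTENUATION",
]

# ---------------------------------------------------------------------------
# profiles


@dataclass(frozen=True)
class ClassProfile:
    """Log-normal intensity model for one (class, compartment) stratum.

    ``log_mean``/``log_cov`` parameterise the natural-log intensities;
    ``cell_fraction`` is the expected share of a specimen's cells drawn from
    this stratum.
    """

    path_category: str
    gleason_group: str
    compartment: str
    log_mean: tuple[float, ...]
    log_cov: tuple[tuple[float, ...], ...]
    cell_fraction: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "log_mean", tuple(float(x) for x in self.log_mean))
        object.__setattr__(
            self, "log_cov", tuple(tuple(float(x) for x in row) for row in self.log_cov)
        )
        if self.path_category not in PATH_CATEGORIES:
            raise DefinitionError(f"unknown path_category {self.path_category!r}")
        if self.gleason_group not in GLEASON_GROUPS:
            raise DefinitionError(f"unknown gleason_group {self.gleason_group!r}")
        if self.compartment not in COMPARTMENTS:
            raise DefinitionError(f"unknown compartment {self.compartment!r}")
        cov = self.cov_array
        if cov.shape != (len(self.log_mean), len(self.log_mean)):
            raise DefinitionError("log_cov shape does not match log_mean length")
        if not np.allclose(cov, cov.T):
            raise DefinitionError("log_cov must be symmetric")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise DefinitionError("log_cov must be positive definite") from exc
        if not 0.0 <= self.cell_fraction <= 1.0:
            raise DefinitionError(f"cell_fraction {self.cell_fraction} outside [0, 1]")

    @property
    def mean_array(self) -> np.ndarray:
        return np.asarray(self.log_mean, dtype=float)

    @property
    def cov_array(self) -> np.ndarray:
        return np.asarray(self.log_cov, dtype=float)


def profile_from_effects(
    baseline: ClassProfile,
    log_fold_changes: Sequence[float],
    **overrides,
) -> ClassProfile:
    """Shift a baseline profile's log-means by per-marker log fold changes.

    Convenience for encoding directional class effects: the returned profile
    has ``log_mean = baseline.log_mean + log_fold_changes`` and the same
    covariance. Keyword overrides (``path_category``, ``gleason_group``,
    ``compartment``, ``cell_fraction``) relabel the result.
    """
    shifts = np.asarray(log_fold_changes, dtype=float)
    if shifts.shape != (len(baseline.log_mean),):
        raise DefinitionError(
            f"expected {len(baseline.log_mean)} log fold changes, got shape {shifts.shape}"
        )
    return replace(
        baseline,
        log_mean=tuple(baseline.mean_array + shifts),
        **overrides,
    )


# ---------------------------------------------------------------------------
# cohort configuration


@dataclass(frozen=True)
class CohortConfig:
    """Full description of a synthetic cohort; fixed seed => identical table."""

    marker_names: tuple[str, ...]
    patients: tuple[str, ...]
    phases: tuple[str, ...]
    cells_per_specimen: int
    profiles: tuple[ClassProfile, ...]
    intensity_scale: float = 4095.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_names", tuple(self.marker_names))
        object.__setattr__(self, "patients", tuple(self.patients))
        object.__setattr__(self, "phases", tuple(self.phases))
        object.__setattr__(self, "profiles", tuple(self.profiles))
        if self.cells_per_specimen < 1:
            raise ConfigurationError("cells_per_specimen must be >= 1")
        if not self.profiles:
            raise ConfigurationError("at least one profile is required")
        p = len(self.marker_names)
        for prof in self.profiles:
            if len(prof.log_mean) != p:
                raise ConfigurationError(
                    "profile dimensionality does not match marker_names"
                )
        total = sum(prof.cell_fraction for prof in self.profiles)
        if abs(total - 1.0) > 1e-8:
            raise ConfigurationError(f"profile cell_fractions sum to {total}, not 1")


def largest_remainder_counts(fractions: Sequence[float], total: int) -> np.ndarray:
    """Deterministic integer allocation of ``total`` by largest remainder.

    Guarantees the counts sum to ``total`` and each count is within one of
    ``fraction * total``.
    """
    fractions = np.asarray(fractions, dtype=float)
    raw = fractions * total
    counts = np.floor(raw).astype(int)
    shortfall = total - counts.sum()
    if shortfall > 0:
        remainders = raw - counts
        # stable tie-break: larger remainder first, then input order
        order = np.lexsort((np.arange(len(fractions)), -remainders))
        counts[order[:shortfall]] += 1
    return counts


_FRAMES_PER_SPECIMEN_CELLS = 250  # synthetic frame granularity


def generate_cohort(config: CohortConfig) -> CellTable:
    """Sample a synthetic cohort.

    For every patient x phase specimen, cells are allocated to profiles by
    deterministic largest-remainder rounding of the configured fractions, then
    drawn as multivariate normals in log-intensity space and exponentiated.
    Values above the 12-bit ceiling are clipped to ``intensity_scale`` and the
    affected cells flagged; exponentiation keeps every intensity > 0.
    """
    rng = np.random.default_rng(config.seed)
    fractions = [prof.cell_fraction for prof in config.profiles]
    rows: list[pd.DataFrame] = []
    for patient in config.patients:
        for phase in config.phases:
            counts = largest_remainder_counts(fractions, config.cells_per_specimen)
            blocks = []
            for prof, n in zip(config.profiles, counts):
                if n == 0:
                    continue
                draws = rng.multivariate_normal(
                    prof.mean_array, prof.cov_array, size=n, method="cholesky"
                )
                intensities = np.exp(draws)
                clipped = (intensities > config.intensity_scale).any(axis=1)
                intensities = np.minimum(intensities, config.intensity_scale)
                block = pd.DataFrame(intensities, columns=list(config.marker_names))
                block["compartment"] = prof.compartment
                block["path_category"] = prof.path_category
                block["gleason_group"] = prof.gleason_group
                block["clipped"] = clipped
                blocks.append(block)
            spec = pd.concat(blocks, ignore_index=True)
            n_spec = len(spec)
            spec.insert(0, "cell_id", [f"c{i:07d}" for i in range(n_spec)])
            spec.insert(1, "patient_id", patient)
            spec.insert(2, "phase", phase)
            spec.insert(
                3,
                "frame_id",
                [
                    f"{patient}:{phase}:f{i // _FRAMES_PER_SPECIMEN_CELLS:03d}"
                    for i in range(n_spec)
                ],
            )
            rows.append(spec)
    data = pd.concat(rows, ignore_index=True)
    cols = [
        "cell_id",
        "patient_id",
        "phase",
        "frame_id",
        "compartment",
        "path_category",
        "gleason_group",
    ] + list(config.marker_names) + ["clipped"]
    return CellTable(
        data[cols],
        config.marker_names,
        {"source": "synthetic", "seed": config.seed},
    )


# ---------------------------------------------------------------------------
# default study-like configuration

#: Baseline (benign epithelium) natural-log intensity means on the 12-bit
#: scale; geometric means ~ 900 (DAPI), 245 (AMACR), 490 (5mC), 365 (5hmC).
PANEL_I_BASELINE_LOG_MEAN = (6.8, 5.5, 6.2, 5.9)

#: Cancer-vs-benign log fold changes for Panel I (DAPI, AMACR, 5mC, 5hmC):
#: DNA content and AMACR rise while both epigenetic cytosine modifications
#: are lost.
PANEL_I_CANCER_EFFECT = (0.35, 0.5, -0.8, -0.6)

PANEL_II_BASELINE_LOG_MEAN = (6.8, 5.8, 6.0, 6.1, 5.4)

#: Panel II (DAPI, SAFB, H3K9me3, H3K27me3, nAR): heterochromatin mark
#: H3K9me3 and nuclear androgen receptor rise; SAFB and H3K27me3 fall.
PANEL_II_CANCER_EFFECT = (0.35, -0.5, 0.6, -0.6, 0.7)

#: Multiplier applied to the cancer effect vector per pathological class,
#: ordered by increasing severity.
CLASS_SEVERITY = {
    "B": 0.0,
    "ASAP": 0.3,
    "AC": 1.0,
    "LAC": 1.3,
    "StageII": 1.5,
    "StageIII": 1.8,
}

#: Class separation shrinks with stromal content and vanishes in pure stroma,
#: where the markers showed no significant covariation with disease.
COMPARTMENT_ATTENUATION = {"E": 1.0, "E+s": 0.7, "ES": 0.35, "S": 0.0}

#: Compartment shares of imaged cells (epithelial share matches the
#: 17,881 / 139,165 development proportion).
_COMPARTMENT_MIX = {"E": 0.13, "E+s": 0.22, "ES": 0.38, "S": 0.27}

#: Class mix within each compartment; the benign share of epithelium mirrors
#: the 3,829 / 17,881 development proportion.
_CLASS_MIX = {
    "B": 0.21,
    "ASAP": 0.12,
    "AC": 0.20,
    "LAC": 0.22,
    "StageII": 0.13,
    "StageIII": 0.12,
}

_CLASS_TO_GLEASON = {
    "B": "B",
    "ASAP": "unknown",
    "AC": "G33",
    "LAC": "G43",
    "StageII": "G34",
    "StageIII": "G34",
}

_LOG_SD = 0.5
_LOG_CORR = 0.3


def _default_cov(p: int, sd: float = _LOG_SD, corr: float = _LOG_CORR) -> np.ndarray:
    cov = np.full((p, p), corr * sd * sd)
    np.fill_diagonal(cov, sd * sd)
    return cov


def _panel(panel: str) -> tuple[tuple[str, ...], np.ndarray, np.ndarray]:
    if panel == "I":
        return PANEL_I, np.array(PANEL_I_BASELINE_LOG_MEAN), np.array(PANEL_I_CANCER_EFFECT)
    if panel == "II":
        return PANEL_II, np.array(PANEL_II_BASELINE_LOG_MEAN), np.array(PANEL_II_CANCER_EFFECT)
    raise DefinitionError(f"unknown panel {panel!r} (expected 'I' or 'II')")


def default_profiles(
    panel: str = "I",
    effect_scale: float = 1.0,
    compartment_mix: Mapping[str, float] | None = None,
    class_mix: Mapping[str, float] | None = None,
) -> tuple[ClassProfile, ...]:
    """Study-like profile grid over classes x tissue compartments.

    ``effect_scale`` multiplies every class effect; 0 gives the null cohort in
    which all strata share one distribution.
    """
    markers, baseline, effect = _panel(panel)
    comp_mix = dict(_COMPARTMENT_MIX if compartment_mix is None else compartment_mix)
    cls_mix = dict(_CLASS_MIX if class_mix is None else class_mix)
    cov = _default_cov(len(markers))
    profiles = []
    for comp, comp_frac in comp_mix.items():
        atten = COMPARTMENT_ATTENUATION[comp]
        for cls, cls_frac in cls_mix.items():
            shift = effect * CLASS_SEVERITY[cls] * atten * effect_scale
            profiles.append(
                ClassProfile(
                    path_category=cls,
                    gleason_group=_CLASS_TO_GLEASON[cls],
                    compartment=comp,
                    log_mean=tuple(baseline + shift),
                    log_cov=tuple(map(tuple, cov)),
                    cell_fraction=comp_frac * cls_frac,
                )
            )
    return tuple(profiles)


def default_cohort_config(
    panel: str = "I",
    n_patients: int = 5,
    phases: Sequence[str] = ("biopsy1", "prostatectomy"),
    cells_per_specimen: int = 2000,
    seed: int = 0,
    effect_scale: float = 1.0,
) -> CohortConfig:
    """Scaled-down study-like cohort (default 5 patients, 2 phases)."""
    markers, _, _ = _panel(panel)
    return CohortConfig(
        marker_names=markers,
        patients=tuple(f"P{i + 1}" for i in range(n_patients)),
        phases=tuple(phases),
        cells_per_specimen=cells_per_specimen,
        profiles=default_profiles(panel, effect_scale=effect_scale),
        seed=seed,
    )


def null_cohort_config(
    panel: str = "I",
    n_patients: int = 5,
    phases: Sequence[str] = ("biopsy1", "prostatectomy"),
    cells_per_specimen: int = 2000,
    seed: int = 0,
) -> CohortConfig:
    """Cohort with all class profiles identical (no signal anywhere)."""
    return default_cohort_config(
        panel=panel,
        n_patients=n_patients,
        phases=phases,
        cells_per_specimen=cells_per_specimen,
        seed=seed,
        effect_scale=0.0,
    )


def culture_cohort_config(
    kind: str,
    n_cells: int = 2000,
    panel: str = "I",
    seed: int = 0,
) -> CohortConfig:
    """Cultured-cell validation specimen: a single profile, compartment NA.

    ``kind='normal_primary'`` emulates primary normal prostate epithelial
    cells (benign baseline); ``kind='cancer_line'`` emulates an established
    adenocarcinoma cell line (strong cancer effect).
    """
    markers, baseline, effect = _panel(panel)
    cov = _default_cov(len(markers))
    if kind == "normal_primary":
        cls, gs, shift = "B", "B", np.zeros(len(markers))
    elif kind == "cancer_line":
        cls, gs, shift = "AC", "G34", effect * 1.6
    else:
        raise DefinitionError(f"unknown culture kind {kind!r}")
    profile = ClassProfile(
        path_category=cls,
        gleason_group=gs,
        compartment="NA",
        log_mean=tuple(baseline + shift),
        log_cov=tuple(map(tuple, cov)),
        cell_fraction=1.0,
    )
    return CohortConfig(
        marker_names=markers,
        patients=(kind,),
        phases=("culture",),
        cells_per_specimen=n_cells,
        profiles=(profile,),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# logistic-truth simulation (for parameter-recovery calibration)


def generate_logistic_table(
    beta: Sequence[float],
    n_cells: int,
    marker_names: Sequence[str] = PANEL_I,
    log_mean: Sequence[float] | None = None,
    log_cov: np.ndarray | None = None,
    seed: int = 0,
) -> CellTable:
    """Cohort whose aberrant/benign labels follow an exact logistic law.

    Log intensities are drawn multivariate normal; each cell's outcome is
    Bernoulli with log-odds ``beta[0] + beta[1:] . x``. The returned table is
    already on the log scale (it *is* the model's design matrix), so the fit
    of the logistic stage targets exactly the ``beta`` used here. Used for
    parameter-recovery calibration of the estimator.
    """
    beta = np.asarray(beta, dtype=float)
    p = len(marker_names)
    if beta.shape != (p + 1,):
        raise DefinitionError(f"beta must have length {p + 1} (intercept first)")
    mean = (
        np.asarray(log_mean, dtype=float)
        if log_mean is not None
        else np.array(PANEL_I_BASELINE_LOG_MEAN[:p])
    )
    cov = np.asarray(log_cov, dtype=float) if log_cov is not None else _default_cov(p)
    rng = np.random.default_rng(seed)
    x = rng.multivariate_normal(mean, cov, size=n_cells, method="cholesky")
    eta = beta[0] + x @ beta[1:]
    prob = 1.0 / (1.0 + np.exp(-eta))
    aberrant = rng.random(n_cells) < prob
    df = pd.DataFrame(x, columns=list(marker_names))
    df.insert(0, "cell_id", [f"c{i:07d}" for i in range(n_cells)])
    df.insert(1, "patient_id", "SIM")
    df.insert(2, "phase", "biopsy1")
    df.insert(3, "frame_id", "SIM:f000")
    df.insert(4, "compartment", "E")
    df.insert(5, "path_category", np.where(aberrant, "AC", "B"))
    df.insert(6, "gleason_group", np.where(aberrant, "G33", "B"))
    return CellTable(
        df,
        tuple(marker_names),
        {
            "source": "synthetic-logistic",
            "seed": seed,
            "log_transformed": True,
            "truth_beta": [float(b) for b in beta],
        },
    )
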