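"""Synthetic cohorts with the structure the distance method assumes.

The generator emulates a multi-group expression study: a homeostatic
baseline profile, group centroids displaced from it, samples scattered
around their centroid, and (optionally) survival times linearly coupled
to each sample's distance from the normal center.

Model
-----
* The baseline centroid b is per-gene log-normal: log b_i ~ N(base_log_mean,
  base_log_sd²) — right-skewed positive values like normalized expression.
* Each group's centroid is the baseline displaced in LOG space along a
  random (seed-fixed) unit direction u: c = b ⊙ exp(drift · u).  ``drift``
  is thus the Euclidean norm of the log-space displacement, so no gene
  subset is privileged and values stay positive without clipping.  The
  normal group uses drift 0.
* Samples are the centroid with multiplicative log-normal noise:
  x = c ⊙ exp(ε), ε_i ~ N(0, dispersion²) per gene.  ``dispersion`` is
  the per-gene log-sd, so the drift/dispersion ratio is a signal-to-noise
  ratio that does not depend on the gene count.
* Survival: days = intercept + slope · r_normal + N(0, noise_sd),
  truncated at 0, where r_normal is the sample's distance to the normal
  center under the chosen metric.

Everything is driven by one integer seed; the same seed reproduces the
cohort byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateDataError
from .io import ExpressionMatrix, SampleMetadata

#: glioma-like survival line: days lost per unit cosine distance
DEFAULT_SURVIVAL_SLOPE = -1.35e4
DEFAULT_SURVIVAL_INTERCEPT = 1.94e3
#: fraction of survival variance the distance explains by default
DEFAULT_SURVIVAL_R2 = 0.09


@dataclass(frozen=True)
class GroupDesign:
    """One sample group: label, size, log-space drift and dispersion."""

    label: str
    n_samples: int
    drift: float
    dispersion: float

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError(f"group {self.label!r}: n_samples >= 1 required")
        if self.drift < 0:
            raise ConfigurationError(f"group {self.label!r}: drift must be >= 0")
        if self.dispersion <= 0:
            raise ConfigurationError(f"group {self.label!r}: dispersion must be > 0")


@dataclass(frozen=True)
class SimulationDesign:
    """Full description of a synthetic cohort.

    Defaults mirror a small paired oncology design: three groups (normal
    tissue, primary tumor, metastasis) of 8 samples each, tumor groups
    drifted away from the baseline, moderate biological dispersion.
    """

    n_genes: int = 1000
    groups: tuple[GroupDesign, ...] = (
        GroupDesign("normal", 8, 0.0, 0.05),
        GroupDesign("tumor", 8, 1.0, 0.10),
        GroupDesign("metastasis", 8, 0.8, 0.10),
    )
    base_log_mean: float = 3.0
    base_log_sd: float = 1.0
    survival_slope: float = DEFAULT_SURVIVAL_SLOPE
    survival_intercept: float = DEFAULT_SURVIVAL_INTERCEPT
    #: None = calibrate so the population R² equals DEFAULT_SURVIVAL_R2
    survival_noise_sd: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if not self.groups:
            raise ConfigurationError("at least one group is required")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"duplicate group labels: {labels}")
        if self.survival_noise_sd is not None and self.survival_noise_sd < 0:
            raise ConfigurationError("survival_noise_sd must be >= 0")

    def with_seed(self, seed: int) -> "SimulationDesign":
        return replace(self, seed=int(seed))


def generate_cohort(design: SimulationDesign) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Draw one cohort: expression matrix plus group metadata.

    Draw order (baseline, then per-group direction and noise) does not
    depend on the drift/dispersion values, so cohorts generated from the
    same seed but different drifts share their random numbers — useful
    for drift-response studies with common random numbers.
    """
    rng = np.random.default_rng(design.seed)
    p = design.n_genes
    baseline = np.exp(rng.normal(design.base_log_mean, design.base_log_sd, size=p))

    gene_ids = [f"g{i:05d}" for i in range(p)]
    cols: dict[str, np.ndarray] = {}
    labels: list[str] = []
    for g in design.groups:
        u = rng.normal(size=p)
        u /= np.linalg.norm(u)
        centroid = baseline * np.exp(g.drift * u)
        noise = rng.normal(0.0, g.dispersion, size=(p, g.n_samples))
        X = centroid[:, None] * np.exp(noise)
        for j in range(g.n_samples):
            sid = f"{g.label}_{j:03d}"
            cols[sid] = X[:, j]
            labels.append(g.label)

    values = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    matrix = ExpressionMatrix(
        values, transform_log="none",
        provenance=[f"synthetic cohort (seed={design.seed}, "
                    f"{p} genes, {len(labels)} samples)"],
    )
    meta = SampleMetadata(
        pd.DataFrame({"group": labels},
                     index=pd.Index(values.columns, name="sample_id"))
    )
    return matrix, meta


def noise_sd_for_r_squared(
    slope: float, distances: Sequence[float], r_squared: float
) -> float:
    """Noise sd making the population R² of the survival line equal
    ``r_squared`` given the realized distance spread.

    R² = s²·Var(r) / (s²·Var(r) + σ²), hence
    σ = |s|·sd(r)·sqrt((1 − R²)/R²).
    """
    if not (0.0 < r_squared < 1.0):
        raise ConfigurationError("target r_squared must be in (0, 1)")
    sd_r = float(np.std(np.asarray(distances, dtype=float)))
    if sd_r == 0.0:
        raise DegenerateDataError("distances have zero spread")
    return abs(slope) * sd_r * np.sqrt((1.0 - r_squared) / r_squared)


def attach_survival(
    metadata: SampleMetadata,
    profiles: pd.DataFrame,
    design: SimulationDesign,
    normal_label: str = "normal",
    only_groups: Optional[Sequence[str]] = None,
) -> SampleMetadata:
    """Plant survival times linearly coupled to distance-from-normal.

    ``profiles`` must contain a column for the normal center.  Survival
    is drawn for every sample (or only for ``only_groups`` if given),
    truncated at 0 days, with its own deterministic substream of the
    design seed so expression and survival draws never interleave.

    When the design leaves ``survival_noise_sd`` unset, the noise is
    calibrated from the realized distance spread of the samples that
    receive survival so the population R² of the line equals
    DEFAULT_SURVIVAL_R2.
    """
    if normal_label not in profiles.columns:
        raise ConfigurationError(
            f"profiles lack a distance column for the normal center "
            f"{normal_label!r}; columns: {list(profiles.columns)}"
        )
    rng = np.random.default_rng([design.seed, 83])  # survival substream
    r = profiles[normal_label]
    if only_groups is not None:
        mask = metadata.groups.reindex(r.index).isin(set(only_groups))
    else:
        mask = pd.Series(True, index=r.index)
    noise_sd = design.survival_noise_sd
    if noise_sd is None:
        noise_sd = noise_sd_for_r_squared(
            design.survival_slope, r[mask], DEFAULT_SURVIVAL_R2)
    surv = (design.survival_intercept
            + design.survival_slope * r.to_numpy(dtype=float)
            + rng.normal(0.0, noise_sd, size=len(r)))
    surv = np.maximum(surv, 0.0)
    series = pd.Series(surv, index=profiles.index, name="survival_days")
    series = series.where(mask)
    return metadata.with_survival(series)


# ---------------------------------------------------------------------------
# ready-made designs
# ---------------------------------------------------------------------------

def three_group_design(
    n_per_group: int = 50,
    drift: float = 1.0,
    dispersion: float = 0.1,
    n_genes: int = 300,
    seed: int = 0,
) -> SimulationDesign:
    """Normal / low-grade / high-grade cohort: the normal group sits at the
    baseline and the two disease groups drift progressively farther."""
    return SimulationDesign(
        n_genes=n_genes,
        groups=(
            GroupDesign("normal", n_per_group, 0.0, dispersion),
            GroupDesign("lowgrade", n_per_group, drift, dispersion),
            GroupDesign("highgrade", n_per_group, 2.0 * drift, dispersion),
        ),
        seed=seed,
    )


def survival_design(
    n_tumor: int = 400,
    n_normal: int = 50,
    drift: float = 1.0,
    dispersion: float = 0.05,
    n_genes: int = 300,
    seed: int = 0,
    survival_noise_sd: Optional[float] = None,
) -> SimulationDesign:
    """Prognosis cohort: one large tumor group whose spread of distances
    to the normal center carries the planted survival signal."""
    return SimulationDesign(
        n_genes=n_genes,
        groups=(
            GroupDesign("normal", n_normal, 0.0, dispersion),
            GroupDesign("tumor", n_tumor, drift, dispersion),
        ),
        survival_noise_sd=survival_noise_sd,
        seed=seed,
    )
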