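"""Synthetic methylation cohorts with known, injected age acceleration.

The generative model is deliberately the simplest one the downstream
analysis assumes.  Each sample i in phenotype group g draws an individual
epigenetic acceleration ``accel_i ~ Normal(delta_g, accel_sd)`` (years); its
effective epigenetic age is ``age_i + accel_i``.  Probe j then reads

    beta_{j,i} = clip_[0,1]( b0_j + s_j * (age_i + accel_i)
                             + sex_effect_j * sex_i + eps_{j,i} ),

with independent Gaussian probe noise eps.  Betas drift linearly with age,
so a matched "toy clock" with weights ``1/(m s)`` and intercept ``-b0/s``
reads back the effective age exactly in the noise-free case, making the
injected group offsets directly comparable to clock residuals downstream.

Defaults mirror the cohort structure the pipeline targets: three groups of
99/132/84 samples (painful neuropathy, painless reference, healthy
controls), ages uniform on 41-84 years, and group offsets of +3 / 0 / -2
years.  Detection p-values are tiny except for sporadic injected failures,
exercising the QC stage.

Randomness comes from one seed per cohort; each sample gets its own
deterministically spawned substream, so adding samples or reordering probes
never perturbs the values of existing samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .clocks import ClockDefinition
from .errors import ConfigError
from .io import (
    BetaMatrix,
    DetectionPMatrix,
    SampleSheet,
    write_beta_matrix,
    write_clock_definition,
    write_detection_p_matrix,
    write_sample_sheet,
)

GENERATOR_VERSION = "1"


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the standard study conditions.

    ``baseline_beta`` and ``age_slope`` may be scalars (uniform across
    probes) or length-``n_cpgs`` arrays.  ``acceleration`` maps each group
    label to its mean epigenetic age offset in years.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"PDN": 99, "PLDN": 132, "CTRL": 84}
    )
    age_range: tuple[float, float] = (41.0, 84.0)
    male_fraction: float = 0.74
    n_cpgs: int = 50
    baseline_beta: float | np.ndarray = 0.2
    age_slope: float | np.ndarray = 0.005   # beta units per year
    sex_effect: float = 0.01                # beta units added for sex = 1
    acceleration: Mapping[str, float] = field(
        default_factory=lambda: {"PDN": 3.0, "PLDN": 0.0, "CTRL": -2.0}
    )
    accel_sd: float = 3.0                   # years, between-individual
    probe_noise_sd: float = 0.01            # beta units
    detp_fail_rate: float = 1e-4
    seed: int = 0

    def validate(self) -> None:
        if not self.n_per_group or any(n <= 0 for n in self.n_per_group.values()):
            raise ConfigError("n_per_group: every group needs a positive count")
        if self.n_cpgs < 4:
            raise ConfigError("n_cpgs must be >= 4")
        if self.accel_sd < 0 or self.probe_noise_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if not 0 <= self.male_fraction <= 1:
            raise ConfigError("male_fraction must lie in [0, 1]")
        if not 0 <= self.detp_fail_rate <= 1:
            raise ConfigError("detp_fail_rate must lie in [0, 1]")
        if self.age_range[0] >= self.age_range[1] or self.age_range[0] <= 0:
            raise ConfigError("age_range must be an increasing pair of positive years")
        if set(self.acceleration) != set(self.n_per_group):
            raise ConfigError("acceleration must map exactly the groups in n_per_group")

    def b0_array(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.baseline_beta, dtype=float),
                               (self.n_cpgs,)).copy()

    def slope_array(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.age_slope, dtype=float),
                               (self.n_cpgs,)).copy()

    def probe_ids(self) -> list[str]:
        return [f"cg{j:05d}" for j in range(self.n_cpgs)]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated cohort (what the pipeline should recover)."""

    acceleration: pd.Series          # per-sample true offset, years
    group_offsets: Mapping[str, float]
    seed: int
    generator_version: str
    clipped_fraction: float


def _mid_range_check(cfg: SimulationConfig) -> None:
    b0, s = cfg.b0_array(), cfg.slope_array()
    ages = np.array(cfg.age_range)
    offsets = np.array(list(cfg.acceleration.values()))
    lo = (b0[:, None] + s[:, None] * (ages.min() + offsets.min())).min()
    hi = (b0[:, None] + s[:, None] * (ages.max() + offsets.max())).max() + cfg.sex_effect
    if lo < 0.05 or hi > 0.95:
        warnings.warn(
            f"expected betas span [{lo:.3f}, {hi:.3f}], outside the [0.05, 0.95] "
            "mid-range; clipping will distort linearity",
            stacklevel=3,
        )


def generate_cohort(
    cfg: SimulationConfig,
) -> tuple[BetaMatrix, DetectionPMatrix, SampleSheet, SyntheticTruth]:
    """Draw a full synthetic cohort: betas, detection p-values, sheet, truth."""
    cfg.validate()
    _mid_range_check(cfg)
    b0, slope = cfg.b0_array(), cfg.slope_array()
    m = cfg.n_cpgs
    probe_ids = cfg.probe_ids()

    sample_ids, groups = [], []
    for g, n in cfg.n_per_group.items():
        for i in range(n):
            sample_ids.append(f"{g}_{i:03d}")
            groups.append(g)
    n_total = len(sample_ids)

    streams = np.random.SeedSequence(cfg.seed).spawn(n_total)
    betas = np.empty((m, n_total))
    detp = np.empty((m, n_total))
    ages = np.empty(n_total)
    sexes = np.empty(n_total, dtype=int)
    accel = np.empty(n_total)
    n_clipped = 0
    for i, (sid, g) in enumerate(zip(sample_ids, groups)):
        rng = np.random.default_rng(streams[i])
        ages[i] = rng.uniform(*cfg.age_range)
        sexes[i] = int(rng.random() < cfg.male_fraction)
        accel[i] = rng.normal(cfg.acceleration[g], cfg.accel_sd)
        eps = rng.normal(0.0, cfg.probe_noise_sd, m)
        raw = b0 + slope * (ages[i] + accel[i]) + cfg.sex_effect * sexes[i] + eps
        clipped = np.clip(raw, 0.0, 1.0)
        n_clipped += int(np.count_nonzero(clipped != raw))
        betas[:, i] = clipped
        base_p = rng.uniform(0.0, 1e-3, m)
        fails = rng.random(m) < cfg.detp_fail_rate
        base_p[fails] = rng.uniform(0.02, 0.5, int(fails.sum()))
        detp[:, i] = base_p

    beta_df = pd.DataFrame(betas, index=probe_ids, columns=sample_ids)
    detp_df = pd.DataFrame(detp, index=probe_ids, columns=sample_ids)
    sheet_df = pd.DataFrame(
        {"group": groups, "age": ages, "sex": sexes},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = SyntheticTruth(
        acceleration=pd.Series(accel, index=sample_ids, name="true_acceleration"),
        group_offsets=dict(cfg.acceleration),
        seed=cfg.seed,
        generator_version=GENERATOR_VERSION,
        clipped_fraction=n_clipped / (m * n_total),
    )
    return BetaMatrix(beta_df), DetectionPMatrix(detp_df), SampleSheet(sheet_df), truth


def generate_toy_clock(cfg: SimulationConfig, name: str = "toy_clock") -> ClockDefinition:
    """The clock matched to the generator: reads back effective age exactly.

    Requires uniform baseline and slope across probes.  With weights
    ``w_j = 1/(m s)`` and intercept ``-b0/s``, the identity
    ``sum_j w_j beta_{j,s} + intercept = age_s + accel_s`` holds exactly when
    probe noise and the sex effect are zero; a nonzero sex effect adds a
    constant ``sex_effect/s`` for sex = 1 samples, absorbed downstream by
    the sex covariate of the reference model.
    """
    b0, s = cfg.b0_array(), cfg.slope_array()
    if np.ptp(b0) != 0 or np.ptp(s) != 0:
        raise ConfigError("toy clock needs uniform baseline_beta and age_slope")
    if s[0] == 0:
        raise ConfigError("toy clock undefined for age_slope = 0")
    w = 1.0 / (cfg.n_cpgs * s[0])
    return ClockDefinition(
        name=name,
        intercept=float(-b0[0] / s[0]),
        weights={pid: float(w) for pid in cfg.probe_ids()},
        transform="identity",
        units="years",
    )


def write_cohort(cfg: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a cohort and emit it in the formats the loaders read.

    Writes beta.tsv, detection_p.tsv, samples.csv, truth.csv, and the toy
    clock (toy_clock.csv + toy_clock.json).  Returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    beta, detp, sheet, truth = generate_cohort(cfg)
    paths = {
        "beta": out / "beta.tsv",
        "detection_p": out / "detection_p.tsv",
        "samples": out / "samples.csv",
        "truth": out / "truth.csv",
        "clock": out / "toy_clock.csv",
    }
    write_beta_matrix(beta, paths["beta"])
    write_detection_p_matrix(detp, paths["detection_p"])
    write_sample_sheet(sheet, paths["samples"])
    truth_df = truth.acceleration.to_frame()
    truth_df["group_offset"] = [truth.group_offsets[g] for g in sheet.data["group"]]
    truth_df.to_csv(paths["truth"], index_label="sample_id")
    write_clock_definition(generate_toy_clock(cfg), paths["clock"])
    return paths


def config_from_dict(d: Mapping) -> SimulationConfig:
    """Build a SimulationConfig from a parsed YAML/JSON mapping."""
    kwargs = dict(d)
    if "age_range" in kwargs:
        kwargs["age_range"] = tuple(float(v) for v in kwargs["age_range"])
    cfg = SimulationConfig(**kwargs)
    cfg.validate()
    return cfg
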