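"""Synthetic confluence datasets emulating plate-scale growth experiments.

The experiments behind the model are plate-scale: wells seeded at three
confluence levels, supplied with a grid of initial glucose concentrations,
optionally treated with the glucose-uptake inhibitor, and imaged every 3 h
for 4 days.  Two designs are emulated:

* Dataset A - 3 seeding levels x 10 glucose levels
  {0, 0.1, 0.2, 0.5, 0.8, 1, 2, 5, 8, 10 mM} x 4 replicates = 120 wells,
  no inhibitor.
* Dataset B - 3 seeding levels x 5 glucose levels {0.5, 1, 2, 5, 10 mM}
  x 3 doses {0, 2, 10 uM} x 4 replicates = 180 wells.

Trajectories are produced by the forward model with per-well bystander
death rates drawn from the exponential-decay relation evaluated at each
well's *accessible* initial glucose, then perturbed by an additive
Gaussian noise model on the confluence scale and clipped to [0, 100].
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import params_from_dict, params_to_dict
from .model import (
    BystanderRelation,
    GlobalParams,
    InhibitionParams,
    TimeCourse,
    Well,
    accessible_glucose,
    default_time_grid,
    simulate_forward,
)

__all__ = [
    "DesignSpec",
    "NoiseSpec",
    "TruthParams",
    "Dataset",
    "SchemaError",
    "make_design",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

logger = logging.getLogger(__name__)

DATASET_A_GLUCOSE = (0.0, 0.1, 0.2, 0.5, 0.8, 1.0, 2.0, 5.0, 8.0, 10.0)
DATASET_B_GLUCOSE = (0.5, 1.0, 2.0, 5.0, 10.0)
DOSES = (0.0, 2.0, 10.0)
SEEDING_LEVELS = {"low": 0.40, "intermediate": 0.65, "high": 0.80}


class SchemaError(ValueError):
    """Raised when a dataset file violates the expected schema."""


@dataclass(frozen=True)
class DesignSpec:
    """Factorial layout of one plate-scale experiment.

    ``seeding_jitter`` perturbs each replicate's initial confluence by a
    uniform offset (fraction units) to emulate plating variability; the
    jittered value is recorded on the well, so the design stays exactly
    self-describing.
    """

    dataset_tag: str = "A"
    seeding_levels: Mapping[str, float] = field(default_factory=lambda: dict(SEEDING_LEVELS))
    glucose_levels: Sequence[float] = DATASET_A_GLUCOSE
    doses: Sequence[float] = (0.0,)
    replicates: int = 4
    times: Sequence[float] = tuple(default_time_grid())
    seed: int = 0
    seeding_jitter: float = 0.03
    initial_dead_confluence: float = 0.02

    def __post_init__(self) -> None:
        if not self.seeding_levels or not self.glucose_levels or not self.doses:
            raise ValueError("seeding, glucose and dose grids must all be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @classmethod
    def dataset_a(cls, seed: int = 0, **overrides) -> "DesignSpec":
        kwargs = {"glucose_levels": DATASET_A_GLUCOSE, "doses": (0.0,), **overrides}
        return cls(dataset_tag="A", seed=seed, **kwargs)

    @classmethod
    def dataset_b(cls, seed: int = 1, **overrides) -> "DesignSpec":
        kwargs = {"glucose_levels": DATASET_B_GLUCOSE, "doses": DOSES, **overrides}
        return cls(dataset_tag="B", seed=seed, **kwargs)

    @property
    def time_grid(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def n_wells(self) -> int:
        return len(self.seeding_levels) * len(self.glucose_levels) * len(self.doses) * self.replicates


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement noise on the confluence scale.

    ``additive_sd`` is the i.i.d. Gaussian SD in confluence points;
    ``multiplicative_cv`` adds an optional signal-proportional component.
    """

    additive_sd: float = 0.5
    multiplicative_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.multiplicative_cv < 0:
            raise ValueError("noise magnitudes must be >= 0")


@dataclass(frozen=True)
class TruthParams:
    """Generating parameters of a synthetic dataset.

    The bystander relation defaults are configurable stand-ins (no
    literature values exist for the decay coefficients); the inhibition
    constants default to the literature per-dose point estimates.
    """

    globals_: GlobalParams = field(default_factory=GlobalParams)
    relation: BystanderRelation = field(default_factory=lambda: BystanderRelation(0.8, 0.4, 0.03))
    inhibition: InhibitionParams = field(default_factory=InhibitionParams.default)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    kbys_jitter_cv: float = 0.0

    def kbys_for_well(self, well: Well) -> float:
        """Bystander rate implied by the well's accessible initial glucose."""
        n0 = well.initial_confluence * self.globals_.theta
        g_in = self.inhibition.for_dose(well.dose)
        return float(self.relation.rate(accessible_glucose(well.G0, n0, g_in)))


@dataclass
class Dataset:
    """A design plus its (possibly noisy) confluence time courses."""

    wells: list[Well]
    courses: dict[str, TimeCourse]
    time_grid: np.ndarray
    seed: int | None = None
    truth: TruthParams | None = None
    true_kbys: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ValueError("well ids must be unique")

    def well(self, well_id: str) -> Well:
        return next(w for w in self.wells if w.well_id == well_id)

    def subset(self, well_ids) -> "Dataset":
        keep = set(well_ids)
        return Dataset(
            wells=[w for w in self.wells if w.well_id in keep],
            courses={k: v for k, v in self.courses.items() if k in keep},
            time_grid=self.time_grid,
            seed=self.seed,
            truth=self.truth,
            true_kbys={k: v for k, v in self.true_kbys.items() if k in keep},
        )

    def __len__(self) -> int:
        return len(self.wells)


def make_design(spec: DesignSpec) -> list[Well]:
    """Expand a design spec to a deterministic full-factorial well list."""
    rng = np.random.default_rng(spec.seed)
    wells = []
    for label, frac in spec.seeding_levels.items():
        for g0 in spec.glucose_levels:
            for dose in spec.doses:
                for rep in range(1, spec.replicates + 1):
                    jitter = rng.uniform(-spec.seeding_jitter, spec.seeding_jitter)
                    conf = float(np.clip(frac + jitter, 0.01, 0.99))
                    wells.append(Well(
                        well_id=f"{spec.dataset_tag}-{label}-g{g0:g}-d{dose:g}-r{rep}",
                        initial_confluence=conf,
                        G0=float(g0),
                        dose=float(dose),
                        replicate=rep,
                        dataset_tag=spec.dataset_tag,
                        initial_dead_confluence=spec.initial_dead_confluence,
                    ))
    return wells


def generate_dataset(
    design: DesignSpec | Sequence[Well],
    truth: TruthParams | None = None,
    seed: int = 0,
    *,
    time_grid: np.ndarray | None = None,
    rtol: float = 1e-8,
) -> Dataset:
    """Simulate every well of a design and apply the noise model.

    Fully reproducible: the same design, truth and seed give identical
    datasets.  Noise draws are made per well in well order.
    """
    truth = truth or TruthParams()
    if isinstance(design, DesignSpec):
        wells = make_design(design)
        time_grid = design.time_grid if time_grid is None else np.asarray(time_grid, float)
    else:
        wells = list(design)
        time_grid = default_time_grid() if time_grid is None else np.asarray(time_grid, float)

    rng = np.random.default_rng(seed)
    courses: dict[str, TimeCourse] = {}
    true_kbys: dict[str, float] = {}
    for well in wells:
        kbys = truth.kbys_for_well(well)
        if truth.kbys_jitter_cv > 0:
            sigma = float(np.sqrt(np.log1p(truth.kbys_jitter_cv ** 2)))
            kbys *= float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))
        g_in = truth.inhibition.for_dose(well.dose)
        try:
            sim = simulate_forward(well, truth.globals_, kbys, g_in, time_grid, rtol=rtol)
        except Exception as exc:  # annotate failures with the offending well
            raise RuntimeError(f"simulation failed for well {well.well_id}") from exc
        live = sim.course.live.copy()
        dead = sim.course.dead.copy()
        noise = truth.noise
        if noise.additive_sd > 0 or noise.multiplicative_cv > 0:
            live = live * (1.0 + rng.normal(0.0, noise.multiplicative_cv, live.shape)) \
                + rng.normal(0.0, noise.additive_sd, live.shape)
            dead = dead * (1.0 + rng.normal(0.0, noise.multiplicative_cv, dead.shape)) \
                + rng.normal(0.0, noise.additive_sd, dead.shape)
            live = np.clip(live, 0.0, 100.0)
            dead = np.clip(dead, 0.0, 100.0)
        courses[well.well_id] = TimeCourse(times=time_grid.copy(), live=live, dead=dead)
        true_kbys[well.well_id] = kbys
    return Dataset(wells=wells, courses=courses, time_grid=time_grid,
                   seed=seed, truth=truth, true_kbys=true_kbys)


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

_MEASUREMENT_COLUMNS = ["well_id", "time_days", "live_pct", "dead_pct"]


def write_dataset(dataset: Dataset, path) -> None:
    """Write measurements to tidy CSV plus a JSON sidecar with the design.

    The sidecar (``<path>.json`` next to the CSV) records the wells, the
    seed and the generating truth so a round trip is lossless.
    """
    path = Path(path)
    rows = []
    for well in dataset.wells:
        tc = dataset.courses[well.well_id]
        for t, live, dead in zip(tc.times, tc.live, tc.dead):
            rows.append((well.well_id, t, live, dead))
    pd.DataFrame(rows, columns=_MEASUREMENT_COLUMNS).to_csv(path, index=False, float_format="%.10g")

    sidecar = {
        "seed": dataset.seed,
        "time_grid": [float(t) for t in dataset.time_grid],
        "wells": [
            {
                "well_id": w.well_id,
                "initial_confluence": w.initial_confluence,
                "G0": w.G0,
                "dose": w.dose,
                "replicate": w.replicate,
                "dataset_tag": w.dataset_tag,
                "initial_dead_confluence": w.initial_dead_confluence,
            }
            for w in dataset.wells
        ],
        "true_kbys": dataset.true_kbys,
    }
    if dataset.truth is not None:
        sidecar["truth"] = {
            "globals": params_to_dict(dataset.truth.globals_),
            "relation": params_to_dict(dataset.truth.relation),
            "inhibition": params_to_dict(dataset.truth.inhibition),
            "noise": {"additive_sd": dataset.truth.noise.additive_sd,
                      "multiplicative_cv": dataset.truth.noise.multiplicative_cv},
            "kbys_jitter_cv": dataset.truth.kbys_jitter_cv,
        }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_dataset(path) -> Dataset:
    """Read a dataset written by :func:`write_dataset`.

    Missing columns raise :class:`SchemaError` naming the column; unknown
    extra columns are preserved in spirit (ignored) with a logged warning;
    out-of-range values are reported with their row numbers.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in _MEASUREMENT_COLUMNS]
    if extra:
        logger.warning("ignoring unknown column(s) in %s: %s", path, ", ".join(extra))
        warnings.warn(f"ignoring unknown column(s): {', '.join(extra)}", stacklevel=2)

    bad = df.index[
        (df["live_pct"] < 0) | (df["live_pct"] > 100)
        | (df["dead_pct"] < 0) | (df["time_days"] < 0)
        | df[["time_days", "live_pct", "dead_pct"]].isna().any(axis=1)
    ]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise SchemaError(f"out-of-range or missing values at file row(s): {rows}")

    sidecar_path = path.with_suffix(path.suffix + ".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    well_meta = {w["well_id"]: w for w in sidecar.get("wells", [])}

    wells: list[Well] = []
    courses: dict[str, TimeCourse] = {}
    time_grid = None
    for well_id, grp in df.groupby("well_id", sort=False):
        grp = grp.sort_values("time_days")
        tc = TimeCourse(times=grp["time_days"].to_numpy(),
                        live=grp["live_pct"].to_numpy(),
                        dead=grp["dead_pct"].to_numpy())
        courses[str(well_id)] = tc
        time_grid = tc.times if time_grid is None else time_grid
        meta = well_meta.get(well_id)
        if meta is not None:
            wells.append(Well(**meta))
        else:
            wells.append(Well(well_id=str(well_id), initial_confluence=float(tc.live[0]) / 100.0,
                              G0=0.0, initial_dead_confluence=float(tc.dead[0]) / 100.0))

    truth = None
    if "truth" in sidecar:
        t = sidecar["truth"]
        truth = TruthParams(
            globals_=params_from_dict(t["globals"]),
            relation=params_from_dict(t["relation"]),
            inhibition=params_from_dict(t["inhibition"]),
            noise=NoiseSpec(**t.get("noise", {})),
            kbys_jitter_cv=t.get("kbys_jitter_cv", 0.0),
        )
    return Dataset(wells=wells, courses=courses, time_grid=np.asarray(time_grid, float),
                   seed=sidecar.get("seed"), truth=truth,
                   true_kbys=sidecar.get("true_kbys", {}))
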