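"""Synthetic mechano-NPS and CyTOF-like data with known ground truth.

Everything downstream — pulse extraction, the physical model, the MechanoAge
classifier, Mechano-RISQ, and the CyTOF signature analysis — can be exercised
end-to-end on data from this module, with the generating parameters serving
as ground truth.  The trace generator is phenomenological at the sub-pulse
level: it reproduces the three-region pulse structure (node-pore sub-pulses,
a long contraction sub-pulse, post-contraction recovery sub-pulses on a noisy
baseline) rather than solving channel electrokinetics.

The default population parameters are stand-ins: the study they emulate does
not publish per-group feature distributions, so the defaults were chosen once
to be biophysically plausible (younger cells softer and faster-recovering;
older cells with more mass on slow/infinite recovery; high-risk cells ~0.5 um
smaller) and are configurable, not constants of the method.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .device_physics import (
    RECOVERY_CLASSES,
    DeviceGeometry,
    average_strain,
    forward_relative_blockade,
    transverse_deformation,
)
from .pulse_extraction import CurrentTrace

__all__ = [
    "PopulationSpec",
    "DonorSpec",
    "CohortSpec",
    "AcquisitionSpec",
    "TraceGroundTruth",
    "simulate_population",
    "simulate_trace",
    "simulate_event_train",
    "ground_truth_from_row",
    "simulate_cohort",
    "simulate_cytof",
    "default_population_spec",
    "default_cohort_spec",
    "DEFAULT_CYTOF_PANEL",
    "DEFAULT_OLDER_EFFECTS",
    "DEFAULT_HR_EFFECTS",
    "population_spec_from_yaml",
    "cohort_spec_from_yaml",
]


def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent, named RNG substream derived from one integer seed."""
    digest = hashlib.sha256(name.encode()).digest()[:4]
    key = int.from_bytes(digest, "little")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# ------------------------------------------------------------------- specs


@dataclass
class PopulationSpec:
    """Generating distribution of one cell population.

    ``recovery_distribution`` is a probability vector over the five recovery
    bins (0 ms; 50-60; 60-70; 70-120; infinite), slowest last.
    """

    group_label: str  # 'younger' | 'older' | 'high_risk'
    mean_diameter: float  # um
    sd_diameter: float  # um
    wcdi_location: float
    wcdi_scale: float
    recovery_distribution: tuple[float, ...]
    n_cells: int
    seed: int

    def __post_init__(self) -> None:
        if self.group_label not in {"younger", "older", "high_risk"}:
            raise ValueError(f"unknown group label {self.group_label!r}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be at least 1")
        if self.sd_diameter <= 0:
            raise ValueError("sd_diameter must be positive")
        p = np.asarray(self.recovery_distribution, dtype=float)
        if p.shape != (len(RECOVERY_CLASSES),):
            raise ValueError("recovery_distribution needs one entry per bin")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("recovery_distribution must be a probability "
                             "simplex (sum 1 within 1e-12)")


_DEFAULT_POPULATIONS: dict[str, dict] = {
    # Younger: mean free diameter 17.5 um so the applied strain at
    # wc = 10.5 um averages ~0.4; soft (high wCDI), mostly fast-recovering.
    "younger": dict(mean_diameter=17.5, sd_diameter=1.0,
                    wcdi_location=4.8, wcdi_scale=0.35,
                    recovery_distribution=(0.55, 0.20, 0.12, 0.08, 0.05)),
    # Older: stiffer, heavy mass on the 70-120 ms and infinite bins.
    "older": dict(mean_diameter=17.5, sd_diameter=1.0,
                  wcdi_location=3.8, wcdi_scale=0.35,
                  recovery_distribution=(0.15, 0.15, 0.15, 0.30, 0.25)),
    # High-risk: ~0.5 um smaller than average-risk, intermediate mechanics.
    "high_risk": dict(mean_diameter=17.0, sd_diameter=1.0,
                      wcdi_location=4.1, wcdi_scale=0.35,
                      recovery_distribution=(0.30, 0.18, 0.15, 0.20, 0.17)),
}


def default_population_spec(group_label: str, n_cells: int, seed: int,
                            **overrides) -> PopulationSpec:
    params = {**_DEFAULT_POPULATIONS[group_label], **overrides}
    return PopulationSpec(group_label=group_label, n_cells=n_cells,
                          seed=seed, **params)


@dataclass
class DonorSpec:
    donor_id: str
    age: float  # years
    risk_group: str  # 'AR' | 'HR' | 'FHx'
    population: PopulationSpec
    split: str = "train"  # 'train' | 'validation'

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.risk_group not in {"AR", "HR", "FHx"}:
            raise ValueError(f"unknown risk group {self.risk_group!r}")


@dataclass
class CohortSpec:
    donors: list[DonorSpec]

    def __post_init__(self) -> None:
        ids = [d.donor_id for d in self.donors]
        if len(set(ids)) != len(ids):
            raise ValueError("donor ids must be unique")


@dataclass
class AcquisitionSpec:
    """Acquisition constants of the simulated instrument.

    10 kHz sampling resolves ms-scale sub-pulses at low cost; currents are
    normalised to a baseline of 1 with Gaussian noise sigma relative to it.
    Segment transit speed is configured directly (``u_flow_*``) rather than
    solved from channel hydrodynamics; the 25 kPa driving pressure lives in
    the geometry as metadata only.
    """

    sampling_rate_hz: float = 10_000.0
    baseline_current: float = 1.0
    noise_sigma: float = 1e-4
    u_flow_mean: float = 15.0  # um/ms in the node-pore segments
    u_flow_sd: float = 0.8
    u_flow_bounds: tuple[float, float] = (13.0, 17.0)

    def __post_init__(self) -> None:
        if self.sampling_rate_hz < 1000.0:
            raise ValueError("sampling rate must be at least 1 kHz")
        if self.baseline_current <= 0:
            raise ValueError("baseline current must be positive")


@dataclass
class TraceGroundTruth:
    """True pulse-level quantities for one simulated cell."""

    D_cell_um: float
    dI_np_rel: float  # relative node-pore blockade
    dI_c_rel: float  # relative contraction blockade
    dT_cont_ms: float
    recovery_class: str
    recovery_time_ms: float  # measured from the first post-pore onset; inf ok
    U_flow_um_per_ms: float
    post_excess: float = 0.25  # unrecovered depth excess over dI_np (relative)
    entry_time_ms: float = 50.0

    def __post_init__(self) -> None:
        if not (0.0 < self.dI_np_rel < 1.0):
            raise ValueError("dI_np_rel must lie in (0, 1)")
        if self.dT_cont_ms <= 0:
            raise ValueError("dT_cont must be positive")
        if self.recovery_class not in RECOVERY_CLASSES:
            raise ValueError(f"unknown recovery class {self.recovery_class!r}")


# --------------------------------------------------- mechano-NPS populations

# Ground-truth recovery times are drawn 1 ms inside each printed bin (the
# 70-120 ms bin on [71, 114]) so that every finite recovery is observable
# within the 120 ms window: node transits can only delay, never advance, the
# measured crossing.
_RECOVERY_TIME_RANGES: dict[str, tuple[float, float] | None] = {
    "0ms": None,  # recovered on arrival
    "50-60ms": (51.0, 59.0),
    "60-70ms": (61.0, 69.0),
    "70-120ms": (71.0, 114.0),
    "Inf": None,
}


def simulate_population(
    spec: PopulationSpec,
    geometry: DeviceGeometry | None = None,
    acquisition: AcquisitionSpec | None = None,
) -> pd.DataFrame:
    """Draw a cell population and its derived mechanophenotypes.

    Free diameters come from a normal truncated to
    (wc + 0.5 um, pore width - 0.5 um) so strain and pore transit are always
    defined; wCDI from a truncated normal (> 0.5); the recovery bin from
    ``recovery_distribution`` with a uniform in-bin recovery time.  The
    contraction blockade is phenomenological, ``dI_c = r * dI_np`` with
    r ~ U(1.5, 2.2) per cell.  Phenotype columns (``L_deform_um`` etc.) are
    computed from the ground-truth pulse quantities with the same physical
    model the analysis pipeline applies, so simulator and pipeline agree by
    construction on clean data.

    Deterministic under a fixed ``spec.seed``.
    """
    geometry = geometry or DeviceGeometry()
    acq = acquisition or AcquisitionSpec()
    rng = _substream(spec.seed, f"population:{spec.group_label}")
    n = spec.n_cells
    wc = geometry.contraction_width

    lo, hi = wc + 0.5, geometry.pore_width - 0.5
    a, b = (lo - spec.mean_diameter) / spec.sd_diameter, \
           (hi - spec.mean_diameter) / spec.sd_diameter
    D = stats.truncnorm.rvs(a, b, loc=spec.mean_diameter,
                            scale=spec.sd_diameter, size=n, random_state=rng)

    wlo = 0.5
    wa = (wlo - spec.wcdi_location) / spec.wcdi_scale
    wcdi = stats.truncnorm.rvs(wa, np.inf, loc=spec.wcdi_location,
                               scale=spec.wcdi_scale, size=n, random_state=rng)

    ulo, uhi = acq.u_flow_bounds
    ua, ub = (ulo - acq.u_flow_mean) / acq.u_flow_sd, \
             (uhi - acq.u_flow_mean) / acq.u_flow_sd
    U = stats.truncnorm.rvs(ua, ub, loc=acq.u_flow_mean, scale=acq.u_flow_sd,
                            size=n, random_state=rng)

    bins = rng.choice(len(RECOVERY_CLASSES), size=n,
                      p=np.asarray(spec.recovery_distribution, dtype=float))
    t_rec = np.zeros(n)
    for i, b_ in enumerate(bins):
        cls = RECOVERY_CLASSES[b_]
        rng_range = _RECOVERY_TIME_RANGES[cls]
        if cls == "Inf":
            t_rec[i] = np.inf
        elif rng_range is None:
            t_rec[i] = 0.0
        else:
            t_rec[i] = rng.uniform(*rng_range)

    ratio = rng.uniform(1.5, 2.2, size=n)
    excess = rng.uniform(0.15, 0.35, size=n)

    dI_np = forward_relative_blockade(D, geometry.effective_diameter,
                                      geometry.effective_length)
    dI_c = ratio * dI_np
    # invert wCDI for the transit time the generator implies
    dT_cont = (geometry.contraction_length
               / (U * geometry.channel_height)) * D / wcdi
    L_def, delta = transverse_deformation(dI_c, geometry, D)
    strain = average_strain(D, wc)

    return pd.DataFrame({
        "cell_id": [f"{spec.group_label}_{spec.seed}_{i}" for i in range(n)],
        "group_label": spec.group_label,
        "D_cell_um": D,
        "wCDI": wcdi,
        "dT_cont_ms": dT_cont,
        "L_deform_um": L_def,
        "delta_deform": delta,
        "recovery_class": [RECOVERY_CLASSES[b_] for b_ in bins],
        "recovery_time_ms": t_rec,
        "strain": strain,
        "U_flow_um_per_ms": U,
        "dI_np_rel": dI_np,
        "dI_c_rel": dI_c,
        "post_excess": excess,
    })


def ground_truth_from_row(row: pd.Series | Mapping,
                          entry_time_ms: float = 50.0) -> TraceGroundTruth:
    """Package one ``simulate_population`` row for the trace generator."""
    return TraceGroundTruth(
        D_cell_um=row["D_cell_um"],
        dI_np_rel=row["dI_np_rel"],
        dI_c_rel=row["dI_c_rel"],
        dT_cont_ms=row["dT_cont_ms"],
        recovery_class=row["recovery_class"],
        recovery_time_ms=row["recovery_time_ms"],
        U_flow_um_per_ms=row["U_flow_um_per_ms"],
        post_excess=row["post_excess"],
        entry_time_ms=entry_time_ms,
    )


# ------------------------------------------------------------------ traces


def _cell_deficit(
    cell: TraceGroundTruth,
    geometry: DeviceGeometry,
    time_ms: np.ndarray,
) -> np.ndarray:
    """Relative current deficit contributed by one cell over a time grid."""
    if cell.D_cell_um >= geometry.pore_width:
        raise ValueError("cell diameter >= pore width: cannot transit the "
                         "sensing pore")
    U = cell.U_flow_um_per_ms
    node = geometry.node_length / U
    pore = geometry.pore_length / U
    rec_pore = geometry.recovery_length / U

    deficit = np.zeros_like(time_ms)
    t = cell.entry_time_ms
    # pre-contraction node-pore segments
    for _ in range(geometry.pre_pore_count):
        t += node
        deficit[(time_ms >= t) & (time_ms < t + pore)] = cell.dI_np_rel
        t += pore
    # contraction channel
    t += node
    deficit[(time_ms >= t) & (time_ms < t + cell.dT_cont_ms)] = cell.dI_c_rel
    t += cell.dT_cont_ms
    # recovery segments: depth relaxes to dI_np at the recovery time,
    # measured from the onset of the first post-contraction sub-pulse
    t += node
    first_post_onset = t
    unrecovered = cell.dI_np_rel * (1.0 + cell.post_excess)
    for _ in range(geometry.post_pore_count):
        mask = (time_ms >= t) & (time_ms < t + rec_pore)
        rel = time_ms[mask] - first_post_onset
        deficit[mask] = np.where(rel < cell.recovery_time_ms,
                                 unrecovered, cell.dI_np_rel)
        t += rec_pore + node
    return deficit


def event_duration_ms(cell: TraceGroundTruth, geometry: DeviceGeometry) -> float:
    U = cell.U_flow_um_per_ms
    node = geometry.node_length / U
    pore = geometry.pore_length / U
    rec = geometry.recovery_length / U
    return (geometry.pre_pore_count * (node + pore) + node + cell.dT_cont_ms
            + geometry.post_pore_count * (node + rec))


def simulate_event_train(
    geometry: DeviceGeometry,
    cells: Sequence[TraceGroundTruth],
    acquisition: AcquisitionSpec | None = None,
    *,
    total_ms: float | None = None,
    noise_seed: int = 0,
) -> CurrentTrace:
    """Current trace containing one event per cell (overlaps allowed).

    Deficits of co-occupying cells add, which is what makes coincident events
    detectable as anomalously structured pulses downstream.
    """
    acq = acquisition or AcquisitionSpec()
    if total_ms is None:
        total_ms = max(
            c.entry_time_ms + event_duration_ms(c, geometry) for c in cells
        ) + 50.0
    n = int(round(total_ms * acq.sampling_rate_hz / 1000.0))
    time_ms = np.arange(n) * (1000.0 / acq.sampling_rate_hz)
    deficit = np.zeros(n)
    for c in cells:
        deficit += _cell_deficit(c, geometry, time_ms)
    current = acq.baseline_current * (1.0 - deficit)
    if acq.noise_sigma > 0:
        rng = _substream(noise_seed, "trace-noise")
        current = current + rng.normal(
            0.0, acq.noise_sigma * acq.baseline_current, size=n)
    return CurrentTrace(time_ms, current, acq.sampling_rate_hz)


def simulate_trace(
    geometry: DeviceGeometry,
    cell: TraceGroundTruth,
    acquisition: AcquisitionSpec | None = None,
    *,
    noise_seed: int = 0,
) -> CurrentTrace:
    """Single-cell current trace (see :func:`simulate_event_train`)."""
    return simulate_event_train(geometry, [cell], acquisition,
                                noise_seed=noise_seed)


# ------------------------------------------------------------------ cohorts


def default_cohort_spec(
    n_younger: int = 5,
    n_older: int = 5,
    n_high_risk: int = 0,
    cells_per_donor: int = 100,
    seed: int = 0,
) -> CohortSpec:
    """Cohort with per-donor variation around the group defaults.

    Donor ages are uniform in the class ranges (<35 / >50 y); donor-level
    biological variation perturbs the group mean diameter, wCDI location and
    recovery mixture (Dirichlet with concentration 50 x base).
    """
    rng = _substream(seed, "cohort")
    donors: list[DonorSpec] = []

    def _make(group: str, risk: str, age_lo: float, age_hi: float,
              idx: int) -> DonorSpec:
        base = _DEFAULT_POPULATIONS["high_risk" if risk == "HR" else group]
        p = rng.dirichlet(np.asarray(base["recovery_distribution"]) * 50.0)
        p = tuple(p / p.sum())
        pop = PopulationSpec(
            group_label="high_risk" if risk == "HR" else group,
            mean_diameter=base["mean_diameter"] + rng.normal(0, 0.2),
            sd_diameter=base["sd_diameter"],
            wcdi_location=base["wcdi_location"] + rng.normal(0, 0.1),
            wcdi_scale=base["wcdi_scale"],
            recovery_distribution=p,
            n_cells=cells_per_donor,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        did = f"{risk}-{group[0].upper()}{idx}"
        return DonorSpec(donor_id=did, age=float(rng.uniform(age_lo, age_hi)),
                         risk_group=risk, population=pop)

    for i in range(n_younger):
        donors.append(_make("younger", "AR", 20.0, 34.0, i))
    for i in range(n_older):
        donors.append(_make("older", "AR", 51.0, 75.0, i))
    for i in range(n_high_risk):
        donors.append(_make("younger", "HR", 20.0, 34.0, i))
    return CohortSpec(donors=donors)


def simulate_cohort(
    cohort: CohortSpec,
    geometry: DeviceGeometry | None = None,
    acquisition: AcquisitionSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every donor's cells; returns (cells, donor_meta) tables."""
    frames = []
    meta = []
    for d in cohort.donors:
        cells = simulate_population(d.population, geometry, acquisition)
        cells.insert(0, "donor_id", d.donor_id)
        cells["cell_id"] = d.donor_id + ":" + cells["cell_id"]
        frames.append(cells)
        meta.append({"donor_id": d.donor_id, "age": d.age,
                     "risk_group": d.risk_group, "split": d.split})
    return (pd.concat(frames, ignore_index=True), pd.DataFrame(meta))


# -------------------------------------------------------------------- CyTOF

DEFAULT_CYTOF_PANEL: tuple[str, ...] = (
    "pRb", "CD44", "pS6", "KRT19", "p38", "GSK3", "mTOR", "KRT7", "KRT14",
    "CD271", "EpCAM", "CD49f", "CD133", "ECadherin", "Vimentin", "pERK",
    "pAKT", "pSTAT1", "pSTAT3", "pSTAT5", "pNFkB", "CyclinB1", "Ki67",
    "pH3", "cPARP", "CD10", "CD24",
)

#: Age-associated shifts seen in luminal cells: pRb, CD44, pS6 up; KRT19 down.
DEFAULT_OLDER_EFFECTS: dict[str, float] = {
    "pRb": 0.8, "CD44": 0.8, "pS6": 0.8, "KRT19": -0.8,
}
#: High-risk shifts: a milder ageing-like signature plus KRT14 gain.
DEFAULT_HR_EFFECTS: dict[str, float] = {
    "pRb": 0.6, "CD44": 0.5, "pS6": 0.5, "KRT19": -0.5, "KRT14": 0.6,
}


def simulate_cytof(
    panel: Sequence[str] | None = None,
    groups: Sequence[str] = ("younger", "older"),
    effects: Mapping[str, Mapping[str, float]] | None = None,
    n_per_group: int = 500,
    seed: int = 0,
    *,
    lineage: str = "luminal",
    condition: str = "control",
    log_sigma: float = 0.4,
) -> pd.DataFrame:
    """Log-normal marker intensities with group-wise log-fold shifts.

    ``effects`` maps group -> {marker: shift in natural-log units}; unlisted
    groups/markers are unshifted.  Marker base levels are drawn once per call
    (log-means uniform on [3.5, 5.5]) so intensities are well above 1 and
    log1p-based fold changes track the planted shifts closely.  Returns a
    table with ``cell_id, lineage, group, condition`` plus one column per
    marker (27 by default).
    """
    panel = tuple(panel) if panel is not None else DEFAULT_CYTOF_PANEL
    if len(panel) < 1:
        raise ValueError("panel must contain at least one marker")
    if len(set(panel)) != len(panel):
        raise ValueError("marker names must be unique")
    effects = {g: dict(m) for g, m in (effects or {}).items()}
    for g, shifts in effects.items():
        missing = set(shifts) - set(panel)
        if missing:
            raise ValueError(f"effect markers absent from panel: {sorted(missing)}")

    rng = _substream(seed, f"cytof:{condition}:{lineage}")
    base_mu = rng.uniform(3.5, 5.5, size=len(panel))
    frames = []
    for g in groups:
        shift = np.array([effects.get(g, {}).get(m, 0.0) for m in panel])
        logx = rng.normal(base_mu + shift, log_sigma, size=(n_per_group, len(panel)))
        df = pd.DataFrame(np.exp(logx), columns=list(panel))
        df.insert(0, "condition", condition)
        df.insert(0, "group", g)
        df.insert(0, "lineage", lineage)
        df.insert(0, "cell_id",
                  [f"{condition}:{g}:{i}" for i in range(n_per_group)])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------- configs


def population_spec_from_yaml(path: str | Path) -> PopulationSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if "seed" not in data:
        raise ValueError("population config must set an explicit seed")
    data["recovery_distribution"] = tuple(data["recovery_distribution"])
    return PopulationSpec(**data)


def cohort_spec_from_yaml(path: str | Path) -> CohortSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    donors = []
    for d in data["donors"]:
        pop = dict(d.pop("population"))
        if "seed" not in pop:
            raise ValueError("each population config must set an explicit seed")
        pop["recovery_distribution"] = tuple(pop["recovery_distribution"])
        donors.append(DonorSpec(population=PopulationSpec(**pop), **d))
    return CohortSpec(donors=donors)
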