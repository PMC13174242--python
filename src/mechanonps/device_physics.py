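"""Physical model of the mechano-NPS channel.

Converts raw sub-pulse quantities into cell-level mechanophenotypes:

* free cell diameter ``D_cell`` from the relative node-pore blockade
  ``dI/I = D**3 / (De**2 * L) * 1 / (1 - 0.8 * (D / De)**3)``,
* transverse deformation of the cell in the contraction channel under an
  oblate-spheroid assumption (``V_deform = pi * w_c * L_deform**2 / 6``),
* the whole-cell deformability index
  ``wCDI = (L_c / (U_flow * h)) * (D_cell / dT_cont)``, a dimensionless
  quantity inversely related to cortical tension,
* the average applied strain ``(D_cell - w_c) / D_cell``, and
* microsphere calibration of the channel's effective diameter ``De``.

All lengths are in micrometres, times in milliseconds, velocities in
micrometres per millisecond; currents are normalised so blockades are
dimensionless fractions of the baseline.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "DeviceGeometry",
    "forward_relative_blockade",
    "diameter_from_blockade",
    "calibrate_De",
    "transverse_deformation",
    "compute_wCDI",
    "average_strain",
    "estimate_Uflow",
    "phenotypes_from_features",
    "RECOVERY_CLASSES",
]

# Pole of the 1/(1 - 0.8 x^3) shape-correction factor, in units of De.
_POLE_FACTOR = (1.0 / 0.8) ** (1.0 / 3.0)

#: Canonical recovery-class labels, slowest last.
RECOVERY_CLASSES = ("0ms", "50-60ms", "60-70ms", "70-120ms", "Inf")


@dataclass
class DeviceGeometry:
    """Channel dimensions and acquisition constants.

    Defaults are the production device: nodes 50 x 85 um, pores 700 x 22 um,
    contraction channel 3000 x 10.5 um, channel height 22.3 um, recovery
    segments 700 um, driven at 25 kPa / 1 V.  ``effective_diameter`` (De) and
    ``effective_length`` (L) parameterise the blockade relation and come from
    microsphere calibration; L defaults to the pore length (the sensing
    segment).  ``pre_pore_count`` / ``post_pore_count`` give the number of
    node-pore segments before and after the contraction channel.
    """

    node_length: float = 50.0
    node_width: float = 85.0
    pore_length: float = 700.0
    pore_width: float = 22.0
    contraction_length: float = 3000.0
    contraction_width: float = 10.5
    channel_height: float = 22.3
    recovery_length: float = 700.0
    effective_diameter: float = 25.0
    effective_length: float = 700.0
    pre_pore_count: int = 2
    post_pore_count: int = 3
    pressure_kPa: float = 25.0  # metadata only
    voltage_V: float = 1.0  # metadata only

    def __post_init__(self) -> None:
        if self.contraction_width >= self.pore_width:
            raise ValueError("contraction width must be narrower than the pore")
        for name in (
            "node_length", "node_width", "pore_length", "pore_width",
            "contraction_length", "contraction_width", "channel_height",
            "recovery_length", "effective_diameter", "effective_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pre_pore_count < 1 or self.post_pore_count < 1:
            raise ValueError("pore counts must be at least 1")

    @property
    def contraction_volume(self) -> float:
        """Full contraction-channel volume Lc * wc * h (um^3)."""
        return self.contraction_length * self.contraction_width * self.channel_height

    @property
    def diameter_pole(self) -> float:
        """Diameter at which the blockade correction factor diverges (um)."""
        return self.effective_diameter * _POLE_FACTOR

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DeviceGeometry":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def forward_relative_blockade(
    D_cell: float | np.ndarray,
    De: float,
    L: float,
) -> float | np.ndarray:
    """Relative current blockade dI/I of a sphere of diameter ``D_cell``.

    Implements ``D**3/(De**2 L) * 1/(1 - 0.8 (D/De)**3)``, valid for
    ``0 <= D_cell < De * (1/0.8)**(1/3)`` and strictly increasing there.
    """
    D = np.asarray(D_cell, dtype=float)
    if De <= 0 or L <= 0:
        raise ValueError("De and L must be positive")
    if np.any(D < 0):
        raise ValueError("D_cell must be non-negative")
    ratio3 = (D / De) ** 3
    denom = 1.0 - 0.8 * ratio3
    if np.any(denom <= 0):
        raise ValueError(
            f"D_cell at/beyond the pole of the correction factor "
            f"(admissible D_cell < {De * _POLE_FACTOR:.4f} um)"
        )
    out = D**3 / (De**2 * L) / denom
    return out if out.ndim else float(out)


def diameter_from_blockade(
    dI_over_I: float,
    De: float,
    L: float,
    *,
    xtol: float = 1e-6,
) -> float:
    """Numerically invert the blockade relation for the free cell diameter.

    Bisection-style bracketed root finding on (0, pole); the forward map is
    strictly monotone so the root is unique.  ``xtol`` is the absolute
    diameter tolerance in micrometres.  The admissible domain is capped at
    99% of the pole diameter: the correction factor diverges there, so
    blockades beyond that cap (or >= 1, which would null the current) are
    reported as unattainable rather than inverted to a near-pole diameter.
    """
    if dI_over_I <= 0:
        raise ValueError("dI_over_I must be positive")
    eps = 1e-9
    upper = De * _POLE_FACTOR * 0.99
    f_hi = min(forward_relative_blockade(upper, De, L), 1.0 - 1e-12)
    if dI_over_I >= f_hi:
        raise ValueError(
            f"blockade ratio {dI_over_I:.4g} unattainable: admissible range is "
            f"(0, {f_hi:.4g}) for De={De}, L={L}"
        )
    root = brentq(
        lambda d: forward_relative_blockade(d, De, L) - dI_over_I,
        eps,
        upper,
        xtol=xtol,
    )
    return float(root)


def calibrate_De(
    microsphere_blockades: Sequence[float],
    known_diameter: float,
    L: float,
) -> float:
    """Effective channel diameter from polystyrene-microsphere blockades.

    Minimises the squared residual between the blockade relation evaluated at
    the known microsphere diameter and the measured relative blockades (1-D
    bounded minimisation over De).  With a single noiseless measurement this
    reduces to exact inversion.
    """
    blockades = np.asarray(microsphere_blockades, dtype=float)
    if blockades.size == 0:
        raise ValueError("need at least one microsphere blockade")
    if np.any(blockades <= 0):
        raise ValueError("blockade measurements must be positive")
    if known_diameter <= 0:
        raise ValueError("known_diameter must be positive")

    def sse(De: float) -> float:
        if known_diameter >= De * _POLE_FACTOR:
            return np.inf
        pred = forward_relative_blockade(known_diameter, De, L)
        return float(np.sum((pred - blockades) ** 2))

    # De must exceed known_diameter / pole-factor for the sphere to register.
    lo = known_diameter / _POLE_FACTOR * (1.0 + 1e-6)
    hi = max(10.0 * known_diameter, lo * 10.0)
    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def transverse_deformation(
    dIc_over_I: float | np.ndarray,
    geometry: DeviceGeometry,
    D_cell: float | np.ndarray,
) -> tuple[float | np.ndarray, float | np.ndarray]:
    """Deformation length and transverse deformation in the contraction channel.

    The deformed cell is modelled as an oblate spheroid of volume
    ``pi * w_c * L_deform**2 / 6``; the contraction blockade is taken as the
    deformed-cell/channel volume ratio with proportionality constant 1, so

        ``L_deform = sqrt(6 * dIc_over_I * V_contraction / (pi * w_c))``

    and ``delta_deform = L_deform / D_cell``.
    """
    dIc = np.asarray(dIc_over_I, dtype=float)
    D = np.asarray(D_cell, dtype=float)
    if np.any(dIc < 0):
        raise ValueError("dIc_over_I must be non-negative")
    if np.any(D <= 0):
        raise ValueError("D_cell must be positive")
    L_deform = np.sqrt(
        6.0 * dIc * geometry.contraction_volume / (np.pi * geometry.contraction_width)
    )
    delta = L_deform / D
    if L_deform.ndim:
        return L_deform, delta
    return float(L_deform), float(delta)


def compute_wCDI(
    D_cell: float | np.ndarray,
    dT_cont: float | np.ndarray,
    U_flow: float | np.ndarray,
    geometry: DeviceGeometry,
) -> float | np.ndarray:
    """Whole-cell deformability index (dimensionless).

    ``wCDI = (L_c / (U_flow * h)) * (D_cell / dT_cont)``.  Softer cells
    transit the contraction channel faster (smaller ``dT_cont``), giving a
    larger index; the ``D_cell`` factor removes the trivial size dependence.
    """
    D = np.asarray(D_cell, dtype=float)
    dT = np.asarray(dT_cont, dtype=float)
    U = np.asarray(U_flow, dtype=float)
    if np.any(D <= 0) or np.any(U <= 0):
        raise ValueError("D_cell and U_flow must be positive")
    if np.any(~np.isfinite(dT)) or np.any(dT <= 0):
        raise ValueError("dT_cont must be finite and positive "
                         "(contraction transit is always finite)")
    out = (geometry.contraction_length / (U * geometry.channel_height)) * (D / dT)
    return out if out.ndim else float(out)


def average_strain(
    D_cell: float | np.ndarray,
    wc: float,
) -> float | np.ndarray:
    """Applied strain (D_cell - w_c)/D_cell of a cell squeezed to width wc."""
    D = np.asarray(D_cell, dtype=float)
    if np.any(D <= wc):
        raise ValueError("strain undefined: D_cell must exceed the "
                         "contraction width for the cell to be compressed")
    out = (D - wc) / D
    return out if out.ndim else float(out)


def estimate_Uflow(
    pre_pore_durations_ms: Iterable[float],
    geometry: DeviceGeometry,
) -> float:
    """Node-pore fluid velocity from pre-contraction sub-pulse durations.

    ``U_flow = L_pore / mean(duration)`` in um/ms.
    """
    durations = np.asarray(list(pre_pore_durations_ms), dtype=float)
    if durations.size == 0:
        raise ValueError("need at least one pre-contraction sub-pulse duration")
    if np.any(durations <= 0):
        raise ValueError("sub-pulse durations must be positive")
    return float(geometry.pore_length / durations.mean())


def phenotypes_from_features(
    features: pd.DataFrame,
    geometry: DeviceGeometry,
) -> pd.DataFrame:
    """Map a per-cell sub-pulse feature table to mechanophenotypes.

    Expects columns ``cell_id, I_baseline, dI_np, dI_c, dT_cont_ms, dT_r_ms``
    (and optionally ``U_flow_um_per_ms``; otherwise per-cell U_flow must be
    supplied via a ``pre_pore_durations`` column of lists).  Returns the
    phenotype table ``cell_id, D_cell_um, wCDI, dT_cont_ms, L_deform_um,
    delta_deform, recovery_class, U_flow_um_per_ms``.
    """
    from .feature_engineering import recovery_class_of  # local, avoids cycle

    De = geometry.effective_diameter
    L = geometry.effective_length
    rows = []
    for rec in features.itertuples(index=False):
        dI_np_rel = rec.dI_np / rec.I_baseline
        dI_c_rel = rec.dI_c / rec.I_baseline
        D = diameter_from_blockade(dI_np_rel, De, L)
        if hasattr(rec, "U_flow_um_per_ms"):
            U = rec.U_flow_um_per_ms
        else:
            U = estimate_Uflow(rec.pre_pore_durations, geometry)
        wcdi = compute_wCDI(D, rec.dT_cont_ms, U, geometry)
        L_def, delta = transverse_deformation(dI_c_rel, geometry, D)
        rows.append({
            "cell_id": rec.cell_id,
            "D_cell_um": D,
            "wCDI": wcdi,
            "dT_cont_ms": rec.dT_cont_ms,
            "L_deform_um": L_def,
            "delta_deform": delta,
            "recovery_class": recovery_class_of(rec.dT_r_ms),
            "U_flow_um_per_ms": U,
        })
    return pd.DataFrame(
        rows,
        columns=["cell_id", "D_cell_um", "wCDI", "dT_cont_ms", "L_deform_um",
                 "delta_deform", "recovery_class", "U_flow_um_per_ms"],
    )
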