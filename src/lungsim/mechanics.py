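"""Forced-oscillation input impedance of an airway tree.

Each airway segment is a rigid tube carrying oscillatory flow. Its complex
acoustic impedance at frequency f follows the Womersley solution

    Z_a(f) = j 2 f rho l / r^2 * [1 - 2 J1(a*sqrt(-j)) / (a*sqrt(-j) J0(a*sqrt(-j)))]^-1

with a = r sqrt(2 pi rho f / mu) the Womersley number, J0/J1 complex Bessel
functions, rho/mu the density and dynamic viscosity of humid air at 37 C. As
f -> 0 this reduces to the Poiseuille resistance 8 mu l / (pi r^4). Terminal
airways additionally carry a lumped alveolar compartment of elastance E_t, so
Z_t = Z_a - j E_t / omega. Lung input impedance is the series/parallel
reduction of the whole tree; respiratory-system impedance adds central-airway
and chest-wall resistances, chest-wall elastance, and optionally a parallel
upper-airway shunt.

All formulas are evaluated in SI (Pa s / m^3) and converted once to the
clinical unit cmH2O s / L (divide by 98,066.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import jve

from .errors import (
    ConfigurationError,
    DomainError,
    MetricError,
    ValidationError,
)
from .tree import AirwayBranch, AirwayTree

#: 1 Pa s / m^3 in cmH2O s / L  (1 cmH2O = 98.0665 Pa, 1 m^3 = 1000 L)
PA_S_M3_TO_CMH2O_S_L = 1.0 / 98066.5

#: default evaluation grid, Hz; includes the band anchors 0.2, 5 and 20 Hz
DEFAULT_FREQUENCIES = (0.2, 0.5, 1.0, 2.0, 5.0, 8.0, 12.0, 16.0, 20.0, 24.0, 32.0)


@dataclass(frozen=True)
class GasProperties:
    """Density (kg/m^3) and dynamic viscosity (Pa s) of the oscillated gas.

    Defaults are humid air at 37 C.
    """

    density: float = 1.16
    viscosity: float = 1.85e-5

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise DomainError("gas density and viscosity must be positive")


@dataclass(frozen=True)
class ElastanceModel:
    """Even distribution of total lung elastance over terminal airway units.

    Each of N identical terminal units gets elastance E_t = E_L * N so that the
    parallel combination of all units returns the total E_L.
    """

    total_elastance: float = 10.0  # cmH2O/L

    def __post_init__(self) -> None:
        if self.total_elastance < 0:
            raise DomainError("total elastance must be non-negative")

    def terminal_elastance(self, n_terminals: int) -> float:
        if n_terminals <= 0:
            raise DomainError("need at least one terminal unit")
        return self.total_elastance * n_terminals


@dataclass
class RespiratoryConfig:
    """Extra-pulmonary series elements and the optional upper-airway shunt.

    ``shunt_table`` holds per-frequency complex upper-airway impedance
    (columns frequency_hz, r_uaw, x_uaw in cmH2O s/L); it is interpolated
    linearly in log-frequency and extrapolated at the grid edges.
    """

    r_central: float = 0.5       # cmH2O s/L
    r_chest_wall: float = 0.5    # cmH2O s/L
    e_chest_wall: float = 10.6   # cmH2O/L
    shunt_table: pd.DataFrame | None = None
    shunt_enabled: bool = False

    def __post_init__(self) -> None:
        if self.r_central < 0 or self.r_chest_wall < 0:
            raise DomainError("series resistances must be non-negative")
        if self.e_chest_wall <= 0:
            raise DomainError("chest-wall elastance must be positive")
        if self.shunt_table is not None:
            f = self.shunt_table["frequency_hz"].to_numpy(dtype=float)
            if len(f) < 2 or np.any(np.diff(f) <= 0):
                raise ConfigurationError(
                    "shunt_table needs >= 2 strictly increasing frequencies"
                )

    def shunt_impedance(self, frequency_hz: float) -> complex:
        if self.shunt_table is None:
            raise ConfigurationError("shunt requested but no shunt_table configured")
        logf = np.log(self.shunt_table["frequency_hz"].to_numpy(dtype=float))
        r = self.shunt_table["r_uaw"].to_numpy(dtype=float)
        x = self.shunt_table["x_uaw"].to_numpy(dtype=float)
        t = np.log(frequency_hz)
        # linear interpolation in log f with linear extrapolation at the edges
        re = _interp_extrap(t, logf, r)
        im = _interp_extrap(t, logf, x)
        return complex(re, im)


def _interp_extrap(t: float, xs: np.ndarray, ys: np.ndarray) -> float:
    if t <= xs[0]:
        slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
        return float(ys[0] + slope * (t - xs[0]))
    if t >= xs[-1]:
        slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        return float(ys[-1] + slope * (t - xs[-1]))
    return float(np.interp(t, xs, ys))


def default_shunt_table() -> pd.DataFrame:
    """Packaged upper-airway shunt impedance table (synthetic fixture).

    Literature-plausible magnitudes generated from a resistance-inertance-
    compliance description of the upper-airway walls; a documented, replaceable
    stand-in, not measured data.
    """
    from importlib import resources

    path = Path(resources.files("lungsim").joinpath("data/upper_airway_shunt_synthetic.csv"))
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# elemental impedances
# ---------------------------------------------------------------------------

def womersley_number(
    radius_m: float | np.ndarray,
    frequency_hz: float,
    gas: GasProperties = GasProperties(),
) -> float | np.ndarray:
    """alpha = r sqrt(2 pi rho f / mu); zero iff the frequency is zero."""
    radius = np.asarray(radius_m, dtype=float)
    if np.any(radius <= 0):
        raise DomainError("radius must be positive")
    if frequency_hz < 0:
        raise DomainError("frequency must be non-negative")
    alpha = radius * np.sqrt(2.0 * np.pi * gas.density * frequency_hz / gas.viscosity)
    return float(alpha) if np.isscalar(radius_m) else alpha


def _womersley_factor(alpha: np.ndarray) -> np.ndarray:
    """[1 - 2 J1(z)/(z J0(z))]^-1 with z = alpha sqrt(-j), stable at all alpha.

    The Bessel ratio is evaluated with exponentially scaled functions (jve),
    whose scaling cancels in the ratio, so no overflow occurs at large alpha.
    Below alpha = 3e-3 a series expansion avoids the catastrophic cancellation
    of 1 - J-ratio; the two branches agree to better than 1e-9 at the switch.
    """
    alpha = np.asarray(alpha, dtype=float)
    z = alpha * np.exp(-0.25j * np.pi)  # alpha * sqrt(-j)
    out = np.empty(z.shape, dtype=complex)
    small = alpha < 3e-3
    if np.any(small):
        z2 = z[small] ** 2
        out[small] = (-8.0 / z2) * (1.0 - z2 / 6.0 - z2 * z2 / 1152.0)
    big = ~small
    if np.any(big):
        zb = z[big]
        ratio = 2.0 * jve(1, zb) / (zb * jve(0, zb))
        out[big] = 1.0 / (1.0 - ratio)
    if not np.all(np.isfinite(out)):
        raise ValidationError("non-finite Womersley factor")
    return out


def airway_impedance_vec(
    diameter_mm: np.ndarray,
    length_mm: np.ndarray,
    frequency_hz: float,
    gas: GasProperties = GasProperties(),
) -> np.ndarray:
    """Complex Womersley impedance of airway segments, vectorised (cmH2O s/L)."""
    if frequency_hz <= 0:
        raise DomainError(
            "frequency must be positive (use poiseuille_resistance for f = 0)"
        )
    d = np.asarray(diameter_mm, dtype=float)
    l = np.asarray(length_mm, dtype=float)
    if np.any(d <= 0) or np.any(l <= 0):
        raise DomainError("branch geometry must be positive")
    r_m = d / 2000.0
    l_m = l / 1000.0
    alpha = r_m * np.sqrt(2.0 * np.pi * gas.density * frequency_hz / gas.viscosity)
    z_si = (
        1j * 2.0 * frequency_hz * gas.density * l_m / (r_m * r_m)
    ) * _womersley_factor(alpha)
    return z_si * PA_S_M3_TO_CMH2O_S_L


def branch_impedance(
    branch: AirwayBranch,
    frequency_hz: float,
    gas: GasProperties = GasProperties(),
) -> complex:
    """Womersley impedance of one airway branch at f > 0 (cmH2O s/L)."""
    z = airway_impedance_vec(
        np.array([branch.diameter_mm]), np.array([branch.length_mm]), frequency_hz, gas
    )
    return complex(z[0])


def poiseuille_resistance(
    branch: AirwayBranch, gas: GasProperties = GasProperties()
) -> float:
    """Static laminar-flow resistance 8 mu l / (pi r^4) in cmH2O s/L."""
    r = branch.radius_m
    l = branch.length_m
    if r <= 0 or l <= 0:
        raise DomainError("branch geometry must be positive")
    return 8.0 * gas.viscosity * l / (np.pi * r**4) * PA_S_M3_TO_CMH2O_S_L


def terminal_impedance(
    branch: AirwayBranch,
    terminal_elastance: float,
    frequency_hz: float,
    gas: GasProperties = GasProperties(),
) -> complex:
    """Z_t = Z_a - j E_t / omega: airway segment plus its alveolar compartment."""
    if terminal_elastance < 0:
        raise DomainError("terminal elastance must be non-negative")
    omega = 2.0 * np.pi * frequency_hz
    return branch_impedance(branch, frequency_hz, gas) - 1j * terminal_elastance / omega


# ---------------------------------------------------------------------------
# tree reduction
# ---------------------------------------------------------------------------

def _reduce_tree(
    tree: AirwayTree,
    z_airway: np.ndarray,
    frequency_hz: float,
    elastance: ElastanceModel,
) -> complex:
    """Series/parallel lumped-element reduction, deepest generation first.

    Equivalent to the post-order recursion Z_in(b) = Z_a(b) + (sum_c 1/Z_in(c))^-1
    but iterates generations with vectorised accumulation, so 26-generation
    depth poses no recursion-limit problem.
    """
    omega = 2.0 * np.pi * frequency_hz
    e_t = elastance.terminal_elastance(tree.n_terminals)
    z_total = z_airway.astype(complex).copy()
    z_total[tree.is_terminal] += -1j * e_t / omega
    y_children = np.zeros(tree.n_branches, dtype=complex)
    g_max = int(tree.generation.max())
    for g in range(g_max, 1, -1):
        idx = np.flatnonzero(tree.generation == g)
        np.add.at(y_children, tree.parent[idx], 1.0 / z_total[idx])
        pidx = np.flatnonzero((tree.generation == g - 1) & ~tree.is_terminal)
        z_total[pidx] = z_airway[pidx] + 1.0 / y_children[pidx]
    return complex(z_total[tree.root_id])


def input_impedance(
    tree: AirwayTree,
    frequency_hz: float,
    gas: GasProperties = GasProperties(),
    elastance: ElastanceModel = ElastanceModel(),
) -> complex:
    """Lung input impedance Z_L(f) at the tracheal opening (cmH2O s/L)."""
    tree.validate()
    z_a = airway_impedance_vec(tree.diameter_mm, tree.length_mm, frequency_hz, gas)
    return _reduce_tree(tree, z_a, frequency_hz, elastance)


def respiratory_impedance(
    z_lung: complex,
    frequency_hz: float,
    config: RespiratoryConfig = RespiratoryConfig(),
) -> complex:
    """Respiratory-system impedance from lung impedance.

    Adds central-airway and chest-wall resistance in series and the chest-wall
    elastic reactance -j E_cw / omega; if the shunt is enabled the result is
    placed in parallel with the upper-airway impedance Z_uaw(f).
    """
    if frequency_hz <= 0:
        raise DomainError("frequency must be positive")
    omega = 2.0 * np.pi * frequency_hz
    z = (
        z_lung
        + config.r_central
        + config.r_chest_wall
        - 1j * config.e_chest_wall / omega
    )
    if config.shunt_enabled:
        z_uaw = config.shunt_impedance(frequency_hz)
        z = z * z_uaw / (z + z_uaw)
    return z


# ---------------------------------------------------------------------------
# spectra and metrics
# ---------------------------------------------------------------------------

@dataclass
class ImpedanceSpectrum:
    """Complex lung and respiratory-system impedance over a frequency grid."""

    frequencies_hz: np.ndarray
    z_lung: np.ndarray
    z_rs: np.ndarray
    stage: str = "respiratory_system"

    @property
    def R_lung(self) -> np.ndarray:
        return self.z_lung.real

    @property
    def X_lung(self) -> np.ndarray:
        return self.z_lung.imag

    @property
    def R_rs(self) -> np.ndarray:
        return self.z_rs.real

    @property
    def X_rs(self) -> np.ndarray:
        return self.z_rs.imag

    def at(self, frequency_hz: float) -> tuple[complex, complex]:
        """(Z_lung, Z_rs) at an exact grid frequency."""
        hit = np.flatnonzero(np.isclose(self.frequencies_hz, frequency_hz))
        if hit.size == 0:
            raise MetricError(f"frequency {frequency_hz} Hz not in spectrum grid")
        i = int(hit[0])
        return complex(self.z_lung[i]), complex(self.z_rs[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_hz": self.frequencies_hz,
                "R_lung": self.R_lung,
                "X_lung": self.X_lung,
                "R_rs": self.R_rs,
                "X_rs": self.X_rs,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


#: JSON/report keys of the derived band metrics
METRIC_KEYS = (
    "Rrs0.2",
    "Rrs5",
    "Rrs20",
    "Rrs0.2-5",
    "Rrs5-20",
    "Xrs0.2",
    "Xrs5",
    "Xrs20",
    "Ers0.2",
    "Ers5",
)


@dataclass(frozen=True)
class ImpedanceMetrics:
    """Point, band-difference and low-frequency elastance metrics.

    Resistances/reactances in cmH2O s/L; elastances (Ers) in cmH2O/L computed
    as 2 pi f |X_rs(f)| at 0.2 and 5 Hz only, where reactance is dominated by
    elastic mechanics. The magnitude is used so elastance is positive even
    though low-frequency X_rs is negative.
    """

    rrs_0p2: float
    rrs_5: float
    rrs_20: float
    rrs_0p2_5: float
    rrs_5_20: float
    xrs_0p2: float
    xrs_5: float
    xrs_20: float
    ers_0p2: float
    ers_5: float

    def to_dict(self) -> dict[str, float]:
        vals = (
            self.rrs_0p2,
            self.rrs_5,
            self.rrs_20,
            self.rrs_0p2_5,
            self.rrs_5_20,
            self.xrs_0p2,
            self.xrs_5,
            self.xrs_20,
            self.ers_0p2,
            self.ers_5,
        )
        return dict(zip(METRIC_KEYS, vals))


def derived_metrics(spectrum: ImpedanceSpectrum, stage: str = "rs") -> ImpedanceMetrics:
    """Band metrics from a spectrum containing 0.2, 5 and 20 Hz exactly."""
    if stage not in ("rs", "lung"):
        raise MetricError("stage must be 'rs' or 'lung'")
    z = {}
    for f in (0.2, 5.0, 20.0):
        z_lung, z_rs = spectrum.at(f)
        z[f] = z_rs if stage == "rs" else z_lung
    return ImpedanceMetrics(
        rrs_0p2=z[0.2].real,
        rrs_5=z[5.0].real,
        rrs_20=z[20.0].real,
        rrs_0p2_5=z[0.2].real - z[5.0].real,
        rrs_5_20=z[5.0].real - z[20.0].real,
        xrs_0p2=z[0.2].imag,
        xrs_5=z[5.0].imag,
        xrs_20=z[20.0].imag,
        ers_0p2=2.0 * np.pi * 0.2 * abs(z[0.2].imag),
        ers_5=2.0 * np.pi * 5.0 * abs(z[5.0].imag),
    )


def frequency_sweep(
    tree: AirwayTree,
    gas: GasProperties = GasProperties(),
    elastance: ElastanceModel = ElastanceModel(),
    config: RespiratoryConfig = RespiratoryConfig(),
    frequencies_hz: Sequence[float] = DEFAULT_FREQUENCIES,
    allow_outside_range: bool = False,
) -> ImpedanceSpectrum:
    """Evaluate lung and respiratory-system impedance over a frequency grid."""
    freqs = np.asarray(frequencies_hz, dtype=float)
    if freqs.ndim != 1 or freqs.size == 0 or np.any(np.diff(freqs) <= 0):
        raise DomainError("frequencies must be a strictly increasing 1-D grid")
    if not allow_outside_range and (freqs[0] < 0.2 - 1e-12 or freqs[-1] > 32.0 + 1e-12):
        raise DomainError(
            "default frequency range is [0.2, 32] Hz; pass allow_outside_range=True to override"
        )
    tree.validate()
    z_lung = np.empty(freqs.size, dtype=complex)
    z_rs = np.empty(freqs.size, dtype=complex)
    for i, f in enumerate(freqs):
        try:
            z_a = airway_impedance_vec(tree.diameter_mm, tree.length_mm, f, gas)
            z_lung[i] = _reduce_tree(tree, z_a, f, elastance)
            z_rs[i] = respiratory_impedance(z_lung[i], f, config)
        except Exception as exc:  # annotate with the offending frequency
            raise type(exc)(f"at {f} Hz: {exc}") from exc
    return ImpedanceSpectrum(frequencies_hz=freqs, z_lung=z_lung, z_rs=z_rs)


class ImpedanceEngine:
    """Cached per-frequency airway impedances for repeated narrowed sweeps.

    Computing Bessel functions for all ~65k branches dominates a sweep; a
    narrowing perturbation touches only a handful of branches, so the engine
    caches the base-tree Z_a per frequency and recomputes only the narrowed
    columns. ``sweep()`` with no arguments reproduces :func:`frequency_sweep`
    bit-for-bit.
    """

    def __init__(
        self,
        tree: AirwayTree,
        gas: GasProperties = GasProperties(),
        elastance: ElastanceModel = ElastanceModel(),
        config: RespiratoryConfig = RespiratoryConfig(),
        frequencies_hz: Sequence[float] = DEFAULT_FREQUENCIES,
    ) -> None:
        tree.validate()
        self.tree = tree
        self.gas = gas
        self.elastance = elastance
        self.config = config
        self.frequencies_hz = np.asarray(frequencies_hz, dtype=float)
        if np.any(np.diff(self.frequencies_hz) <= 0):
            raise DomainError("frequencies must be strictly increasing")
        self._z_a = [
            airway_impedance_vec(tree.diameter_mm, tree.length_mm, f, gas)
            for f in self.frequencies_hz
        ]

    def sweep(
        self,
        narrow_ids: Sequence[int] | None = None,
        diameter_factor: float = 1.0,
    ) -> ImpedanceSpectrum:
        ids = np.asarray(
            [] if narrow_ids is None else narrow_ids, dtype=np.int64
        ).ravel()
        if ids.size and not 0 < diameter_factor <= 1:
            raise DomainError("diameter_factor must be in (0, 1]")
        z_lung = np.empty(self.frequencies_hz.size, dtype=complex)
        z_rs = np.empty_like(z_lung)
        for i, f in enumerate(self.frequencies_hz):
            z_a = self._z_a[i]
            if ids.size:
                z_a = z_a.copy()
                z_a[ids] = airway_impedance_vec(
                    self.tree.diameter_mm[ids] * diameter_factor,
                    self.tree.length_mm[ids],
                    f,
                    self.gas,
                )
            z_lung[i] = _reduce_tree(self.tree, z_a, f, self.elastance)
            z_rs[i] = respiratory_impedance(z_lung[i], f, self.config)
        return ImpedanceSpectrum(
            frequencies_hz=self.frequencies_hz.copy(), z_lung=z_lung, z_rs=z_rs
        )
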