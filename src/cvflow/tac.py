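"""Time-attenuation curves and the gamma-variate bolus model.

Dynamic CTA acquires a short series of whole-brain volumes (19 by default)
while a contrast bolus passes through the cerebral vasculature.  For every
vascular structure of interest a time-attenuation curve (TAC) records the
mean attenuation (HU) at each acquisition time.  The contrast bolus itself
is modelled with the standard gamma-variate shape

    y(t) = baseline + K * (t - t0)**alpha * exp(-(t - t0) / beta),  t > t0

whose peak sits at ``t0 + alpha * beta``.  The arterial phase (A-TAC) and
venous phase (V-TAC) are selected from the middle-cerebral-artery (MCA) and
superior-sagittal-sinus (SSS) TACs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionGrid",
    "GammaVariateParams",
    "Tac",
    "PhaseSelection",
    "PhaseSelectionError",
    "eval_gamma_variate",
    "sample_tac",
    "select_phases",
    "default_grid",
]


class PhaseSelectionError(ValueError):
    """No admissible arterial time point exists before the venous peak."""


@dataclass(frozen=True)
class AcquisitionGrid:
    """Strictly increasing acquisition times, in seconds."""

    times: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        if len(times) < 3:
            raise ValueError("acquisition grid needs at least 3 time points")
        if any(t <= 0 for t in times):
            raise ValueError("acquisition times must be positive")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("acquisition times must be strictly increasing")
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def spacing(self) -> float:
        """Median inter-volume interval (exact for uniform grids)."""
        return float(np.median(np.diff(self.array)))

    @property
    def start(self) -> float:
        return self.times[0]

    @property
    def end(self) -> float:
        return self.times[-1]


def default_grid(n_volumes: int = 19, spacing: float = 2.0, start: float = 8.0) -> AcquisitionGrid:
    """Default 19-volume grid at 2.0 s spacing starting 8.0 s after injection."""
    return AcquisitionGrid(tuple(start + spacing * i for i in range(n_volumes)))


@dataclass(frozen=True)
class GammaVariateParams:
    """Gamma-variate bolus parameters.

    t0       bolus arrival time (s)
    alpha    shape (dimensionless, > 0)
    beta     timescale (s, > 0)
    K        amplitude scale (HU, > 0)
    baseline pre-contrast attenuation (HU)
    """

    t0: float
    alpha: float
    beta: float
    K: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.K <= 0:
            raise ValueError("K must be positive")

    @property
    def peak_time(self) -> float:
        return self.t0 + self.alpha * self.beta

    @property
    def peak_enhancement(self) -> float:
        """Enhancement above baseline at the analytic mode."""
        x = self.alpha * self.beta
        return self.K * x**self.alpha * np.exp(-self.alpha)


@dataclass(frozen=True)
class Tac:
    """One vessel's attenuation samples on an acquisition grid."""

    grid: AcquisitionGrid
    values: tuple[float, ...]
    baseline: float | None = None

    def __post_init__(self) -> None:
        values = tuple(float(v) for v in self.values)
        if len(values) != len(self.grid):
            raise ValueError("values length must equal grid length")
        object.__setattr__(self, "values", values)
        if self.baseline is None:
            # pre-contrast volume is acquired first
            object.__setattr__(self, "baseline", values[0])

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @property
    def enhancement(self) -> np.ndarray:
        """Baseline-corrected attenuation at every grid point."""
        return self.array - self.baseline

    def shifted(self, dt_samples: int) -> "Tac":
        """TAC translated later by an integer number of grid samples."""
        v = np.roll(self.array, dt_samples)
        v[:dt_samples] = self.values[0]
        return Tac(self.grid, tuple(v), baseline=self.baseline)


@dataclass(frozen=True)
class PhaseSelection:
    """Selected arterial (A-TAC) and venous (V-TAC) time points."""

    a_tac: float
    v_tac: float

    def __post_init__(self) -> None:
        if not self.a_tac < self.v_tac:
            raise ValueError("a_tac must precede v_tac")


def eval_gamma_variate(params: GammaVariateParams, t) -> np.ndarray | float:
    """Evaluate the gamma-variate bolus curve at time(s) ``t`` (HU).

    Returns the baseline for t <= t0 and
    ``baseline + K*(t-t0)**alpha * exp(-(t-t0)/beta)`` afterwards; the curve
    is continuous at t0 for alpha > 0.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("t must be finite")
    dt = np.maximum(t_arr - params.t0, 0.0)
    with np.errstate(over="ignore"):
        enh = params.K * dt**params.alpha * np.exp(-dt / params.beta)
    out = params.baseline + enh
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def sample_tac(
    params: GammaVariateParams,
    grid: AcquisitionGrid,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> Tac:
    """Sample the bolus model on an acquisition grid with i.i.d. Gaussian noise.

    ``seed`` may be an integer (reproducible: identical inputs give an
    identical TAC) or an existing :class:`numpy.random.Generator`.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    clean = np.asarray(eval_gamma_variate(params, grid.array), dtype=float)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        clean = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    return Tac(grid, tuple(clean), baseline=params.baseline)


def select_phases(mca_affected: Tac, mca_contralateral: Tac, sss: Tac) -> PhaseSelection:
    """Select A-TAC and V-TAC from the bilateral MCA and SSS curves.

    V-TAC is the grid time of the maximum enhancement of the superior
    sagittal sinus.  A-TAC is the grid time, restricted to times strictly
    before V-TAC, with the best *bilateral* arterial opacification —
    operationalized as the maximum over time of the minimum of the two
    baseline-corrected MCA enhancements (the pre-venous constraint encodes
    "less affected by cortical veins and venous sinuses").  Ties break
    toward the earlier time.
    """
    if not (mca_affected.grid == mca_contralateral.grid == sss.grid):
        raise ValueError("all TACs must share one acquisition grid")
    times = sss.grid.array
    v_idx = int(np.argmax(sss.enhancement))  # argmax takes the earliest tie
    v_tac = times[v_idx]
    pre = times < v_tac
    if not pre.any():
        raise PhaseSelectionError(
            f"no acquisition time precedes the venous peak at {v_tac:g} s"
        )
    bilateral = np.minimum(mca_affected.enhancement, mca_contralateral.enhancement)
    masked = np.where(pre, bilateral, -np.inf)
    a_tac = times[int(np.argmax(masked))]
    return PhaseSelection(a_tac=float(a_tac), v_tac=float(v_tac))
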