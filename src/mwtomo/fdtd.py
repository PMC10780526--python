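"""2D transverse-magnetic FDTD solver with a convolutional PML.

The solver advances the TMz reduction of Maxwell's curl equations (one
out-of-plane electric component Ez, in-plane Hx and Hy) on a staggered Yee
grid with per-cell lossy-dielectric update coefficients

    Ca = (1 - sigma*dt/(2*eps)) / (1 + sigma*dt/(2*eps))
    Cb = (dt/(eps*dx))          / (1 + sigma*dt/(2*eps))

(eps absolute permittivity). Antennas are idealized 2D Hertzian elements:
additive ("soft") Ez point sources at the nearest grid cell, with receivers
sampling Ez at the same cells. The grid is terminated by a convolutional
perfectly matched layer (polynomial grading) backed by a PEC wall; the
matching medium fills everything outside the imaging circle, including
under the PML, which keeps the minimum permittivity on the grid at 10 and
the paper-default 4.72 ps time step inside the 2D Courant bound
dt <= dx*sqrt(eps_min)/(c0*sqrt(2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import C0, EPS0, MU0, ConfigError, DomainConfig, SolverConfig
from .phantoms import PhantomCase


class CourantError(ValueError):
    """Time step violates the 2D stability bound."""


class InstabilityError(RuntimeError):
    """Non-finite field values appeared during time stepping."""


# ---------------------------------------------------------------------------
# excitation pulse
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseWaveform:
    """Gaussian-modulated sinusoid sampled at the solver time step."""

    samples: np.ndarray       # (n_steps,), arbitrary source units
    center_frequency: float   # Hz
    spectral_width: float     # Hz, std of the (one-sided) amplitude spectrum
    delay: float              # s


def design_pulse(
    band_low: float, band_high: float, dt: float, n_steps: int
) -> PulseWaveform:
    """Pulse whose power spectrum is 10 dB down exactly at the band edges.

    A Gaussian envelope of width tau modulating a sinusoid at the band
    center has a Gaussian amplitude spectrum of std sigma_f = 1/(2*pi*tau);
    the -10 dB *power* points sit at center +/- sigma_f*sqrt(ln 10).
    The delay is 4.5 envelope stds, placing the start below 1e-4 of peak.
    """
    if not (0 < band_low < band_high):
        raise ConfigError("require 0 < band_low < band_high")
    if band_high >= 0.5 / dt:
        raise ConfigError(
            f"band_high {band_high:.3g} Hz violates the Nyquist limit {0.5/dt:.3g} Hz"
        )
    fc = 0.5 * (band_low + band_high)
    half_band = 0.5 * (band_high - band_low)
    sigma_f = half_band / np.sqrt(np.log(10.0))
    tau = 1.0 / (2 * np.pi * sigma_f)
    t0 = 4.5 * tau
    t = np.arange(n_steps) * dt
    samples = np.exp(-((t - t0) ** 2) / (2 * tau**2)) * np.sin(
        2 * np.pi * fc * (t - t0)
    )
    return PulseWaveform(
        samples=samples, center_frequency=fc, spectral_width=sigma_f, delay=t0
    )


def measure_band_edges(
    samples: np.ndarray, dt: float, drop_db: float = 10.0
) -> tuple[float, float]:
    """Measured frequencies where spectral power falls ``drop_db`` below peak.

    Linear interpolation of the dB power spectrum between FFT bins; returns
    (lower_edge_hz, upper_edge_hz) bracketing the spectral peak.
    """
    spec = np.abs(np.fft.rfft(samples))
    freqs = np.fft.rfftfreq(len(samples), dt)
    power_db = 20 * np.log10(np.maximum(spec, 1e-300) / spec.max())
    k_peak = int(np.argmax(power_db))

    def _cross(ks) -> float:
        prev = None
        for k in ks:
            if power_db[k] <= -drop_db:
                assert prev is not None
                # interpolate between k and the previous (inner) bin
                f1, f2 = freqs[prev], freqs[k]
                p1, p2 = power_db[prev], power_db[k]
                return f1 + ((-drop_db) - p1) * (f2 - f1) / (p2 - p1)
            prev = k
        raise ValueError("spectrum never drops to the requested level")

    lower = _cross(range(k_peak, -1, -1))
    upper = _cross(range(k_peak, len(freqs)))
    return lower, upper


# ---------------------------------------------------------------------------
# antenna array
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AntennaArray:
    """Evenly spaced antenna ring: physical positions and nearest grid cells."""

    positions: np.ndarray      # (n_antennas, 2) mm, (x, y)
    grid_indices: tuple[tuple[int, int], ...]  # (row, col) per antenna

    @classmethod
    def from_domain(cls, cfg: DomainConfig, start_angle: float = 0.0) -> "AntennaArray":
        """Ring of ``cfg.n_antennas`` antennas at ``cfg.antenna_radius``,
        counter-clockwise from ``start_angle`` degrees (east)."""
        angles = np.deg2rad(start_angle + 360.0 * np.arange(cfg.n_antennas) / cfg.n_antennas)
        pos = cfg.antenna_radius * np.column_stack([np.cos(angles), np.sin(angles)])
        n = cfg.n_cells
        delta = cfg.domain_size / n

        def _idx(coord: float) -> int:
            i = int(round((coord + cfg.domain_size / 2) / delta - 0.5))
            return min(max(i, 0), n - 1)

        grid = tuple((_idx(y), _idx(x)) for x, y in pos)
        return cls(positions=pos, grid_indices=grid)

    @property
    def n_antennas(self) -> int:
        return len(self.grid_indices)


# ---------------------------------------------------------------------------
# simulation state
# ---------------------------------------------------------------------------

def _cpml_profiles(
    n_nodes: int, half: bool, cfg: SolverConfig, eps_edge: float
) -> tuple[np.ndarray, np.ndarray]:
    """CPML recursion coefficients (b, c) along one axis.

    Polynomial conductivity grading of order ``pml_order`` scaled for the
    background permittivity at the wall; ``half=True`` evaluates at the
    staggered (H) node positions. Both profiles are measured from the E-grid
    walls (node 0 and node n-1): a half-cell misalignment of the staggered
    profile degrades the layer by tens of dB. Outside the layer b=1, c=0 so
    the psi accumulators stay exactly zero there.
    """
    d = cfg.pml_cells
    m = cfg.pml_order
    sigma_max = (
        cfg.pml_sigma_factor
        * (m + 1) * np.log(1.0 / cfg.pml_target_reflection)
        * EPS0 * C0 * np.sqrt(eps_edge) / (2.0 * d * cfg.dx)
    ) if d > 0 else 0.0
    # CPML alpha is kept at zero: at this band (0.5-2 GHz) even alpha ~ 0.02
    # S/m has alpha/eps0 comparable to omega, which distorts the stretch in
    # the shallow layer and costs tens of dB of reflection. The lossy
    # matching-medium background handles late-time/low-frequency energy.
    alpha = 0.0

    pos = np.arange(n_nodes) + (0.5 if half else 0.0)
    wall_r = n_nodes if half else n_nodes - 1  # E-grid coordinate of the far wall
    depth = np.maximum(d - pos, pos - (wall_r - d)) / d if d > 0 else np.zeros(n_nodes)
    depth = np.clip(depth, 0.0, 1.0)
    sigma = sigma_max * depth**m
    in_layer = depth > 0
    b = np.where(in_layer, np.exp(-(sigma + alpha) * cfg.dt / EPS0), 1.0)
    c = np.where(in_layer, sigma * (b - 1.0) / np.maximum(sigma + alpha, 1e-30), 0.0)
    return b, c


@dataclass
class SimulationState:
    """Yee-grid field state plus precomputed update and CPML coefficients."""

    cfg: SolverConfig
    ez: np.ndarray            # (n, n)
    hx: np.ndarray            # (n-1, n)
    hy: np.ndarray            # (n, n-1)
    ca: np.ndarray            # (n, n)
    cb: np.ndarray            # (n, n)
    mh: float                 # dt / (mu0 * dx)
    # CPML psi accumulators (difference units) and per-axis coefficients
    psi_hx: np.ndarray = field(repr=False, default=None)
    psi_hy: np.ndarray = field(repr=False, default=None)
    psi_ez_x: np.ndarray = field(repr=False, default=None)
    psi_ez_y: np.ndarray = field(repr=False, default=None)
    b_e: np.ndarray = field(repr=False, default=None)
    c_e: np.ndarray = field(repr=False, default=None)
    b_h: np.ndarray = field(repr=False, default=None)
    c_h: np.ndarray = field(repr=False, default=None)
    step_count: int = 0

    @property
    def n(self) -> int:
        return self.ez.shape[0]

    def reset(self) -> None:
        """Zero all fields and accumulators (reused between transmitters)."""
        for a in (self.ez, self.hx, self.hy, self.psi_hx, self.psi_hy,
                  self.psi_ez_x, self.psi_ez_y):
            a.fill(0.0)
        self.step_count = 0


def build_simulation(
    phantom: PhantomCase, array: AntennaArray, cfg: SolverConfig
) -> SimulationState:
    """Precompute per-cell update coefficients and CPML profiles.

    Raises :class:`CourantError` when ``cfg.dt`` exceeds the eps-aware 2D
    stability bound — e.g. any vacuum cell (eps_r = 1) makes the paper
    default dt = 4.72 ps unstable (limit ~4.714 ps), while the phantom
    minimum eps_r = 10 admits it (limit ~14.9 ps).
    """
    eps_r = np.asarray(phantom.eps_map, dtype=float)
    sigma = np.asarray(phantom.sigma_map, dtype=float)
    n = eps_r.shape[0]
    if eps_r.shape != sigma.shape or eps_r.shape[0] != eps_r.shape[1]:
        raise ConfigError("phantom maps must be square and congruent")

    eps_min = float(eps_r.min())
    dt_max = cfg.courant_limit(eps_min)
    if cfg.dt > dt_max:
        raise CourantError(
            f"dt = {cfg.dt:.4g} s unstable for eps_min = {eps_min:.4g}: "
            f"admissible dt <= {dt_max:.4g} s"
        )

    eps = eps_r * EPS0
    loss = sigma * cfg.dt / (2.0 * eps)
    ca = (1.0 - loss) / (1.0 + loss)
    cb = (cfg.dt / (eps * cfg.dx)) / (1.0 + loss)

    eps_edge = float(np.mean([eps_r[0, :].mean(), eps_r[-1, :].mean(),
                              eps_r[:, 0].mean(), eps_r[:, -1].mean()]))
    b_e, c_e = _cpml_profiles(n, half=False, cfg=cfg, eps_edge=eps_edge)
    b_h, c_h = _cpml_profiles(n - 1, half=True, cfg=cfg, eps_edge=eps_edge)

    return SimulationState(
        cfg=cfg,
        ez=np.zeros((n, n)),
        hx=np.zeros((n - 1, n)),
        hy=np.zeros((n, n - 1)),
        ca=ca,
        cb=cb,
        mh=cfg.dt / (MU0 * cfg.dx),
        psi_hx=np.zeros((n - 1, n)),
        psi_hy=np.zeros((n, n - 1)),
        psi_ez_x=np.zeros((n, n - 1)),
        psi_ez_y=np.zeros((n - 1, n)),
        b_e=b_e, c_e=c_e, b_h=b_h, c_h=c_h,
    )


def step(
    state: SimulationState,
    source_value: float = 0.0,
    tx_cell: tuple[int, int] | None = None,
) -> SimulationState:
    """One leapfrog update (H half-step then E full step), in place.

    The source is soft: ``source_value`` is added to Ez at ``tx_cell`` after
    the field update, equivalent to an impressed line current at that cell.
    """
    ez, hx, hy = state.ez, state.hx, state.hy

    # H from curl of Ez (differences in "grid units", dx folded into mh)
    d_ez_y = ez[1:, :] - ez[:-1, :]
    state.psi_hx *= state.b_h[:, None]
    state.psi_hx += state.c_h[:, None] * d_ez_y
    hx -= state.mh * (d_ez_y + state.psi_hx)

    d_ez_x = ez[:, 1:] - ez[:, :-1]
    state.psi_hy *= state.b_h[None, :]
    state.psi_hy += state.c_h[None, :] * d_ez_x
    hy += state.mh * (d_ez_x + state.psi_hy)

    # Ez interior from curl of H with loss coefficients
    d_hy_x = hy[1:-1, 1:] - hy[1:-1, :-1]
    px = state.psi_ez_x[1:-1, 1:]
    px *= state.b_e[None, 1:-1]
    px += state.c_e[None, 1:-1] * d_hy_x

    d_hx_y = hx[1:, 1:-1] - hx[:-1, 1:-1]
    py = state.psi_ez_y[1:, 1:-1]
    py *= state.b_e[1:-1, None]
    py += state.c_e[1:-1, None] * d_hx_y

    ez[1:-1, 1:-1] = state.ca[1:-1, 1:-1] * ez[1:-1, 1:-1] + state.cb[1:-1, 1:-1] * (
        (d_hy_x + px) - (d_hx_y + py)
    )

    if tx_cell is not None and source_value != 0.0:
        ez[tx_cell] += source_value

    state.step_count += 1
    return state


def run_single_tx(
    sim: SimulationState,
    array: AntennaArray,
    tx_index: int,
    pulse: PulseWaveform,
) -> np.ndarray:
    """Drive one transmitter and record Ez at every antenna cell.

    Returns an (n_antennas, n_steps) trace array; the transmitter's own
    cell is recorded like any receiver.
    """
    if not (0 <= tx_index < array.n_antennas):
        raise ConfigError(f"tx_index {tx_index} out of range")
    sim.reset()
    n_steps = len(pulse.samples)
    rx_rows = np.array([r for r, _ in array.grid_indices])
    rx_cols = np.array([c for _, c in array.grid_indices])
    tx_cell = array.grid_indices[tx_index]
    out = np.empty((array.n_antennas, n_steps))
    for nstep in range(n_steps):
        step(sim, float(pulse.samples[nstep]), tx_cell)
        out[:, nstep] = sim.ez[rx_rows, rx_cols]
        if nstep % 500 == 499 and not np.isfinite(sim.ez[rx_rows, rx_cols]).all():
            raise InstabilityError(
                f"non-finite fields at step {nstep} (tx {tx_index})"
            )
    if not np.isfinite(out).all():
        bad = int(np.argwhere(~np.isfinite(out))[0, 1])
        raise InstabilityError(f"non-finite trace values at step {bad} (tx {tx_index})")
    return out


@dataclass(frozen=True)
class SignalTensor:
    """Raw multistatic traces: (transmitter, receiver, time)."""

    data: np.ndarray   # (n_antennas, n_antennas, n_steps)

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[0] != self.data.shape[1]:
            raise ConfigError("SignalTensor must be (n_ant, n_ant, n_steps)")


def run_multistatic(
    phantom: PhantomCase,
    array: AntennaArray,
    cfg: SolverConfig,
    pulse: PulseWaveform | None = None,
    progress: bool = False,
) -> SignalTensor:
    """Full multistatic acquisition: every antenna transmits in turn.

    Deterministic given its inputs; 16 antennas yield 256 traces. The
    default pulse is the 0.5–2 GHz design at the solver time step.
    """
    if pulse is None:
        pulse = design_pulse(cfg.band_low, cfg.band_high, cfg.dt, cfg.n_steps)
    sim = build_simulation(phantom, array, cfg)
    n_ant = array.n_antennas
    data = np.empty((n_ant, n_ant, len(pulse.samples)))
    for tx in range(n_ant):
        try:
            data[tx] = run_single_tx(sim, array, tx, pulse)
        except InstabilityError as exc:
            raise InstabilityError(f"transmitter {tx}: {exc}") from exc
    return SignalTensor(data=data)


def homogeneous_phantom(
    cfg: DomainConfig, eps_r: float | None = None, sigma: float | None = None
) -> PhantomCase:
    """Uniform-medium phantom (defaults to the matching medium everywhere).

    Used for calibration/empty-domain runs and solver validation; the label
    is the constant permittivity image.
    """
    n = cfg.n_cells
    e = cfg.matching_eps if eps_r is None else float(eps_r)
    s = cfg.matching_sigma if sigma is None else float(sigma)
    return PhantomCase(
        case_id="homogeneous",
        shapes=[],
        eps_map=np.full((n, n), e),
        sigma_map=np.full((n, n), s),
        label_eps=np.full((cfg.label_size, cfg.label_size), e),
        group_index=0,
    )


def export_trace_ascii(trace: np.ndarray, dt: float, path) -> None:
    """Two-column ASCII dump (time_s, ez) of one trace for inspection."""
    t = np.arange(len(trace)) * dt
    np.savetxt(path, np.column_stack([t, trace]), header="time_s ez")


def scattered_field(total: SignalTensor, incident: SignalTensor) -> SignalTensor:
    """Empty-domain subtraction: scattered = total - incident."""
    if total.data.shape != incident.data.shape:
        raise ConfigError("tensor shapes differ")
    return SignalTensor(data=total.data - incident.data)
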