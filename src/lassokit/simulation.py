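"""Metropolis Monte Carlo of an excluded-volume loop on a periodic thread.

The system is a ring of N beads with stiff harmonic bonds (k = 20000
kJ/mol/nm^2, r0 = 0.38 nm, the mean Calpha-Calpha distance) and a purely
repulsive r^-12 excluded-volume potential (A = 4*eps*sigma^12 =
0.16777216e-4 kJ nm^12/mol, i.e. a ~0.4 nm contact diameter at the
simulation temperatures, slightly above r0 so strands cannot slip through
each other), cut off at 2 nm.  For thread thickness w > 0 the loop
encircles an immobile straight thread of N_B = max(N/2 + 5, 12) beads made
periodic along its axis (box length 0.38*N_B nm) so the loop cannot slip
off; thread beads are w times thicker than loop beads.  No angular or
attractive terms are present.

Sampling uses Metropolis Monte Carlo instead of Langevin dynamics: the
observables of interest are equilibrium ensemble averages, and MC with the
same potential energy samples the same Boltzmann ensemble.  The move set
is single-bead displacement plus crankshaft rotations (which preserve all
bond lengths exactly); moves that would change the winding number of the
loop around the thread axis are rejected, so threading is conserved by
construction.  Temperatures are Gromacs-style (Kelvin with energies in
kJ/mol), beta = 1/(k_B T), k_B = 0.0083145 kJ/mol/K.

Equilibration is removed by the chord-correlation rule: frames up to three
times the time at which the chord (bond-vector) autocorrelation first
drops to 0.1 are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "KB",
    "N_SMALL",
    "SimConfig",
    "Frame",
    "Trajectory",
    "TooSmallLoopError",
    "InsufficientSamplingError",
    "build_system",
    "potential_energy",
    "run_simulation",
    "chord_correlation",
    "check_threading",
    "winding_number",
]

KB = 0.0083145  # kJ/mol/K

#: smallest loop that fits around a thread of thickness w
N_SMALL = {0: 3, 1: 4, 2: 6, 3: 7, 4: 7}


class TooSmallLoopError(ValueError):
    pass


class InsufficientSamplingError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Simulation condition (one loop length, thread thickness, temperature)."""

    n: int
    w: int = 0
    temperature: float = 100.0  # K (Gromacs units)
    r0: float = 0.38  # nm equilibrium bond length
    k_bond: float = 20000.0  # kJ/mol/nm^2
    vdw_a: float = 0.16777216e-4  # kJ nm^12 / mol
    vdw_cutoff: float = 2.0  # nm
    energy_cap: float = 1e6  # kJ/mol, per-pair cap keeps MC well defined
    seed: int = 0
    stride: int = 2  # sweeps between recorded frames
    target_frames: int = 200  # decorrelated frames to collect
    tune_sweeps: int = 400  # move-size auto-tuning phase (then frozen)
    equil_sweeps: int | None = None  # unrecorded pre-equilibration; default 20*N
    max_arc: int = 12  # largest crankshaft arc (beads moved)
    max_frames: int = 200_000  # hard cap on recorded frames

    def __post_init__(self) -> None:
        if self.w not in N_SMALL:
            raise ValueError("thread thickness w must be in {0,1,2,3,4}")
        if self.n < N_SMALL[self.w]:
            raise TooSmallLoopError(
                f"loop of {self.n} beads is too small for thread thickness "
                f"{self.w} (minimum {N_SMALL[self.w]})"
            )
        for name in ("temperature", "r0", "k_bond", "vdw_a", "vdw_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_thread_beads(self) -> int:
        return max(self.n // 2 + 5, 12) if self.w > 0 else 0

    @property
    def box(self) -> float:
        return self.r0 * self.n_thread_beads if self.w > 0 else 0.0

    @property
    def vdw_a_thread(self) -> float:
        # additive-radii mixing: thread beads are w times thicker, so the
        # loop-thread contact distance scales by (1 + w) / 2
        return self.vdw_a * ((1.0 + self.w) / 2.0) ** 12

    @property
    def beta(self) -> float:
        return 1.0 / (KB * self.temperature)


@dataclass
class Frame:
    coords: np.ndarray  # (N, 3) loop bead coordinates, nm, unwrapped
    step: int  # MC sweep index
    energy: float  # kJ/mol


@dataclass
class Trajectory:
    frames: np.ndarray  # (F, N, 3) post-burn-in loop coordinates
    energies: np.ndarray  # (F,)
    config: SimConfig
    thread: np.ndarray  # (N_B, 3) thread bead coordinates (empty if w = 0)
    tau_frames: int  # chord-correlation decorrelation time, in frames
    burn_in_frames: int  # frames removed (3 * tau)
    acceptance: dict = field(default_factory=dict)

    @property
    def n_effective(self) -> float:
        return self.frames.shape[0] / max(self.tau_frames, 1)


def build_system(config: SimConfig) -> tuple[Frame, np.ndarray]:
    """Initial state: straight thread on the z axis, loop encircling it.

    The loop starts as a planar regular N-gon perpendicular to the thread
    (or free-floating for w = 0).  Returns (frame, thread_coords).
    """
    n = config.n
    circum_r = config.r0 / (2.0 * np.sin(np.pi / n))
    th = 2.0 * np.pi * np.arange(n) / n
    loop = np.stack(
        [circum_r * np.cos(th), circum_r * np.sin(th), np.zeros(n)], axis=1
    )
    if config.w > 0:
        nb = config.n_thread_beads
        thread = np.zeros((nb, 3))
        thread[:, 2] = config.r0 * np.arange(nb)
        loop[:, 2] += config.box / 2.0
    else:
        thread = np.zeros((0, 3))
    e = potential_energy(loop, config, thread)
    if e >= config.energy_cap:
        raise TooSmallLoopError(
            "initial state has hard excluded-volume overlap; loop too small"
        )
    return Frame(coords=loop, step=0, energy=e), thread


@njit(cache=False)
def _pair_energy(r2, a_coeff, cutoff2, cap):
    if r2 >= cutoff2:
        return 0.0
    if r2 < 1e-12:
        return cap
    e = a_coeff / r2**6
    return e if e < cap else cap


@njit(cache=False)
def _total_energy(loop, thread, r0, k_bond, a_loop, a_thread, cutoff, box, cap):
    n = loop.shape[0]
    cutoff2 = cutoff * cutoff
    e = 0.0
    for i in range(n):
        j = (i + 1) % n
        dx = loop[j, 0] - loop[i, 0]
        dy = loop[j, 1] - loop[i, 1]
        dz = loop[j, 2] - loop[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        e += 0.5 * k_bond * (r - r0) ** 2
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # ring-closing bond pair
            dx = loop[j, 0] - loop[i, 0]
            dy = loop[j, 1] - loop[i, 1]
            dz = loop[j, 2] - loop[i, 2]
            e += _pair_energy(dx * dx + dy * dy + dz * dz, a_loop, cutoff2, cap)
    nb = thread.shape[0]
    for i in range(n):
        for j in range(nb):
            dx = loop[i, 0] - thread[j, 0]
            dy = loop[i, 1] - thread[j, 1]
            dz = loop[i, 2] - thread[j, 2]
            if box > 0.0:
                dz -= box * np.round(dz / box)
            e += _pair_energy(dx * dx + dy * dy + dz * dz, a_thread, cutoff2, cap)
    return e


def potential_energy(
    coords: np.ndarray, config: SimConfig, thread: np.ndarray | None = None
) -> float:
    """Total potential energy (kJ/mol) of a loop frame.

    Harmonic ring bonds + repulsive r^-12 between non-bonded loop pairs
    and between loop and thread beads (minimum image along the thread
    axis); per-pair terms are capped so overlapping beads give a large but
    finite energy.  The immobile thread-thread contribution is a constant
    and is omitted.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if thread is None:
        thread = np.zeros((0, 3))
    return float(
        _total_energy(
            coords,
            np.asarray(thread, dtype=np.float64),
            config.r0,
            config.k_bond,
            config.vdw_a,
            config.vdw_a_thread,
            config.vdw_cutoff,
            config.box,
            config.energy_cap,
        )
    )


@njit(cache=False)
def _winding_angle(loop):
    """Total signed angle swept by the loop's xy projection around z."""
    n = loop.shape[0]
    total = 0.0
    for i in range(n):
        j = (i + 1) % n
        x0, y0 = loop[i, 0], loop[i, 1]
        x1, y1 = loop[j, 0], loop[j, 1]
        cross = x0 * y1 - y0 * x1
        dot = x0 * x1 + y0 * y1
        total += np.arctan2(cross, dot)
    return total


def winding_number(coords: np.ndarray) -> int:
    """Winding number of the loop's projection around the z axis."""
    return int(np.round(_winding_angle(np.asarray(coords, dtype=np.float64)) / (2 * np.pi)))


def check_threading(coords: np.ndarray, config: SimConfig) -> bool:
    """True iff the loop winds exactly once around the thread axis."""
    if config.w == 0:
        return True
    return abs(winding_number(coords)) == 1


@njit(cache=False)
def _delta_e_bead(loop, thread, i, new, r0, k_bond, a_loop, a_thread, cutoff, box, cap):
    n = loop.shape[0]
    cutoff2 = cutoff * cutoff
    de = 0.0
    for nb_ in (-1, 1):
        j = (i + nb_) % n
        dx = loop[j, 0] - loop[i, 0]
        dy = loop[j, 1] - loop[i, 1]
        dz = loop[j, 2] - loop[i, 2]
        r_old = np.sqrt(dx * dx + dy * dy + dz * dz)
        dx = loop[j, 0] - new[0]
        dy = loop[j, 1] - new[1]
        dz = loop[j, 2] - new[2]
        r_new = np.sqrt(dx * dx + dy * dy + dz * dz)
        de += 0.5 * k_bond * ((r_new - r0) ** 2 - (r_old - r0) ** 2)
    for j in range(n):
        if j == i or j == (i + 1) % n or j == (i - 1) % n:
            continue
        dx = loop[j, 0] - loop[i, 0]
        dy = loop[j, 1] - loop[i, 1]
        dz = loop[j, 2] - loop[i, 2]
        de -= _pair_energy(dx * dx + dy * dy + dz * dz, a_loop, cutoff2, cap)
        dx = loop[j, 0] - new[0]
        dy = loop[j, 1] - new[1]
        dz = loop[j, 2] - new[2]
        de += _pair_energy(dx * dx + dy * dy + dz * dz, a_loop, cutoff2, cap)
    nt = thread.shape[0]
    for j in range(nt):
        dx = loop[i, 0] - thread[j, 0]
        dy = loop[i, 1] - thread[j, 1]
        dz = loop[i, 2] - thread[j, 2]
        if box > 0.0:
            dz -= box * np.round(dz / box)
        de -= _pair_energy(dx * dx + dy * dy + dz * dz, a_thread, cutoff2, cap)
        dx = new[0] - thread[j, 0]
        dy = new[1] - thread[j, 1]
        dz = new[2] - thread[j, 2]
        if box > 0.0:
            dz -= box * np.round(dz / box)
        de += _pair_energy(dx * dx + dy * dy + dz * dz, a_thread, cutoff2, cap)
    return de


@njit(cache=False)
def _arc_winding(loop, i0, m, new_arc):
    """Signed angle over the edges touched by the arc, old and new."""
    n = loop.shape[0]
    old = 0.0
    new = 0.0
    for k in range(m + 1):
        ia = (i0 + k) % n
        ib = (i0 + k + 1) % n
        x0, y0 = loop[ia, 0], loop[ia, 1]
        x1, y1 = loop[ib, 0], loop[ib, 1]
        old += np.arctan2(x0 * y1 - y0 * x1, x0 * x1 + y0 * y1)
        if 1 <= k <= m - 1:
            x0n, y0n = new_arc[k - 1, 0], new_arc[k - 1, 1]
        else:
            x0n, y0n = x0, y0
        if 1 <= k + 1 <= m - 1:
            x1n, y1n = new_arc[k, 0], new_arc[k, 1]
        else:
            x1n, y1n = x1, y1
        new += np.arctan2(x0n * y1n - y0n * x1n, x0n * x1n + y0n * y1n)
    return old, new


@njit(cache=False)
def _run_mc(
    loop,
    thread,
    r0,
    k_bond,
    a_loop,
    a_thread,
    cutoff,
    box,
    cap,
    beta,
    check_wind,
    n_sweeps,
    stride,
    max_arc,
    seed,
    step_disp,
    theta_max,
    tune,
    frames_out,
    energies_out,
):
    np.random.seed(seed)
    n = loop.shape[0]
    cutoff2 = cutoff * cutoff
    new = np.empty(3)
    new_arc = np.empty((n, 3))  # sized for the largest (half-ring) arcs
    acc_d = 0
    try_d = 0
    acc_c = 0
    try_c = 0
    nframes = 0
    for sweep in range(n_sweeps):
        for _mv in range(n):
            i = np.random.randint(0, n)
            if np.random.random() < 0.5 or n < 5:
                # single-bead displacement
                try_d += 1
                new[0] = loop[i, 0] + step_disp * (2.0 * np.random.random() - 1.0)
                new[1] = loop[i, 1] + step_disp * (2.0 * np.random.random() - 1.0)
                new[2] = loop[i, 2] + step_disp * (2.0 * np.random.random() - 1.0)
                de = _delta_e_bead(
                    loop, thread, i, new, r0, k_bond, a_loop, a_thread, cutoff, box, cap
                )
                if de <= 0.0 or np.random.random() < np.exp(-beta * de):
                    if check_wind:
                        # winding change over the two edges at bead i
                        jm = (i - 1) % n
                        jp = (i + 1) % n
                        old_ang = np.arctan2(
                            loop[jm, 0] * loop[i, 1] - loop[jm, 1] * loop[i, 0],
                            loop[jm, 0] * loop[i, 0] + loop[jm, 1] * loop[i, 1],
                        ) + np.arctan2(
                            loop[i, 0] * loop[jp, 1] - loop[i, 1] * loop[jp, 0],
                            loop[i, 0] * loop[jp, 0] + loop[i, 1] * loop[jp, 1],
                        )
                        new_ang = np.arctan2(
                            loop[jm, 0] * new[1] - loop[jm, 1] * new[0],
                            loop[jm, 0] * new[0] + loop[jm, 1] * new[1],
                        ) + np.arctan2(
                            new[0] * loop[jp, 1] - new[1] * loop[jp, 0],
                            new[0] * loop[jp, 0] + new[1] * loop[jp, 1],
                        )
                        if np.round((new_ang - old_ang) / (2.0 * np.pi)) != 0:
                            continue
                    loop[i, 0] = new[0]
                    loop[i, 1] = new[1]
                    loop[i, 2] = new[2]
                    acc_d += 1
            else:
                # crankshaft: rotate arc i+1 .. i+m-1 about chord (i, i+m)
                # mostly short local arcs; occasional half-ring pivots mix
                # the slow global size/shape modes
                try_c += 1
                if np.random.random() < 0.25 and n // 2 > max_arc:
                    mmax = n // 2
                else:
                    mmax = min(max_arc, n - 2)
                m = 2 + np.random.randint(0, mmax - 1) if mmax > 2 else 2
                j = (i + m) % n
                ax = loop[j, 0] - loop[i, 0]
                ay = loop[j, 1] - loop[i, 1]
                az = loop[j, 2] - loop[i, 2]
                an = np.sqrt(ax * ax + ay * ay + az * az)
                if an < 1e-12:
                    continue
                ax /= an
                ay /= an
                az /= an
                theta = theta_max * (2.0 * np.random.random() - 1.0)
                ct = np.cos(theta)
                st = np.sin(theta)
                # Rodrigues rotation of the interior arc beads about the chord
                for k in range(1, m):
                    idx = (i + k) % n
                    px = loop[idx, 0] - loop[i, 0]
                    py = loop[idx, 1] - loop[i, 1]
                    pz = loop[idx, 2] - loop[i, 2]
                    ad = ax * px + ay * py + az * pz
                    cx = ay * pz - az * py
                    cy = az * px - ax * pz
                    cz = ax * py - ay * px
                    new_arc[k - 1, 0] = loop[i, 0] + px * ct + cx * st + ax * ad * (1 - ct)
                    new_arc[k - 1, 1] = loop[i, 1] + py * ct + cy * st + ay * ad * (1 - ct)
                    new_arc[k - 1, 2] = loop[i, 2] + pz * ct + cz * st + az * ad * (1 - ct)
                # nonbonded delta: moved arc vs static beads and thread
                de = 0.0
                for k in range(1, m):
                    idx = (i + k) % n
                    for jj in range(n):
                        # skip beads inside the moved arc (internal distances
                        # are rotation-invariant) and bonded neighbours
                        off = (jj - i) % n
                        if 1 <= off <= m - 1:
                            continue
                        doff = (jj - idx) % n
                        if doff == 1 or doff == n - 1:
                            continue
                        dx = loop[jj, 0] - loop[idx, 0]
                        dy = loop[jj, 1] - loop[idx, 1]
                        dz = loop[jj, 2] - loop[idx, 2]
                        de -= _pair_energy(dx * dx + dy * dy + dz * dz, a_loop, cutoff2, cap)
                        dx = loop[jj, 0] - new_arc[k - 1, 0]
                        dy = loop[jj, 1] - new_arc[k - 1, 1]
                        dz = loop[jj, 2] - new_arc[k - 1, 2]
                        de += _pair_energy(dx * dx + dy * dy + dz * dz, a_loop, cutoff2, cap)
                    for jj in range(thread.shape[0]):
                        dx = loop[idx, 0] - thread[jj, 0]
                        dy = loop[idx, 1] - thread[jj, 1]
                        dz = loop[idx, 2] - thread[jj, 2]
                        if box > 0.0:
                            dz -= box * np.round(dz / box)
                        de -= _pair_energy(dx * dx + dy * dy + dz * dz, a_thread, cutoff2, cap)
                        dx = new_arc[k - 1, 0] - thread[jj, 0]
                        dy = new_arc[k - 1, 1] - thread[jj, 1]
                        dz = new_arc[k - 1, 2] - thread[jj, 2]
                        if box > 0.0:
                            dz -= box * np.round(dz / box)
                        de += _pair_energy(dx * dx + dy * dy + dz * dz, a_thread, cutoff2, cap)
                if de <= 0.0 or np.random.random() < np.exp(-beta * de):
                    if check_wind:
                        old_ang, new_ang = _arc_winding(loop, i, m, new_arc)
                        if np.round((new_ang - old_ang) / (2.0 * np.pi)) != 0:
                            continue
                    for k in range(1, m):
                        idx = (i + k) % n
                        loop[idx, 0] = new_arc[k - 1, 0]
                        loop[idx, 1] = new_arc[k - 1, 1]
                        loop[idx, 2] = new_arc[k - 1, 2]
                    acc_c += 1
        if tune and (sweep + 1) % 50 == 0:
            if try_d > 0:
                r = acc_d / try_d
                if r > 0.5:
                    step_disp *= 1.2
                elif r < 0.3:
                    step_disp *= 0.8
            if try_c > 0:
                r = acc_c / try_c
                if r > 0.5:
                    theta_max = min(theta_max * 1.2, np.pi)
                elif r < 0.3:
                    theta_max *= 0.8
            acc_d = 0
            try_d = 0
            acc_c = 0
            try_c = 0
        if stride > 0 and (sweep + 1) % stride == 0:
            frames_out[nframes] = loop
            energies_out[nframes] = _total_energy(
                loop, thread, r0, k_bond, a_loop, a_thread, cutoff, box, cap
            )
            nframes += 1
    rate_d = acc_d / try_d if try_d > 0 else 0.0
    rate_c = acc_c / try_c if try_c > 0 else 0.0
    return nframes, step_disp, theta_max, rate_d, rate_c


def chord_correlation(
    frames: np.ndarray, lag_grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, int]:
    """Bond-vector time autocorrelation of a trajectory.

    C(tau) averages the dot product of unit bond ("chord") vectors over
    all bonds and time origins, normalised so C(0) = 1.  Returns
    (lags, C, tau01) where tau01 is the first lag with C <= 0.1.

    Raises InsufficientSamplingError when C never reaches 0.1.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    bonds = np.roll(frames, -1, axis=1) - frames
    bonds /= np.linalg.norm(bonds, axis=2, keepdims=True)
    f = frames.shape[0]
    # FFT autocorrelation over time for every (bond, component)
    nfft = 1 << int(np.ceil(np.log2(2 * f)))
    fw = np.fft.rfft(bonds, n=nfft, axis=0)
    ac = np.fft.irfft(fw * np.conj(fw), n=nfft, axis=0)[:f]
    ac = ac.sum(axis=(1, 2))  # sum over bonds and xyz
    norm = np.arange(f, 0, -1, dtype=np.float64)  # number of time origins
    c = ac / (norm * ac[0] / f)
    c /= c[0]
    if lag_grid is None:
        lag_grid = np.arange(f)
    else:
        lag_grid = np.asarray(lag_grid, dtype=np.int64)
    cvals = c[lag_grid]
    below = np.nonzero(c <= 0.1)[0]
    if below.size == 0:
        raise InsufficientSamplingError(
            "chord correlation never reached 0.1 within the run"
        )
    return lag_grid, cvals, int(below[0])


def _rg_equilibration_index(frames: np.ndarray) -> int:
    """First frame whose Rg reaches the stationary band.

    The initial regular-polygon state can be far from the equilibrium
    loop size (very expanded for large N); the chord-correlation rule
    alone does not see that slow global mode.  The stationary Rg level
    is taken as the median over the last half of the run; burn-in
    extends to the first frame at which the Rg series crosses it.
    """
    rg = np.sqrt(
        ((frames - frames.mean(axis=1, keepdims=True)) ** 2)
        .sum(axis=2)
        .mean(axis=1)
    )
    ref = float(np.median(rg[len(rg) // 2 :]))
    start_side = rg[0] - ref
    if start_side == 0.0:
        return 0
    crossed = np.nonzero((rg - ref) * np.sign(start_side) <= 0)[0]
    if crossed.size == 0:
        return len(rg) // 2
    return int(crossed[0])


def run_simulation(config: SimConfig) -> Trajectory:
    """Run Metropolis MC until ``target_frames`` decorrelated frames exist.

    The run proceeds in chunks; after each chunk the chord correlation
    time tau is re-estimated, the first 3*tau frames are treated as
    burn-in, and the run stops once (frames - 3*tau) / tau >=
    ``target_frames``.  Move sizes are auto-tuned to 30-50% acceptance
    during an initial phase and then frozen.  Deterministic for a fixed
    config (including seed).
    """
    frame0, thread = build_system(config)
    loop = frame0.coords.copy()
    args = (
        config.r0,
        config.k_bond,
        config.vdw_a,
        config.vdw_a_thread,
        config.vdw_cutoff,
        config.box,
        config.energy_cap,
        config.beta,
        config.w > 0,
    )
    step_disp = np.sqrt(KB * config.temperature / config.k_bond)
    theta_max = 0.5
    # tuning phase (not recorded)
    dummy_f = np.empty((1, config.n, 3))
    dummy_e = np.empty(1)
    _, step_disp, theta_max, _, _ = _run_mc(
        loop, thread, *args, config.tune_sweeps, 0, config.max_arc,
        config.seed % (2**31 - 1), step_disp, theta_max, True, dummy_f, dummy_e,
    )
    # unrecorded pre-equilibration: the regular-polygon start is far from
    # the equilibrium size/shape for large loops and its slow global modes
    # outlive the chord-correlation time
    equil = config.equil_sweeps if config.equil_sweeps is not None else 20 * config.n
    if equil > 0:
        _run_mc(
            loop, thread, *args, equil, 0, config.max_arc,
            (config.seed + 104729) % (2**31 - 1), step_disp, theta_max, False,
            dummy_f, dummy_e,
        )
    frames_list = []
    energies_list = []
    chunk_frames = max(4 * config.target_frames, 400)
    total_frames = 0
    tau = None
    acc = {}
    chunk_idx = 0
    while True:
        chunk_idx += 1
        fbuf = np.empty((chunk_frames, config.n, 3))
        ebuf = np.empty(chunk_frames)
        nf, step_disp, theta_max, rd, rc = _run_mc(
            loop, thread, *args, chunk_frames * config.stride, config.stride,
            config.max_arc, (config.seed + 7919 * chunk_idx) % (2**31 - 1),
            step_disp, theta_max, False, fbuf, ebuf,
        )
        frames_list.append(fbuf[:nf])
        energies_list.append(ebuf[:nf])
        total_frames += nf
        acc = {"displacement": rd, "crankshaft": rc}
        all_frames = np.concatenate(frames_list) if len(frames_list) > 1 else frames_list[0]
        try:
            _, _, tau = chord_correlation(all_frames)
        except InsufficientSamplingError:
            tau = None
        if tau is not None and tau >= 1:
            burn_est = max(3 * tau, _rg_equilibration_index(all_frames))
            n_eff = (total_frames - burn_est) / tau
            if n_eff >= config.target_frames:
                break
        if total_frames >= config.max_frames:
            if tau is None:
                raise InsufficientSamplingError(
                    "decorrelation time could not be estimated within the frame cap"
                )
            break
    all_energies = np.concatenate(energies_list) if len(energies_list) > 1 else energies_list[0]
    tau = max(tau, 1)
    burn = max(3 * tau, _rg_equilibration_index(all_frames))
    traj = Trajectory(
        frames=all_frames[burn:],
        energies=all_energies[burn:],
        config=config,
        thread=thread,
        tau_frames=tau,
        burn_in_frames=burn,
        acceptance=acc,
    )
    if config.w > 0:
        ok = all(check_threading(fr, config) for fr in traj.frames)
        if not ok:
            raise RuntimeError(
                "threading violated in a recorded frame despite move-level checks"
            )
    return traj
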