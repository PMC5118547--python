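"""First-order photocycle kinetics: schemes, rate matrices, propagation.

A photocycle is modelled as a continuous-time linear system dp/dt = K p over
a set of named states, where p holds the population fraction of the
photoexcited molecules in each state and K is the first-order rate matrix
built from the scheme's edges.  K[i, j] (i != j) is the rate constant of the
j -> i transition; each diagonal entry is minus its column's off-diagonal
sum, so total population is conserved exactly.

The default scheme is the strictly sequential, irreversible inward-pump
photocycle

    K --2 us--> L --210 us--> M1 --6.0 ms--> M2 --200 ms--> P13C --91 s--> ground

where K is the early red-shifted intermediate, L the blue-shifted one, M1/M2
the two kinetically distinct deprotonated-Schiff-base (M) states, and P13C
the long-lived 13-cis ground state whose thermal reversion (bicycle-pedal
isomerization) closes the cycle.  Because the chain is irreversible the rate
matrix is lower triangular and the observable time constants equal the edge
lifetimes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .spectra import Spectrum

__all__ = [
    "PhotocycleScheme",
    "RateMatrix",
    "SpeciesSpectra",
    "TransientSurface",
    "default_scheme",
    "DEFAULT_TIME_CONSTANTS",
    "build_rate_matrix",
    "propagate_populations",
    "apparent_time_constants",
    "simulate_surface",
    "log_time_grid",
]

#: The five sequential phase lifetimes of the dark-adapted inward-pump
#: photocycle, in seconds: K decay, the two M-rise phases, M decay, and the
#: thermal 13-cis -> all-trans recovery.
DEFAULT_TIME_CONSTANTS: tuple[float, ...] = (2e-6, 210e-6, 6.0e-3, 200e-3, 91.0)

DEFAULT_STATES: tuple[str, ...] = ("K", "L", "M1", "M2", "P13C", "ground_AT")


@dataclass
class PhotocycleScheme:
    """Named kinetic states connected by first-order transitions.

    ``states`` is ordered; ``states[0]`` is the initial photoproduct that
    receives the photoexcited population at t = 0.  ``edges`` holds
    (from_state, to_state, rate constant in s^-1) triples.
    ``excited_fraction`` is the fraction of molecules that enter the cycle
    per flash; it scales simulated difference-absorption amplitudes only.
    """

    states: Sequence[str]
    edges: Sequence[tuple[str, str, float]]
    excited_fraction: float = 1.0
    ground_state: str | None = None

    def __post_init__(self) -> None:
        self.states = list(self.states)
        self.edges = [tuple(e) for e in self.edges]
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate state names")
        if not 0.0 < self.excited_fraction <= 1.0:
            raise ValueError("excited_fraction must lie in (0, 1]")
        if self.ground_state is not None and self.ground_state not in self.states:
            raise ValueError(f"unknown ground state {self.ground_state!r}")
        seen: set[tuple[str, str]] = set()
        for frm, to, rate in self.edges:
            for name in (frm, to):
                if name not in self.states:
                    raise ValueError(f"unknown state name {name!r} in edge")
            if frm == to:
                raise ValueError(f"self-edge on state {frm!r}")
            if rate <= 0:
                raise ValueError(f"non-positive rate on edge {frm!r} -> {to!r}")
            if (frm, to) in seen:
                raise ValueError(f"duplicate edge {frm!r} -> {to!r}")
            seen.add((frm, to))
        self._check_reachability()

    def _check_reachability(self) -> None:
        adj: dict[str, list[str]] = {s: [] for s in self.states}
        for frm, to, _ in self.edges:
            adj[frm].append(to)
        reached = {self.states[0]}
        stack = [self.states[0]]
        while stack:
            for nxt in adj[stack.pop()]:
                if nxt not in reached:
                    reached.add(nxt)
                    stack.append(nxt)
        required = set(self.states) - {self.ground_state} if self.ground_state else set(self.states)
        missing = required - reached
        if missing:
            raise ValueError(f"states not reachable from initial photoproduct: {sorted(missing)}")


@dataclass
class RateMatrix:
    """Square first-order rate matrix K (s^-1) over a scheme's states.

    Column convention: K[i, j], i != j, is the j -> i rate; diagonals are
    the negated column sums so that 1^T K = 0 (population conservation).
    """

    matrix: np.ndarray
    states: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.states)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match state count")
        off = self.matrix - np.diag(np.diag(self.matrix))
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        colsums = self.matrix.sum(axis=0)
        if np.max(np.abs(colsums)) > 1e-9 * max(1.0, np.abs(self.matrix).max()):
            raise ValueError("column sums must vanish (population conservation)")

    @property
    def n_states(self) -> int:
        return len(self.states)


def build_rate_matrix(scheme: PhotocycleScheme) -> RateMatrix:
    """Assemble the conservative rate matrix of a scheme."""
    n = len(scheme.states)
    idx = {s: i for i, s in enumerate(scheme.states)}
    k = np.zeros((n, n))
    for frm, to, rate in scheme.edges:
        k[idx[to], idx[frm]] += rate
    np.fill_diagonal(k, 0.0)
    np.fill_diagonal(k, -k.sum(axis=0))
    return RateMatrix(k, list(scheme.states))


def _is_triangular(m: np.ndarray) -> bool:
    return np.all(np.triu(m, 1) == 0) or np.all(np.tril(m, -1) == 0)


def propagate_populations(
    K: RateMatrix,
    p0: np.ndarray,
    times: np.ndarray,
    return_info: bool = False,
):
    """Populations p(t) of dp/dt = K p, analytically via eigendecomposition.

    The photocycle spans ~8 decades in time, which makes naive stepwise
    integration stiff; diagonalizing K instead gives p(t) to machine
    precision at arbitrary times.  If the eigensystem is (near-)degenerate
    — relative eigenvalue gap below 1e-9 — the function falls back to dense
    stiff ODE integration and flags it in the returned info dict.

    Returns the (n_times, n_states) population matrix, or
    ``(populations, info)`` when ``return_info`` is true.
    """
    p0 = np.asarray(p0, dtype=float)
    times = np.asarray(times, dtype=float)
    if p0.shape != (K.n_states,):
        raise ValueError("p0 length does not match state count")
    if np.any(p0 < 0) or abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("p0 must be non-negative and sum to 1")

    m = K.matrix
    info: dict = {"method": "eig"}
    lam, vec = np.linalg.eig(m)
    scale = max(1.0, np.abs(lam).max())
    gaps = np.abs(lam[:, None] - lam[None, :])[~np.eye(lam.size, dtype=bool)]
    if gaps.size and gaps.min() < 1e-9 * scale:
        info["method"] = "ode_fallback"
        info["reason"] = "near-degenerate eigensystem"
        sol = solve_ivp(
            lambda t, p: m @ p,
            (0.0, float(times.max())),
            p0,
            t_eval=times,
            method="BDF",
            rtol=1e-10,
            atol=1e-12,
            jac=lambda t, p: m,
        )
        pops = sol.y.T
    else:
        c = np.linalg.solve(vec, p0.astype(complex))
        pops = np.real(np.exp(np.outer(times, lam)) * c[None, :] @ vec.T)
    return (pops, info) if return_info else pops


def apparent_time_constants(K: RateMatrix) -> np.ndarray:
    """Observable phase lifetimes: -1/Re(lambda) over nonzero eigenvalues.

    For an irreversible sequential chain (triangular K) the eigenvalues sit
    on the diagonal, so the apparent lifetimes equal the edge lifetimes
    exactly.  Complex eigenvalues (oscillatory kinetics) are rejected as
    unphysical for first-order photocycle schemes.
    """
    m = K.matrix
    lam = np.diag(m).astype(complex) if _is_triangular(m) else np.linalg.eigvals(m)
    if np.any(np.abs(lam.imag) > 1e-9 * np.maximum(np.abs(lam.real), 1e-300)):
        raise ValueError("complex eigenvalues: oscillatory kinetics unsupported")
    re = lam.real
    nonzero = re[np.abs(re) > 1e-12 * max(1.0, np.abs(re).max())]
    return np.sort(-1.0 / nonzero)


@dataclass
class SpeciesSpectra:
    """Per-state molar absorption profiles on a common wavelength grid."""

    wavelengths: np.ndarray
    profiles: dict[str, np.ndarray]
    ground: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.ground = np.asarray(self.ground, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.ground.shape != self.wavelengths.shape:
            raise ValueError("ground profile does not match wavelength grid")
        if np.any(self.ground < 0):
            raise ValueError("ground profile must be non-negative")
        for name, prof in self.profiles.items():
            prof = np.asarray(prof, dtype=float)
            if prof.shape != self.wavelengths.shape:
                raise ValueError(f"profile {name!r} does not match wavelength grid")
            if np.any(prof < 0):
                raise ValueError(f"profile {name!r} must be non-negative")
            self.profiles[name] = prof


@dataclass
class TransientSurface:
    """Flash-induced absorbance change dA(time, wavelength).

    Times are seconds after the flash (strictly increasing, > 0);
    wavelengths are nm.  ``noise_sd`` and ``seed`` record how synthetic
    noise was generated, when applicable.
    """

    times: np.ndarray
    wavelengths: np.ndarray
    delta_a: np.ndarray
    noise_sd: float | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.delta_a = np.asarray(self.delta_a, dtype=float)
        if np.any(self.times <= 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be positive and strictly increasing")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.delta_a.shape != (self.times.size, self.wavelengths.size):
            raise ValueError("delta_a shape does not match grids")


def log_time_grid(
    t_start: float = 1e-7, t_end: float = 2.0, points_per_decade: int = 30
) -> np.ndarray:
    """Logarithmic time grid covering the observation window (default
    100 ns to 2 s, 30 points per decade)."""
    n = int(np.ceil(np.log10(t_end / t_start) * points_per_decade)) + 1
    return np.logspace(np.log10(t_start), np.log10(t_end), n)


def simulate_surface(
    K: RateMatrix,
    spectra: SpeciesSpectra,
    times: np.ndarray,
    excited_fraction: float = 1.0,
    p0: np.ndarray | None = None,
) -> TransientSurface:
    """Synthesize a transient difference-absorption surface.

        dA(t, lambda) = f_ex * sum_s p_s(t) * (eps_s(lambda) - eps_ground(lambda))

    where p is the within-cycle population (initially all in the first
    state).  States whose profile equals the ground profile (e.g. the
    recovered ground state) contribute nothing, so dA tends to the terminal
    intermediate's difference spectrum at the end of the window.
    """
    missing = [s for s in K.states if s not in spectra.profiles]
    if missing:
        raise ValueError(f"spectra missing for states: {missing}")
    if p0 is None:
        p0 = np.zeros(K.n_states)
        p0[0] = 1.0
    pops = propagate_populations(K, p0, times)
    eps = np.stack([spectra.profiles[s] for s in K.states])  # (n_states, n_wl)
    diff = eps - spectra.ground[None, :]
    da = excited_fraction * pops @ diff
    return TransientSurface(times, spectra.wavelengths.copy(), da)


def default_scheme(
    time_constants: Sequence[float] = DEFAULT_TIME_CONSTANTS,
    excited_fraction: float = 1.0,
) -> PhotocycleScheme:
    """The sequential irreversible default photocycle.

    The five lifetimes parameterize, in order, K -> L, L -> M1, M1 -> M2,
    M2 -> P13C and P13C -> ground_AT.
    """
    if len(time_constants) != len(DEFAULT_STATES) - 1:
        raise ValueError(f"expected {len(DEFAULT_STATES) - 1} time constants")
    edges = [
        (DEFAULT_STATES[i], DEFAULT_STATES[i + 1], 1.0 / tau)
        for i, tau in enumerate(time_constants)
    ]
    return PhotocycleScheme(
        states=DEFAULT_STATES,
        edges=edges,
        excited_fraction=excited_fraction,
        ground_state=DEFAULT_STATES[-1],
    )
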