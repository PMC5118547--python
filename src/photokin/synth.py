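"""Seeded synthetic-data generators emulating the study's measurements.

Every input the analysis chain consumes — transient-absorption surfaces,
dark-adaptation recovery traces, dark/light absorption spectra, HPLC
chromatograms and pH pumping-assay panels — can be generated here from one
:class:`ScenarioConfig`.  The defaults encode the characterized system: a
sequential five-phase photocycle (2 us, 210 us, 6.0 ms, 200 ms, 91 s),
pure-isomer bands at 568 nm (all-trans) and 549 nm (13-cis), a dark-adapted
composition of 92% all-trans relaxing to 50:50 under light, a 0-150 s
illumination window in the assay, and a D216E mutant with threefold the
wildtype inward H+ pumping activity.

All randomness flows from one master seed through fixed per-generator
substreams, so identical (config, seed) pairs give bit-identical outputs
and adding a generator never perturbs existing fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .assay import PHTrace
from .hplc import Chromatogram
from .kinetics import (
    DEFAULT_TIME_CONSTANTS,
    SpeciesSpectra,
    TransientSurface,
    build_rate_matrix,
    default_scheme,
    log_time_grid,
    simulate_surface,
)
from .spectra import Spectrum, compose_mixture, gaussian_band

__all__ = [
    "ScenarioConfig",
    "GENOTYPES",
    "make_species_spectra",
    "make_transient_dataset",
    "make_dark_adaptation_trace",
    "make_absorption_pair",
    "make_chromatogram",
    "make_assay_panel",
    "AssayPanel",
]

# Fixed substream identifiers: new generators append, never renumber.
_STREAM_SURFACE = 1
_STREAM_RECOVERY = 2
_STREAM_SPECTRA = 3
_STREAM_CHROM = 4
_STREAM_ASSAY = 5

#: Relative inward H+ pumping activity and expression level per genotype.
#: D216E pumps about threefold faster than wildtype; the carboxylate
#: mutants E35D/Q, D74E, D108E/N and D216N are strongly reduced.  The
#: special genotype "ClR" emulates an inward Cl- pump control.
GENOTYPES: dict[str, dict[str, float]] = {
    "WT": {"activity": 1.0, "expression": 1.0},
    "D216E": {"activity": 3.0, "expression": 0.85},
    "D216N": {"activity": 0.05, "expression": 0.9},
    "E35D": {"activity": 0.1, "expression": 0.95},
    "E35Q": {"activity": 0.05, "expression": 0.9},
    "D74E": {"activity": 0.08, "expression": 0.8},
    "D108E": {"activity": 0.1, "expression": 0.9},
    "D108N": {"activity": 0.05, "expression": 0.85},
    "ClR": {"activity": 1.0, "expression": 1.0},
}


@dataclass
class ScenarioConfig:
    """All tunable study conditions with the characterized defaults."""

    # photocycle
    time_constants: tuple[float, ...] = DEFAULT_TIME_CONSTANTS
    excited_fraction: float = 0.05
    # band centers, nm
    ground_band_nm: float = 568.0       # pure all-trans ground state
    k_shift_nm: float = 20.0            # K is red-shifted
    l_shift_nm: float = -30.0           # L is blue-shifted
    m_band_nm: float = 410.0            # deprotonated Schiff base
    p13c_band_nm: float = 549.0         # 13-cis ground state
    fwhm_cm1: float = 3800.0
    # observation grids
    wl_start_nm: float = 360.0
    wl_stop_nm: float = 710.0
    wl_step_nm: float = 10.0
    t_start_s: float = 1e-7
    t_end_s: float = 2.0
    points_per_decade: int = 30
    # isomer composition
    f_dark: float = 0.92
    f_light: float = 0.50
    # dark-adaptation recovery (585 nm probe)
    recovery_probe_nm: float = 585.0
    recovery_duration_s: float = 600.0
    recovery_dt_s: float = 1.0
    recovery_amplitude: float = 0.05
    recovery_offset: float = 0.5
    # HPLC
    hplc_retention_min: dict = field(
        default_factory=lambda: {
            "13-cis": (8.0, 16.0),      # syn, anti oxime
            "all-trans": (11.0, 20.0),
        }
    )
    hplc_sigma_min: float = 0.15
    hplc_syn_fraction: float = 0.6
    hplc_total_area: float = 1.0
    hplc_t_max_min: float = 25.0
    hplc_dt_min: float = 0.01
    # pumping assay
    light_on_s: float = 0.0
    light_off_s: float = 150.0
    assay_t_start_s: float = -30.0
    assay_t_stop_s: float = 250.0
    assay_dt_s: float = 1.0
    base_slope_ph_per_s: float = 1.0e-3
    cell_response_tau_s: float = 200.0
    relax_tau_s: float = 300.0
    ph0: float = 7.0
    cccp_h_factor: float = 0.02         # protonophore abolishes H+ pumping
    cccp_cl_factor: float = 2.0         # and accelerates Cl- pumping
    pigment_peak_absorbance: float = 0.5
    # noise standard deviations per data kind
    noise_sd_surface: float = 5.0e-4
    noise_sd_trace: float = 1.0e-3
    noise_sd_spectrum: float = 0.0
    noise_sd_chrom: float = 5.0e-3
    noise_sd_ph: float = 2.0e-3
    # master seed
    seed: int = 0

    def with_(self, **kwargs) -> "ScenarioConfig":
        """A copy of the config with the given fields replaced."""
        return replace(self, **kwargs)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(self.wl_start_nm, self.wl_stop_nm + 0.5 * self.wl_step_nm, self.wl_step_nm)

    @property
    def times(self) -> np.ndarray:
        return log_time_grid(self.t_start_s, self.t_end_s, self.points_per_decade)


def make_species_spectra(cfg: ScenarioConfig, wavelengths: np.ndarray | None = None) -> SpeciesSpectra:
    """Per-intermediate absorption bands for the default photocycle.

    K is red-shifted and L blue-shifted relative to the 568 nm ground band;
    M2 carries the 410 nm deprotonated-Schiff-base band and M1 — the state
    in L/M equilibrium — a 50/50 superposition of the L and M bands, so
    both M-rise phases appear in the difference data; P13C is the 549 nm
    13-cis ground state.
    """
    wl = cfg.wavelengths if wavelengths is None else np.asarray(wavelengths, dtype=float)

    def band(center: float) -> np.ndarray:
        return gaussian_band(wl, center, cfg.fwhm_cm1).absorbance

    ground = band(cfg.ground_band_nm)
    l_band = band(cfg.ground_band_nm + cfg.l_shift_nm)
    m_band = band(cfg.m_band_nm)
    profiles = {
        "K": band(cfg.ground_band_nm + cfg.k_shift_nm),
        "L": l_band,
        "M1": 0.5 * l_band + 0.5 * m_band,
        "M2": m_band,
        "P13C": band(cfg.p13c_band_nm),
        "ground_AT": ground,
    }
    return SpeciesSpectra(wavelengths=wl, profiles=profiles, ground=ground)


def make_transient_dataset(cfg: ScenarioConfig | None = None) -> TransientSurface:
    """Flash-photolysis surface from the default photocycle plus noise.

    Wavelengths 360-710 nm in 10 nm steps; logarithmic times from 100 ns
    to 2 s; additive Gaussian noise of s.d. ``cfg.noise_sd_surface``.
    """
    cfg = cfg or ScenarioConfig()
    scheme = default_scheme(cfg.time_constants, cfg.excited_fraction)
    surface = simulate_surface(
        build_rate_matrix(scheme),
        make_species_spectra(cfg),
        cfg.times,
        excited_fraction=cfg.excited_fraction,
    )
    if cfg.noise_sd_surface > 0:
        rng = cfg.rng(_STREAM_SURFACE)
        surface.delta_a = surface.delta_a + rng.normal(
            0.0, cfg.noise_sd_surface, surface.delta_a.shape
        )
    surface.noise_sd = cfg.noise_sd_surface
    surface.seed = cfg.seed
    return surface


def make_dark_adaptation_trace(cfg: ScenarioConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """585 nm absorption recovery after light adaptation, sampled every 1 s.

    Single-exponential recovery with the slowest photocycle lifetime (the
    thermal 13-cis -> all-trans reversion, 91 s by default):
    A(t) = A_inf - a * exp(-t / tau).  Returns ``(times, absorbance)``.
    """
    cfg = cfg or ScenarioConfig()
    tau = cfg.time_constants[-1]
    t = np.arange(cfg.recovery_dt_s, cfg.recovery_duration_s + 0.5 * cfg.recovery_dt_s,
                  cfg.recovery_dt_s)
    a = cfg.recovery_offset - cfg.recovery_amplitude * np.exp(-t / tau)
    if cfg.noise_sd_trace > 0:
        a = a + cfg.rng(_STREAM_RECOVERY).normal(0.0, cfg.noise_sd_trace, a.shape)
    return t, a


def _pure_band_pair(cfg: ScenarioConfig, wl: np.ndarray) -> tuple[Spectrum, Spectrum]:
    s_at = gaussian_band(wl, cfg.ground_band_nm, cfg.fwhm_cm1, label="pure all-trans")
    s_13c = gaussian_band(wl, cfg.p13c_band_nm, cfg.fwhm_cm1, label="pure 13-cis")
    return s_at, s_13c


def make_absorption_pair(cfg: ScenarioConfig | None = None) -> tuple[Spectrum, Spectrum]:
    """Dark- and light-adapted absorption spectra as isomer mixtures.

    Both are linear mixtures of wavenumber-Gaussian pure bands (568 nm
    all-trans, 549 nm 13-cis) at the configured dark (92:8) and light
    (50:50) compositions, on a 1 nm grid.
    """
    cfg = cfg or ScenarioConfig()
    wl = np.arange(330.0, 751.0, 1.0)
    s_at, s_13c = _pure_band_pair(cfg, wl)
    s_dark = compose_mixture(s_at, s_13c, cfg.f_dark, label="dark-adapted")
    s_light = compose_mixture(s_at, s_13c, cfg.f_light, label="light-adapted")
    if cfg.noise_sd_spectrum > 0:
        rng = cfg.rng(_STREAM_SPECTRA)
        s_dark.absorbance = s_dark.absorbance + rng.normal(0, cfg.noise_sd_spectrum, wl.shape)
        s_light.absorbance = s_light.absorbance + rng.normal(0, cfg.noise_sd_spectrum, wl.shape)
    return s_dark, s_light


def make_chromatogram(cfg: ScenarioConfig | None = None, condition: str = "dark") -> Chromatogram:
    """Synthetic oxime HPLC pattern for the dark- or light-adapted sample.

    Each isomer elutes as a syn/anti peak pair at fixed retention times;
    per-isomer summed areas are proportional to the configured composition
    (dark 92:8, light 50:50).  Gaussian detector noise is added.
    """
    cfg = cfg or ScenarioConfig()
    if condition not in ("dark", "light"):
        raise ValueError("condition must be 'dark' or 'light'")
    f_at = cfg.f_dark if condition == "dark" else cfg.f_light
    t = np.arange(0.0, cfg.hplc_t_max_min + 0.5 * cfg.hplc_dt_min, cfg.hplc_dt_min)
    signal = np.zeros_like(t)
    windows: dict[str, list[tuple[float, float]]] = {}
    sig = cfg.hplc_sigma_min
    for isomer, (t_syn, t_anti) in cfg.hplc_retention_min.items():
        frac = f_at if isomer == "all-trans" else 1.0 - f_at
        windows[isomer] = [(t_syn - 1.0, t_syn + 1.0), (t_anti - 1.0, t_anti + 1.0)]
        for center, split in ((t_syn, cfg.hplc_syn_fraction), (t_anti, 1.0 - cfg.hplc_syn_fraction)):
            area = cfg.hplc_total_area * frac * split
            signal += area / (sig * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - center) / sig) ** 2)
    if cfg.noise_sd_chrom > 0:
        stream = _STREAM_CHROM if condition == "dark" else _STREAM_CHROM + 100
        signal = signal + cfg.rng(stream).normal(0.0, cfg.noise_sd_chrom, signal.shape)
    return Chromatogram(times=t, signal=signal, windows=windows)


@dataclass
class AssayPanel:
    """One genotype's pumping-assay panel plus its bleach spectra."""

    genotype: str
    traces: list[PHTrace]
    pigment_spectrum: Spectrum
    bleached_spectrum: Spectrum


def _ph_trace(
    cfg: ScenarioConfig,
    slope: float,
    salt: str,
    cccp: bool,
    sample: str,
    rng: np.random.Generator,
) -> PHTrace:
    t = np.arange(cfg.assay_t_start_s, cfg.assay_t_stop_s + 0.5 * cfg.assay_dt_s, cfg.assay_dt_s)
    ph = np.full_like(t, cfg.ph0)
    tau = cfg.cell_response_tau_s
    amp = slope * tau
    lit = (t >= cfg.light_on_s) & (t <= cfg.light_off_s)
    ph[lit] = cfg.ph0 + amp * (1.0 - np.exp(-(t[lit] - cfg.light_on_s) / tau))
    after = t > cfg.light_off_s
    peak = amp * (1.0 - np.exp(-(cfg.light_off_s - cfg.light_on_s) / tau))
    ph[after] = cfg.ph0 + peak * np.exp(-(t[after] - cfg.light_off_s) / cfg.relax_tau_s)
    if cfg.noise_sd_ph > 0:
        ph = ph + rng.normal(0.0, cfg.noise_sd_ph, ph.shape)
    return PHTrace(
        times=t, ph=ph, light_on=cfg.light_on_s, light_off=cfg.light_off_s,
        salt=salt, cccp=cccp, sample=sample,
    )


def make_assay_panel(cfg: ScenarioConfig | None = None, genotype: str = "WT") -> AssayPanel:
    """Full salt x CCCP pumping panel plus bleach spectra for a genotype.

    H+-pump genotypes alkalinize in NaCl, CsCl and Na2SO4 and are abolished
    by CCCP; the "ClR" genotype alkalinizes only in the Cl- salts, is flat
    in sulfate, and is accelerated by CCCP.  The pigment/bleached spectrum
    pair scales with the genotype's expression level so activities can be
    expression-normalized.
    """
    cfg = cfg or ScenarioConfig()
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; known: {sorted(GENOTYPES)}")
    info = GENOTYPES[genotype]
    chloride_pump = genotype == "ClR"
    rng = cfg.rng(_STREAM_ASSAY + 1000 * (sorted(GENOTYPES).index(genotype)))

    slope0 = cfg.base_slope_ph_per_s * info["activity"] * info["expression"]
    traces = []
    for salt in ("NaCl", "CsCl", "Na2SO4"):
        for cccp in (False, True):
            s = slope0
            if chloride_pump:
                if salt == "Na2SO4":
                    s = 0.0
                elif cccp:
                    s *= cfg.cccp_cl_factor
            elif cccp:
                s *= cfg.cccp_h_factor
            traces.append(_ph_trace(cfg, s, salt, cccp, genotype, rng))

    wl = np.arange(300.0, 751.0, 1.0)
    scale = cfg.pigment_peak_absorbance * info["expression"]
    pigment = gaussian_band(wl, cfg.ground_band_nm - 1.0, cfg.fwhm_cm1, amplitude=scale,
                            label=f"{genotype} pigment")
    oxime = gaussian_band(wl, 360.0, cfg.fwhm_cm1, amplitude=0.67 * scale,
                          label="retinal oxime")
    bleached = Spectrum(wl, oxime.absorbance.copy(), label=f"{genotype} bleached")
    return AssayPanel(
        genotype=genotype, traces=traces, pigment_spectrum=pigment, bleached_spectrum=bleached
    )
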