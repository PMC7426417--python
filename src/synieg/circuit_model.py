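"""Kinetic model of synthetic immediate-early gene (SynIEG) circuits.

A SynIEG couples a serum/light-responsive FOS-type promoter to interchangeable
mRNA and protein regulatory elements (3'UTRs, degrons, fluorescent reporters).
This module simulates the resulting multi-step regulation as a small ODE
system driven by normalized pathway inputs:

* ``E(t)`` — Erk pathway activity in [0, 1], set by serum or optogenetic light.
* ``D(t)`` — DNA-damage signal in [0, 1], rising after doxorubicin addition.
* ``S(t)`` — protein-synthesis indicator (0 under cycloheximide).

State variables: an Erk-induced, synthesis-dependent adaptation repressor
``Z`` (Zfp36-like), per-integration-site transcription rates ``T_i``, pooled
mRNA ``M`` and reporter protein ``P``.  Regulatory arms are switched on by the
circuit's parts list: the FOS 3'UTR makes mRNA decay Z-dependent, the BTG2
3'UTR places translation under miR-21 control (relieved by DNA damage), and
the FRA1 degron destabilizes the protein except while Erk is active.

Time is in minutes; concentrations and fluorescence are arbitrary units.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import AnalysisError, CalibrationError, ValidationError

__all__ = [
    "StimulusProgram",
    "PathwaySignals",
    "CircuitSpec",
    "KineticParams",
    "Trajectory",
    "Promoter",
    "UTR3",
    "UTR5",
    "Degron",
    "Reporter",
    "Mir21Status",
    "make_stimulus",
    "simulate_circuit",
    "calibrate_defaults",
    "CIRCUIT_PRESETS",
    "STIMULUS_PRESETS",
    "get_circuit_preset",
    "get_stimulus_preset",
]


class Promoter(str, Enum):
    FOS = "FOS"
    BTG2 = "BTG2"


class UTR5(str, Enum):
    FOS = "FOS"
    BTG2 = "BTG2"


class UTR3(str, Enum):
    FOS = "FOS"
    BTG2 = "BTG2"
    TUBULIN = "TUBULIN"


class Degron(str, Enum):
    NONE = "NONE"
    FRA1 = "FRA1"


class Reporter(str, Enum):
    msfYFP = "msfYFP"
    dGFP = "dGFP"


class Mir21Status(str, Enum):
    ENDOGENOUS = "ENDOGENOUS"
    OVEREXPRESSED = "OVEREXPRESSED"
    SPONGE = "SPONGE"


@dataclass(frozen=True)
class StimulusProgram:
    """Experimental condition: serum, light, doxorubicin, CHX and MEKi schedules.

    ``drug_addition_time_min`` is when serum and/or doxorubicin hit the dish;
    before it both inputs are absent (starvation).  ``erk_tau_min`` is a
    first-order rise time constant applied to the serum arm of E(t) only:
    growth-factor receptor activation of Erk is minutes-slow, whereas
    optogenetic membrane recruitment is effectively instantaneous on this
    grid, so light windows always produce step inputs.
    """

    duration_min: float = 180.0
    dt_min: float = 2.0
    serum_fraction: float = 0.0
    light_windows: tuple[tuple[float, float], ...] = ()
    doxorubicin_nM: float = 0.0
    cycloheximide: bool = False
    meki_time_min: float | None = None
    drug_addition_time_min: float = 0.0
    erk_tau_min: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValidationError("duration_min must be > 0")
        if self.dt_min <= 0:
            raise ValidationError("dt_min must be > 0")
        if self.serum_fraction < 0 or self.doxorubicin_nM < 0:
            raise ValidationError("concentrations must be >= 0")
        if self.drug_addition_time_min < 0:
            raise ValidationError("drug_addition_time_min must be >= 0")
        if self.erk_tau_min < 0:
            raise ValidationError("erk_tau_min must be >= 0")
        if self.meki_time_min is not None and self.meki_time_min < 0:
            raise ValidationError("meki_time_min must be >= 0")
        windows = tuple(tuple(float(x) for x in w) for w in self.light_windows)
        object.__setattr__(self, "light_windows", windows)
        prev_end = -np.inf
        for start, end in windows:
            if start < 0 or end > self.duration_min:
                raise ValidationError(
                    f"light window ({start}, {end}) outside [0, {self.duration_min}]"
                )
            if end <= start:
                raise ValidationError(f"ill-ordered light window ({start}, {end})")
            if start < prev_end:
                raise ValidationError("light windows overlap or are unsorted")
            prev_end = end

    @property
    def breakpoints(self) -> np.ndarray:
        """Times where an input switches discontinuously (for piecewise integration)."""
        pts = {0.0, self.duration_min, self.drug_addition_time_min}
        for start, end in self.light_windows:
            pts.update((start, end))
        if self.meki_time_min is not None:
            pts.add(float(self.meki_time_min))
        return np.array(sorted(p for p in pts if 0.0 <= p <= self.duration_min))


@dataclass(frozen=True)
class PathwaySignals:
    """Normalized pathway inputs sampled on a shared uniform time grid."""

    time_grid: np.ndarray
    erk: np.ndarray
    damage: np.ndarray
    synthesis: np.ndarray
    breakpoints: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        t = np.asarray(self.time_grid, dtype=float)
        for name in ("erk", "damage", "synthesis"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != t.shape:
                raise ValidationError(f"{name} does not share the time grid")
            if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
                raise ValidationError(f"{name} values outside [0, 1]")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "time_grid", t)

    @property
    def dt(self) -> float:
        steps = np.diff(self.time_grid)
        if len(steps) == 0:
            raise ValidationError("time grid needs at least two points")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValidationError("time grid is not uniform")
        return float(steps[0])


@dataclass(frozen=True)
class CircuitSpec:
    """Parts list of one SynIEG transgene.

    The BTG2 promoter reuses the FOS transcription law scaled by
    ``KineticParams.btg2_promoter_scale`` (the two promoters show similar
    serum-induced output and no separate kinetics are modeled).
    """

    promoter: Promoter = Promoter.FOS
    utr5: UTR5 = UTR5.FOS
    utr3: UTR3 = UTR3.FOS
    degron: Degron = Degron.NONE
    reporter: Reporter = Reporter.msfYFP
    n_sites: int = 8
    mir21_status: Mir21Status = Mir21Status.ENDOGENOUS

    def __post_init__(self) -> None:
        object.__setattr__(self, "promoter", Promoter(self.promoter))
        object.__setattr__(self, "utr5", UTR5(self.utr5))
        object.__setattr__(self, "utr3", UTR3(self.utr3))
        object.__setattr__(self, "degron", Degron(self.degron))
        object.__setattr__(self, "reporter", Reporter(self.reporter))
        object.__setattr__(self, "mir21_status", Mir21Status(self.mir21_status))
        if self.n_sites < 1:
            raise ValidationError("n_sites must be >= 1")


# Shipped defaults below were fixed once by calibrate_defaults() against the
# package's trajectory-level behavioral targets (transcription peak/adaptation
# timing, 3-h fold-changes, AND-gate synergy); see docs/methods.md.
@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the regulatory links.  All rates are per minute."""

    k_tx: float = 1.0                  # transcription rate scale per site (a.u./min)
    k_z: float = 0.055                 # repressor synthesis rate
    delta_z: float = 0.008             # repressor decay
    K_z: float = 1.0                   # repression half-point (a.u.)
    hill_h: float = 8.0                # repression Hill exponent
    delta_m0: float = 0.015            # basal mRNA decay
    alpha_fos: float = 3.08            # FOS-3'UTR Z-dependent destabilization gain
    K_deg: float = 0.6                 # destabilization half-saturation (a.u.)
    k_tl: float = 0.05                 # translation rate
    eps_min: float = 0.05              # residual translation under full miR-21 repression
    k_damage: float = 0.025            # damage signal rise rate after doxorubicin
    delta_p_yfp: float = 0.0012        # basal msfYFP decay (stable reporter)
    delta_p_dgfp: float = 0.012        # basal dGFP decay (destabilized reporter, ~10x)
    delta_p_degron: float = 0.012      # basal decay of FRA1-degron-tagged protein
    f_stab: float = 0.95               # Erk-dependent degron stabilization fraction
    m_over: float = 1.0                # miR-21 activity multiplier, overexpression
    m_sponge: float = 0.0              # miR-21 activity multiplier, sponge
    k_leak: float = 0.010              # basal (Erk-independent) transcription fraction
    background_yfp_au: float = 861.0   # autofluorescence offset, YFP channel (a.u.)
    background_gfp_au: float = 51.5    # autofluorescence offset, GFP channel (a.u.)
    btg2_promoter_scale: float = 1.0   # BTG2-promoter output relative to FOS
    erk_smoothing_min: float = 0.0     # optional extra first-order Erk filter

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValidationError(f"{f.name} must be >= 0")
        if self.hill_h < 1:
            raise ValidationError("hill_h must be >= 1")
        if not self.eps_min < 1:
            raise ValidationError("eps_min must be < 1")
        if not self.f_stab < 1:
            raise ValidationError("f_stab must be < 1")
        if not self.delta_p_dgfp > self.delta_p_yfp:
            raise ValidationError("dGFP must be less stable than msfYFP")

    def replace(self, **kwargs) -> "KineticParams":
        return dataclasses.replace(self, **kwargs)

    def delta_p_basal(self, spec: CircuitSpec) -> float:
        """Basal protein decay: the degron overrides the reporter's stability."""
        if spec.degron is Degron.FRA1:
            return self.delta_p_degron
        return self.delta_p_yfp if spec.reporter is Reporter.msfYFP else self.delta_p_dgfp

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "KineticParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown kinetic parameters: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass
class Trajectory:
    """Simulated time courses of one circuit under one stimulus.

    ``protein`` is the observable fluorescence trace: reporter protein plus
    the channel's constitutive autofluorescence offset.
    ``tx_rates`` has shape (n_sites, n_times).
    """

    time_grid: np.ndarray
    erk: np.ndarray
    damage: np.ndarray
    repressor: np.ndarray
    tx_rates: np.ndarray
    mrna: np.ndarray
    protein: np.ndarray
    spec: CircuitSpec
    params: KineticParams

    @property
    def n_sites(self) -> int:
        return self.tx_rates.shape[0]

    @property
    def mean_tx_rate(self) -> np.ndarray:
        return self.tx_rates.mean(axis=0)

    def to_frame(self):
        import pandas as pd

        cols = {
            "time_min": self.time_grid,
            "erk": self.erk,
            "damage": self.damage,
            "Z": self.repressor,
        }
        for i in range(self.n_sites):
            cols[f"T_site{i + 1}"] = self.tx_rates[i]
        cols["mRNA"] = self.mrna
        cols["protein"] = self.protein
        return pd.DataFrame(cols)


def make_stimulus(program: StimulusProgram, k_damage_per_min: float | None = None) -> PathwaySignals:
    """Map an experimental condition onto pathway input signals.

    E(t) = 1 while a light window is active; the serum arm is 1 after drug
    addition (first-order rise if the program sets ``erk_tau_min``).  MEK
    inhibition zeroes E from ``meki_time_min`` onward.  D(t) rises as
    ``1 - exp(-k_D (t - t_add))`` after doxorubicin addition.  S(t) is 0 under
    cycloheximide.
    """
    if k_damage_per_min is None:
        k_damage_per_min = KineticParams().k_damage
    n = int(round(program.duration_min / program.dt_min)) + 1
    t = np.arange(n) * program.dt_min

    erk = np.zeros(n)
    t_add = program.drug_addition_time_min
    if program.serum_fraction > 0:
        after = t >= t_add
        if program.erk_tau_min > 0:
            erk[after] = 1.0 - np.exp(-(t[after] - t_add) / program.erk_tau_min)
        else:
            erk[after] = 1.0
    for start, end in program.light_windows:
        erk[(t >= start) & (t < end)] = 1.0
    if program.meki_time_min is not None:
        erk[t >= program.meki_time_min] = 0.0

    damage = np.zeros(n)
    if program.doxorubicin_nM > 0:
        after = t >= t_add
        damage[after] = 1.0 - np.exp(-k_damage_per_min * (t[after] - t_add))

    synthesis = np.zeros(n) if program.cycloheximide else np.ones(n)
    return PathwaySignals(
        time_grid=t, erk=erk, damage=damage, synthesis=synthesis,
        breakpoints=program.breakpoints,
    )


def _translation_efficiency(spec: CircuitSpec, params: KineticParams, damage: np.ndarray) -> np.ndarray:
    """miR-21 arm: only transcripts with the BTG2 3'UTR are repressed.

    Endogenous miR-21 leaves a residual efficiency eps_min that DNA damage
    relieves; a sponge titrates miR-21 away (activity m_sponge, default 0);
    overexpression pins repression on regardless of damage (activity m_over).
    """
    damage = np.asarray(damage, dtype=float)
    if spec.utr3 is not UTR3.BTG2:
        return np.ones_like(damage)
    span = 1.0 - params.eps_min
    if spec.mir21_status is Mir21Status.ENDOGENOUS:
        activity = 1.0 - damage          # damage titrates miR-21 activity away
    elif spec.mir21_status is Mir21Status.SPONGE:
        activity = np.full_like(damage, params.m_sponge)
    else:
        activity = np.full_like(damage, params.m_over)
    return np.clip(1.0 - span * activity, 0.0, 1.0)


def _tx_scale(spec: CircuitSpec, params: KineticParams) -> float:
    scale = params.k_tx
    if spec.promoter is Promoter.BTG2:
        scale *= params.btg2_promoter_scale
    return scale


def _repression(z: float | np.ndarray, params: KineticParams) -> float | np.ndarray:
    kh = params.K_z ** params.hill_h
    return kh / (kh + np.maximum(z, 0.0) ** params.hill_h)


def _mrna_decay(z: float | np.ndarray, spec: CircuitSpec, params: KineticParams):
    if spec.utr3 is UTR3.FOS:
        z = np.maximum(z, 0.0)
        return params.delta_m0 * (1.0 + params.alpha_fos * z / (params.K_deg + z))
    return params.delta_m0


def _steady_initial_state(spec: CircuitSpec, params: KineticParams,
                          eps0: float) -> tuple[float, float, float]:
    """Pre-stimulus steady state (E=0, D=0): supported by leak transcription only."""
    z0 = 0.0
    m0 = spec.n_sites * _tx_scale(spec, params) * params.k_leak / params.delta_m0
    p0 = params.k_tl * eps0 * m0 / params.delta_p_basal(spec)
    return z0, m0, p0


def simulate_circuit(
    spec: CircuitSpec,
    params: KineticParams,
    signals: PathwaySignals,
    seed: int | None = None,
    initial_state: str | tuple[float, float, float] = "steady",
    rtol: float = 1e-8,
) -> Trajectory:
    """Integrate the circuit ODEs on the signal grid.

    Deterministic by default (the basis for all summary statistics).  When
    ``seed`` is given, per-site transcription is replaced by a two-state
    telegraph process whose on-rate follows the deterministic promoter
    activity; mRNA and protein are then driven by the realized rates.

    ``initial_state`` is ``"steady"`` (pre-stimulus steady state), ``"zero"``,
    or an explicit ``(Z0, M0, P0)`` tuple.
    """
    t = signals.time_grid
    dt = signals.dt  # validates uniformity
    erk_grid = signals.erk.copy()
    if params.erk_smoothing_min > 0:
        # optional extra first-order filter on E(t); exact per-step update
        a = np.exp(-dt / params.erk_smoothing_min)
        sm = np.empty_like(erk_grid)
        sm[0] = erk_grid[0]
        for i in range(1, len(erk_grid)):
            sm[i] = a * sm[i - 1] + (1 - a) * erk_grid[i]
        erk_grid = sm
    dmg_grid = signals.damage
    syn_grid = signals.synthesis

    def E(ti: float) -> float:
        return float(np.interp(ti, t, erk_grid))

    def Dm(ti: float) -> float:
        return float(np.interp(ti, t, dmg_grid))

    def S(ti: float) -> float:
        return float(np.interp(ti, t, syn_grid))

    eps_grid = _translation_efficiency(spec, params, dmg_grid)

    def eps(ti: float) -> float:
        return float(np.interp(ti, t, eps_grid))

    scale = _tx_scale(spec, params)
    n_sites = spec.n_sites
    dp_basal = params.delta_p_basal(spec)
    use_fstab = spec.degron is Degron.FRA1

    if initial_state == "steady":
        y0 = _steady_initial_state(spec, params, float(eps_grid[0]))
    elif initial_state == "zero":
        y0 = (0.0, 0.0, 0.0)
    else:
        y0 = tuple(float(v) for v in initial_state)  # type: ignore[arg-type]
        if len(y0) != 3 or any(v < 0 for v in y0):
            raise ValidationError("initial_state must be 'steady', 'zero' or (Z0, M0, P0) >= 0")

    if seed is None:
        def site_rate(ti: float, z: float) -> float:
            return scale * (params.k_leak + E(ti) * _repression(z, params))

        def rhs(ti: float, y: np.ndarray) -> list[float]:
            z, m, p = np.maximum(y, 0.0)
            dz = params.k_z * E(ti) * S(ti) - params.delta_z * z
            tx = site_rate(ti, z)
            dm = n_sites * tx - _mrna_decay(z, spec, params) * m
            dp_rate = dp_basal * (1.0 - params.f_stab * E(ti)) if use_fstab else dp_basal
            dp = params.k_tl * eps(ti) * m - dp_rate * p
            return [dz, dm, dp]

        z_arr, m_arr, p_arr = _integrate_piecewise(rhs, t, y0, signals.breakpoints, rtol)
        tx_rates = np.vstack([scale * (params.k_leak + erk_grid * _repression(z_arr, params))] * n_sites)
    else:
        z_arr, tx_rates, m_arr, p_arr = _simulate_telegraph(
            spec, params, t, erk_grid, dmg_grid, syn_grid, eps_grid, y0, seed
        )

    bg = (params.background_yfp_au if spec.reporter is Reporter.msfYFP
          else params.background_gfp_au)
    protein = np.maximum(p_arr, 0.0) + bg
    return Trajectory(
        time_grid=t,
        erk=erk_grid,
        damage=dmg_grid.copy(),
        repressor=np.maximum(z_arr, 0.0),
        tx_rates=np.maximum(tx_rates, 0.0),
        mrna=np.maximum(m_arr, 0.0),
        protein=protein,
        spec=spec,
        params=params,
    )


def _integrate_piecewise(rhs, t: np.ndarray, y0: Sequence[float],
                         breakpoints: np.ndarray, rtol: float):
    """solve_ivp segment-by-segment between input discontinuities (stiff-safe)."""
    t0, t1 = float(t[0]), float(t[-1])
    brk = [b for b in np.atleast_1d(breakpoints) if t0 < b < t1]
    edges = np.array([t0, *sorted(set(brk)), t1])
    ys = [np.asarray(y0, dtype=float)]
    out_t = [np.array([t0])]
    out_y = [np.asarray(y0, dtype=float).reshape(3, 1)]
    y = np.asarray(y0, dtype=float)
    for a, b in zip(edges[:-1], edges[1:]):
        t_eval = t[(t > a + 1e-9) & (t <= b + 1e-9)]
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", t_eval=t_eval if len(t_eval) else None,
                        rtol=rtol, atol=1e-10, max_step=(b - a))
        if not sol.success:
            raise AnalysisError(f"ODE integration failed on [{a}, {b}]: {sol.message}")
        y = sol.y[:, -1] if sol.y.size else y
        if len(t_eval):
            out_t.append(sol.t)
            out_y.append(sol.y)
    tt = np.concatenate(out_t)
    yy = np.concatenate(out_y, axis=1)
    # map back onto the requested grid (guards duplicate edge samples)
    idx = np.searchsorted(tt, t - 1e-9)
    idx = np.clip(idx, 0, len(tt) - 1)
    return yy[0, idx], yy[1, idx], yy[2, idx]


def _simulate_telegraph(spec, params, t, erk, dmg, syn, eps_grid, y0, seed):
    """Seeded two-state telegraph transcription; M and P follow the realized rates.

    The on-rate scales with the deterministic promoter activity E·K^h/(K^h+Z^h)
    so the ensemble mean matches the deterministic model.  Exponential-Euler
    updates on a 10x-refined grid keep the linear M/P dynamics accurate.
    """
    rng = np.random.default_rng(seed)
    refine = 10
    dt = float(t[1] - t[0])
    dtf = dt / refine
    tf = np.arange(len(t) * refine - (refine - 1)) * dtf + t[0]

    def interp(arr):
        return np.interp(tf, t, arr)

    e_f, s_f, eps_f = interp(erk), interp(syn), interp(eps_grid)
    # deterministic repressor on the fine grid (Z is a cell-wide protein)
    z = np.empty_like(tf)
    z[0] = y0[0]
    for i in range(1, len(tf)):
        a = np.exp(-params.delta_z * dtf)
        drive = params.k_z * e_f[i - 1] * s_f[i - 1]
        z[i] = a * z[i - 1] + (1 - a) * (drive / params.delta_z if params.delta_z > 0 else 0.0)
        if params.delta_z == 0:
            z[i] = z[i - 1] + drive * dtf
    activity = np.clip(e_f * _repression(z, params), 0.0, 1.0)

    k_off = 0.5  # per min; bursts of ~2 min
    scale = _tx_scale(spec, params)
    n_sites = spec.n_sites
    on = rng.random(n_sites) < activity[0]
    tx_f = np.empty((n_sites, len(tf)))
    for i, p_target in enumerate(activity):
        p_on = min(p_target, 0.995)
        k_on = k_off * p_on / max(1.0 - p_on, 1e-6)
        p_switch_on = 1.0 - np.exp(-k_on * dtf)
        p_switch_off = 1.0 - np.exp(-k_off * dtf)
        u = rng.random(n_sites)
        on = np.where(on, u >= p_switch_off, u < p_switch_on)
        tx_f[:, i] = scale * (params.k_leak + on.astype(float))

    m = np.empty_like(tf)
    p = np.empty_like(tf)
    m[0], p[0] = y0[1], y0[2]
    dp_basal = params.delta_p_basal(spec)
    use_fstab = spec.degron is Degron.FRA1
    total_tx = tx_f.sum(axis=0)
    for i in range(1, len(tf)):
        dm = float(_mrna_decay(z[i - 1], spec, params))
        am = np.exp(-dm * dtf)
        m[i] = am * m[i - 1] + (1 - am) * total_tx[i - 1] / dm
        dp = dp_basal * (1.0 - params.f_stab * e_f[i - 1]) if use_fstab else dp_basal
        ap = np.exp(-dp * dtf)
        p[i] = ap * p[i - 1] + (1 - ap) * params.k_tl * eps_f[i - 1] * m[i - 1] / dp
    sel = np.arange(0, len(tf), refine)
    return z[sel], tx_f[:, sel], m[sel], p[sel]


# ---------------------------------------------------------------------------
# presets

CIRCUIT_PRESETS: dict[str, CircuitSpec] = {
    "fos-tubulin": CircuitSpec(utr3=UTR3.TUBULIN),
    "fos-btg2": CircuitSpec(utr3=UTR3.BTG2),
    "fos-fos": CircuitSpec(utr3=UTR3.FOS),
    "btg2-fos": CircuitSpec(promoter=Promoter.BTG2, utr5=UTR5.BTG2, utr3=UTR3.FOS),
    "btg2-btg2": CircuitSpec(promoter=Promoter.BTG2, utr5=UTR5.BTG2, utr3=UTR3.BTG2),
    "fos-fra1deg-fos": CircuitSpec(utr3=UTR3.FOS, degron=Degron.FRA1),
    "and-gate": CircuitSpec(utr3=UTR3.BTG2, reporter=Reporter.dGFP),
}

_SERUM_TAU = 24.0  # min; first-order serum->Erk rise used by the serum presets

STIMULUS_PRESETS: dict[str, StimulusProgram] = {
    "starve": StimulusProgram(),
    "serum10": StimulusProgram(serum_fraction=0.10, erk_tau_min=_SERUM_TAU),
    "serum1": StimulusProgram(serum_fraction=0.01, erk_tau_min=_SERUM_TAU),
    "transient20": StimulusProgram(light_windows=((0.0, 20.0),)),
    "sustained": StimulusProgram(light_windows=((0.0, 180.0),)),
    "sustained90": StimulusProgram(light_windows=((0.0, 90.0),)),
    "dox": StimulusProgram(doxorubicin_nM=860.0),
    "serum1+dox": StimulusProgram(serum_fraction=0.01, doxorubicin_nM=860.0,
                                  erk_tau_min=_SERUM_TAU),
    "serum10+chx": StimulusProgram(serum_fraction=0.10, cycloheximide=True,
                                   erk_tau_min=_SERUM_TAU),
    "serum10+meki30": StimulusProgram(serum_fraction=0.10, meki_time_min=30.0,
                                      erk_tau_min=_SERUM_TAU),
}


def get_circuit_preset(name: str) -> CircuitSpec:
    try:
        return CIRCUIT_PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown circuit preset {name!r}; known: {sorted(CIRCUIT_PRESETS)}"
        ) from None


def get_stimulus_preset(name: str) -> StimulusProgram:
    try:
        return STIMULUS_PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown stimulus preset {name!r}; known: {sorted(STIMULUS_PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# calibration

def _fold_percent(traj: Trajectory) -> float:
    p = traj.protein
    baseline = 0.5 * (p[0] + p[1])
    return 100.0 * (p[-1] / baseline - 1.0)


def _tx_timing(traj: Trajectory, t_add: float = 0.0) -> tuple[float, float | None]:
    """(time-to-peak, adaptation time) of mean transcription, relative to t_add."""
    tx = traj.mean_tx_rate
    t = traj.time_grid
    sel = t >= t_add
    tx, t = tx[sel], t[sel]
    base = tx[0]
    i_peak = int(np.argmax(tx))
    peak_t = t[i_peak] - t_add
    thresh = base + 0.05 * (tx[i_peak] - base)
    after = np.where(tx[i_peak:] <= thresh)[0]
    adapt_t = (t[i_peak + after[0]] - t_add) if len(after) else None
    return peak_t, adapt_t


DEFAULT_CONSTRAINTS: dict[str, float] = {
    "tx_peak_min": 30.0,        # serum transcription peak time
    "tx_adapt_max_min": 90.0,   # serum transcription back near baseline by
    "fold_tubulin_pct": 40.0,   # fos-tubulin sustained 3-h percent increase
    "fold_fra1_pct": 20.0,      # fos-Fra1deg-fos sustained 3-h percent increase
    "and_gate_fold": 4.0,       # AND-gate serum+dox endpoint fold
    "single_input_fold_max": 1.5,
    "tubulin_duration_ratio": 1.0,  # fos-tubulin fold(sustained)/fold(transient)
}


def _evaluate_constraints(params: KineticParams,
                          constraints: Mapping[str, float]) -> dict[str, float]:
    """Relative residual per constraint (0 = satisfied exactly; bounds clip at 0)."""
    res: dict[str, float] = {}
    if "tx_peak_min" in constraints or "tx_adapt_max_min" in constraints:
        sig = make_stimulus(get_stimulus_preset("serum10"), params.k_damage)
        traj = simulate_circuit(get_circuit_preset("fos-btg2"), params, sig)
        peak, adapt = _tx_timing(traj)
        if "tx_peak_min" in constraints:
            res["tx_peak_min"] = abs(peak - constraints["tx_peak_min"]) / constraints["tx_peak_min"]
        if "tx_adapt_max_min" in constraints:
            bound = constraints["tx_adapt_max_min"]
            res["tx_adapt_max_min"] = 0.0 if (adapt is not None and adapt <= bound) else (
                ((adapt or 2 * bound) - bound) / bound)
    if "fold_tubulin_pct" in constraints or "tubulin_duration_ratio" in constraints:
        sig = make_stimulus(get_stimulus_preset("sustained"), params.k_damage)
        fold = _fold_percent(simulate_circuit(get_circuit_preset("fos-tubulin"), params, sig))
        if "fold_tubulin_pct" in constraints:
            res["fold_tubulin_pct"] = abs(fold - constraints["fold_tubulin_pct"]) / constraints["fold_tubulin_pct"]
        if "tubulin_duration_ratio" in constraints:
            sig_t = make_stimulus(get_stimulus_preset("transient20"), params.k_damage)
            fold_t = _fold_percent(simulate_circuit(get_circuit_preset("fos-tubulin"), params, sig_t))
            ratio = (1.0 + fold / 100.0) / (1.0 + fold_t / 100.0)
            res["tubulin_duration_ratio"] = abs(ratio - constraints["tubulin_duration_ratio"])
    if "fold_fra1_pct" in constraints:
        sig = make_stimulus(get_stimulus_preset("sustained"), params.k_damage)
        fold = _fold_percent(simulate_circuit(get_circuit_preset("fos-fra1deg-fos"), params, sig))
        res["fold_fra1_pct"] = abs(fold - constraints["fold_fra1_pct"]) / constraints["fold_fra1_pct"]
    if "and_gate_fold" in constraints:
        and_spec = get_circuit_preset("and-gate")
        folds = {}
        for cond in ("serum1", "dox", "serum1+dox"):
            sig = make_stimulus(get_stimulus_preset(cond), params.k_damage)
            traj = simulate_circuit(and_spec, params, sig)
            folds[cond] = 1.0 + _fold_percent(traj) / 100.0
        res["and_gate_fold"] = abs(folds["serum1+dox"] - constraints["and_gate_fold"]) / constraints["and_gate_fold"]
        if "single_input_fold_max" in constraints:
            tau = constraints["single_input_fold_max"]
            worst = max(folds["serum1"], folds["dox"])
            res["single_input_fold_max"] = max(0.0, (worst - tau) / tau)
    return res


# search box for the free parameters (coarse grid stage); k_tx and k_tl are
# pure scales absorbed by the fluorescence units and stay fixed.
_CALIBRATION_BOX: dict[str, tuple[float, float]] = {
    "k_z": (0.02, 0.12),
    "delta_z": (0.01, 0.05),
    "K_z": (0.6, 2.0),
    "alpha_fos": (2.0, 16.0),
    "delta_p_degron": (0.003, 0.02),
    "k_leak": (0.005, 0.08),
    "eps_min": (0.03, 0.2),
    "background_yfp_au": (100.0, 20000.0),
    "background_gfp_au": (50.0, 5000.0),
    "k_tl": (0.05, 2.0),
}


def calibrate_defaults(
    constraints: Mapping[str, float] | None = None,
    base: KineticParams | None = None,
    search: Mapping[str, tuple[float, float]] | None = None,
    n_grid: int = 4,
    tol: float = 0.15,
    seed: int = 0,
) -> KineticParams:
    """Find one parameter set meeting the behavioral constraints within ``tol``.

    Coarse random/grid search over ``search`` (Latin-hypercube-style seeded
    draws plus the box corners' midpoint), followed by Nelder-Mead refinement
    of the worst-case relative residual.  Raises :class:`CalibrationError`
    with the best residuals if the set is infeasible at this resolution.
    """
    constraints = dict(DEFAULT_CONSTRAINTS if constraints is None else constraints)
    base = base or KineticParams()
    box = dict(_CALIBRATION_BOX if search is None else search)
    names = list(box)
    rng = np.random.default_rng(seed)

    def build(vec: np.ndarray) -> KineticParams:
        return base.replace(**{n: float(np.clip(v, *box[n])) for n, v in zip(names, vec)})

    def score(vec: np.ndarray) -> float:
        try:
            res = _evaluate_constraints(build(vec), constraints)
        except ValidationError:
            return np.inf
        return max(res.values()) if res else 0.0

    lo = np.array([box[n][0] for n in names])
    hi = np.array([box[n][1] for n in names])
    start = np.array([getattr(base, n) for n in names], dtype=float)
    candidates = [np.clip(start, lo, hi)]
    n_draws = max(n_grid ** 2, 8)
    candidates.extend(lo + rng.random((n_draws, len(names))) * (hi - lo))

    best_vec = min(candidates, key=score)
    best = score(best_vec)

    from scipy.optimize import minimize

    if best > 0:
        sol = minimize(score, best_vec, method="Nelder-Mead",
                       options={"maxfev": 300, "xatol": 1e-3, "fatol": 1e-3})
        if sol.fun < best:
            best, best_vec = sol.fun, sol.x

    params = build(best_vec)
    residuals = _evaluate_constraints(params, constraints)
    if max(residuals.values(), default=0.0) > tol:
        detail = ", ".join(f"{k}: {v:.3f}" for k, v in sorted(residuals.items()))
        raise CalibrationError(
            f"constraint set infeasible at this search resolution (best residuals: {detail})"
        )
    return params
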