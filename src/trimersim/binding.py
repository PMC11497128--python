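"""Ternary-complex formation engine for FAP x 4-1BB bispecific costimulators.

A bispecific costimulatory antibody binds independently and sequentially to a
tumor-stroma target (FAP, on fibroblasts) and to the costimulatory receptor
4-1BB (CD137, on activated T cells).  The pharmacologically active species is
the trimeric complex -- antibody engaged with both receptors at once.  Because
high antibody concentrations occupy each receptor with *separate* antibody
molecules, trimeric-complex formation follows a bell-shaped curve in antibody
concentration (the hook/prozone effect), peaking at the geometric mean of the
two dissociation constants.

This module provides:

* mass-action ODE simulation of the four species (free antibody, the two
  binary dimers, the trimer) in a defined in vitro cell system, with either a
  constant 4-1BB level or a transient trapezoidal 4-1BB pulse that mimics
  T-cell activation by a co-administered CD3 T-cell bispecific;
* an independent equilibrium root-finding solver for the constant-4-1BB steady
  state, used as an oracle for the ODE path;
* bell-curve scans over antibody concentration.

Units: concentrations in nM, time in hours, rate constants in 1/(nM*h) and
1/h, volumes in litres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

AVOGADRO = 6.02214076e23

#: Default association rate for both arms, 1/(nM*h).  Approximately 1e6 /M/s,
#: the diffusion-limited order of magnitude for antibody-antigen binding.
#: Equilibrium quantities do not depend on it (asserted by test).
DEFAULT_KON = 3.6

#: Median FAP receptors per fibroblast in colon cancer.
COLON_MEDIAN_FAP = 2960.0

#: Default integrator tolerances.  The trimer concentration in the in vitro
#: system is O(1e-9 nM) (a few thousandths of a complex per T cell on ~3e-6 nM
#: total 4-1BB), so the absolute tolerance must sit far below that for the
#: steady state to agree with the equilibrium oracle to 1e-6 relative.
ODE_RTOL = 1e-8
ODE_ATOL = 1e-18

#: Default first-order persistence half-life (hours) of the trimeric complex
#: after 4-1BB down-regulation (the immune synapse outlives free-receptor
#: availability).
DEFAULT_PERSISTENCE_HALFLIFE = 48.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

def receptors_to_concentration(count: float, volume: float) -> float:
    """Convert a receptor count in a volume (L) to a concentration in nM."""
    if volume <= 0:
        raise ValueError(f"volume must be positive, got {volume}")
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return count / (AVOGADRO * volume) * 1e9


def concentration_to_receptors(conc_nm: float, volume: float) -> float:
    """Inverse of :func:`receptors_to_concentration`."""
    if volume <= 0:
        raise ValueError(f"volume must be positive, got {volume}")
    return conc_nm * AVOGADRO * volume / 1e9


@dataclass(frozen=True)
class BispecificMolecule:
    """Binding parameters of one (virtual) bispecific costimulator.

    Parameters
    ----------
    kd_fap, kd_41bb
        Dissociation constants of the FAP and 4-1BB arms, nM.
    kon_fap, kon_41bb
        Association rates, 1/(nM*h); off-rates follow as ``kon * kd``.
    avidity_factor
        Dimensionless multiplier on the association rate of the second
        (membrane-crosslinking) binding step.  The solution-phase model
        under-predicts absolute trimer counts because crosslinking on
        apposed cell surfaces is effectively two-dimensional; this single
        scalar is calibrated against printed anchors (see
        :mod:`trimersim.effect`).
    mw
        Molar mass, g/mol; used only for clinical mg -> nmol conversion.
    """

    kd_fap: float
    kd_41bb: float = 0.2
    kon_fap: float = DEFAULT_KON
    kon_41bb: float = DEFAULT_KON
    avidity_factor: float = 1.0
    mw: float = 150_000.0

    def __post_init__(self) -> None:
        for name in ("kd_fap", "kd_41bb", "kon_fap", "kon_41bb",
                     "avidity_factor", "mw"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")

    @property
    def koff_fap(self) -> float:
        return self.kon_fap * self.kd_fap

    @property
    def koff_41bb(self) -> float:
        return self.kon_41bb * self.kd_41bb

    def with_avidity(self, avidity_factor: float) -> "BispecificMolecule":
        return replace(self, avidity_factor=avidity_factor)

    def with_fap_affinity_fold(self, fold: float) -> "BispecificMolecule":
        """Molecule with FAP affinity increased ``fold``-fold (kd / fold)."""
        return replace(self, kd_fap=self.kd_fap / fold)


#: The clinically tested reference molecule (FAP KD 0.7 nM, 4-1BB KD 0.2 nM).
def reference_molecule(avidity_factor: float = 1.0) -> BispecificMolecule:
    return BispecificMolecule(kd_fap=0.7, avidity_factor=avidity_factor)


def enhanced_molecule(avidity_factor: float = 1.0,
                      fold: float = 10.0) -> BispecificMolecule:
    """Virtual molecule with a ``fold``-fold increase in FAP-binding affinity."""
    return BispecificMolecule(kd_fap=0.7 / fold, avidity_factor=avidity_factor)


@dataclass(frozen=True)
class FourOneBBProfile:
    """Time course of total 4-1BB receptors per T cell.

    The default is a trapezoidal pulse emulating T-cell activation by a CD3
    T-cell bispecific: near-zero baseline, linear rise from treatment start,
    plateau at the peak between 24 and 48 h, linear return to baseline by
    84 h.  Setting ``constant_level`` overrides the dynamics entirely
    (used for equilibrium oracles and for simulations run at a fixed
    150 receptors per T cell).
    """

    baseline: float = 0.0
    peak: float = 150.0
    t_rise_start: float = 0.0
    t_peak_lo: float = 24.0
    t_peak_hi: float = 48.0
    t_return: float = 84.0
    constant_level: float | None = None

    def __post_init__(self) -> None:
        if self.constant_level is not None:
            if self.constant_level < 0:
                raise ValueError("constant_level must be non-negative")
            return
        if not 0 <= self.baseline <= self.peak:
            raise ValueError("require 0 <= baseline <= peak")
        if not (0 <= self.t_rise_start < self.t_peak_lo
                <= self.t_peak_hi < self.t_return):
            raise ValueError("require t_rise_start < t_peak_lo <= t_peak_hi < t_return")

    @property
    def is_constant(self) -> bool:
        return self.constant_level is not None

    def level_at(self, t):
        """Total 4-1BB receptors per T cell at time ``t`` (hours, array ok)."""
        if self.constant_level is not None:
            return np.full_like(np.asarray(t, dtype=float), self.constant_level)
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.baseline, dtype=float)
        rising = (t >= self.t_rise_start) & (t < self.t_peak_lo)
        out[rising] = self.baseline + (self.peak - self.baseline) * (
            (t[rising] - self.t_rise_start) / (self.t_peak_lo - self.t_rise_start))
        out[(t >= self.t_peak_lo) & (t <= self.t_peak_hi)] = self.peak
        falling = (t > self.t_peak_hi) & (t < self.t_return)
        out[falling] = self.peak + (self.baseline - self.peak) * (
            (t[falling] - self.t_peak_hi) / (self.t_return - self.t_peak_hi))
        return out

    def breakpoints(self) -> list[float]:
        if self.is_constant:
            return []
        return [self.t_rise_start, self.t_peak_lo, self.t_peak_hi, self.t_return]


def constant_profile(level: float) -> FourOneBBProfile:
    return FourOneBBProfile(constant_level=level)


@dataclass(frozen=True)
class InVitroSystem:
    """Composition of the in vitro killing-assay well.

    Defaults reflect the assay the model was developed on: 200 uL wells with
    10,000 FAP-expressing fibroblasts, 5,000 PBMCs (half of them T cells) and
    5,000 MKN-45 tumor cells (the tumor cells enter only through the CD3
    bispecific's 4-1BB induction, which is summarised by ``r41bb_profile``).
    """

    volume: float = 2.0e-4
    n_fibroblasts: int = 10_000
    fap_per_fibroblast: float = COLON_MEDIAN_FAP
    n_pbmc: int = 5_000
    tcell_fraction: float = 0.5
    n_tumor_cells: int = 5_000
    r41bb_profile: FourOneBBProfile = field(default_factory=FourOneBBProfile)

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if min(self.n_fibroblasts, self.n_pbmc, self.n_tumor_cells) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.fap_per_fibroblast < 0:
            raise ValueError("fap_per_fibroblast must be non-negative")
        if not 0 < self.tcell_fraction <= 1:
            raise ValueError("tcell_fraction must be in (0, 1]")

    @property
    def n_tcells(self) -> float:
        return self.n_pbmc * self.tcell_fraction

    @property
    def fap_total_nm(self) -> float:
        """Total FAP concentration in the well, nM."""
        return receptors_to_concentration(
            self.n_fibroblasts * self.fap_per_fibroblast, self.volume)

    def r41bb_total_nm(self, t) -> np.ndarray:
        """Total 4-1BB concentration in the well at time ``t``, nM."""
        per_cell = self.r41bb_profile.level_at(t)
        return per_cell * self.n_tcells / (AVOGADRO * self.volume) * 1e9

    @property
    def nm_per_tcell_unit(self) -> float:
        """Concentration (nM) of one receptor on every T cell in the well."""
        return receptors_to_concentration(self.n_tcells, self.volume)

    def with_fap(self, fap_per_fibroblast: float) -> "InVitroSystem":
        return replace(self, fap_per_fibroblast=fap_per_fibroblast)

    def with_profile(self, profile: FourOneBBProfile) -> "InVitroSystem":
        return replace(self, r41bb_profile=profile)


def colon_median_system(profile: FourOneBBProfile | None = None) -> InVitroSystem:
    """The standard well with fibroblasts at the colon-cancer median FAP."""
    system = InVitroSystem(fap_per_fibroblast=COLON_MEDIAN_FAP)
    if profile is not None:
        system = system.with_profile(profile)
    return system


@dataclass(frozen=True)
class BindingState:
    """Species trajectories from one binding simulation (all nM, t in hours)."""

    t: np.ndarray
    free_ab: np.ndarray
    ab_fap: np.ndarray
    ab_41bb: np.ndarray
    trimer: np.ndarray
    tc_per_tcell: np.ndarray

    @property
    def terminal_tc_per_tcell(self) -> float:
        return float(self.tc_per_tcell[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_h": self.t,
            "free_ab_nM": self.free_ab,
            "ab_fap_nM": self.ab_fap,
            "ab_41bb_nM": self.ab_41bb,
            "trimer_nM": self.trimer,
            "tc_per_tcell": self.tc_per_tcell,
        })


# ---------------------------------------------------------------------------
# ODE core
# ---------------------------------------------------------------------------

def _rhs_active(t, y, kon1, koff1, kon2, koff2, alpha, f_tot, btot_of_t,
                eps_b, k_pers):
    """Mass-action kinetics while free 4-1BB is being supplied.

    Free receptor pools are algebraic (conservation against the instantaneous
    totals); the soft factor ``s`` shuts mass-action dissociation of the
    trimer off when the free 4-1BB pool is exhausted (receptor released from
    a complex would be internalised immediately), handing over to the slow
    first-order persistence decay.
    """
    a, af, ab, tr = y
    f = max(f_tot - af - tr, 0.0)
    b = max(btot_of_t(t) - ab - tr, 0.0)
    s = 1.0 if eps_b == 0.0 else b / (b + eps_b)
    form_af = kon1 * a * f
    form_ab = kon2 * a * b
    cross_af = alpha * kon2 * af * b     # AF + B -> T
    cross_ab = alpha * kon1 * ab * f     # AB + F -> T
    pers = (1.0 - s) * k_pers * tr
    d_a = -form_af + koff1 * af - form_ab + koff2 * ab + pers
    d_af = form_af - koff1 * af - cross_af + s * koff2 * tr
    d_ab = form_ab - koff2 * ab - cross_ab + s * koff1 * tr
    d_tr = cross_af + cross_ab - s * (koff1 + koff2) * tr - pers
    return (d_a, d_af, d_ab, d_tr)


def _rhs_locked(t, y, kon1, koff1, kon2, koff2, alpha, f_tot, btot_of_t,
                k_pers):
    """Kinetics during/after 4-1BB down-regulation.

    The trimer is treated as a stabilised synapse: no mass-action
    dissociation or further crosslinking, only slow first-order decay that
    returns the antibody (and, through conservation, the FAP receptor) while
    the 4-1BB moiety is internalised.  Binary 4-1BB dimers keep exchanging
    with whatever free receptor the declining profile still allows.
    """
    a, af, ab, tr = y
    f = max(f_tot - af - tr, 0.0)
    b = max(btot_of_t(t) - ab - tr, 0.0)
    form_af = kon1 * a * f
    form_ab = kon2 * a * b
    pers = k_pers * tr
    d_a = -form_af + koff1 * af - form_ab + koff2 * ab + pers
    d_af = form_af - koff1 * af
    d_ab = form_ab - koff2 * ab
    d_tr = -pers
    return (d_a, d_af, d_ab, d_tr)


def simulate_binding(molecule: BispecificMolecule,
                     system: InVitroSystem,
                     conc: float,
                     duration: float = 120.0,
                     n_eval: int = 241,
                     rtol: float = ODE_RTOL,
                     atol: float = ODE_ATOL,
                     persistence_halflife: float = DEFAULT_PERSISTENCE_HALFLIFE,
                     ) -> BindingState:
    """Integrate trimeric-complex formation in a closed in vitro well.

    Parameters
    ----------
    conc
        Total bispecific antibody concentration added to the well, nM.
    duration
        Simulated time, hours (the assay endpoint is 120 h).

    Returns
    -------
    BindingState
        Full species trajectories including trimeric complexes per T cell.
    """
    if conc < 0:
        raise ValueError("conc must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    t_eval = np.linspace(0.0, duration, n_eval)
    if conc == 0.0 or system.fap_total_nm == 0.0:
        zeros = np.zeros_like(t_eval)
        free = np.full_like(t_eval, conc)
        return BindingState(t_eval, free, zeros.copy(), zeros.copy(),
                            zeros.copy(), zeros.copy())

    profile = system.r41bb_profile
    f_tot = system.fap_total_nm
    btot_of_t = system.r41bb_total_nm
    k_pers = math.log(2.0) / persistence_halflife
    kin = (molecule.kon_fap, molecule.koff_fap,
           molecule.kon_41bb, molecule.koff_41bb, molecule.avidity_factor)

    if profile.is_constant:
        segments = [(0.0, duration, "active")]
        eps_b = 0.0
    else:
        # Integrate piecewise at profile kinks; mass action while the pulse
        # is rising or at plateau, persistence mode once down-regulation
        # starts.
        eps_b = 1e-12
        cuts = sorted({0.0, duration,
                       *[b for b in profile.breakpoints() if 0.0 < b < duration]})
        segments = []
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            mode = "active" if hi <= profile.t_peak_hi else "locked"
            segments.append((lo, hi, mode))

    y = np.array([conc, 0.0, 0.0, 0.0])
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for lo, hi, mode in segments:
        seg_eval = t_eval[(t_eval >= lo) & (t_eval <= hi)]
        seg_eval = np.unique(np.concatenate(([lo], seg_eval, [hi])))
        if mode == "active":
            rhs = _rhs_active
            args = (*kin, f_tot, btot_of_t, eps_b, k_pers)
        else:
            rhs = _rhs_locked
            args = (*kin, f_tot, btot_of_t, k_pers)
        sol = solve_ivp(rhs, (lo, hi), y, method="LSODA", t_eval=seg_eval,
                        rtol=rtol, atol=atol, args=args)
        if not sol.success:  # pragma: no cover - integrator failure surfaced
            raise RuntimeError(f"binding ODE failed on [{lo}, {hi}]: {sol.message}")
        ts.append(sol.t)
        ys.append(sol.y)
        y = sol.y[:, -1]

    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1)
    # drop duplicated segment-boundary points
    keep = np.concatenate(([True], np.diff(t_all) > 0))
    t_all = t_all[keep]
    y_all = y_all[:, keep]
    tc = y_all[3] / system.nm_per_tcell_unit
    return BindingState(t_all, y_all[0], y_all[1], y_all[2], y_all[3], tc)


def terminal_tc(molecule: BispecificMolecule, system: InVitroSystem,
                conc: float, duration: float = 120.0, **kwargs) -> float:
    """Trimeric complexes per T cell at the end of the simulated period."""
    return simulate_binding(molecule, system, conc, duration,
                            n_eval=9, **kwargs).terminal_tc_per_tcell


# ---------------------------------------------------------------------------
# Equilibrium oracle (constant 4-1BB)
# ---------------------------------------------------------------------------

def optimal_concentration(molecule: BispecificMolecule) -> float:
    """Concentration maximising trimeric-complex formation, nM.

    The geometric mean of the two dissociation constants -- the exact argmax
    of the bell curve in the no-depletion regime.
    """
    return math.sqrt(molecule.kd_fap * molecule.kd_41bb)


def _equilibrium_species(molecule: BispecificMolecule, a_tot: float,
                         f_tot: float, b_tot: float) -> dict[str, float]:
    """Solve the coupled binding equilibrium under mass conservation.

    Free species parameterisation: with free antibody A, free FAP F and free
    4-1BB B, the complexes are AF = A F / kd1, AB = A B / kd2 and
    T = alpha A F B / (kd1 kd2) (the crosslinking step's KD is the solution
    KD divided by the avidity factor; the thermodynamic cycle is consistent
    because both orderings accumulate the same factor).  Nested bounded
    root-finding on the three conservation laws.
    """
    kd1, kd2 = molecule.kd_fap, molecule.kd_41bb
    alpha = molecule.avidity_factor
    if a_tot == 0.0 or f_tot == 0.0 or b_tot == 0.0:
        return {"A": a_tot, "F": f_tot, "B": b_tot, "AF": 0.0, "AB": 0.0,
                "T": 0.0}

    def b_free(a: float, f: float) -> float:
        return b_tot / (1.0 + a / kd2 + alpha * a * f / (kd1 * kd2))

    def f_resid(f: float, a: float) -> float:
        b = b_free(a, f)
        return f * (1.0 + a / kd1 + alpha * a * b / (kd1 * kd2)) - f_tot

    def f_free(a: float) -> float:
        return brentq(f_resid, 0.0, f_tot, args=(a,), xtol=1e-300, rtol=1e-15)

    def a_resid(a: float) -> float:
        f = f_free(a)
        b = b_free(a, f)
        af = a * f / kd1
        ab = a * b / kd2
        tr = alpha * a * f * b / (kd1 * kd2)
        return a + af + ab + tr - a_tot

    a = brentq(a_resid, 0.0, a_tot, xtol=1e-300, rtol=1e-15)
    f = f_free(a)
    b = b_free(a, f)
    return {"A": a, "F": f, "B": b, "AF": a * f / kd1, "AB": a * b / kd2,
            "T": alpha * a * f * b / (kd1 * kd2)}


def equilibrium_tc(molecule: BispecificMolecule, system: InVitroSystem,
                   conc: float) -> float:
    """Equilibrium trimeric complexes per T cell at constant 4-1BB.

    Independent of the ODE path (bounded root-finding on the conservation
    laws); requires ``constant_level`` to be set on the system's 4-1BB
    profile.
    """
    if not system.r41bb_profile.is_constant:
        raise ValueError("equilibrium_tc requires a constant 4-1BB profile")
    if conc < 0:
        raise ValueError("conc must be non-negative")
    b_tot = float(system.r41bb_total_nm(0.0))
    species = _equilibrium_species(molecule, conc, system.fap_total_nm, b_tot)
    return species["T"] / system.nm_per_tcell_unit


# ---------------------------------------------------------------------------
# Bell curves
# ---------------------------------------------------------------------------

def default_concentration_grid(n: int = 60, lo: float = 2e-5,
                               hi: float = 50.0) -> np.ndarray:
    """Log-spaced antibody concentration grid over the explored range, nM."""
    return np.geomspace(lo, hi, n)


def bell_curve(molecule: BispecificMolecule, system: InVitroSystem,
               conc_grid: Sequence[float] | None = None,
               duration: float = 120.0, **kwargs) -> pd.DataFrame:
    """Terminal trimeric complexes per T cell over a concentration grid.

    Returns a DataFrame with columns ``conc_nM`` and ``tc_per_tcell``; the
    response is unimodal (bell-shaped on a log axis) with its maximum near
    the geometric mean of the two KDs.
    """
    if conc_grid is None:
        conc_grid = default_concentration_grid()
    conc_grid = np.asarray(conc_grid, dtype=float)
    if conc_grid.size == 0 or np.any(conc_grid <= 0):
        raise ValueError("conc_grid must be non-empty and strictly positive")
    tc = [terminal_tc(molecule, system, c, duration, **kwargs)
          for c in conc_grid]
    return pd.DataFrame({"conc_nM": conc_grid, "tc_per_tcell": tc})
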