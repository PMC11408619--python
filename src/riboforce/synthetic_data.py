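"""Synthetic force-spectroscopy traces with known ground truth.

The generator emulates a bead-tethered riboswitch aptamer in a magnetic
force spectroscopy instrument.  The molecule is a two-state system
(folded/unfolded) whose transition rates depend exponentially on applied
force (Bell/Kramers):

    k_unfold(F) = k_unfold0 * exp(+F * x_unfold / kBT) * s(c)
    k_refold(F) = k_fold0   * exp(-F * x_fold   / kBT) * g(c)

Two mechanistically distinct ligand modes are supported:

``kinetic_stabilizer``
    The ligand slows unfolding of the (single) folded state without creating
    a new one: s(c) = 1 / (1 + (stabilization_factor - 1) * c / (c + K_D)).
    Optionally it also speeds refolding, g(c) = 1 + (fold_enhancement_factor
    - 1) * c / (c + K_D).  This is the compound-4-like mechanism: a subtle,
    concentration-dependent shift of the rupture-force peak.

``pseudoknot_inducer``
    On each refolding, the molecule enters a distinct, much more stable
    pseudoknot state with probability c / (c + K_D), and thereafter unfolds
    with its own Bell parameters (pk_k_unfold0, pk_x_unfold).  This is the
    cognate-ligand-like mechanism: a second rupture-force peak at high force
    and a long-lifetime component in the folded dwell distribution, with the
    first peak position unchanged.

Force ramps are discretized at the sampling rate with per-sample transition
probability 1 - exp(-k(F) dt); constant-force recordings use exact
(Gillespie) exponential dwell sampling.  Extension is baseline_nm +
compliance * F + delta_L * [unfolded] + Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .trace_model import (
    ConditionLabel,
    DwellSegment,
    FoldingEvent,
    Ligand,
    Trace,
)
from . import dose_response as _dr

__all__ = [
    "KineticModel",
    "ProtocolParams",
    "ResolutionError",
    "simulate_ramp_trace",
    "simulate_constant_force_trace",
    "simulate_titration",
    "simulate_ramp_cohort",
    "simulate_constant_force_cohort",
    "kd_for_half_effect",
]

#: thermal energy at the 22 degC measurement temperature, pN*nm
KBT_22C = 4.07


class ResolutionError(ValueError):
    """Transition rates exceed what the sampling rate can resolve.

    Raised when k * dt > 0.5 at forces where the departing state still has
    non-negligible occupancy; advises a finer time step.
    """


@dataclass
class KineticModel:
    """Bell-model kinetic parameters of one tethered molecule.

    Rates in 1/s, distances in nm, kBT in pN*nm, K_D in molar.  The default
    parameter set places the control rupture-force distribution around 9 pN
    (inside the 5-15 pN analysis window) for the default 2 pN/s ramp, with
    an equilibrium force near 7 pN for constant-force work.
    """

    k_unfold0: float = 1.3e-3
    x_unfold: float = 3.0
    k_fold0: float = 8.0
    x_fold: float = 2.0
    delta_L: float = 15.0
    kBT: float = KBT_22C
    ligand_mode: str = "none"  # none | kinetic_stabilizer | pseudoknot_inducer
    K_D_ligand: float = 400e-6
    stabilization_factor: float = 2.0
    fold_enhancement_factor: float = 1.0
    pk_k_unfold0: float = 6.7e-4
    pk_x_unfold: float = 1.5
    baseline_nm: float = 60.0
    compliance_nm_per_pn: float = 0.2
    delta_L_range: tuple[float, float] = (10.0, 25.0)

    def __post_init__(self) -> None:
        for name in ("k_unfold0", "k_fold0", "pk_k_unfold0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.kBT <= 0:
            raise ValueError("kBT must be > 0")
        lo, hi = self.delta_L_range
        if not lo <= self.delta_L <= hi:
            raise ValueError(
                f"delta_L {self.delta_L} outside configured range [{lo}, {hi}]"
            )
        if self.ligand_mode not in ("none", "kinetic_stabilizer", "pseudoknot_inducer"):
            raise ValueError(f"unknown ligand_mode {self.ligand_mode!r}")
        if self.K_D_ligand <= 0:
            raise ValueError("K_D_ligand must be > 0")
        if self.stabilization_factor < 1 or self.fold_enhancement_factor < 1:
            raise ValueError("stabilization/fold-enhancement factors must be >= 1")

    # -- concentration-dependent rate factors ------------------------------

    def occupancy(self, c: float) -> float:
        """Ligand-bound fraction c / (c + K_D)."""
        return c / (c + self.K_D_ligand) if c > 0 else 0.0

    def unfold_slowdown(self, c: float) -> float:
        """s(c): multiplicative factor on the unfolding rate (<= 1)."""
        if self.ligand_mode != "kinetic_stabilizer":
            return 1.0
        return 1.0 / (1.0 + (self.stabilization_factor - 1.0) * self.occupancy(c))

    def refold_speedup(self, c: float) -> float:
        """g(c): multiplicative factor on the refolding rate (>= 1)."""
        if self.ligand_mode != "kinetic_stabilizer":
            return 1.0
        return 1.0 + (self.fold_enhancement_factor - 1.0) * self.occupancy(c)

    def pk_probability(self, c: float) -> float:
        """Probability that a refolding event lands in the pseudoknot state."""
        if self.ligand_mode != "pseudoknot_inducer":
            return 0.0
        return self.occupancy(c)

    # -- force-dependent rates ---------------------------------------------

    def k_unfold(self, force, c: float = 0.0):
        return self.k_unfold0 * np.exp(np.asarray(force) * self.x_unfold / self.kBT) * self.unfold_slowdown(c)

    def k_unfold_pk(self, force):
        return self.pk_k_unfold0 * np.exp(np.asarray(force) * self.pk_x_unfold / self.kBT)

    def k_refold(self, force, c: float = 0.0):
        return self.k_fold0 * np.exp(-np.asarray(force) * self.x_fold / self.kBT) * self.refold_speedup(c)

    def baseline(self, force):
        return self.baseline_nm + self.compliance_nm_per_pn * np.asarray(force)


@dataclass
class ProtocolParams:
    """Measurement protocol: ramp or constant-force, plus noise and seed."""

    kind: str = "ramp"  # ramp | constant_force
    f_min: float = 1.0
    f_max: float = 25.0
    ramp_rate: float = 2.0  # pN/s
    n_cycles: int = 50
    hold_force: float = 7.0
    hold_duration: float = 1800.0  # s (30 min)
    sample_rate: float = 30.0  # Hz
    noise_sd: float = 3.0  # nm
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("ramp", "constant_force"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.kind == "ramp" and not self.f_min < self.f_max:
            raise ValueError("f_min must be < f_max for ramps")
        if self.hold_duration <= 0 or self.sample_rate <= 0:
            raise ValueError("durations and sample_rate must be > 0")
        if self.kind == "ramp" and self.ramp_rate <= 0:
            raise ValueError("ramp_rate must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def kd_for_half_effect(half_effect_conc: float, factor: float) -> float:
    """Ligand K_D that places the half-maximal *effect* at a given concentration.

    In kinetic_stabilizer mode the log-rate (and hence rupture-force) shift is
    proportional to log(1 + (factor-1) * c/(c+K_D)), which reaches half its
    saturating value at c = K_D / sqrt(factor).  Inverting: K_D = sqrt(factor)
    * c_half.  Use this to plant a target EC50 in a simulated cohort.
    """
    if factor <= 1:
        raise ValueError("factor must be > 1 for a concentration effect")
    return float(np.sqrt(factor) * half_effect_conc)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _infer_ligand(model: KineticModel, concentration: float) -> Ligand:
    if concentration == 0:
        return Ligand.CONTROL
    if model.ligand_mode == "kinetic_stabilizer":
        return Ligand.COMPOUND4
    if model.ligand_mode == "pseudoknot_inducer":
        return Ligand.PREQ1
    return Ligand.OTHER


def _next_true(mask: np.ndarray, start: int) -> int | None:
    if start >= mask.size:
        return None
    off = int(np.argmax(mask[start:]))
    idx = start + off
    return idx if mask[idx] else None


def _survival_checked_max_rate(k: np.ndarray, dt: float) -> float:
    """Max rate over the part of the profile the state actually survives to.

    Occupancy of the departing state decays as exp(-cumulative hazard); rates
    at forces the state reaches with probability < 1e-3 are irrelevant to any
    computed statistic (the deepest tail used downstream is the 95th
    percentile) and are not held against the time step.
    """
    surv = np.exp(-np.cumsum(k) * dt)
    reachable = np.ones_like(k, dtype=bool)
    reachable[1:] = surv[:-1] > 1e-3
    return float(np.max(k[reachable])) if np.any(reachable) else 0.0


def _check_ramp_resolution(model: KineticModel, f_up: np.ndarray, dt: float, c: float) -> None:
    checks = {
        "unfolding (pre-pseudoknot)": model.k_unfold(f_up, c),
        "refolding": model.k_refold(f_up[::-1], c),
    }
    if model.ligand_mode == "pseudoknot_inducer":
        checks["unfolding (pseudoknot)"] = model.k_unfold_pk(f_up)
    for name, k in checks.items():
        kmax = _survival_checked_max_rate(np.asarray(k, dtype=float), dt)
        if kmax * dt > 0.5:
            raise ResolutionError(
                f"{name} rate reaches {kmax:.3g}/s where the state is still "
                f"occupied; k*dt = {kmax * dt:.2f} > 0.5 at dt = {dt:.4g} s. "
                "Increase sample_rate or reduce the rates."
            )


def simulate_ramp_trace(
    model: KineticModel,
    protocol: ProtocolParams,
    concentration: float = 0.0,
    *,
    bead_id: str = "bead0",
    replicate: int = 0,
    rng=None,
    force_scale: float = 1.0,
    ligand: Ligand | None = None,
) -> tuple[Trace, list[FoldingEvent]]:
    """Simulate a force-ramp recording; return the trace and true events.

    The hidden folded/unfolded state evolves as a time-inhomogeneous Markov
    chain discretized at the sampling rate (transition probability per sample
    1 - exp(-k dt)).  ``force_scale`` models per-bead force-calibration error:
    rates see ``force_scale * F`` while the trace reports the nominal F.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    rng = _as_rng(rng if rng is not None else protocol.seed)
    fs = protocol.sample_rate
    dt = 1.0 / fs

    n_half = max(2, int(round((protocol.f_max - protocol.f_min) / protocol.ramp_rate * fs)))
    f_up = protocol.f_min + (protocol.f_max - protocol.f_min) * np.arange(n_half) / n_half
    f_cycle = np.concatenate([f_up, f_up[::-1]])
    force = np.tile(f_cycle, protocol.n_cycles)
    n = force.size
    t = np.arange(n) * dt
    cyc = np.repeat(np.arange(protocol.n_cycles), f_cycle.size)

    f_true = force_scale * force
    _check_ramp_resolution(model, force_scale * f_up, dt, concentration)

    p_pre = 1.0 - np.exp(-model.k_unfold(f_true, concentration) * dt)
    p_fold = 1.0 - np.exp(-model.k_refold(f_true, concentration) * dt)
    fire_pre = rng.random(n) < p_pre
    fire_fold = rng.random(n) < p_fold
    inducer = model.ligand_mode == "pseudoknot_inducer"
    if inducer:
        p_pk = 1.0 - np.exp(-model.k_unfold_pk(f_true) * dt)
        fire_pk = rng.random(n) < p_pk
    p_enter_pk = model.pk_probability(concentration)

    unfolded = np.zeros(n, dtype=bool)
    events: list[FoldingEvent] = []
    state_folded = True
    in_pk = inducer and rng.random() < p_enter_pk
    i = 0
    while i < n:
        if state_folded:
            mask = fire_pk if (inducer and in_pk) else fire_pre
            j = _next_true(mask, i)
            if j is None:
                break
            events.append(
                FoldingEvent("unfold", float(force[j]), model.delta_L, float(t[j]), int(cyc[j]))
            )
            unfolded[j:] = True
            state_folded = False
        else:
            j = _next_true(fire_fold, i)
            if j is None:
                break
            events.append(
                FoldingEvent("refold", float(force[j]), model.delta_L, float(t[j]), int(cyc[j]))
            )
            unfolded[j:] = False
            state_folded = True
            in_pk = inducer and rng.random() < p_enter_pk
        i = j + 1

    extension = model.baseline(force) + model.delta_L * unfolded
    extension = extension + rng.normal(0.0, protocol.noise_sd, n)
    cond = ConditionLabel(
        ligand if ligand is not None else _infer_ligand(model, concentration),
        concentration,
        replicate,
    )
    trace = Trace(bead_id, cond, t, extension, force, fs, cycle_id=cyc)
    return trace, events


def simulate_constant_force_trace(
    model: KineticModel,
    protocol: ProtocolParams,
    concentration: float = 0.0,
    *,
    bead_id: str = "bead0",
    replicate: int = 0,
    rng=None,
    force_scale: float = 1.0,
    ligand: Ligand | None = None,
) -> tuple[Trace, list[DwellSegment], np.ndarray]:
    """Simulate a constant-force recording at ``protocol.hold_force``.

    Dwells are sampled exactly (exponential waiting times); the trace is then
    emitted at the sampling rate with Gaussian noise.  Returns the trace, the
    ground-truth dwell list (first and last flagged censored) and the
    per-sample boolean unfolded array.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    rng = _as_rng(rng if rng is not None else protocol.seed)
    fs = protocol.sample_rate
    dt = 1.0 / fs
    F = protocol.hold_force
    f_true = force_scale * F
    T = protocol.hold_duration

    k_pre = float(model.k_unfold(f_true, concentration))
    k_pk = float(model.k_unfold_pk(f_true))
    k_f = float(model.k_refold(f_true, concentration))
    inducer = model.ligand_mode == "pseudoknot_inducer"
    for name, k in (("unfolding", k_pre), ("refolding", k_f)) + (
        (("pseudoknot unfolding", k_pk),) if inducer else ()
    ):
        if k * dt > 0.5:
            raise ResolutionError(
                f"{name} rate {k:.3g}/s unresolvable at dt = {dt:.4g} s "
                f"(k*dt = {k * dt:.2f} > 0.5); increase sample_rate."
            )
    p_enter_pk = model.pk_probability(concentration)

    starts: list[float] = []
    durations: list[float] = []
    states: list[bool] = []  # True = unfolded
    t_cum = 0.0
    unfolded_now = False
    in_pk = inducer and rng.random() < p_enter_pk
    while t_cum < T:
        if unfolded_now:
            rate = k_f
        else:
            rate = k_pk if (inducer and in_pk) else k_pre
        dwell = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        dwell = min(dwell, T - t_cum)
        starts.append(t_cum)
        durations.append(dwell)
        states.append(unfolded_now)
        t_cum += dwell
        unfolded_now = not unfolded_now
        if not unfolded_now:
            in_pk = inducer and rng.random() < p_enter_pk

    dwells = [
        DwellSegment(
            "unfolded" if s else "folded",
            start,
            dur,
            censored=(i == 0 or i == len(starts) - 1),
        )
        for i, (s, start, dur) in enumerate(zip(states, starts, durations))
    ]

    n = int(round(T * fs))
    t = np.arange(n) * dt
    ends = np.cumsum(durations)
    idx = np.minimum(np.searchsorted(ends, t, side="right"), len(states) - 1)
    unfolded = np.asarray(states, dtype=bool)[idx]

    extension = model.baseline(F) + model.delta_L * unfolded
    extension = extension + rng.normal(0.0, protocol.noise_sd, n)
    cond = ConditionLabel(
        ligand if ligand is not None else _infer_ligand(model, concentration),
        concentration,
        replicate,
    )
    trace = Trace(bead_id, cond, t, extension, np.full(n, F), fs)
    return trace, dwells, unfolded


def simulate_titration(
    model: str,
    true_params: dict[str, float],
    concentrations: Sequence[float],
    noise_cv: float = 0.0,
    n_replicates: int = 1,
    rng=None,
) -> pd.DataFrame:
    """Draw a (concentration, signal) table from a named dose-response curve.

    ``model`` is one of ``mfs_saturation``, ``one_site_total``,
    ``termination``; noise is multiplicative Gaussian with coefficient of
    variation ``noise_cv``.
    """
    if model not in _dr.CURVES:
        raise ValueError(f"unknown titration model {model!r}")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    x = np.asarray(concentrations, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentrations must be >= 0")
    rng = _as_rng(rng)
    y0 = _dr.CURVES[model](x, **true_params)
    rows = []
    for rep in range(n_replicates):
        y = y0 * (1.0 + noise_cv * rng.standard_normal(x.size))
        rows.append(
            pd.DataFrame({"concentration_molar": x, "signal": y, "replicate": rep})
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Cohorts: many beads x many concentrations, with per-molecule heterogeneity


def _cohort_beads(n_beads: int, rng: np.random.Generator, delta_L_sd_range=(12.0, 22.0)):
    lo, hi = delta_L_sd_range
    for b in range(n_beads):
        yield (
            f"bead{b:03d}",
            float(rng.uniform(lo, hi)),  # per-molecule unfolding size
            float(np.clip(rng.normal(1.0, 0.05), 0.85, 1.15)),  # force calibration
        )


def simulate_ramp_cohort(
    model: KineticModel,
    protocol: ProtocolParams,
    concentrations: Sequence[float],
    n_beads: int,
    rng=None,
) -> tuple[list[Trace], dict[tuple[str, float], list[FoldingEvent]]]:
    """Ramp traces for ``n_beads`` molecules at each concentration.

    Each molecule gets its own unfolding size (uniform over 12-22 nm) and a
    5%-scale force-calibration factor, shared across its concentrations so
    that per-bead control normalization is meaningful.  Concentration 0 is
    labelled the control condition.
    """
    rng = _as_rng(rng)
    traces: list[Trace] = []
    truth: dict[tuple[str, float], list[FoldingEvent]] = {}
    for bead_id, dL, fscale in _cohort_beads(n_beads, rng):
        bead_model = KineticModel(
            **{**model.__dict__, "delta_L": dL},
        )
        for c in concentrations:
            tr, ev = simulate_ramp_trace(
                bead_model,
                protocol,
                float(c),
                bead_id=bead_id,
                rng=rng,
                force_scale=fscale,
            )
            traces.append(tr)
            truth[(bead_id, float(c))] = ev
    return traces, truth


def simulate_constant_force_cohort(
    model: KineticModel,
    protocol: ProtocolParams,
    concentrations: Sequence[float],
    n_beads: int,
    rng=None,
) -> tuple[list[Trace], dict[tuple[str, float], list[DwellSegment]]]:
    """Constant-force traces for ``n_beads`` molecules at each concentration."""
    rng = _as_rng(rng)
    traces: list[Trace] = []
    truth: dict[tuple[str, float], list[DwellSegment]] = {}
    for bead_id, dL, fscale in _cohort_beads(n_beads, rng):
        bead_model = KineticModel(**{**model.__dict__, "delta_L": dL})
        for c in concentrations:
            tr, dwells, _ = simulate_constant_force_trace(
                bead_model,
                protocol,
                float(c),
                bead_id=bead_id,
                rng=rng,
                force_scale=fscale,
            )
            traces.append(tr)
            truth[(bead_id, float(c))] = dwells
    return traces, truth
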