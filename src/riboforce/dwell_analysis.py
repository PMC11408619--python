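"""Constant-force pipeline: state assignment, dwell times, mixture kinetics.

At constant force a tethered two-state molecule hops between a folded
(short-extension) and an unfolded (long-extension) level.  This module

- screens out traces whose extension excursions exceed what the structure
  can produce, or that never hop (:func:`exclude_noisy`);
- assigns a folded/unfolded state to every sample with a fixed-level
  two-state Viterbi decoder — emission levels from the two dominant modes
  of the extension histogram, Gaussian emissions with a shared width, and a
  small symmetric switching prior (:func:`assign_states`);
- run-length-encodes the state path into dwell segments, flagging the
  recording-edge dwells as censored (:func:`extract_dwells`);
- fits exponential mixtures (1-3 components) to dwell durations by EM with
  multistart, selecting the order by BIC (:func:`fit_exp_mixture`) — a
  single lifetime describes the control and kinetic-stabilizer conditions,
  while a pseudoknot-inducing ligand adds a long-lifetime component whose
  weight is the pseudoknot occupancy;
- aggregates log-rates across molecules after per-bead control
  normalization (:func:`aggregate_rates`), the Bell/Kramers-motivated scale
  on which bead-to-bead force-calibration error is additive and cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .dose_response import fit_saturation
from .trace_model import DwellSegment, ExpMixtureFit, Trace

__all__ = [
    "NoiseVerdict",
    "StatePath",
    "StateAssignmentError",
    "ExpMixtureSelection",
    "exclude_noisy",
    "assign_states",
    "extract_dwells",
    "dwell_table",
    "fit_exp_mixture",
    "aggregate_rates",
    "summarize_rates",
    "occupancy_vs_concentration",
]


class StateAssignmentError(ValueError):
    """The extension histogram does not resolve two states."""


@dataclass(frozen=True)
class NoiseVerdict:
    passed: bool
    reasons: tuple[str, ...]
    max_window_range: float


def exclude_noisy(
    trace: Trace,
    expected_structure_length: float,
    window_s: float = 1.0,
    check_folding: bool = True,
) -> NoiseVerdict:
    """Screen a constant-force trace for artifacts and dead molecules.

    Fails when the peak-to-peak extension range inside any sliding window
    exceeds twice the expected structure length (tracking artifacts, bead
    collisions), when the trace never transitions, or — for pseudoknot-
    inducer conditions — when the molecule never visits the folded level.

    The range is evaluated on a 5-sample median-filtered copy so that it
    responds to genuine excursions lasting a few samples, not to the extreme
    tails of per-sample Gaussian tracking noise.
    """
    if expected_structure_length <= 0:
        raise ValueError("expected_structure_length must be > 0")
    w = int(round(window_s * trace.sample_rate))
    if w > len(trace):
        raise ValueError("window longer than trace")
    z = signal.medfilt(trace.extension, 5) if len(trace) >= 5 else trace.extension
    zmax = ndimage.maximum_filter1d(z, size=w, mode="nearest")
    zmin = ndimage.minimum_filter1d(z, size=w, mode="nearest")
    max_range = float(np.max(zmax - zmin))
    reasons: list[str] = []
    if max_range > 2.0 * expected_structure_length:
        reasons.append("window-range-exceeds-2x-structure")
    # core width sees frequent hopping; the extreme width also catches a
    # level that is visited only rarely (a molecule that almost never folds)
    core_lo, core_hi = np.percentile(z, [2.5, 97.5])
    ext_lo, ext_hi = np.percentile(z, [0.1, 99.9])
    L = expected_structure_length
    if core_hi - core_lo >= 0.5 * L:
        pass  # both levels well populated
    elif ext_hi - ext_lo >= 0.75 * L:
        if check_folding:
            mid = 0.5 * (ext_lo + ext_hi)
            below = float(np.mean(z < mid))
            if below < 0.005:
                reasons.append("never-folds")
            elif below > 0.995:
                reasons.append("never-unfolds")
    else:
        reasons.append("no-transitions")
    return NoiseVerdict(passed=not reasons, reasons=tuple(reasons), max_window_range=max_range)


@dataclass
class StatePath:
    """Per-sample folded/unfolded assignment with the fitted emission levels."""

    states: np.ndarray  # int8: 0 = folded (lower level), 1 = unfolded
    level_folded: float
    level_unfolded: float
    emission_sd: float
    sample_rate: float
    method: str = "fixed-level-viterbi"

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if not self.level_unfolded > self.level_folded:
            raise ValueError("unfolded level must exceed folded level")


def _histogram_modes(z: np.ndarray, min_level_sep: float) -> list[float]:
    """Locate modes of the extension distribution via a smoothed histogram."""
    n_bins = max(50, min(400, z.size // 20))
    hist, edges = np.histogram(z, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    binw = edges[1] - edges[0]
    sd = np.std(z, ddof=1)
    bw = max(1.06 * sd * z.size ** (-1 / 5), binw)  # Silverman, floored at a bin
    smooth = ndimage.gaussian_filter1d(hist.astype(float), sigma=bw / binw)
    # zero-pad so modes at the histogram edges are found too
    pad = max(3, int(np.ceil(3 * bw / binw)))
    padded = np.concatenate([np.zeros(pad), smooth, np.zeros(pad)])
    dist = max(1, int(round(min_level_sep / binw)))
    peaks, props = signal.find_peaks(padded, distance=dist, height=0.01 * smooth.max())
    peaks = peaks - pad
    order = np.argsort(props["peak_heights"])[::-1]
    out = []
    for p in peaks[order]:
        p = min(max(int(p), 0), centers.size - 1)
        out.append(float(centers[p]))
    return out


def assign_states(
    trace: Trace,
    switch_prob: float = 0.01,
    min_level_sep: float = 5.0,
    min_run: int = 2,
) -> StatePath:
    """Two-state Viterbi decoding of a constant-force extension trace.

    The two dominant histogram modes (separated by at least
    ``min_level_sep`` nm) fix the emission levels; a shared Gaussian width
    is estimated robustly from the residuals to the nearer level.  The
    symmetric switching prior (default 0.01 per sample) penalizes spurious
    flips; surviving runs shorter than ``min_run`` samples (events faster
    than the camera can resolve) are merged into their neighbors.
    """
    z = trace.extension
    modes = _histogram_modes(z, min_level_sep)
    levels = None
    for i in range(1, len(modes)):
        if abs(modes[i] - modes[0]) >= min_level_sep:
            levels = sorted([modes[0], modes[i]])
            break
    if levels is None:
        raise StateAssignmentError("no two-state structure resolved in extension histogram")
    lo, hi = levels

    nearest = np.where(np.abs(z - lo) <= np.abs(z - hi), lo, hi)
    resid = z - nearest
    sd = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    sd = max(sd, 1e-6)

    # log emission likelihoods per state
    ll = np.empty((z.size, 2))
    ll[:, 0] = -0.5 * ((z - lo) / sd) ** 2
    ll[:, 1] = -0.5 * ((z - hi) / sd) ** 2
    log_stay = np.log1p(-switch_prob)
    log_switch = np.log(switch_prob)

    # Viterbi
    n = z.size
    back = np.empty((n, 2), dtype=np.int8)
    score = ll[0].copy()
    for i in range(1, n):
        stay = score + log_stay
        switch = score[::-1] + log_switch
        better_stay = stay >= switch
        back[i] = np.where(better_stay, [0, 1], [1, 0])
        score = np.where(better_stay, stay, switch) + ll[i]
    states = np.empty(n, dtype=np.int8)
    states[-1] = int(np.argmax(score))
    for i in range(n - 1, 0, -1):
        states[i - 1] = back[i, states[i]]

    states = _merge_short_runs(states, min_run)
    return StatePath(states, lo, hi, sd, trace.sample_rate)


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """(start, length, state) for each maximal run."""
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [states.size]])
    return [(int(s), int(e - s), int(states[s])) for s, e in zip(starts, ends)]


def _merge_short_runs(states: np.ndarray, min_run: int) -> np.ndarray:
    states = states.copy()
    while True:
        runs = _runs(states)
        if len(runs) <= 1:
            return states
        short = [r for r in runs if r[1] < min_run]
        if not short:
            return states
        s, ln, st = min(short, key=lambda r: r[1])
        states[s : s + ln] = 1 - st  # absorb into neighbours


def extract_dwells(path: StatePath, sample_rate: float | None = None) -> list[DwellSegment]:
    """Run-length encode a state path into dwell segments.

    Durations are run length over the sampling rate; the first and last
    segments are censored (their true start/end lies outside the record).
    """
    fs = sample_rate if sample_rate is not None else path.sample_rate
    runs = _runs(path.states)
    out = []
    for i, (start, length, st) in enumerate(runs):
        out.append(
            DwellSegment(
                state="unfolded" if st else "folded",
                start=start / fs,
                duration=length / fs,
                censored=(i == 0 or i == len(runs) - 1),
            )
        )
    return out


def dwell_table(dwells_by_trace: dict[tuple[str, str, float], list[DwellSegment]]) -> pd.DataFrame:
    """Long-form dwell table keyed by (bead_id, ligand, concentration)."""
    rows = []
    for (bead, lig, conc), dwells in dwells_by_trace.items():
        for d in dwells:
            rows.append(
                {
                    "bead_id": bead,
                    "ligand": lig,
                    "concentration": conc,
                    "state": d.state.value,
                    "start": d.start,
                    "duration": d.duration,
                    "censored": d.censored,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Exponential mixtures


@dataclass
class ExpMixtureSelection:
    """Fits at each candidate order plus the BIC-selected best."""

    fits: dict[int, ExpMixtureFit]
    best: ExpMixtureFit


def _em_exponential(
    t: np.ndarray,
    k: int,
    n_restarts: int,
    rng: np.random.Generator,
    max_iter: int = 300,
    tol: float = 1e-8,
):
    """EM for a k-component exponential mixture, all restarts in parallel.

    Returns (taus, weights, loglik, converged) of the best restart.  The
    relative log-likelihood tolerance of 1e-8 resolves BIC differences
    (which are O(1)) with orders of magnitude to spare.
    """
    n = t.size
    R = n_restarts
    q = np.sort(rng.uniform(0.05, 0.95, size=(R, k)), axis=1)
    taus = np.quantile(t, q) * rng.uniform(0.5, 2.0, size=(R, k))
    taus = np.clip(taus, 1e-12, None)
    w = np.full((R, k), 1.0 / k)
    ll_prev = np.full(R, -np.inf)
    converged = np.zeros(R, dtype=bool)
    ll = ll_prev
    for _ in range(max_iter):
        log_comp = (
            np.log(w)[:, None, :]
            - np.log(taus)[:, None, :]
            - t[None, :, None] / taus[:, None, :]
        )  # (R, n, k)
        m = log_comp.max(axis=2)
        norm = m + np.log(np.exp(log_comp - m[:, :, None]).sum(axis=2))
        ll = norm.sum(axis=1)  # (R,)
        r = np.exp(log_comp - norm[:, :, None])
        nk = np.clip(r.sum(axis=1), 1e-12, None)  # (R, k)
        w = nk / nk.sum(axis=1, keepdims=True)
        taus = np.clip((r * t[None, :, None]).sum(axis=1) / nk, 1e-12, None)
        converged |= np.abs(ll - ll_prev) < tol * (1.0 + np.abs(ll))
        if converged.all():
            break
        ll_prev = ll
    best = int(np.argmax(ll))
    return taus[best], w[best], float(ll[best]), bool(converged[best])


def fit_exp_mixture(
    durations,
    k_max: int = 3,
    n_restarts: int = 20,
    rng=None,
) -> ExpMixtureSelection:
    """MLE exponential-mixture fits of dwell durations for k = 1..k_max.

    k = 1 is the closed form (lifetime = sample mean); k >= 2 uses EM with
    ``n_restarts`` seeded multistarts.  BIC = -2 loglik + (2k - 1) ln n
    selects the best order (k lifetimes plus k - 1 free weights).
    """
    t = np.asarray(durations, dtype=float)
    t = t[np.isfinite(t) & (t > 0)]
    n = t.size
    if n < 10:
        raise ValueError(f"need >= 10 dwells to fit a lifetime mixture (got {n})")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    fits: dict[int, ExpMixtureFit] = {}
    tau1 = float(np.mean(t))
    ll1 = float(-n * (np.log(tau1) + 1.0))
    fits[1] = ExpMixtureFit(1, (tau1,), (1.0,), ll1, -2 * ll1 + 1 * np.log(n), n)

    for k in range(2, k_max + 1):
        taus, w, ll, conv = _em_exponential(t, k, n_restarts, gen)
        if not conv:
            warnings.warn(f"EM for k={k} did not converge; best found reported")
        order = np.argsort(taus)
        taus, w = taus[order], w[order]
        w = w / w.sum()
        bic = -2 * ll + (2 * k - 1) * np.log(n)
        fits[k] = ExpMixtureFit(
            k, tuple(map(float, taus)), tuple(map(float, w)), float(ll), float(bic), n, conv
        )

    best_fit = min(fits.values(), key=lambda f: f.bic)
    return ExpMixtureSelection(fits=fits, best=best_fit)


# ---------------------------------------------------------------------------
# Aggregation across molecules


def aggregate_rates(
    dwells_df: pd.DataFrame,
    control_ligand: str = "control",
    mixture_ligands: tuple[str, ...] = ("preq1",),
    k_max: int = 2,
    rng=None,
) -> pd.DataFrame:
    """Per-bead/condition log-rates, normalized to the same bead's control.

    Folded-state unfolding rate is log(1 / mean uncensored folded lifetime);
    for pseudoknot-inducer conditions the BIC-selected mixture replaces the
    pooled mean — the short component is reported as the (pre-pseudoknot)
    unfolding rate, the long component separately, and its weight as the
    pseudoknot occupancy.  ``norm_log_*`` columns subtract the same bead's
    control value; beads lacking a control are dropped with a warning.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    d = dwells_df[~dwells_df["censored"]]
    rows = []
    for (bead, lig, conc), g in d.groupby(["bead_id", "ligand", "concentration"]):
        folded = g.loc[g["state"] == "folded", "duration"].to_numpy()
        unfolded = g.loc[g["state"] == "unfolded", "duration"].to_numpy()
        row = {
            "bead_id": bead,
            "ligand": lig,
            "concentration": conc,
            "log_unfold_rate": np.nan,
            "log_unfold_rate_long": np.nan,
            "log_refold_rate": np.nan,
            "long_component_weight": 0.0,
            "n_folded_dwells": folded.size,
            "n_unfolded_dwells": unfolded.size,
        }
        if lig in mixture_ligands and folded.size >= 10:
            sel = fit_exp_mixture(folded, k_max=k_max, rng=gen)
            f = sel.best
            row["log_unfold_rate"] = -np.log(f.lifetimes[0])
            if f.n_components >= 2:
                row["log_unfold_rate_long"] = -np.log(f.lifetimes[-1])
                row["long_component_weight"] = float(f.weights[-1])
        elif folded.size:
            row["log_unfold_rate"] = -np.log(np.mean(folded))
        if unfolded.size:
            row["log_refold_rate"] = -np.log(np.mean(unfolded))
        rows.append(row)
    out = pd.DataFrame(rows)

    ctrl = (
        out[out["ligand"] == control_ligand]
        .set_index("bead_id")[["log_unfold_rate", "log_refold_rate"]]
        .rename(columns=lambda c: c + "_ctrl")
    )
    missing = set(out["bead_id"]) - set(ctrl.index)
    if missing:
        warnings.warn(f"{len(missing)} bead(s) without control dropped from aggregation")
        out = out[~out["bead_id"].isin(missing)]
    out = out.join(ctrl, on="bead_id")
    out["norm_log_unfold_rate"] = out["log_unfold_rate"] - out["log_unfold_rate_ctrl"]
    out["norm_log_refold_rate"] = out["log_refold_rate"] - out["log_refold_rate_ctrl"]
    return out.drop(columns=["log_unfold_rate_ctrl", "log_refold_rate_ctrl"])


def summarize_rates(rates_df: pd.DataFrame) -> pd.DataFrame:
    """Across-bead mean and SD of the normalized log-rates per condition."""
    return (
        rates_df.groupby(["ligand", "concentration"])
        .agg(
            norm_log_unfold_mean=("norm_log_unfold_rate", "mean"),
            norm_log_unfold_sd=("norm_log_unfold_rate", "std"),
            norm_log_refold_mean=("norm_log_refold_rate", "mean"),
            norm_log_refold_sd=("norm_log_refold_rate", "std"),
            long_weight_mean=("long_component_weight", "mean"),
            n_beads=("bead_id", "nunique"),
        )
        .reset_index()
    )


def occupancy_vs_concentration(
    fits_by_concentration: dict[float, ExpMixtureSelection],
    fit: bool = True,
):
    """Long-lifetime (pseudoknot) component weight per concentration.

    Takes BIC-selected mixture fits of folded dwells, one per concentration.
    "Long" is judged against the zero-concentration (control) lifetime: any
    component with lifetime > 3x the control lifetime counts as pseudoknot.
    A single-exponential best fit therefore contributes weight 0 when its
    lifetime matches the control and weight 1 when the pseudoknot dominates
    so completely that only the long lifetime remains (saturating ligand).
    Optionally fits the hyperbolic saturation model to the weights.
    Returns (table, DoseResponseFit or None).
    """
    concs = sorted(fits_by_concentration)
    tau_ref = fits_by_concentration[concs[0]].best.lifetimes[0]
    rows = []
    for conc in concs:
        best = fits_by_concentration[conc].best
        w = float(
            sum(wi for ti, wi in zip(best.lifetimes, best.weights) if ti > 3 * tau_ref)
        )
        rows.append({"concentration": conc, "long_component_weight": w, "n_dwells": best.n_dwells})
    table = pd.DataFrame(rows)
    sat = None
    if fit and (table["long_component_weight"] > 0).any() and len(table) >= 4:
        try:
            sat = fit_saturation(
                table["concentration"].to_numpy(),
                table["long_component_weight"].to_numpy(),
            )
        except ValueError:
            sat = None
    if not (table["long_component_weight"] > 0).any():
        warnings.warn("single-exponential selected at every concentration; no pseudoknot component")
    return table, sat
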