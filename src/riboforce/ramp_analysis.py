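"""Force-ramp pipeline: QC, cycle segmentation, jump detection, selection,
normalization, high-force statistics and the concentration-response fit.

The analysis mirrors how rupture-force data from a magnetic force
spectroscopy ramp experiment is reduced:

1.  Beads whose positional noise is inconsistent with tethered Brownian
    motion are excluded (:func:`qc_brownian`).
2.  The repeated up/down force protocol is cut into cycles
    (:func:`segment_cycles`) and each ramp phase is scanned for abrupt
    extension jumps (:func:`detect_events`) — by density clustering of the
    force-extension points (the production method) or by an exhaustive
    least-squares changepoint search (an independent oracle used for
    validation).
3.  Per-bead statistics (:func:`structure_stats`) feed the selection filter
    (:func:`select_structures`): analyzable structures unfold at 5-15 pN
    with a 10-25 nm step under control conditions, show > 20 analyzable
    cycles with an unfolding event in > 80% of them, and appear in more than
    half of the conditions.
4.  Forces are normalized per bead by the control medians
    (:func:`normalize_forces`), which cancels bead-to-bead force-calibration
    differences; dose responses are then read off either as the shift of the
    modal rupture force (kinetic stabilizers) or as the fraction of cycles
    above the control 95th percentile or with no unfolding at all
    (pseudoknot inducers, :func:`high_force_fraction`), and fitted with
    :func:`fit_saturation`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.cluster import HDBSCAN

from .dose_response import fit_saturation  # re-exported: pipeline fit lives here
from .synthetic_data import KBT_22C
from .trace_model import EventDirection, FoldingEvent, RampCycle, Trace

__all__ = [
    "SelectionCriteria",
    "StructureStats",
    "QCResult",
    "qc_brownian",
    "segment_cycles",
    "detect_events",
    "detect_phase_events",
    "cycle_table",
    "structure_stats",
    "select_structures",
    "normalize_forces",
    "high_force_fraction",
    "peak_median",
    "fit_saturation",
    "analyze_ramp_cohort",
    "ramp_dose_response",
]


@dataclass(frozen=True)
class SelectionCriteria:
    """Filter defining an analyzable structure (control-condition windows)."""

    unfold_force_window: tuple[float, float] = (5.0, 15.0)
    unfold_size_window: tuple[float, float] = (10.0, 25.0)
    min_cycles: int = 21  # "more than 20" analyzable cycles
    min_unfold_fraction: float = 0.8  # strict >
    min_condition_presence: float = 0.5  # strict >

    def __post_init__(self) -> None:
        for w in (self.unfold_force_window, self.unfold_size_window):
            if not w[0] < w[1]:
                raise ValueError("selection windows must be non-empty")
        for f in (self.min_unfold_fraction, self.min_condition_presence):
            if not 0 < f <= 1:
                raise ValueError("fractions must be in (0, 1]")


@dataclass
class StructureStats:
    """Per-bead, per-condition ramp summary."""

    bead_id: str
    ligand: str
    concentration: float
    n_cycles_analyzable: int
    n_cycles_with_unfold: int
    median_unfold_force: float
    median_unfold_size: float
    median_refold_force: float
    fraction_high_force: float = np.nan
    selected: bool = False

    def __post_init__(self) -> None:
        if self.n_cycles_with_unfold > self.n_cycles_analyzable:
            raise ValueError("n_cycles_with_unfold > n_cycles_analyzable")


@dataclass(frozen=True)
class QCResult:
    passed: bool
    variance_ratios: np.ndarray
    n_windows: int


def qc_brownian(
    trace: Trace,
    tolerance_factor: float = 2.0,
    window_s: float = 1.0,
    high_force_fraction_of_range: float = 0.8,
    kBT: float = KBT_22C,
) -> QCResult:
    """Check that positional noise matches tethered Brownian motion.

    In high-force quiescent windows the extension variance of a tethered
    bead is ~ kBT * L / F (L = tether extension, F = applied force).  Each
    window is linearly detrended and its variance compared to that
    expectation; the trace passes if the ratio lies inside
    [1/tolerance_factor, tolerance_factor] in a majority of windows.
    """
    if tolerance_factor < 1:
        raise ValueError("tolerance_factor must be >= 1")
    w = int(round(window_s * trace.sample_rate))
    if w < 4 or len(trace) < w:
        raise ValueError("trace shorter than one QC window")
    f = trace.force
    f_thresh = f.min() + high_force_fraction_of_range * (f.max() - f.min())
    mask = f >= f_thresh
    ratios = []
    # contiguous high-force runs, tiled into windows
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    for lo, hi in edges.reshape(-1, 2):
        for s in range(lo, hi - w + 1, w):
            seg = trace.extension[s : s + w]
            tt = np.arange(w, dtype=float)
            resid = seg - np.polyval(np.polyfit(tt, seg, 1), tt)
            var_obs = float(np.var(resid, ddof=2))
            L = float(np.median(seg))
            F = float(np.median(f[s : s + w]))
            var_exp = kBT * max(L, 1e-9) / max(F, 1e-9)
            ratios.append(var_obs / var_exp)
    ratios = np.asarray(ratios)
    if ratios.size == 0:
        raise ValueError("no high-force windows available for QC")
    ok = (ratios >= 1.0 / tolerance_factor) & (ratios <= tolerance_factor)
    return QCResult(passed=bool(np.mean(ok) > 0.5), variance_ratios=ratios, n_windows=ratios.size)


def segment_cycles(trace: Trace, smooth_s: float = 1.0) -> list[RampCycle]:
    """Cut a repeated up/down force ramp into cycles.

    Cycle boundaries are the minima of the median-filtered force; the peak
    inside each minimum-to-minimum span splits it into up and down phases.
    Incomplete trailing half-cycles are dropped with a warning.
    """
    f = trace.force
    n = f.size
    k = int(round(smooth_s * trace.sample_rate))
    k = max(3, k | 1)  # odd
    fm = signal.medfilt(f, kernel_size=min(k, (n - 1) | 1)) if n > 3 else f
    f_lo, f_hi = fm.min(), fm.max()
    rng = f_hi - f_lo
    if rng <= 0:
        warnings.warn("force profile is flat; no ramp cycles found")
        return []
    prom = 0.4 * rng
    minima, _ = signal.find_peaks(-fm, prominence=prom)

    def refine(idx: int, to_min: bool) -> int:
        # the median filter shifts extrema by up to half a kernel; snap to
        # the raw-force extremum nearby
        lo = max(0, idx - k)
        hi = min(n, idx + k + 1)
        local = np.argmin(f[lo:hi]) if to_min else np.argmax(f[lo:hi])
        return lo + int(local)

    # the profile typically starts and ends at low force: count the ends
    # as boundaries when they sit in the bottom quarter of the range
    bounds = [refine(m, to_min=True) for m in minima]
    if fm[0] < f_lo + 0.25 * rng:
        bounds.insert(0, 0)
    if fm[-1] < f_lo + 0.25 * rng:
        bounds.append(n - 1)
    bounds = sorted(set(bounds))
    cycles: list[RampCycle] = []
    dropped = 0
    for i, (m0, m1) in enumerate(zip(bounds[:-1], bounds[1:])):
        span = fm[m0 : m1 + 1]
        p = refine(m0 + int(np.argmax(span)), to_min=False)
        p = min(max(p, m0), m1)
        if span.max() < f_lo + 0.75 * rng or p == m0 or p == m1:
            dropped += 1
            continue
        cycles.append(
            RampCycle(
                cycle_index=len(cycles),
                up_slice=slice(m0, p + 1),
                down_slice=slice(p + 1, m1 + 1),
                f_min=float(min(fm[m0], fm[m1])),
                f_max=float(fm[p]),
            )
        )
    if bounds and bounds[-1] < n - 1 - k:
        dropped += 1  # trailing samples after the last complete cycle
    if not cycles:
        warnings.warn("fewer than one complete ramp; no cycles segmented")
    elif dropped:
        warnings.warn(f"{dropped} incomplete ramp span(s) dropped")
    return cycles


# ---------------------------------------------------------------------------
# Event detection


def _linfit(F: np.ndarray, z: np.ndarray) -> tuple[float, float]:
    """Least-squares z = a + b*F; degenerate force spans fall back to mean."""
    if F.size < 2 or np.ptp(F) < 1e-12:
        return float(np.mean(z)), 0.0
    b, a = np.polyfit(F, z, 1)
    return float(a), float(b)


def _cluster_phase(
    F: np.ndarray,
    z: np.ndarray,
    min_cluster_size: int,
) -> np.ndarray:
    X = np.column_stack([F, z])
    return HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(X)


def _label_split(labels: np.ndarray, a: int, b: int) -> int | None:
    """Best single time-axis split of two interleaved cluster labels.

    Position (into the phase) minimizing the number of a-labelled samples on
    one side plus b-labelled on the other, over both orientations; None when
    the clusters do not separate in time at all.
    """
    idx = np.flatnonzero((labels == a) | (labels == b))
    if idx.size < 2:
        return None
    is_b = (labels[idx] == b).astype(int)
    n = is_b.size
    b_before = np.concatenate([[0], np.cumsum(is_b)])  # b's in [0, s)
    s_range = np.arange(n + 1)
    total_b = b_before[-1]
    cost_ab = b_before + ((n - s_range) - (total_b - b_before))
    cost_ba = (s_range - b_before) + (total_b - b_before)
    if cost_ab.min() <= cost_ba.min():
        s = int(np.argmin(cost_ab))
    else:
        s = int(np.argmin(cost_ba))
    if s == 0 or s == n:
        return None
    return int(idx[s])  # first sample of the later block


def _events_from_clusters(
    F: np.ndarray,
    z: np.ndarray,
    t: np.ndarray,
    labels: np.ndarray,
    min_jump_nm: float,
) -> list[tuple[float, float, float]]:
    """(force, size, time) for each adjacent-cluster boundary jump.

    Clusters are ordered by force; for each adjacent pair the event sample
    is the best time-axis split between the two memberships, the event force
    is the force there, and the size is the offset between the two clusters'
    linear force-extension trends evaluated at that force.
    """
    ids = [l for l in np.unique(labels) if l >= 0]
    if len(ids) < 2:
        return []
    ids.sort(key=lambda l: float(np.median(F[labels == l])))
    out = []
    for lo_id, hi_id in zip(ids[:-1], ids[1:]):
        k = _label_split(labels, lo_id, hi_id)
        if k is None:
            continue
        fb = float(F[k])
        a_lo, b_lo = _linfit(F[labels == lo_id], z[labels == lo_id])
        a_hi, b_hi = _linfit(F[labels == hi_id], z[labels == hi_id])
        offset = (a_hi + b_hi * fb) - (a_lo + b_lo * fb)
        if offset >= min_jump_nm:
            out.append((fb, float(offset), float(t[k])))
    return out


def _seg_linear_sse(c1, cF, cz, cFF, cFz, czz, lo, hi):
    """SSE of a per-segment linear fit z~F on [lo, hi) from prefix sums."""
    n = c1[hi] - c1[lo]
    if n < 2:
        return 0.0
    sF = cF[hi] - cF[lo]
    sz = cz[hi] - cz[lo]
    sFF = cFF[hi] - cFF[lo]
    sFz = cFz[hi] - cFz[lo]
    szz = czz[hi] - czz[lo]
    Sff = sFF - sF * sF / n
    Sfz = sFz - sF * sz / n
    Szz = szz - sz * sz / n
    if Sff <= 1e-12:
        return max(Szz, 0.0)
    return max(Szz - Sfz * Sfz / Sff, 0.0)


def _changepoint_phase(
    F: np.ndarray,
    z: np.ndarray,
    t: np.ndarray,
    min_jump_nm: float,
    min_seg: int = 10,
    max_changepoints: int = 4,
    single: bool = False,
) -> list[tuple[float, float, float]]:
    """Greedy exhaustive least-squares changepoint search with a BIC stop.

    Each segment carries its own linear force-extension trend; at every
    stage the single split that most reduces the residual sum of squares is
    found exhaustively and accepted while the BIC improves.  With ``single``
    the best single split of the whole phase is reported instead — the
    dominant transition, matching what one boundary between two density
    clusters expresses.
    """
    n = F.size
    if n < 2 * min_seg:
        return []
    c1 = np.arange(n + 1, dtype=float)
    cF = np.concatenate([[0], np.cumsum(F)])
    cz = np.concatenate([[0], np.cumsum(z)])
    cFF = np.concatenate([[0], np.cumsum(F * F)])
    cFz = np.concatenate([[0], np.cumsum(F * z)])
    czz = np.concatenate([[0], np.cumsum(z * z)])

    def sse(lo, hi):
        return _seg_linear_sse(c1, cF, cz, cFF, cFz, czz, lo, hi)

    def best_split(lo, hi):
        ks = np.arange(lo + min_seg, hi - min_seg + 1)
        if ks.size == 0:
            return None, np.inf
        vals = np.array([sse(lo, k) + sse(k, hi) for k in ks])
        i = int(np.argmin(vals))
        return int(ks[i]), float(vals[i])

    if single:
        k, v = best_split(0, n)
        if k is None:
            return []
        # the split must still beat the no-split model on BIC
        bic0 = n * np.log(max(sse(0, n), 1e-300) / n) + 2 * np.log(n)
        bic1 = n * np.log(max(v, 1e-300) / n) + 5 * np.log(n)
        if bic1 >= bic0:
            return []
        a_l, b_l = _linfit(F[:k], z[:k])
        a_r, b_r = _linfit(F[k:], z[k:])
        fb = float(F[k])
        jump = (a_r + b_r * fb) - (a_l + b_l * fb)
        if jump >= min_jump_nm:
            return [(fb, float(jump), float(t[k]))]
        return []

    bounds = [0, n]
    total_sse = sse(0, n)

    def bic(sse_val, n_seg):
        # 2 linear params per segment + 1 per changepoint location
        p = 3 * n_seg - 1
        return n * np.log(max(sse_val, 1e-300) / n) + p * np.log(n)

    while len(bounds) - 1 <= max_changepoints:
        candidates = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            k, v = best_split(lo, hi)
            if k is not None:
                candidates.append((v - sse(lo, hi), k))
        if not candidates:
            break
        gain, k = min(candidates)
        new_sse = total_sse + gain
        if bic(new_sse, len(bounds)) >= bic(total_sse, len(bounds) - 1):
            break
        bounds = sorted(bounds + [k])
        total_sse = new_sse

    out = []
    for i in range(1, len(bounds) - 1):
        lo, k, hi = bounds[i - 1], bounds[i], bounds[i + 1]
        a_l, b_l = _linfit(F[lo:k], z[lo:k])
        a_r, b_r = _linfit(F[k:hi], z[k:hi])
        fb = float(F[k])
        jump = (a_r + b_r * fb) - (a_l + b_l * fb)
        if jump >= min_jump_nm:
            out.append((fb, float(jump), float(t[k])))
    return out


def detect_phase_events(
    force: np.ndarray,
    extension: np.ndarray,
    time: np.ndarray,
    direction: str,
    method: str = "cluster",
    min_jump_nm: float = 5.0,
    min_cluster_size: int = 10,
    single: bool = False,
) -> list[tuple[float, float, float]]:
    """Detect extension jumps in one ramp phase; returns (force, size, time).

    For an up phase a jump is an increase of extension with force (unfold);
    a down phase reads the same geometry as a refold.  With ``single`` the
    changepoint method reports only the dominant transition.  An
    unclusterable phase yields an empty list, never an error.
    """
    F = np.asarray(force, dtype=float)
    z = np.asarray(extension, dtype=float)
    t = np.asarray(time, dtype=float)
    if F.size < 30:
        return []
    if method == "cluster":
        labels = _cluster_phase(F, z, min_cluster_size)
        return _events_from_clusters(F, z, t, labels, min_jump_nm)
    if method == "changepoint":
        # in time order a refold (down phase) is a *drop* in extension
        sign = 1.0 if direction == "up" else -1.0
        return _changepoint_phase(
            F, sign * z, t, min_jump_nm, min_seg=min(10, F.size // 3), single=single
        )
    raise ValueError(f"unknown detection method {method!r}")


def detect_events(
    trace: Trace,
    cycles: list[RampCycle] | None = None,
    method: str = "cluster",
    min_jump_nm: float = 5.0,
    min_cluster_size: int = 10,
    multi_event: bool = False,
) -> list[FoldingEvent]:
    """Detect unfolding/refolding jumps in every cycle of a ramp trace.

    By default at most one unfold (up phase) and one refold (down phase) is
    reported per cycle — the largest jump wins; ``multi_event`` reports all
    jumps above the minimum size.
    """
    if cycles is None:
        cycles = segment_cycles(trace)
    events: list[FoldingEvent] = []
    for cyc in cycles:
        for sl, direction, kind in (
            (cyc.up_slice, "up", EventDirection.UNFOLD),
            (cyc.down_slice, "down", EventDirection.REFOLD),
        ):
            found = detect_phase_events(
                trace.force[sl],
                trace.extension[sl],
                trace.time[sl],
                direction,
                method=method,
                min_jump_nm=min_jump_nm,
                min_cluster_size=min_cluster_size,
                single=not multi_event,
            )
            if not found:
                continue
            if not multi_event:
                found = [max(found, key=lambda e: e[1])]
            for fb, size, tb in found:
                events.append(FoldingEvent(kind, fb, size, tb, cyc.cycle_index))
    return events


# ---------------------------------------------------------------------------
# Per-bead statistics, selection, normalization


def cycle_table(
    traces_events: list[tuple[Trace, list[RampCycle], list[FoldingEvent]]],
) -> pd.DataFrame:
    """One row per analyzable cycle: unfold/refold force and size (or NaN)."""
    rows = []
    for trace, cycles, events in traces_events:
        by_cycle: dict[int, dict] = {
            c.cycle_index: {
                "bead_id": trace.bead_id,
                "ligand": trace.condition.ligand.value,
                "concentration": trace.condition.concentration,
                "cycle_index": c.cycle_index,
                "unfold_force": np.nan,
                "unfold_size": np.nan,
                "refold_force": np.nan,
                "refold_size": np.nan,
            }
            for c in cycles
        }
        for ev in events:
            row = by_cycle.get(ev.cycle_index)
            if row is None:
                continue
            if ev.direction is EventDirection.UNFOLD:
                row["unfold_force"], row["unfold_size"] = ev.force, ev.size
            else:
                row["refold_force"], row["refold_size"] = ev.force, ev.size
        rows.extend(by_cycle.values())
    return pd.DataFrame(rows)


def structure_stats(cycles_df: pd.DataFrame) -> pd.DataFrame:
    """Aggregate the cycle table per bead/condition.

    Cycles with no detected events count as analyzable but without an
    unfolding (the structure never opened); medians over cycles with events.
    """
    def agg(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        has_unfold = g["unfold_force"].notna()
        return pd.Series(
            {
                "n_cycles_analyzable": n,
                "n_cycles_with_unfold": int(has_unfold.sum()),
                "unfold_fraction": float(has_unfold.mean()) if n else np.nan,
                "median_unfold_force": float(g["unfold_force"].median()),
                "median_unfold_size": float(g["unfold_size"].median()),
                "median_refold_force": float(g["refold_force"].median()),
            }
        )

    out = (
        cycles_df.groupby(["bead_id", "ligand", "concentration"], sort=True)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    for c in ("n_cycles_analyzable", "n_cycles_with_unfold"):
        out[c] = out[c].astype(int)
    return out


def select_structures(
    stats_df: pd.DataFrame,
    criteria: SelectionCriteria = SelectionCriteria(),
    control_ligand: str = "control",
) -> pd.DataFrame:
    """Apply the analyzable-structure filter; one verdict row per bead.

    All windows are evaluated on the control condition; the presence
    criterion counts in how many of the tested conditions the bead appears.
    """
    ctrl = stats_df[stats_df["ligand"] == control_ligand]
    if ctrl.empty:
        raise ValueError(f"no control condition ({control_ligand!r}) in stats")
    n_conditions = stats_df[["ligand", "concentration"]].drop_duplicates().shape[0]
    rows = []
    for bead, grp in stats_df.groupby("bead_id"):
        c = grp[grp["ligand"] == control_ligand]
        if c.empty:
            rows.append(
                {
                    "bead_id": bead,
                    "force_in_window": False,
                    "size_in_window": False,
                    "enough_cycles": False,
                    "unfold_fraction_ok": False,
                    "condition_presence_ok": False,
                    "selected": False,
                }
            )
            continue
        c = c.iloc[0]
        flo, fhi = criteria.unfold_force_window
        slo, shi = criteria.unfold_size_window
        presence = grp[["ligand", "concentration"]].drop_duplicates().shape[0] / n_conditions
        v = {
            "bead_id": bead,
            "force_in_window": bool(flo <= c["median_unfold_force"] <= fhi),
            "size_in_window": bool(slo <= c["median_unfold_size"] <= shi),
            "enough_cycles": bool(c["n_cycles_analyzable"] > criteria.min_cycles - 1),
            "unfold_fraction_ok": bool(c["unfold_fraction"] > criteria.min_unfold_fraction),
            "condition_presence_ok": bool(presence > criteria.min_condition_presence),
        }
        v["selected"] = all(v[k] for k in list(v)[1:])
        rows.append(v)
    return pd.DataFrame(rows)


def normalize_forces(
    cycles_df: pd.DataFrame,
    stats_df: pd.DataFrame,
    control_ligand: str = "control",
) -> pd.DataFrame:
    """Divide each cycle's forces by that bead's control medians.

    Adds ``norm_unfold_force`` / ``norm_refold_force``; beads without a
    defined control median are dropped with a warning.  Normalization makes
    forces dimensionless and cancels per-bead force-calibration error.
    """
    ctrl = stats_df[stats_df["ligand"] == control_ligand].set_index("bead_id")
    out = cycles_df.copy()
    med_u = out["bead_id"].map(ctrl["median_unfold_force"])
    med_r = out["bead_id"].map(ctrl["median_refold_force"])
    bad = out["bead_id"][med_u.isna() | (med_u <= 0)].unique()
    if bad.size:
        warnings.warn(
            f"{bad.size} bead(s) without a control unfolding median excluded: "
            + ", ".join(map(str, bad[:5]))
        )
        keep = ~out["bead_id"].isin(bad)
        out, med_u, med_r = out[keep], med_u[keep], med_r[keep]
    out = out.assign(
        norm_unfold_force=out["unfold_force"] / med_u,
        norm_refold_force=out["refold_force"] / med_r,
    )
    return out


def high_force_fraction(
    norm_cycles_df: pd.DataFrame,
    control_ligand: str = "control",
    percentile: float = 95.0,
) -> tuple[pd.DataFrame, float]:
    """Fraction of cycles above the control rupture-force threshold.

    The threshold is the given percentile (linear-interpolation convention)
    of the control normalized unfolding forces; cycles that never unfolded
    count as high-force (the structure withstood the full ramp).  Returns a
    per-condition table and the threshold.
    """
    ctrl_forces = norm_cycles_df.loc[
        norm_cycles_df["ligand"] == control_ligand, "norm_unfold_force"
    ].dropna()
    if ctrl_forces.size < 20:
        raise ValueError("control distribution needs >= 20 unfolding events")
    threshold = float(np.percentile(ctrl_forces, percentile))
    rows = []
    for (lig, conc), g in norm_cycles_df.groupby(["ligand", "concentration"]):
        n = len(g)
        if n == 0:
            continue
        over = (g["norm_unfold_force"] > threshold).sum()
        no_unfold = g["norm_unfold_force"].isna().sum()
        rows.append(
            {
                "ligand": lig,
                "concentration": conc,
                "n_cycles": n,
                "fraction_high_force": (over + no_unfold) / n,
            }
        )
    return pd.DataFrame(rows), threshold


def peak_median(values: np.ndarray, bandwidth: float | None = None) -> float:
    """Median of the values under the dominant mode of their distribution.

    A Gaussian KDE (Silverman bandwidth) locates the modal peak; the result
    is the median of the observations within +-1 bandwidth of the peak.
    This reads off "the force at the maximum of the distribution" robustly
    when a second mode is present.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return np.nan
    if v.size < 3 or np.ptp(v) < 1e-12:
        return float(np.median(v))
    sd = np.std(v, ddof=1)
    bw = bandwidth if bandwidth is not None else 1.06 * sd * v.size ** (-1 / 5)
    grid = np.linspace(v.min() - bw, v.max() + bw, 512)
    dens = np.exp(-0.5 * ((grid[:, None] - v[None, :]) / bw) ** 2).sum(axis=1)
    peak = grid[int(np.argmax(dens))]
    window = v[np.abs(v - peak) <= bw]
    return float(np.median(window)) if window.size else float(peak)


# ---------------------------------------------------------------------------
# Cohort pipeline


def analyze_ramp_cohort(
    traces: list[Trace],
    criteria: SelectionCriteria = SelectionCriteria(),
    method: str = "cluster",
    control_ligand: str = "control",
    run_qc: bool = False,
    min_jump_nm: float = 5.0,
) -> dict:
    """Run the full ramp pipeline over a cohort of traces.

    Returns a dict with the cycle table, per-bead stats, selection verdicts,
    the normalized cycle table restricted to selected beads, and the list of
    excluded beads with reasons.
    """
    exclusions: list[dict] = []
    kept: list[tuple[Trace, list, list]] = []
    for tr in traces:
        if run_qc:
            try:
                qc = qc_brownian(tr)
            except ValueError as e:
                exclusions.append({"bead_id": tr.bead_id, "reason": f"qc-error: {e}"})
                continue
            if not qc.passed:
                exclusions.append({"bead_id": tr.bead_id, "reason": "brownian-noise-qc"})
                continue
        cycles = segment_cycles(tr)
        events = detect_events(tr, cycles, method=method, min_jump_nm=min_jump_nm)
        kept.append((tr, cycles, events))
    cycles_df = cycle_table(kept)
    stats_df = structure_stats(cycles_df)
    verdicts = select_structures(stats_df, criteria, control_ligand)
    selected = set(verdicts.loc[verdicts["selected"], "bead_id"])
    for _, row in verdicts[~verdicts["selected"]].iterrows():
        failed = [k for k in row.index if k not in ("bead_id", "selected") and not row[k]]
        exclusions.append({"bead_id": row["bead_id"], "reason": "selection:" + ",".join(failed)})
    sel_cycles = cycles_df[cycles_df["bead_id"].isin(selected)]
    norm_df = (
        normalize_forces(sel_cycles, stats_df, control_ligand)
        if not sel_cycles.empty
        else sel_cycles
    )
    return {
        "cycles": cycles_df,
        "stats": stats_df,
        "verdicts": verdicts,
        "normalized": norm_df,
        "exclusions": exclusions,
    }


def _bead_bootstrap_se(g: pd.DataFrame, col: str, estimator, n_boot: int, rng) -> float:
    """SE of the pooled response under resampling of whole beads.

    Bead-level resampling respects the per-bead normalization structure: the
    control response is pinned near 1 by construction and its bootstrap SE
    is accordingly small.
    """
    beads = g["bead_id"].unique()
    if beads.size < 2:
        return np.nan
    groups = {b: gb[col].dropna().to_numpy() for b, gb in g.groupby("bead_id")}
    stats = []
    for _ in range(n_boot):
        pick = rng.choice(beads, size=beads.size, replace=True)
        pooled = np.concatenate([groups[b] for b in pick])
        if pooled.size:
            stats.append(estimator(pooled))
    return float(np.std(stats, ddof=1)) if len(stats) > 2 else np.nan


def ramp_dose_response(
    norm_cycles_df: pd.DataFrame,
    direction: str = "unfold",
    ligand: str | None = None,
    control_ligand: str = "control",
    estimator: str = "median",
    n_boot: int = 200,
    rng=None,
):
    """Per-concentration normalized force response with a saturation fit.

    For each concentration (control = 0) the response is a location estimate
    of the normalized rupture-force distribution pooled over selected beads:
    the plain ``median`` (default — the efficient choice when the
    distribution is unimodal, as under a kinetic stabilizer) or
    ``peak_median`` (median under the dominant KDE mode, robust when a
    second high-force mode appears).  Per-point SEs from a bead-level
    bootstrap weight the hyperbolic saturation fit, anchoring the
    self-normalized control response.
    """
    col = {"unfold": "norm_unfold_force", "refold": "norm_refold_force"}[direction]
    est = {"median": np.median, "peak_median": peak_median}[estimator]
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    df = norm_cycles_df
    if ligand is not None:
        df = df[df["ligand"].isin([ligand, control_ligand])]
    rows = []
    for conc, g in df.groupby("concentration"):
        vals = g[col].dropna().to_numpy()
        if vals.size:
            rows.append(
                {
                    "concentration": conc,
                    "response": float(est(vals)),
                    "response_se": _bead_bootstrap_se(g, col, est, n_boot, gen),
                    "n_events": vals.size,
                }
            )
    resp = pd.DataFrame(rows).sort_values("concentration")
    se = resp["response_se"].to_numpy()
    sigma = None
    if np.isfinite(se).all() and (se > 0).all():
        sigma = np.clip(se, max(1e-4, 0.1 * np.nanmedian(se)), None)
    fit = fit_saturation(
        resp["concentration"].to_numpy(), resp["response"].to_numpy(), sigma=sigma
    )
    return resp, fit
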