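"""Domain types and file I/O for force-spectroscopy traces and fit results.

The central container is :class:`Trace`: one bead's time/extension/force
record under a single experimental condition, sampled uniformly (30 Hz on the
instrument this models).  Everything downstream — ramp-cycle segmentation,
folding-event detection, dwell extraction — works on slices of a Trace, so
the raw samples live in exactly one place.

Units are fixed at ingest: seconds, nanometres, piconewtons, molar.  Files
carry units in column names / attributes; a mismatch is an error, never a
silent conversion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Ligand",
    "ConditionLabel",
    "Trace",
    "RampCycle",
    "FoldingEvent",
    "DwellSegment",
    "ExpMixtureFit",
    "DoseResponseFit",
    "TraceFormatError",
    "TraceValidationError",
    "read_traces",
    "write_traces",
]

CSV_COLUMNS = [
    "bead_id",
    "condition_ligand",
    "condition_conc_molar",
    "cycle_id",
    "time_s",
    "extension_nm",
    "force_pn",
]


class TraceFormatError(ValueError):
    """A trace file is malformed (missing column/dataset, bad units)."""


class TraceValidationError(ValueError):
    """A trace violates a structural invariant (identifies the bead)."""


class Ligand(str, enum.Enum):
    CONTROL = "control"
    COMPOUND4 = "compound4"
    PREQ1 = "preq1"
    OTHER = "other"


@dataclass(frozen=True)
class ConditionLabel:
    """Experimental condition: which ligand, at what concentration (molar)."""

    ligand: Ligand = Ligand.CONTROL
    concentration: float = 0.0
    replicate: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "ligand", Ligand(self.ligand))
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.ligand is Ligand.CONTROL and self.concentration != 0:
            raise ValueError("control condition implies concentration = 0")

    @property
    def key(self) -> tuple[str, float, int]:
        return (self.ligand.value, self.concentration, self.replicate)


@dataclass
class Trace:
    """One bead's Z-position record versus time under applied force.

    Parameters
    ----------
    bead_id
        Opaque identifier of the tethered bead/molecule.
    condition
        Ligand condition the trace was recorded under.
    time, extension, force
        Equal-length arrays: time (s, strictly increasing, uniform),
        extension (nm, bead Z-position) and applied force (pN, >= 0).
    sample_rate
        Acquisition rate in Hz; must agree with the time grid to 1%.
    cycle_id
        Optional per-sample ramp-cycle annotation (carried through I/O,
        recomputable with :func:`riboforce.ramp_analysis.segment_cycles`).
    """

    bead_id: str
    condition: ConditionLabel
    time: np.ndarray
    extension: np.ndarray
    force: np.ndarray
    sample_rate: float
    cycle_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.cycle_id is not None:
            self.cycle_id = np.asarray(self.cycle_id, dtype=int)
        self.validate()

    def validate(self) -> None:
        n = self.time.size
        if self.extension.size != n or self.force.size != n:
            raise TraceValidationError(
                f"bead {self.bead_id}: time/extension/force lengths differ "
                f"({n}/{self.extension.size}/{self.force.size})"
            )
        if n == 0:
            raise TraceValidationError(f"bead {self.bead_id}: empty trace")
        if self.sample_rate <= 0:
            raise TraceValidationError(f"bead {self.bead_id}: sample_rate must be > 0")
        dt = np.diff(self.time)
        if n > 1:
            if np.any(dt <= 0):
                raise TraceValidationError(
                    f"bead {self.bead_id}: time not strictly increasing"
                )
            nominal = 1.0 / self.sample_rate
            if np.any(np.abs(dt - nominal) > 0.01 * nominal):
                raise TraceValidationError(
                    f"bead {self.bead_id}: sampling interval deviates from "
                    f"1/sample_rate by more than 1%"
                )
        if np.any(self.force < 0):
            raise TraceValidationError(f"bead {self.bead_id}: negative force")
        if self.cycle_id is not None and self.cycle_id.size != n:
            raise TraceValidationError(
                f"bead {self.bead_id}: cycle_id length mismatch"
            )

    def __len__(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return len(self) / self.sample_rate

    def slice(self, sl: slice) -> "Trace":
        return replace(
            self,
            time=self.time[sl],
            extension=self.extension[sl],
            force=self.force[sl],
            cycle_id=None if self.cycle_id is None else self.cycle_id[sl],
        )


@dataclass(frozen=True)
class RampCycle:
    """One up/down force ramp: index ranges into the parent trace."""

    cycle_index: int
    up_slice: slice
    down_slice: slice
    f_min: float
    f_max: float

    def __post_init__(self) -> None:
        if not self.f_min < self.f_max:
            raise ValueError("f_min must be < f_max")


class EventDirection(str, enum.Enum):
    UNFOLD = "unfold"
    REFOLD = "refold"


@dataclass(frozen=True)
class FoldingEvent:
    """An abrupt extension jump: the structure unfolded or refolded."""

    direction: EventDirection
    force: float
    size: float
    time: float
    cycle_index: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", EventDirection(self.direction))
        if self.size <= 0:
            raise ValueError("event size must be > 0")


class DwellState(str, enum.Enum):
    FOLDED = "folded"
    UNFOLDED = "unfolded"


@dataclass(frozen=True)
class DwellSegment:
    """A contiguous residence in one state at constant force."""

    state: DwellState
    start: float
    duration: float
    censored: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "state", DwellState(self.state))
        if self.duration < 0:
            raise ValueError("duration must be >= 0")


@dataclass(frozen=True)
class ExpMixtureFit:
    """MLE of a 1-3 component exponential mixture over dwell durations."""

    n_components: int
    lifetimes: tuple[float, ...]
    weights: tuple[float, ...]
    loglik: float
    bic: float
    n_dwells: int
    converged: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.n_components <= 3:
            raise ValueError("n_components must be 1-3")
        if len(self.lifetimes) != self.n_components:
            raise ValueError("lifetimes length != n_components")
        if len(self.weights) != self.n_components:
            raise ValueError("weights length != n_components")
        if any(t <= 0 for t in self.lifetimes):
            raise ValueError("lifetimes must be > 0")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if list(self.lifetimes) != sorted(self.lifetimes):
            raise ValueError("lifetimes must be sorted ascending")
        if not np.isfinite(self.bic):
            raise ValueError("bic must be finite")


@dataclass(frozen=True)
class DoseResponseFit:
    """A fitted saturation curve (binding, force response, or termination).

    ``model`` selects the parameterization:

    - ``mfs_saturation``:  y = (u + b*x/K_D) / (1 + x/K_D)
    - ``one_site_total``:  y = B_max*x/(K_D + x) + ns_slope*x + background
    - ``termination``:     y = e_min + (e_max - e_min)*x/(T_50 + x)
    """

    model: str
    params: dict[str, float]
    std_errors: dict[str, float]
    concentrations: np.ndarray
    residual_norm: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.model not in ("mfs_saturation", "one_site_total", "termination"):
            raise ValueError(f"unknown model {self.model!r}")
        half = self.params.get("K_D", self.params.get("T_50"))
        if half is not None and half <= 0:
            raise ValueError("K_D/T_50 must be > 0")
        for k, v in self.params.items():
            if not np.isfinite(v):
                raise ValueError(f"parameter {k} is not finite")
        for k, v in self.std_errors.items():
            if v < 0:
                raise ValueError(f"std error {k} is negative")

    @property
    def half_saturation(self) -> float:
        return self.params.get("K_D", self.params.get("T_50", np.nan))


# ---------------------------------------------------------------------------
# I/O


def _traces_to_frame(traces: Sequence[Trace]) -> pd.DataFrame:
    frames = []
    for tr in traces:
        cyc = tr.cycle_id if tr.cycle_id is not None else np.full(len(tr), -1)
        frames.append(
            pd.DataFrame(
                {
                    "bead_id": tr.bead_id,
                    "condition_ligand": tr.condition.ligand.value,
                    "condition_conc_molar": tr.condition.concentration,
                    "condition_replicate": tr.condition.replicate,
                    "cycle_id": cyc,
                    "time_s": tr.time,
                    "extension_nm": tr.extension,
                    "force_pn": tr.force,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_traces(
    traces: Iterable[Trace], path: str | Path, format: str = "csv"
) -> Path:
    """Write traces to ``path`` in ``csv`` or ``hdf5`` form.

    CSV uses one long table with the documented column set; HDF5 stores one
    group per bead/condition with ``time``/``extension``/``force`` datasets
    and condition attributes.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("write_traces: empty trace collection")
    path = Path(path)
    if format == "csv":
        # %.17g round-trips float64 exactly through text
        _traces_to_frame(traces).to_csv(path, index=False, float_format="%.17g")
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            root = f.create_group("beads")
            for i, tr in enumerate(traces):
                g = root.create_group(f"{tr.bead_id}__{i}")
                g.create_dataset("time", data=tr.time)
                g.create_dataset("extension", data=tr.extension)
                g.create_dataset("force", data=tr.force)
                if tr.cycle_id is not None:
                    g.create_dataset("cycle_id", data=tr.cycle_id)
                g.attrs["bead_id"] = tr.bead_id
                g.attrs["ligand"] = tr.condition.ligand.value
                g.attrs["conc_molar"] = tr.condition.concentration
                g.attrs["replicate"] = tr.condition.replicate
                g.attrs["sample_rate_hz"] = tr.sample_rate
                g.attrs["units"] = "s,nm,pN,molar"
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_traces(path: str | Path, format: str = "csv") -> list[Trace]:
    """Read traces written by :func:`write_traces`.

    Returns one :class:`Trace` per bead/condition pair, validated; any
    invariant violation raises :class:`TraceValidationError` naming the bead.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_csv(path)
    if format == "hdf5":
        return _read_hdf5(path)
    raise ValueError(f"unknown format {format!r}")


def _read_csv(path: Path) -> list[Trace]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if "condition_replicate" not in df.columns:
        df["condition_replicate"] = 0
    traces = []
    keys = ["bead_id", "condition_ligand", "condition_conc_molar", "condition_replicate"]
    for (bead, lig, conc, rep), grp in df.groupby(keys, sort=True):
        t = grp["time_s"].to_numpy()
        if t.size > 1:
            sample_rate = 1.0 / np.median(np.diff(t))
        else:
            sample_rate = 1.0
        cyc = grp["cycle_id"].to_numpy()
        traces.append(
            Trace(
                bead_id=str(bead),
                condition=ConditionLabel(Ligand(lig), float(conc), int(rep)),
                time=t,
                extension=grp["extension_nm"].to_numpy(),
                force=grp["force_pn"].to_numpy(),
                sample_rate=sample_rate,
                cycle_id=None if np.all(cyc < 0) else cyc,
            )
        )
    return traces


def _read_hdf5(path: Path) -> list[Trace]:
    traces = []
    with h5py.File(path, "r") as f:
        if "beads" not in f:
            raise TraceFormatError(f"{path}: missing /beads group")
        for name, g in f["beads"].items():
            for ds in ("time", "extension", "force"):
                if ds not in g:
                    raise TraceFormatError(f"{path}: /beads/{name} missing {ds}")
            traces.append(
                Trace(
                    bead_id=str(g.attrs.get("bead_id", name)),
                    condition=ConditionLabel(
                        Ligand(g.attrs["ligand"]),
                        float(g.attrs["conc_molar"]),
                        int(g.attrs.get("replicate", 0)),
                    ),
                    time=g["time"][:],
                    extension=g["extension"][:],
                    force=g["force"][:],
                    sample_rate=float(g.attrs["sample_rate_hz"]),
                    cycle_id=g["cycle_id"][:] if "cycle_id" in g else None,
                )
            )
    traces.sort(key=lambda tr: (tr.bead_id, tr.condition.key))
    return traces
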