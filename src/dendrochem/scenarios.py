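"""Canned validation scenarios, wave-speed measurement, and trajectory I/O.

The workhorse is the scalar bistable equation

    u_t = D·u_xx + u·(u − α)·(1 − u),      0 ≤ α < 1/2,

a minimal caricature of an intracellular concentration wave: below the
threshold α the species is cleared, above it the concentration runs to the
asymptote 1, and diffusion turns the bistable kinetics into a traveling
front.  On the infinite line the front moves at the closed-form speed
sqrt(2·D)·(1/2 − α), which makes the model a sharp end-to-end test of the
discretization: the numerically measured front speed converges to the
analytic value approximately quadratically in the spatial step dx.

:func:`run_bistable` builds the single-cable model (the reaction is
expressed as a rate (0 − c)·(α − c)·(1 − c) on one diffusing species),
:func:`measure_wave_speed` extracts the front speed between two snapshot
times, and :func:`convergence_study` tabulates |numerical − analytic| speed
errors over (α, dx) grids together with empirical convergence orders.
Concentrations here are dimensionless multiples of the asymptotic value
(the rate form pins the stable states to 0 and 1).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import IO, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .engine import Model
from .morphology import Morphology
from .reactions import Rate
from .regions import Region
from .species import Species

__all__ = [
    "ScenarioError",
    "BistableScenario",
    "Trajectory",
    "run_bistable",
    "front_position",
    "measure_wave_speed",
    "analytic_wave_speed",
    "convergence_study",
    "convergence_orders",
    "random_tree_morphology",
    "write_trajectory",
    "read_trajectory",
]


class ScenarioError(ValueError):
    """Invalid scenario parameters or unusable trajectory."""


@dataclass
class BistableScenario:
    """Parameters of the bistable-wave validation run.

    A single unbranched cable of length ``L`` (µm, default 1000) carries one
    species with diffusion coefficient ``D`` (µm²/ms, default 1), kinetics
    rate (0 − c)(α − c)(1 − c), and an initial unit-concentration seed over
    the leftmost ``seed_width`` µm (default 200).  ``dx`` is the target
    spatial step; ``dt=None`` integrates adaptively (absolute tolerance
    ``atol``), otherwise with fixed steps.  Snapshots default to every
    100 ms up to ``T`` (default 600 ms), bracketing the t = 200..600 ms
    window used for speed measurement.
    """

    alpha: float
    D: float = 1.0
    L: float = 1000.0
    dx: float = 1.0
    seed_width: float = 200.0
    T: float = 600.0
    dt: Optional[float] = None
    atol: float = 1e-13
    rtol: float = 1e-7
    snapshot_times: Optional[Sequence[float]] = None

    def __post_init__(self):
        if not (0.0 <= self.alpha < 0.5):
            raise ScenarioError(f"alpha must be in [0, 0.5), got {self.alpha}")
        for label in ("D", "L", "dx", "T"):
            if getattr(self, label) <= 0:
                raise ScenarioError(f"{label} must be positive")
        if not (0.0 < self.seed_width < self.L):
            raise ScenarioError("seed_width must lie inside the cable")

    @property
    def nseg(self) -> int:
        return max(1, int(round(self.L / self.dx)))

    def times(self) -> np.ndarray:
        if self.snapshot_times is not None:
            times = np.asarray(sorted(set(float(t) for t in self.snapshot_times)))
        else:
            times = np.arange(0.0, self.T + 1e-9, 100.0)
        if times[-1] > self.T + 1e-9:
            raise ScenarioError("snapshot times exceed T")
        return times


@dataclass
class Trajectory:
    """Snapshots of one species along one cable: times (ms), segment-center
    positions (µm), concentration matrix (times × positions, mM), and a
    metadata dict recording the scenario and solver settings."""

    times: np.ndarray
    positions: np.ndarray
    concentrations: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.positions = np.asarray(self.positions, float)
        self.concentrations = np.asarray(self.concentrations, float)
        if np.any(np.diff(self.times) < 0) or np.any(np.diff(self.positions) < 0):
            raise ScenarioError("times and positions must be monotone")
        if self.concentrations.shape != (len(self.times), len(self.positions)):
            raise ScenarioError("concentration matrix shape mismatch")

    def at_time(self, t: float) -> np.ndarray:
        hits = np.nonzero(np.isclose(self.times, t, rtol=0, atol=1e-9))[0]
        if len(hits) == 0:
            raise ScenarioError(f"no snapshot at t={t}")
        return self.concentrations[hits[0]]


def run_bistable(scenario: BistableScenario) -> Trajectory:
    """Simulate the bistable-wave scenario and return its trajectory.

    Adds a boundary warning flag to the metadata if the front comes within
    50 µm of the far end by the final snapshot.
    """
    sc = scenario
    morph = Morphology()
    cable = morph.create_section("cable", L=sc.L, diam=1.0, nseg=sc.nseg)
    cyt = Region([cable], nrn_region="i", name="cyt")
    c = Species(
        cyt,
        d=sc.D,
        name="c",
        initial=lambda node: 1.0 if node.x * sc.L <= sc.seed_width else 0.0,
    )
    wave = Rate(c, (0.0 - c) * (sc.alpha - c) * (1.0 - c))
    model = Model(species=[c], reactions=[wave], morphology=morph,
                  atol=sc.atol)
    model.initialize()
    seg_idx = np.array([n.index for n in c[cyt].nodes])
    times = sc.times()

    rows = []
    if sc.dt is None:
        _, states = model.run_adaptive(sc.T, t_eval=times, atol=sc.atol,
                                       rtol=sc.rtol)
        rows = [states[k, seg_idx] for k in range(len(times))]
    else:
        for t in times:
            if t > model.t + 1e-12:
                model.run_fixed(t, sc.dt)
            rows.append(model.state[seg_idx].copy())

    conc = np.vstack(rows)
    positions = cable.arc_centers()
    metadata = {k: v for k, v in asdict(sc).items()}
    metadata["solver"] = "fixed" if sc.dt is not None else "adaptive-bdf"
    metadata["nseg"] = sc.nseg
    try:
        fp = front_position(positions, conc[-1], max(sc.alpha, 1e-6))
    except ScenarioError:
        fp = None
    metadata["boundary_warning"] = bool(
        conc[-1, -1] > 1e-3 or (fp is not None and fp > sc.L - 50.0)
    )
    return Trajectory(times, positions, conc, metadata)


def front_position(positions, concentrations, threshold: float) -> float:
    """Rightmost linearly-interpolated downward crossing of ``threshold``.

    A crossing exactly on a grid point returns that point.  Raises
    :class:`ScenarioError` if the profile never crosses the threshold.
    """
    x = np.asarray(positions, float)
    c = np.asarray(concentrations, float)
    for i in range(len(c) - 2, -1, -1):
        if c[i] >= threshold > c[i + 1]:
            frac = (c[i] - threshold) / (c[i] - c[i + 1])
            return float(x[i] + frac * (x[i + 1] - x[i]))
    raise ScenarioError("no downward threshold crossing in the profile")


def measure_wave_speed(
    traj: Trajectory, alpha: float, t1: float = 200.0, t2: float = 600.0
) -> float:
    """Average front speed (µm/ms) between snapshots at ``t1`` and ``t2``.

    The front position at each time is the rightmost interpolated crossing
    of concentration = α.
    """
    if t2 <= t1:
        raise ScenarioError("require t2 > t1")
    p1 = front_position(traj.positions, traj.at_time(t1), alpha)
    p2 = front_position(traj.positions, traj.at_time(t2), alpha)
    return (p2 - p1) / (t2 - t1)


def analytic_wave_speed(alpha: float, D: float = 1.0) -> float:
    """Closed-form front speed sqrt(2·D)·(1/2 − α) of the bistable equation.

    Valid for 0 ≤ α ≤ 1; at α = 1/2 the two stable states balance and the
    front is stationary.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ScenarioError(f"alpha must be in [0, 1], got {alpha}")
    if D < 0:
        raise ScenarioError("D must be non-negative")
    return math.sqrt(2.0 * D) * (0.5 - alpha)


def convergence_study(
    alphas: Sequence[float],
    dxs: Sequence[float],
    **scenario_kwargs,
) -> pd.DataFrame:
    """Wave-speed errors over an (α, dx) grid.

    Runs one bistable scenario per combination and returns a tidy frame with
    columns ``alpha, dx, speed, analytic, error``.  Extra keyword arguments
    are forwarded to :class:`BistableScenario` (e.g. ``dt`` for fixed-step
    runs; the default is the adaptive solver at absolute tolerance 1e-13).
    """
    records = []
    for alpha in alphas:
        for dx in dxs:
            sc = BistableScenario(alpha=float(alpha), dx=float(dx),
                                  **scenario_kwargs)
            traj = run_bistable(sc)
            speed = measure_wave_speed(traj, sc.alpha)
            exact = analytic_wave_speed(sc.alpha, sc.D)
            records.append(
                dict(alpha=sc.alpha, dx=sc.dx, speed=speed, analytic=exact,
                     error=abs(speed - exact))
            )
    return pd.DataFrame.from_records(records)


def convergence_orders(table: pd.DataFrame) -> pd.DataFrame:
    """Empirical convergence orders log2(error(dx)/error(dx/2)) per α.

    Consecutive rows of the sorted dx grid are paired; only exact halvings
    are compared.
    """
    records = []
    for alpha, group in table.groupby("alpha"):
        group = group.sort_values("dx", ascending=False)
        dxs = group["dx"].to_numpy()
        errs = group["error"].to_numpy()
        for i in range(len(dxs) - 1):
            if not math.isclose(dxs[i] / dxs[i + 1], 2.0, rel_tol=1e-9):
                continue
            if errs[i + 1] == 0:
                continue
            records.append(
                dict(alpha=alpha, dx_coarse=dxs[i], dx_fine=dxs[i + 1],
                     order=math.log2(errs[i] / errs[i + 1]))
            )
    return pd.DataFrame.from_records(records)


def random_tree_morphology(
    seed: int,
    n_sections: int = 10,
    L_range=(20.0, 200.0),
    diam_range=(0.5, 2.0),
    nseg_range=(1, 9),
) -> Morphology:
    """Reproducible random branched morphology for tests and fixtures.

    Each non-root section attaches to a uniformly chosen earlier section at
    a random end, so the result is always a single connected tree.
    """
    if n_sections < 1:
        raise ScenarioError("n_sections must be >= 1")
    rng = np.random.default_rng(seed)
    morph = Morphology()
    for k in range(n_sections):
        sec = morph.create_section(
            f"sec{k}",
            L=float(rng.uniform(*L_range)),
            diam=float(rng.uniform(*diam_range)),
            nseg=int(rng.integers(nseg_range[0], nseg_range[1] + 1)),
        )
        if k > 0:
            parent = morph.sections[int(rng.integers(0, k))]
            morph.connect(sec, parent, parent_x=int(rng.integers(0, 2)))
    morph.validate()
    return morph


# ---------------------------------------------------------------------------
# trajectory CSV I/O
# ---------------------------------------------------------------------------


def write_trajectory(traj: Trajectory, stream: Union[str, IO[str]]) -> None:
    """Write a trajectory as CSV: '#'-prefixed JSON metadata lines, a header
    row of positions, then one row per time (time in the first column)."""
    close = False
    if isinstance(stream, str):
        stream = open(stream, "w")
        close = True
    try:
        for key in sorted(traj.metadata):
            stream.write(f"# {key}={json.dumps(traj.metadata[key])}\n")
        stream.write(
            "time," + ",".join(repr(float(x)) for x in traj.positions) + "\n"
        )
        for t, row in zip(traj.times, traj.concentrations):
            stream.write(repr(float(t)) + "," +
                         ",".join(repr(float(v)) for v in row) + "\n")
    finally:
        if close:
            stream.close()


def read_trajectory(stream: Union[str, IO[str]]) -> Trajectory:
    """Invert :func:`write_trajectory`."""
    close = False
    if isinstance(stream, str):
        stream = open(stream)
        close = True
    try:
        metadata: dict = {}
        header = None
        times = []
        rows = []
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    try:
                        metadata[key.strip()] = json.loads(val)
                    except json.JSONDecodeError:
                        raise ScenarioError(
                            f"line {lineno}: bad metadata value {val!r}"
                        ) from None
                continue
            fields = line.split(",")
            if header is None:
                if fields[0] != "time":
                    raise ScenarioError(
                        f"line {lineno}: expected 'time' header, got {fields[0]!r}"
                    )
                try:
                    header = np.array([float(v) for v in fields[1:]])
                except ValueError:
                    raise ScenarioError(f"line {lineno}: non-numeric position") \
                        from None
                continue
            try:
                values = [float(v) for v in fields]
            except ValueError:
                raise ScenarioError(f"line {lineno}: non-numeric value") from None
            if len(values) != len(header) + 1:
                raise ScenarioError(f"line {lineno}: wrong number of columns")
            times.append(values[0])
            rows.append(values[1:])
        if header is None:
            raise ScenarioError("missing trajectory header row")
        conc = (np.array(rows) if rows
                else np.empty((0, len(header))))
        return Trajectory(np.array(times), header, conc, metadata)
    finally:
        if close:
            stream.close()
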