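"""Experimental-data-guided Monte Carlo surface erosion.

Enzymatic hydrolysis of a polyester part is a surface process: the enzyme
molecules are too bulky to diffuse into the bulk, so only material in
contact with the medium is removed.  The engine mimics this on a
tetrahedral mesh.  At every iteration only *boundary* elements (at least
one face exposed to the medium) are candidates for removal, and the
simulation is guided by an experimental mass-loss schedule so that the
simulated volume loss tracks the measured one reference by reference.

Each iteration applies one of two criteria:

* **Boundary elements** — if the whole boundary volume is smaller than the
  deficit to the current reference, the complete boundary layer is removed
  (a fast peel used to cross large gaps between consecutive references).
* **Monte Carlo** — otherwise, an amplification factor

      X = deficit / (nfacesavg / 4 * boundvol)

  scales the per-element removal probability

      P_e = X * n_e / 4

  (n_e = exposed faces of element e) so that the *expected* removed volume
  in the iteration equals the remaining deficit.  Each boundary element is
  then removed independently with probability P_e.

Convergence to the current reference is declared when the cumulative
removed percentage exceeds the reference percentage minus an absolute
tolerance (0.01 percentage points by default); the surviving mesh is then
saved as the predicted degraded geometry at that reference's time and the
next reference becomes the target.

The per-iteration ratio of removed volume to entry boundary volume is a
*normalized amplification factor*: extracted from a run on a simple,
experimentally characterised geometry (e.g. a filament), the factor
sequence can be replayed on a different mesh of the same material to
predict its degraded shapes without new experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import TetMesh, compute_exposure

__all__ = [
    "MONTE_CARLO",
    "BOUNDARY_ELEMENTS",
    "DEFAULT_LAMBDA",
    "ErosionError",
    "SimulationStalledError",
    "MaxIterationsError",
    "ReferenceSchedule",
    "ErosionConfig",
    "ErosionState",
    "IterationRecord",
    "select_criterion",
    "amplification_factor",
    "removal_probability",
    "draw_threshold",
    "monte_carlo_step",
    "boundary_removal_step",
    "convergence_check",
    "run_simulation",
    "extract_normalized_factors",
    "apply_normalized_factors",
    "SurfaceErosionModel",
    "ErosionResults",
]

MONTE_CARLO = "Monte Carlo"
BOUNDARY_ELEMENTS = "Boundary elements"

#: default rate parameter of the exponential threshold transform (z = -lambda*ln(1-R))
DEFAULT_LAMBDA = 0.00812

#: columns of the iteration report, mirroring the per-iteration result tables
RECORD_COLUMNS = [
    "iteration",
    "boundary_volume_mm3",
    "reference_removed_pct",
    "criterion",
    "removed_volume_mm3",
    "removed_volume_pct",
    "deviation_pct",
]


class ErosionError(RuntimeError):
    """Base class for erosion-simulation failures."""


class SimulationStalledError(ErosionError):
    """The boundary is empty (mesh exhausted) but the schedule is not met."""


class MaxIterationsError(ErosionError):
    """The iteration guard tripped before the schedule was met."""

    def __init__(self, msg, records):
        super().__init__(msg)
        self.records = records  # partial iteration records for post-mortem


# ---------------------------------------------------------------------------
# Schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceSchedule:
    """Ordered experimental (time, volume-loss %) targets driving the erosion.

    Under the constant-density assumption the measured mass-loss percentages
    are used directly as volume-loss percentages; when per-time densities
    are available, convert first (see
    :func:`erodesim.material.mass_to_volume_loss`).

    Entries must be strictly increasing in both time and loss; a
    non-increasing loss value (e.g. an apparent mass *gain* caused by
    enzyme saturation late in an experiment, as seen for pure PCL at 48 h)
    cannot guide a pure-erosion simulation and must be dropped before
    constructing the schedule.
    """

    times_h: np.ndarray
    vol_loss_pct: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "times_h", np.asarray(self.times_h, dtype=float)
        )
        object.__setattr__(
            self, "vol_loss_pct", np.asarray(self.vol_loss_pct, dtype=float)
        )
        t, v = self.times_h, self.vol_loss_pct
        if t.ndim != 1 or t.shape != v.shape or t.size == 0:
            raise ValueError("schedule needs matching, non-empty time/loss arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("schedule times must be strictly increasing")
        if np.any(v <= 0) or np.any(v >= 100):
            raise ValueError("volume-loss percentages must lie in (0, 100)")
        if np.any(np.diff(v) <= 0):
            raise ValueError(
                "volume-loss percentages must be strictly increasing; drop "
                "saturated entries (e.g. a late measurement below an earlier "
                "one, as happens when enzymatic saturation halts mass loss)"
            )

    def __len__(self) -> int:
        return len(self.times_h)

    @classmethod
    def from_pairs(cls, pairs) -> "ReferenceSchedule":
        """Build from an iterable of (time_h, loss_pct) pairs."""
        arr = np.asarray(list(pairs), dtype=float)
        return cls(times_h=arr[:, 0], vol_loss_pct=arr[:, 1])

    @classmethod
    def from_csv(cls, path) -> "ReferenceSchedule":
        """Read a schedule CSV with columns ``time_h,mass_loss_pct`` and an
        optional ``density_g_cm3`` column (plus optional
        ``initial_density_g_cm3``, constant, for the conversion)."""
        df = pd.read_csv(path)
        required = {"time_h", "mass_loss_pct"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"{path}: schedule CSV needs columns {sorted(required)}, "
                f"found {list(df.columns)}"
            )
        loss = df["mass_loss_pct"].to_numpy(dtype=float)
        if "density_g_cm3" in df.columns:
            from .material import mass_to_volume_loss

            rho0 = (
                float(df["initial_density_g_cm3"].iloc[0])
                if "initial_density_g_cm3" in df.columns
                else float(df["density_g_cm3"].iloc[0])
            )
            loss = mass_to_volume_loss(
                loss, densities=df["density_g_cm3"].to_numpy(dtype=float),
                initial_density=rho0,
            )
        return cls(times_h=df["time_h"].to_numpy(dtype=float), vol_loss_pct=loss)

    def ab_vol_loss(self, total_volume: float) -> np.ndarray:
        """Absolute volume-loss targets in mm^3 for a part of ``total_volume``."""
        return self.vol_loss_pct / 100.0 * total_volume


# ---------------------------------------------------------------------------
# Configuration / state / records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ErosionConfig:
    """Tunable parameters of the erosion engine.

    Parameters
    ----------
    removal_rule : {"expected-volume", "threshold-transform"}
        How a boundary element's removal is decided from its probability
        ``P = X * n_e / 4``.  ``"expected-volume"`` (default) removes with
        probability ``min(P, 1)`` via a uniform draw, so the expected
        removed volume of a Monte Carlo iteration equals the deficit the
        amplification factor was built for.  ``"threshold-transform"``
        draws an exponential threshold ``z = -lambda * ln(1 - R)`` and
        removes when ``z < P``; the effective removal probability is then
        ``1 - exp(-P/lambda)``, which saturates near 1 already for small P
        at the default rate, eroding far more aggressively.
    lam : float
        Rate parameter (mean) of the exponential threshold, dimensionless;
        only used by the threshold-transform rule.  Default 0.00812.
    tolerance : float
        Absolute convergence tolerance in percentage points (default 0.01):
        a reference counts as met when removed % > reference % - tolerance.
    max_iterations : int
        Guard converting a stalled loop into an error.
    probability_clamp : bool
        Cap P at 1 before use as a Bernoulli probability (default on).
    """

    removal_rule: str = "expected-volume"
    lam: float = DEFAULT_LAMBDA
    tolerance: float = 0.01
    max_iterations: int = 10_000
    probability_clamp: bool = True

    def __post_init__(self):
        if self.removal_rule not in ("expected-volume", "threshold-transform"):
            raise ValueError(f"unknown removal_rule {self.removal_rule!r}")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class ErosionState:
    """Evolving simulation state.

    ``iteration`` (i) counts iterations from 1; ``m`` indexes the schedule
    reference currently targeted (1-based).  ``boundvol``, ``nfacesavg``
    and ``X`` hold the values computed on the current iteration's entry
    snapshot once :func:`update_boundary` has run.
    """

    active: np.ndarray
    total_volume: float
    rng: np.random.Generator
    iteration: int = 1
    m: int = 1
    ab_removed_volume: float = 0.0
    boundvol: float = 0.0
    nfacesavg: float = float("nan")
    X: float = float("nan")
    _exposure: np.ndarray | None = field(default=None, repr=False)
    _boundary_idx: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def initial(cls, mesh: TetMesh, rng: np.random.Generator) -> "ErosionState":
        return cls(
            active=mesh.full_active(), total_volume=mesh.total_volume, rng=rng
        )

    @property
    def removed_volume_pct(self) -> float:
        """Cumulative removed volume as % of the initial part volume."""
        return 100.0 * self.ab_removed_volume / self.total_volume


@dataclass(frozen=True)
class IterationRecord:
    """One row of the iteration report (one erosion iteration)."""

    iteration: int
    boundary_volume_mm3: float
    reference_removed_pct: float
    criterion: str
    removed_volume_mm3: float  # cumulative, end of iteration
    removed_volume_pct: float  # cumulative, % of initial volume
    deviation_pct: float  # removed_volume_pct - reference_removed_pct

    def as_dict(self) -> dict:
        return {c: getattr(self, c) for c in RECORD_COLUMNS}


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def update_boundary(mesh: TetMesh, state: ErosionState) -> None:
    """Compute the entry snapshot of the current iteration.

    Labels the boundary elements of the active set, and stores their
    exposed-face counts, total volume (``boundvol``) and mean exposed-face
    count (``nfacesavg``, averaged over boundary elements) on the state.
    """
    exposure = compute_exposure(mesh, state.active)
    bidx = np.flatnonzero(exposure >= 1)
    state._exposure = exposure
    state._boundary_idx = bidx
    state.boundvol = float(mesh.volumes[bidx].sum())
    state.nfacesavg = float(exposure[bidx].mean()) if bidx.size else float("nan")


def _current_deficit(state: ErosionState, schedule: ReferenceSchedule) -> float:
    """Remaining absolute volume (mm^3) to the current reference."""
    target = schedule.ab_vol_loss(state.total_volume)[state.m - 1]
    return target - state.ab_removed_volume


def select_criterion(state: ErosionState, schedule: ReferenceSchedule) -> str:
    """Choose the iteration criterion on the entry snapshot.

    Monte Carlo applies iff the boundary volume strictly exceeds the
    remaining deficit to the current reference; otherwise the whole
    boundary is to be removed.  Requires :func:`update_boundary` first.
    """
    if state._boundary_idx is None:
        raise ErosionError("call update_boundary before select_criterion")
    deficit = _current_deficit(state, schedule)
    if state._boundary_idx.size == 0 and deficit > 0:
        raise SimulationStalledError(
            f"mesh exhausted at iteration {state.iteration} with "
            f"{deficit:.4g} mm^3 still to remove for reference {state.m}"
        )
    return MONTE_CARLO if state.boundvol > deficit else BOUNDARY_ELEMENTS


def amplification_factor(state: ErosionState, schedule: ReferenceSchedule) -> float:
    """Amplification factor X scaling the removal probabilities.

    X = deficit / (nfacesavg/4 * boundvol): the fraction of the boundary
    volume that must go to hit the current reference, corrected by the mean
    exposure of the boundary.  Shrinks toward 0 as the deficit closes.
    """
    if not state.boundvol > 0:
        raise ErosionError("amplification factor undefined: boundary volume is 0")
    deficit = _current_deficit(state, schedule)
    if not deficit > 0:
        raise ErosionError(
            "amplification factor undefined: reference already met "
            "(advance the m counter first)"
        )
    return deficit / (state.nfacesavg / 4.0 * state.boundvol)


def removal_probability(X, n_faces, clamp: bool = True):
    """Per-element removal probability P = X * n_faces / 4.

    ``n_faces`` must be in {1, 2, 3, 4}: only boundary elements are ever
    evaluated.  With ``clamp`` (default) P is capped at 1 so it can be used
    as a Bernoulli probability.
    """
    n = np.asarray(n_faces)
    if np.any((n < 1) | (n > 4)):
        raise ValueError("n_faces must be in {1, 2, 3, 4} (boundary elements only)")
    p = X * n / 4.0
    if clamp:
        p = np.minimum(p, 1.0)
    return float(p) if np.isscalar(n_faces) else p


def draw_threshold(rng: np.random.Generator, lam: float, size=None):
    """Exponential removal threshold(s) z = -lambda * ln(1 - R), R ~ U[0, 1).

    z is exponentially distributed with mean ``lam``.
    """
    r = rng.random(size)
    return -lam * np.log1p(-r)


def convergence_check(
    state: ErosionState, schedule: ReferenceSchedule, tolerance: float = 0.01
) -> bool:
    """True iff the cumulative removed % strictly exceeds the current
    reference % minus the absolute tolerance (percentage points)."""
    ref = schedule.vol_loss_pct[state.m - 1]
    return state.removed_volume_pct > ref - tolerance


# ---------------------------------------------------------------------------
# Iteration steps
# ---------------------------------------------------------------------------


def _make_record(state, schedule, criterion) -> IterationRecord:
    ref = float(schedule.vol_loss_pct[state.m - 1])
    pct = state.removed_volume_pct
    return IterationRecord(
        iteration=state.iteration,
        boundary_volume_mm3=state.boundvol,
        reference_removed_pct=ref,
        criterion=criterion,
        removed_volume_mm3=state.ab_removed_volume,
        removed_volume_pct=pct,
        deviation_pct=pct - ref,
    )


def _remove(mesh, state, remove_idx) -> None:
    state.active[remove_idx] = False
    state.ab_removed_volume += float(mesh.volumes[remove_idx].sum())


def monte_carlo_step(
    mesh: TetMesh,
    state: ErosionState,
    schedule: ReferenceSchedule,
    config: ErosionConfig,
) -> tuple[ErosionState, IterationRecord]:
    """One Monte Carlo iteration.

    Exposure counts, boundary volume, nfacesavg and X are computed once on
    the entry snapshot; every boundary element then gets an independent
    draw against its probability P = X * n_e / 4 (consumed in ascending
    element-id order from the state's RNG stream).  Removals within the
    iteration do not update exposures mid-iteration.
    """
    update_boundary(mesh, state)
    state.X = amplification_factor(state, schedule)
    bidx = state._boundary_idx
    n = state._exposure[bidx].astype(float)
    p = removal_probability(state.X, n, clamp=config.probability_clamp)
    if config.removal_rule == "expected-volume":
        hit = state.rng.random(bidx.size) < p
    else:  # threshold-transform: z below the probability removes the element
        hit = draw_threshold(state.rng, config.lam, bidx.size) < p
    _remove(mesh, state, bidx[hit])
    return state, _make_record(state, schedule, MONTE_CARLO)


def boundary_removal_step(
    mesh: TetMesh, state: ErosionState, schedule: ReferenceSchedule
) -> tuple[ErosionState, IterationRecord]:
    """One boundary-elements iteration: peel the complete boundary layer.

    Applied when the boundary volume cannot cover the deficit to the
    current reference; the incremental removed volume is exactly the entry
    boundary volume.
    """
    update_boundary(mesh, state)
    state.X = float("nan")
    _remove(mesh, state, state._boundary_idx)
    return state, _make_record(state, schedule, BOUNDARY_ELEMENTS)


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


def _run(mesh, schedule, config, rng):
    """Engine loop shared by run_simulation and SurfaceErosionModel.fit.

    Returns (records, snapshots) with snapshots a dict mapping reference
    time (h) to a copy of the active mask at the moment the reference was
    met.
    """
    state = ErosionState.initial(mesh, rng)
    records: list[IterationRecord] = []
    snapshots: dict[float, np.ndarray] = {}
    n_refs = len(schedule)
    while state.m <= n_refs:
        if state.iteration > config.max_iterations:
            raise MaxIterationsError(
                f"no convergence within {config.max_iterations} iterations "
                f"(reference {state.m} of {n_refs})",
                records,
            )
        update_boundary(mesh, state)
        criterion = select_criterion(state, schedule)
        if criterion == MONTE_CARLO:
            _, rec = monte_carlo_step(mesh, state, schedule, config)
        else:
            _, rec = boundary_removal_step(mesh, state, schedule)
        records.append(rec)
        # one large step may overshoot several references at once
        while state.m <= n_refs and convergence_check(
            state, schedule, config.tolerance
        ):
            snapshots[float(schedule.times_h[state.m - 1])] = state.active.copy()
            state.m += 1
        state.iteration += 1
    return records, snapshots


def run_simulation(
    mesh: TetMesh,
    schedule: ReferenceSchedule,
    config: ErosionConfig | None = None,
    seed: int | None = None,
) -> tuple[list[IterationRecord], dict[float, TetMesh]]:
    """Run the guided erosion until every schedule reference is met.

    Returns the iteration records and a map from each reference time (h) to
    the degraded mesh saved when that reference was reached.  Deterministic
    for a given seed.
    """
    config = config or ErosionConfig()
    records, snaps = _run(mesh, schedule, config, np.random.default_rng(seed))
    return records, {t: mesh.submesh(mask) for t, mask in snaps.items()}


# ---------------------------------------------------------------------------
# Normalized-factor transfer to other geometries
# ---------------------------------------------------------------------------


def extract_normalized_factors(records: list[IterationRecord]) -> list[float]:
    """Per-iteration removed-volume fraction of the entry boundary volume.

    Each factor is (incremental removed volume) / (boundary volume at
    iteration entry), in [0, 1]; a boundary-elements iteration yields 1.
    The sequence summarises a guided run in geometry-free form and can be
    replayed on another mesh of the same material and conditions.
    """
    factors = []
    prev = 0.0
    for rec in records:
        inc = rec.removed_volume_mm3 - prev
        prev = rec.removed_volume_mm3
        if rec.boundary_volume_mm3 <= 0:
            warnings.warn(
                f"iteration {rec.iteration}: zero boundary volume, factor skipped"
            )
            continue
        factors.append(float(inc / rec.boundary_volume_mm3))
    return factors


def apply_normalized_factors(
    mesh: TetMesh,
    factors,
    config: ErosionConfig | None = None,
    seed: int | None = None,
) -> list[TetMesh]:
    """Replay a normalized-factor sequence on a new geometry.

    For each factor f the amplification factor on the *new* mesh is chosen
    so that the expected removed boundary-volume fraction equals f
    (X = 4 f boundvol / sum(n_e v_e), the volume-weighted form of the
    guided run's X); f >= 1 peels the whole boundary.  Returns the degraded
    mesh after each step.  Stops early with a warning if the mesh runs out.
    """
    config = config or ErosionConfig()
    rng = np.random.default_rng(seed)
    factors = [float(f) for f in factors]
    if any(f < 0 or f > 1 for f in factors):
        raise ValueError("normalized factors must lie in [0, 1]")
    active = mesh.full_active()
    out: list[TetMesh] = []
    for step, f in enumerate(factors, start=1):
        exposure = compute_exposure(mesh, active)
        bidx = np.flatnonzero(exposure >= 1)
        if bidx.size == 0:
            warnings.warn(f"mesh exhausted after {step - 1} factor steps")
            break
        if f >= 1.0:
            active[bidx] = False
        else:
            n = exposure[bidx].astype(float)
            v = mesh.volumes[bidx]
            boundvol = float(v.sum())
            X = 4.0 * f * boundvol / float((n * v).sum())
            p = removal_probability(X, n, clamp=config.probability_clamp)
            if config.removal_rule == "expected-volume":
                hit = rng.random(bidx.size) < p
            else:
                hit = draw_threshold(rng, config.lam, bidx.size) < p
            active[bidx[hit]] = False
        if not active.any():
            warnings.warn(f"mesh exhausted after {step} factor steps")
            out.append(mesh.submesh(np.zeros(0, dtype=np.int64)))
            break
        out.append(mesh.submesh(active))
    return out


# ---------------------------------------------------------------------------
# Model / Results front-end
# ---------------------------------------------------------------------------


class SurfaceErosionModel:
    """Guided surface-erosion model of an enzymatically degraded part.

    Binds a tetrahedral mesh of the undegraded part to an experimental
    mass-loss schedule; :meth:`fit` runs the guided Monte Carlo erosion and
    returns an :class:`ErosionResults` with the iteration records and the
    predicted degraded geometry at every reference time.

    Parameters
    ----------
    mesh : TetMesh
        Undegraded geometry.
    schedule : ReferenceSchedule
        Experimental (time, loss %) references guiding the run.
    config : ErosionConfig, optional
        Engine parameters; keyword overrides (``removal_rule=...``,
        ``lam=...``, ``tolerance=...`` ...) are also accepted directly.

    Examples
    --------
    >>> mesh = generate_cylinder_mesh(1.9, 50.3, 8, 40)   # doctest: +SKIP
    >>> sched = ReferenceSchedule.from_pairs([(4, 0.84), (24, 6.16)])
    >>> res = SurfaceErosionModel(mesh, sched).fit(seed=0)  # doctest: +SKIP
    >>> print(res.summary())                                # doctest: +SKIP
    """

    def __init__(
        self,
        mesh: TetMesh,
        schedule: ReferenceSchedule,
        config: ErosionConfig | None = None,
        **overrides,
    ):
        self.mesh = mesh
        self.schedule = schedule
        cfg = config or ErosionConfig()
        if overrides:
            cfg = replace(cfg, **overrides)
        self.config = cfg

    @classmethod
    def from_schedule_csv(cls, mesh, path, **kwargs) -> "SurfaceErosionModel":
        return cls(mesh, ReferenceSchedule.from_csv(path), **kwargs)

    def fit(self, seed: int | None = None) -> "ErosionResults":
        """Run the erosion to convergence on every schedule reference."""
        rng = np.random.default_rng(seed)
        records, snapshots = _run(self.mesh, self.schedule, self.config, rng)
        return ErosionResults(self, records, snapshots, seed)


class ErosionResults:
    """Outcome of a guided erosion run.

    Carries the per-iteration records (criterion, boundary volume,
    cumulative removed volume, deviation to the reference), the saved
    active-element snapshots per reference time, and convenience accessors
    for degraded meshes, normalized factors and modulus predictions.
    """

    def __init__(self, model, records, snapshot_masks, seed):
        self.model = model
        self.records: list[IterationRecord] = records
        self.snapshot_masks: dict[float, np.ndarray] = snapshot_masks
        self.seed = seed
        self._meshes: dict[float, TetMesh] = {}

    # -- basic accessors ----------------------------------------------

    @property
    def mesh(self) -> TetMesh:
        return self.model.mesh

    @property
    def schedule(self) -> ReferenceSchedule:
        return self.model.schedule

    @property
    def n_iterations(self) -> int:
        return len(self.records)

    @property
    def times_h(self) -> list[float]:
        return sorted(self.snapshot_masks)

    def removed_pct_at(self, time_h: float) -> float:
        """Cumulative removed volume % of the snapshot saved at ``time_h``."""
        mask = self.snapshot_masks[time_h]
        total = self.mesh.total_volume
        return 100.0 * (total - float(self.mesh.volumes[mask].sum())) / total

    @property
    def final_removed_pct(self) -> float:
        return float(self.records[-1].removed_volume_pct)

    def degraded_mesh(self, time_h: float) -> TetMesh:
        """Predicted degraded geometry at a reference time (lazily built)."""
        if time_h not in self._meshes:
            self._meshes[time_h] = self.mesh.submesh(self.snapshot_masks[time_h])
        return self._meshes[time_h]

    @property
    def snapshots(self) -> dict[float, TetMesh]:
        return {t: self.degraded_mesh(t) for t in self.times_h}

    # -- reporting -----------------------------------------------------

    def records_frame(self) -> pd.DataFrame:
        """Iteration report as a DataFrame (one row per iteration)."""
        return pd.DataFrame([r.as_dict() for r in self.records], columns=RECORD_COLUMNS)

    def to_csv(self, path) -> None:
        """Write the iteration report CSV (canonical column order)."""
        self.records_frame().to_csv(Path(path), index=False)

    def normalized_factors(self) -> list[float]:
        """Per-iteration normalized amplification factors of this run."""
        return extract_normalized_factors(self.records)

    def predict_modulus(self, modulus_model) -> pd.DataFrame:
        """Elastic modulus predicted at each saved reference snapshot."""
        rows = [
            {
                "time_h": t,
                "removed_volume_pct": self.removed_pct_at(t),
                "elastic_modulus_MPa": modulus_model.predict(self.removed_pct_at(t)),
            }
            for t in self.times_h
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text run summary: configuration, iteration table, snapshots."""
        cfg = self.model.config
        mesh = self.mesh
        head = [
            "Guided Monte Carlo surface erosion",
            "=" * 66,
            f"mesh: {mesh.n_elements} tetrahedra, {mesh.n_nodes} nodes, "
            f"{mesh.total_volume:.3f} mm^3",
            "schedule: "
            + ", ".join(
                f"{t:g} h -> {v:g} %"
                for t, v in zip(self.schedule.times_h, self.schedule.vol_loss_pct)
            ),
            f"rule: {cfg.removal_rule} (lambda={cfg.lam}), "
            f"tolerance={cfg.tolerance}%, seed={self.seed}",
            "-" * 66,
        ]
        table = self.records_frame().to_string(
            index=False,
            float_format=lambda x: f"{x:.2f}",
        )
        tail = ["-" * 66]
        for t in self.times_h:
            tail.append(
                f"t = {t:g} h: removed {self.removed_pct_at(t):.2f} % "
                f"({self.degraded_mesh(t).n_elements} elements remain)"
            )
        return "\n".join(head + [table] + tail)
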