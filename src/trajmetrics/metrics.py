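"""Trajectory statistics: RMSD(t), RMSF/B-factor and pseudo-dihedrals.

Three readouts of conformational change in a protein trajectory:

* RMSD(t) = [ (1/M) sum_i m_i |r_i(t) - r_i_ref|^2 ]^(1/2) after least-squares
  superposition onto the reference, with M = sum_i m_i (unit weights when
  mass weighting is off).
* RMSF_i = [ (1/T) sum_t |r_i(t) - r_i_ref|^2 ]^(1/2) over a time window,
  with the window-mean positions as reference; the crystallographic
  Debye-Waller factor follows as B = (8/3) pi^2 RMSF^2.
* A pseudo-dihedral over four (typically non-bonded) C-alpha atoms, used as
  a coarse metric of relative helix orientation — here the KRAS alpha2/alpha3
  quadruple Met67, Thr74, Lys104, Thr87 by author numbering.  Angle ensembles
  are summarized with circular statistics (directional data wrap at +/-180).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import circmean, circstd

from .core import Selection, Structure, Trajectory
from .errors import SelectionError, UndefinedAngleError, WindowError
from .superposition import kabsch_fit

__all__ = [
    "RmsdSeries",
    "RmsfProfile",
    "BFactorProfile",
    "QuadrupleSpec",
    "DihedralSeries",
    "AngleDistribution",
    "DistributionShift",
    "compute_rmsd",
    "compute_rmsf",
    "rmsf_to_bfactor",
    "compute_pseudo_dihedral",
    "summarize_angles",
    "compare_distributions",
    "wrap_angle",
    "dihedral_from_points",
]

BFACTOR_PREFACTOR = 8.0 * np.pi**2 / 3.0

# Window defaults mirror the study protocol (50-ns runs): angle summaries on
# the last 30 ns, RMSF reference positions from the last 2 ns.  On shorter
# trajectories the same fractions of the simulated span are used instead.
ANGLE_WINDOW_PS = 30_000.0
ANGLE_WINDOW_FRACTION = 0.6
RMSF_WINDOW_PS = 2_000.0
RMSF_WINDOW_FRACTION = 0.04


def wrap_angle(angle_deg):
    """Map angles (degrees) onto the (-180, 180] branch."""
    wrapped = np.asarray(angle_deg, dtype=float) - 360.0 * np.floor(
        (np.asarray(angle_deg, dtype=float) + 180.0) / 360.0
    )
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    return wrapped if wrapped.ndim else float(wrapped)


def _default_window(times: np.ndarray, span_ps: float, fraction: float) -> tuple[float, float]:
    t0, t1 = float(times[0]), float(times[-1])
    total = t1 - t0
    if total >= span_ps:
        return t1 - span_ps, t1
    return t1 - fraction * total, t1


def _window_indices(times: np.ndarray, window: tuple[float, float] | None,
                    span_ps: float, fraction: float, min_frames: int = 1) -> np.ndarray:
    if window is None:
        window = _default_window(times, span_ps, fraction)
    t_start, t_end = float(window[0]), float(window[1])
    if t_end < times[0] or t_start > times[-1]:
        raise WindowError(
            f"window [{t_start}, {t_end}] ps outside trajectory "
            f"[{times[0]}, {times[-1]}] ps"
        )
    idx = np.flatnonzero((times >= t_start) & (times <= t_end))
    if len(idx) < min_frames:
        raise WindowError(
            f"window [{t_start}, {t_end}] ps holds {len(idx)} frames; "
            f"need >= {min_frames}"
        )
    return idx


@dataclass
class RmsdSeries:
    """Per-frame RMSD (A) of a selection versus a reference conformation."""

    times: np.ndarray
    values: np.ndarray
    selection: Selection
    fitted: bool
    mass_weighted: bool
    mean_value: float
    mean_window: tuple[float, float]

    def to_records(self):
        return [{"time_ps": float(t), "rmsd_A": float(v)} for t, v in zip(self.times, self.values)]


@dataclass
class RmsfProfile:
    """Per-atom RMSF (A) about the window-mean positions."""

    rmsf: np.ndarray
    window: tuple[float, float]
    reference_positions: np.ndarray
    averaging_time: float
    selection: Selection
    fitted: bool


@dataclass
class BFactorProfile:
    """Per-atom Debye-Waller factor B = (8/3) pi^2 RMSF^2 (A^2)."""

    b: np.ndarray
    source: RmsfProfile


@dataclass(frozen=True)
class QuadrupleSpec:
    """Four atoms defining a pseudo-dihedral, as (chain|None, resid, name).

    The default is the KRAS alpha2/alpha3 helix-orientation quadruple in its
    listed order: Met67-CA, Thr74-CA, Lys104-CA, Thr87-CA.
    """

    atoms: tuple[tuple[str | None, int, str], ...] = (
        (None, 67, "CA"),
        (None, 74, "CA"),
        (None, 104, "CA"),
        (None, 87, "CA"),
    )

    def __post_init__(self) -> None:
        if len(self.atoms) != 4:
            raise ValueError("a dihedral quadruple needs exactly 4 atoms")

    def resolve(self, atom_table) -> np.ndarray:
        """Indices of the four atoms in listed order; each must be unique."""
        if isinstance(atom_table, (Structure, Trajectory)):
            atom_table = atom_table.atoms
        indices = []
        for chain_id, resid, name in self.atoms:
            hits = [
                i
                for i, a in enumerate(atom_table)
                if a.residue_seq == resid
                and a.name.upper() == name.upper()
                and (chain_id is None or a.chain_id == chain_id)
            ]
            if len(hits) != 1:
                raise SelectionError(
                    f"quadruple atom (chain={chain_id}, resid={resid}, name={name}) "
                    f"matched {len(hits)} atoms; need exactly 1"
                )
            indices.append(hits[0])
        idx = np.array(indices, dtype=int)
        if len(set(indices)) != 4:
            raise SelectionError("quadruple atoms must be 4 distinct atoms")
        return idx

    @classmethod
    def parse(cls, text: str) -> "QuadrupleSpec":
        """Parse 'resid:NAME,...' or 'chain:resid:NAME,...' (4 items)."""
        atoms = []
        for item in text.split(","):
            parts = item.strip().split(":")
            if len(parts) == 2:
                atoms.append((None, int(parts[0]), parts[1]))
            elif len(parts) == 3:
                atoms.append((parts[0], int(parts[1]), parts[2]))
            else:
                raise ValueError(f"bad quadruple item {item!r}")
        return cls(atoms=tuple(atoms))


@dataclass
class DihedralSeries:
    """Pseudo-dihedral time series, degrees on (-180, 180]."""

    times: np.ndarray
    angles: np.ndarray
    quadruple: QuadrupleSpec
    meta: dict = field(default_factory=dict)


@dataclass
class AngleDistribution:
    """Windowed histogram + circular summary of a dihedral ensemble."""

    window: tuple[float, float]
    bin_width: float
    edges: np.ndarray
    counts: np.ndarray
    arithmetic_mean: float
    circular_mean: float
    circular_std: float
    mode_bin_center: float
    n_frames: int

    @property
    def density(self) -> np.ndarray:
        """Normalized histogram: sums to 1 when multiplied by bin_width."""
        return self.counts / (self.n_frames * self.bin_width)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class DistributionShift:
    """Shift summary of one angle distribution relative to a reference."""

    delta_circular_mean: float
    delta_mode: float
    circular_std_ratio: float
    overlap: float
    left_shifted: bool
    shift_tolerance: float


def _subset(traj: Trajectory, selection: Selection):
    coords = traj.frames[:, selection.indices, :]
    masses = traj.masses[selection.indices]
    return coords, masses


def compute_rmsd(
    traj: Trajectory,
    selection: Selection,
    reference: str | Structure = "first_frame",
    fit: bool = True,
    mass_weighted: bool = True,
    mean_window: tuple[float, float] | None = None,
) -> RmsdSeries:
    """Mass-weighted RMSD of a selection versus a reference conformation.

    Each frame is optionally superposed onto the reference (same selection,
    same weights) before the deviation is evaluated.  ``reference`` is the
    starting conformation by default, or any atom-compatible Structure.
    ``mean_window`` bounds the frames entering ``mean_value`` (default: the
    full series).
    """
    if selection.n_atoms == 0:
        raise SelectionError("empty selection")
    coords, masses = _subset(traj, selection)
    if isinstance(reference, Structure):
        if reference.n_atoms == traj.n_atoms:
            ref = reference.coords[selection.indices]
        elif reference.n_atoms == selection.n_atoms:
            ref = reference.coords
        else:
            raise ValueError(
                f"reference has {reference.n_atoms} atoms; expected "
                f"{traj.n_atoms} (full table) or {selection.n_atoms} (selection)"
            )
    elif reference == "first_frame":
        ref = coords[0]
    else:
        raise ValueError(f"reference must be 'first_frame' or a Structure, got {reference!r}")

    weights = masses if mass_weighted else np.ones(selection.n_atoms)
    wnorm = weights / weights.sum()
    values = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        if fit:
            values[k] = kabsch_fit(coords[k], ref, weights).post_rmsd
        else:
            values[k] = float(np.sqrt(np.sum(wnorm[:, None] * (coords[k] - ref) ** 2)))

    if mean_window is None:
        mean_window = (float(traj.times[0]), float(traj.times[-1]))
    idx = _window_indices(traj.times, mean_window, 0.0, 1.0, min_frames=1)
    return RmsdSeries(
        times=traj.times.copy(),
        values=values,
        selection=selection,
        fitted=fit,
        mass_weighted=mass_weighted,
        mean_value=float(values[idx].mean()),
        mean_window=(float(mean_window[0]), float(mean_window[1])),
    )


def compute_rmsf(
    traj: Trajectory,
    selection: Selection,
    window: tuple[float, float] | None = None,
    fit: bool = True,
) -> RmsfProfile:
    """Per-atom RMSF about the window-mean positions.

    With fitting on, window frames are first superposed onto the first window
    frame, the mean structure is computed, and the frames are refit to that
    mean (one refinement pass); the refit mean positions are the reference.
    Default window: the last 2 ns, or the last 4% of the span for shorter
    trajectories.
    """
    if selection.n_atoms == 0:
        raise SelectionError("empty selection")
    idx = _window_indices(traj.times, window, RMSF_WINDOW_PS, RMSF_WINDOW_FRACTION, min_frames=2)
    coords, masses = _subset(traj, selection)
    sub = coords[idx]

    if fit:
        fitted = np.stack(
            [kabsch_fit(f, sub[0], masses).transform.apply(f) for f in sub]
        )
        mean0 = fitted.mean(axis=0)
        fitted = np.stack(
            [kabsch_fit(f, mean0, masses).transform.apply(f) for f in sub]
        )
        sub = fitted
    mean_pos = sub.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((sub - mean_pos) ** 2, axis=2), axis=0))
    t_lo, t_hi = float(traj.times[idx[0]]), float(traj.times[idx[-1]])
    return RmsfProfile(
        rmsf=rmsf,
        window=(t_lo, t_hi),
        reference_positions=mean_pos,
        averaging_time=t_hi - t_lo,
        selection=selection,
        fitted=fit,
    )


def rmsf_to_bfactor(profile: RmsfProfile) -> BFactorProfile:
    """Debye-Waller conversion B_i = (8/3) pi^2 RMSF_i^2 (A^2)."""
    return BFactorProfile(b=BFACTOR_PREFACTOR * profile.rmsf**2, source=profile)


def dihedral_from_points(p1, p2, p3, p4, collinear_tol: float = 1e-9):
    """Torsion angle (degrees, IUPAC sign, (-180, 180]) of ordered points.

    Accepts single points or stacked (F, 3) arrays.  The angle is measured
    between the p1-p2-p3 and p2-p3-p4 planes, positive for a clockwise
    rotation of p4 when sighting down p2->p3.
    """
    p1, p2, p3, p4 = (np.atleast_2d(np.asarray(p, float)) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm1 = np.linalg.norm(n1, axis=1)
    norm2 = np.linalg.norm(n2, axis=1)
    scale = max(
        float(np.max(np.linalg.norm(b1, axis=1) * np.linalg.norm(b2, axis=1))),
        float(np.max(np.linalg.norm(b2, axis=1) * np.linalg.norm(b3, axis=1))),
        1.0,
    )
    bad = np.flatnonzero((norm1 <= collinear_tol * scale) | (norm2 <= collinear_tol * scale))
    if len(bad):
        raise UndefinedAngleError(
            f"three consecutive points collinear at frame {int(bad[0])}; torsion undefined"
        )
    b2n = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(np.cross(n1, n2) * b2n, axis=1)
    ang = wrap_angle(np.degrees(np.arctan2(y, x)))
    return ang if np.ndim(ang) else np.array([ang])


def compute_pseudo_dihedral(
    traj: Trajectory, quadruple: QuadrupleSpec | None = None
) -> DihedralSeries:
    """Pseudo-dihedral of the quadruple's four atoms, per frame."""
    quadruple = quadruple or QuadrupleSpec()
    idx = quadruple.resolve(traj.atoms)
    pts = traj.frames[:, idx, :]
    angles = dihedral_from_points(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
    return DihedralSeries(
        times=traj.times.copy(),
        angles=np.asarray(angles, float),
        quadruple=quadruple,
        meta=dict(traj.meta),
    )


def summarize_angles(
    series: DihedralSeries,
    window: tuple[float, float] | None = None,
    bin_width: float = 1.0,
) -> AngleDistribution:
    """Histogram + circular summary of the in-window dihedral ensemble.

    The histogram grid is anchored at 0 degrees with the given bin width
    (default 1), spanning (-180, 180].  The "average" angle is reported both
    as the circular mean (default summary for directional data) and the
    arithmetic mean on the (-180, 180] branch, which coincide for tightly
    clustered distributions away from the branch cut.  Mode ties break
    toward the bin nearer the circular mean.
    """
    if bin_width <= 0 or not np.isclose(360.0 / bin_width, round(360.0 / bin_width)):
        raise ValueError("bin_width must be positive and divide 360")
    idx = _window_indices(series.times, window, ANGLE_WINDOW_PS, ANGLE_WINDOW_FRACTION, min_frames=1)
    angles = wrap_angle(series.angles[idx])

    n_bins = int(round(360.0 / bin_width))
    edges = -180.0 + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(angles, bins=edges)

    cmean = wrap_angle(float(circmean(angles, high=180.0, low=-180.0)))
    cstd = float(circstd(angles, high=180.0, low=-180.0))
    amean = float(np.mean(angles))

    centers = 0.5 * (edges[:-1] + edges[1:])
    max_count = counts.max()
    tied = np.flatnonzero(counts == max_count)
    if len(tied) == 1:
        mode_center = float(centers[tied[0]])
    else:
        circ_dist = np.abs(wrap_angle(centers[tied] - cmean))
        mode_center = float(centers[tied[np.argmin(circ_dist)]])

    t_lo, t_hi = float(series.times[idx[0]]), float(series.times[idx[-1]])
    return AngleDistribution(
        window=(t_lo, t_hi),
        bin_width=float(bin_width),
        edges=edges,
        counts=counts,
        arithmetic_mean=amean,
        circular_mean=cmean,
        circular_std=cstd,
        mode_bin_center=mode_center,
        n_frames=int(len(idx)),
    )


def compare_distributions(
    dist: AngleDistribution,
    reference: AngleDistribution,
    shift_tolerance: float = 1.0,
) -> DistributionShift:
    """Shift of ``dist`` relative to ``reference`` on a shared bin grid.

    Reports the circular-mean and mode displacements (wrapped differences,
    degrees), the ratio of circular standard deviations, and the overlap
    coefficient of the normalized histograms.  ``left_shifted`` is set when
    the circular mean moved below the reference by more than the tolerance.
    """
    if dist.edges.shape != reference.edges.shape or not np.allclose(dist.edges, reference.edges):
        raise ValueError("distributions are on different bin grids")
    delta_mean = float(wrap_angle(dist.circular_mean - reference.circular_mean))
    delta_mode = float(wrap_angle(dist.mode_bin_center - reference.mode_bin_center))
    ratio = float(dist.circular_std / reference.circular_std) if reference.circular_std > 0 else float("inf")
    overlap = float(np.sum(np.minimum(dist.density, reference.density)) * dist.bin_width)
    return DistributionShift(
        delta_circular_mean=delta_mean,
        delta_mode=delta_mode,
        circular_std_ratio=ratio,
        overlap=overlap,
        left_shifted=delta_mean < -shift_tolerance,
        shift_tolerance=shift_tolerance,
    )
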