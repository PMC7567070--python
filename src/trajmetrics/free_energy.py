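"""Free-energy differences from bidirectional nonequilibrium work samples.

Fast-growth alchemical protocols collect work values for switching a system
forward (coupling parameter lambda 0 -> 1) and backward (1 -> 0).  By the
Crooks fluctuation theorem the forward work distribution and the negated
backward work distribution cross exactly at the free-energy difference.  The
Crooks-Gaussian Intersection (CGI) estimator fits a Gaussian to each
distribution and returns the abscissa of their intersection; the Bennett
acceptance ratio (BAR) gives a maximum-likelihood estimate from the same
samples and serves as an independent cross-check.  In a double-system/
single-box setup (both legs of the thermodynamic cycle in one simulation
cell), the estimated quantity is directly the binding free-energy
difference ddG of a mutation; positive ddG destabilizes binding.

Units are kJ/mol throughout; kcal/mol input is converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .errors import ConvergenceError, WorkFileError

__all__ = [
    "KB_KJ_PER_MOL_K",
    "KCAL_TO_KJ",
    "WorkSet",
    "GaussianFitPair",
    "FreeEnergyEstimate",
    "DoubleDifference",
    "read_work_file",
    "fit_gaussians",
    "cgi_estimate",
    "bar_estimate",
    "bootstrap_error",
    "double_difference",
]

KB_KJ_PER_MOL_K = 0.0083144626
KCAL_TO_KJ = 4.184
DEFAULT_TEMPERATURE_K = 298.15

# Bhattacharyya overlap below this flags a meaningless intersection.
OVERLAP_WARN_THRESHOLD = 0.01
# Relative sigma difference below which the equal-variance closed form is used.
EQUAL_VARIANCE_RTOL = 1e-9


@dataclass
class WorkSet:
    """Forward (lambda 0->1) and backward (1->0) work samples, kJ/mol."""

    forward_work: np.ndarray
    backward_work: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE_K
    label: str = ""

    def __post_init__(self) -> None:
        self.forward_work = np.asarray(self.forward_work, dtype=float)
        self.backward_work = np.asarray(self.backward_work, dtype=float)
        for name, arr in (("forward", self.forward_work), ("backward", self.backward_work)):
            if arr.ndim != 1 or len(arr) < 2:
                raise ValueError(f"{name} direction needs >= 2 work values")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} work values must be finite")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")

    @property
    def beta(self) -> float:
        return 1.0 / (KB_KJ_PER_MOL_K * self.temperature)

    @property
    def n_forward(self) -> int:
        return len(self.forward_work)

    @property
    def n_backward(self) -> int:
        return len(self.backward_work)

    def reversed(self) -> "WorkSet":
        """Exchange the roles of the two end states.

        The old backward (1->0) works become the forward works of the
        reversed process and vice versa; by the Crooks relation the implied
        free-energy difference negates.
        """
        return WorkSet(
            forward_work=self.backward_work.copy(),
            backward_work=self.forward_work.copy(),
            temperature=self.temperature,
            label=self.label,
        )


@dataclass(frozen=True)
class GaussianFitPair:
    """Moments of the forward work and of the NEGATED backward work."""

    forward: tuple[float, float, int]
    reverse: tuple[float, float, int]


@dataclass
class FreeEnergyEstimate:
    """A dG estimate (kJ/mol) with optional bootstrap uncertainty."""

    dg: float
    method: str
    temperature: float
    n_forward: int
    n_backward: int
    stderr: float | None = None
    ci95: tuple[float, float] | None = None
    label: str = ""
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "method": self.method,
            "dg": self.dg,
            "stderr": self.stderr,
            "ci95": list(self.ci95) if self.ci95 is not None else None,
            "n_f": self.n_forward,
            "n_b": self.n_backward,
            "temperature": self.temperature,
            "diagnostics": self.diagnostics,
        }


@dataclass
class DoubleDifference:
    """ddG = dG1 - dG2 (kJ/mol); positive values destabilize binding."""

    ddg: float
    stderr: float | None
    mode: str
    legs: tuple[FreeEnergyEstimate, ...] = ()
    label: str = ""

    @property
    def destabilizing(self) -> bool:
        return self.ddg > 0

    @property
    def interpretation(self) -> str:
        return "destabilizing" if self.destabilizing else "stabilizing"


def read_work_file(path: str | Path, dialect: str = "two_column") -> WorkSet:
    """Read work samples from plain text.

    ``two_column`` dialect: rows ``work_f <value>`` / ``work_b <value>``,
    ``#`` comments, optional ``units=kJ/mol|kcal/mol`` header (bare or in a
    comment).  ``pmx_like`` dialect: ``path`` is a directory containing
    ``integA.dat`` (forward) and ``integB.dat`` (backward) with
    ``index value`` rows.
    """
    path = Path(path)
    if dialect == "pmx_like":
        fw = _read_index_value(path / "integA.dat")
        bw = _read_index_value(path / "integB.dat")
        return _build_workset(fw, bw, 1.0, path)
    if dialect != "two_column":
        raise ValueError(f"unknown dialect {dialect!r}")

    factor = 1.0
    forward, backward = [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip() if not raw.lstrip().startswith("#") else raw.lstrip()[1:].strip()
        if not line:
            continue
        if "units=" in line.replace(" ", ""):
            unit = line.replace(" ", "").split("units=", 1)[1].lower()
            if unit.startswith("kcal"):
                factor = KCAL_TO_KJ
            elif unit.startswith("kj"):
                factor = 1.0
            else:
                raise WorkFileError(f"{path}:{lineno}: unknown units {unit!r}")
            continue
        if raw.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2 or parts[0] not in ("work_f", "work_b"):
            raise WorkFileError(
                f"{path}:{lineno}: expected 'work_f <value>' or 'work_b <value>', got {raw!r}"
            )
        try:
            value = float(parts[1])
        except ValueError as exc:
            raise WorkFileError(f"{path}:{lineno}: bad work value {parts[1]!r}") from exc
        (forward if parts[0] == "work_f" else backward).append(value)
    return _build_workset(forward, backward, factor, path)


def _read_index_value(path: Path) -> list[float]:
    if not path.exists():
        raise WorkFileError(f"missing work file {path}")
    values = []
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise WorkFileError(f"{path}: expected 'index value' rows, got {raw!r}")
        values.append(float(parts[1]))
    return values


def _build_workset(forward, backward, factor, path) -> WorkSet:
    if len(forward) < 2 or len(backward) < 2:
        raise WorkFileError(
            f"{path}: need >= 2 work values per direction "
            f"(got {len(forward)} forward, {len(backward)} backward); "
            "the CGI estimator requires both directions"
        )
    return WorkSet(
        forward_work=np.asarray(forward) * factor,
        backward_work=np.asarray(backward) * factor,
        label=str(path),
    )


def fit_gaussians(ws: WorkSet) -> GaussianFitPair:
    """Sample mean and unbiased std of forward work and negated backward work."""
    fw = ws.forward_work
    rv = -ws.backward_work
    return GaussianFitPair(
        forward=(float(fw.mean()), float(fw.std(ddof=1)), len(fw)),
        reverse=(float(rv.mean()), float(rv.std(ddof=1)), len(rv)),
    )


def _bhattacharyya(mu_f, sigma_f, mu_r, sigma_r) -> float:
    if sigma_f == 0.0 and sigma_r == 0.0:
        return 1.0 if mu_f == mu_r else 0.0
    var = sigma_f**2 + sigma_r**2
    if sigma_f == 0.0 or sigma_r == 0.0:
        return 0.0
    return float(
        np.sqrt(2.0 * sigma_f * sigma_r / var) * np.exp(-((mu_f - mu_r) ** 2) / (4.0 * var))
    )


def cgi_estimate(
    ws: WorkSet,
    n_boot: int | None = None,
    seed: int | None = None,
) -> FreeEnergyEstimate:
    """Crooks-Gaussian Intersection estimate of dG.

    The forward work density and the negated-backward work density are each
    fit by a Gaussian; dG is the abscissa where the two densities intersect.
    Matched variances reduce to the closed-form midpoint (mu_F + mu_R) / 2.
    With unequal variances the log-density equality is a quadratic; among its
    real roots the one between the two means is taken (physically, the
    crossing inside the overlap region), falling back to the root nearest
    the midpoint with a recorded diagnostic.  Pass ``n_boot``/``seed`` to
    attach a bootstrap stderr and percentile CI.
    """
    pair = fit_gaussians(ws)
    mu_f, sigma_f, _ = pair.forward
    mu_r, sigma_r, _ = pair.reverse
    diagnostics: dict = {}

    overlap = _bhattacharyya(mu_f, sigma_f, mu_r, sigma_r)
    diagnostics["overlap_bhattacharyya"] = overlap
    if overlap < OVERLAP_WARN_THRESHOLD:
        diagnostics["overlap_warning"] = (
            f"work distributions barely overlap (Bhattacharyya {overlap:.2e}); "
            "the intersection may be meaningless"
        )
        warnings.warn(diagnostics["overlap_warning"], stacklevel=2)

    if abs(sigma_f - sigma_r) <= EQUAL_VARIANCE_RTOL * max(sigma_f, sigma_r, 1e-300):
        # Matched variances (includes the zero-dissipation delta limit).
        dg = 0.5 * (mu_f + mu_r)
        diagnostics["root_selection"] = "equal-variance midpoint"
    else:
        a = sigma_f**2 - sigma_r**2
        b = 2.0 * (mu_f * sigma_r**2 - mu_r * sigma_f**2)
        c = (
            mu_r**2 * sigma_f**2
            - mu_f**2 * sigma_r**2
            - 2.0 * sigma_f**2 * sigma_r**2 * np.log(sigma_f / sigma_r)
        )
        disc = b * b - 4.0 * a * c
        if disc < 0:  # cannot happen for distinct sigmas, guarded anyway
            dg = 0.5 * (mu_f + mu_r)
            diagnostics["root_selection"] = "no real root; midpoint fallback"
        else:
            roots = np.array([(-b + np.sqrt(disc)) / (2 * a), (-b - np.sqrt(disc)) / (2 * a)])
            lo, hi = min(mu_f, mu_r), max(mu_f, mu_r)
            inside = roots[(roots >= lo) & (roots <= hi)]
            if len(inside):
                mid = 0.5 * (mu_f + mu_r)
                dg = float(inside[np.argmin(np.abs(inside - mid))])
                diagnostics["root_selection"] = "root between the two means"
            else:
                mid = 0.5 * (mu_f + mu_r)
                dg = float(roots[np.argmin(np.abs(roots - mid))])
                diagnostics["root_selection"] = (
                    "no root between the means; nearest-to-midpoint fallback"
                )

    est = FreeEnergyEstimate(
        dg=float(dg),
        method="CGI",
        temperature=ws.temperature,
        n_forward=ws.n_forward,
        n_backward=ws.n_backward,
        label=ws.label,
        diagnostics=diagnostics,
    )
    if n_boot:
        stderr, ci95 = bootstrap_error(ws, estimator="CGI", n_boot=n_boot, seed=seed or 0)
        est.stderr, est.ci95 = stderr, ci95
    return est


def bar_estimate(ws: WorkSet, max_iter: int = 200) -> FreeEnergyEstimate:
    """Bennett acceptance-ratio estimate of dG (self-consistent solution).

    Solves sum_i f(beta (W_F,i - dG) + M) = sum_j f(beta (W_B,j + dG) - M)
    with f the Fermi function and M = ln(n_F / n_B), by bracketing and
    root-finding; the solution is unique because the balance is monotone
    in dG.
    """
    beta = ws.beta
    w_f = ws.forward_work
    w_b = ws.backward_work
    m = np.log(ws.n_forward / ws.n_backward)

    def fermi(x):
        return 1.0 / (1.0 + np.exp(np.clip(x, -500, 500)))

    def balance(dg):
        return float(
            np.sum(fermi(beta * (w_f - dg) + m)) - np.sum(fermi(beta * (w_b + dg) - m))
        )

    lo = float(min(w_f.min(), -w_b.max())) - 1.0
    hi = float(max(w_f.max(), -w_b.min())) + 1.0
    it = 0
    while balance(lo) > 0 and it < max_iter:
        lo -= 10.0 / beta
        it += 1
    while balance(hi) < 0 and it < max_iter:
        hi += 10.0 / beta
        it += 1
    if it >= max_iter or balance(lo) > 0 or balance(hi) < 0:
        raise ConvergenceError("BAR bracketing failed within iteration budget")
    if balance(lo) == 0.0:
        dg = lo
    elif balance(hi) == 0.0:
        dg = hi
    else:
        dg = brentq(balance, lo, hi, maxiter=max_iter, xtol=1e-10)
    return FreeEnergyEstimate(
        dg=float(dg),
        method="BAR",
        temperature=ws.temperature,
        n_forward=ws.n_forward,
        n_backward=ws.n_backward,
        label=ws.label,
    )


_ESTIMATORS = {"CGI": cgi_estimate, "BAR": bar_estimate}


def bootstrap_error(
    ws: WorkSet,
    estimator: str = "CGI",
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Bootstrap stderr and 95% percentile CI of a dG estimator.

    Each direction is resampled with replacement independently; the
    estimator is re-run per replicate.  Requires ``n_boot >= 100``; errors
    out if more than 10% of replicates fail.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for stable percentiles")
    est_fn = _ESTIMATORS[estimator.upper()]
    rng = np.random.default_rng(seed)
    replicates = []
    failures = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_boot):
            fw = rng.choice(ws.forward_work, size=ws.n_forward, replace=True)
            bw = rng.choice(ws.backward_work, size=ws.n_backward, replace=True)
            try:
                replicates.append(
                    est_fn(WorkSet(fw, bw, temperature=ws.temperature, label=ws.label)).dg
                )
            except Exception:
                failures += 1
    if failures > 0.1 * n_boot:
        raise ConvergenceError(
            f"{failures}/{n_boot} bootstrap replicates failed for {estimator}"
        )
    reps = np.asarray(replicates)
    stderr = float(reps.std(ddof=1))
    ci95 = (float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5)))
    return stderr, ci95


def double_difference(
    arg: WorkSet | tuple[FreeEnergyEstimate, FreeEnergyEstimate],
    n_boot: int | None = None,
    seed: int | None = None,
    label: str = "",
) -> DoubleDifference:
    """Binding ddG of a mutation.

    Single-box mode (one WorkSet from a double-system/single-box run): the
    CGI estimate is itself the ddG.  Two-leg mode (bound-state and free-state
    estimates): ddG = dG1 - dG2 with errors combined in quadrature.
    Positive ddG destabilizes binding; stabilizing mutations are negative.
    """
    if isinstance(arg, WorkSet):
        est = cgi_estimate(arg, n_boot=n_boot, seed=seed)
        return DoubleDifference(
            ddg=est.dg,
            stderr=est.stderr,
            mode="single_box",
            legs=(est,),
            label=label or arg.label,
        )
    try:
        leg1, leg2 = arg
    except (TypeError, ValueError) as exc:
        raise ValueError(
            "double_difference takes a single-box WorkSet or a pair of FreeEnergyEstimate"
        ) from exc
    if not (isinstance(leg1, FreeEnergyEstimate) and isinstance(leg2, FreeEnergyEstimate)):
        raise ValueError("two-leg mode needs two FreeEnergyEstimate objects")
    stderr = None
    if leg1.stderr is not None and leg2.stderr is not None:
        stderr = float(np.hypot(leg1.stderr, leg2.stderr))
    return DoubleDifference(
        ddg=float(leg1.dg - leg2.dg),
        stderr=stderr,
        mode="two_leg",
        legs=(leg1, leg2),
        label=label,
    )
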