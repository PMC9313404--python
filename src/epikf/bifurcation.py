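"""Equilibrium continuation and bifurcation detection for the neural mass model.

With the afferent input held at its mean, every equilibrium of the model
can be parameterized by the scalar pyramidal potential v = x2 - x3 - x4:
each state component is an explicit function of v, so fixed points are the
roots of a one-dimensional residual.  Sweeping the inhibition/excitation
ratio B/A and classifying stability from the Jacobian eigenvalues yields
the bifurcation structure that explains when the filter-based excitability
estimate is identifiable:

* an Andronov-Hopf (AH) point where the low branch loses stability and a
  limit cycle is born,
* a saddle-node (SN) fold where the stable equilibrium collides with an
  unstable one, and
* a saddle-saddle (SS) fold where two unstable equilibria merge.

Continuation here is a plain parameter sweep with per-ratio root finding;
the branch has simple fold structure so pseudo-arclength machinery is
unnecessary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .model import ModelParameters, N_MODEL_STATES, model_derivatives, simulate

__all__ = [
    "Equilibrium",
    "EquilibriumBranch",
    "find_equilibria",
    "continue_equilibria",
    "detect_bifurcations",
    "limit_cycle_envelope",
    "jacobian",
]


@dataclass
class Equilibrium:
    state: np.ndarray  # 11-component fixed point
    z_value: float  # x2 - x3 - x4 (mV)
    stable: bool
    leading_eigenvalue: complex  # eigenvalue with largest real part

    @property
    def stability(self) -> str:
        return "stable" if self.stable else "unstable"


@dataclass
class EquilibriumBranch:
    """Ordered sweep of equilibria versus B/A plus detected bifurcations."""

    ratios: np.ndarray
    equilibria: list[list[Equilibrium]]
    A: float
    params: ModelParameters
    bifurcations: list[tuple[str, float]] = field(default_factory=list)

    def counts(self) -> np.ndarray:
        return np.array([len(e) for e in self.equilibria])


def _sigmoid(v, p: ModelParameters):
    s = p.sigmoid
    return 2.0 * s.e_s / (1.0 + np.exp(s.h_s * (s.v_s - v)))


def _equilibrium_components(v, p: ModelParameters):
    """x1..x5 at equilibrium as functions of the pyramidal potential v."""
    A, B, G, a, b, g = p.A, p.B, p.G, p.a, p.b, p.g
    x1 = (A / a) * _sigmoid(v, p)
    x2 = (A / a) * (p.input_mean + p.C2 * _sigmoid(p.C1 * x1, p))
    x3 = (B / b) * p.C4 * _sigmoid(p.C3 * x1, p)
    x5 = (B / b) * _sigmoid(p.C3 * x1, p)
    x4 = (G / g) * p.C7 * _sigmoid(p.C5 * x1 - p.C6 * x5, p)
    return x1, x2, x3, x4, x5


def _residual(v, p: ModelParameters):
    _, x2, x3, x4, _ = _equilibrium_components(v, p)
    return x2 - x3 - x4 - v


def equilibrium_state(v: float, p: ModelParameters) -> np.ndarray:
    """Full 11-state fixed point for a root v of the reduced residual."""
    x1, x2, x3, x4, x5 = _equilibrium_components(v, p)
    x = np.zeros(N_MODEL_STATES)
    x[:5] = [x1, x2, x3, x4, x5]
    return x


def _dsigmoid(v, p: ModelParameters):
    s = p.sigmoid
    S = 2.0 * s.e_s / (1.0 + np.exp(s.h_s * (s.v_s - v)))
    return s.h_s * S * (1.0 - S / (2.0 * s.e_s))


def jacobian(x: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Analytic Jacobian of the 11-state vector field at ``x``."""
    x1, x2, x3, x4, x5 = x[:5]
    A, B, G, a, b, g = p.A, p.B, p.G, p.a, p.b, p.g
    J = np.zeros((N_MODEL_STATES, N_MODEL_STATES))
    for i in range(5):
        J[i, i + 5] = 1.0
    dS_v = _dsigmoid(x2 - x3 - x4, p)
    J[5, 1] = A * a * dS_v
    J[5, 2] = -A * a * dS_v
    J[5, 3] = -A * a * dS_v
    J[5, 0] = -a * a
    J[5, 5] = -2 * a
    J[6, 0] = A * a * p.C2 * p.C1 * _dsigmoid(p.C1 * x1, p)
    J[6, 1] = -a * a
    J[6, 6] = -2 * a
    J[7, 0] = B * b * p.C4 * p.C3 * _dsigmoid(p.C3 * x1, p)
    J[7, 2] = -b * b
    J[7, 7] = -2 * b
    dS_f = _dsigmoid(p.C5 * x1 - p.C6 * x5, p)
    J[8, 0] = G * g * p.C7 * p.C5 * dS_f
    J[8, 4] = -G * g * p.C7 * p.C6 * dS_f
    J[8, 3] = -g * g
    J[8, 8] = -2 * g
    J[9, 0] = B * b * p.C3 * _dsigmoid(p.C3 * x1, p)
    J[9, 4] = -b * b
    J[9, 9] = -2 * b
    J[10, 6] = 1.0
    J[10, 7] = -1.0
    J[10, 8] = -1.0
    J[10, 10] = -0.5
    return J


def find_equilibria(
    p: ModelParameters,
    v_range: tuple[float, float] = (-60.0, 60.0),
    n_grid: int = 4001,
) -> list[Equilibrium]:
    """All fixed points of the deterministic model (input at its mean).

    Roots of the scalar reduced residual are bracketed on a dense grid and
    polished with Brent's method; stability comes from the eigenvalues of
    the analytic Jacobian.
    """
    vs = np.linspace(*v_range, n_grid)
    res = _residual(vs, p)
    out: list[Equilibrium] = []
    for i in range(n_grid - 1):
        lo, hi = res[i], res[i + 1]
        if lo == 0.0:
            root = vs[i]
        elif lo * hi < 0:
            try:
                root = brentq(_residual, vs[i], vs[i + 1], args=(p,), xtol=1e-13, rtol=8.9e-16)
            except RuntimeError as err:  # pragma: no cover - brentq is robust here
                raise RuntimeError(
                    f"root polish failed in bracket [{vs[i]:.6f}, {vs[i + 1]:.6f}]"
                ) from err
        else:
            continue
        x = equilibrium_state(root, p)
        eig = np.linalg.eigvals(jacobian(x, p))
        lead = eig[np.argmax(eig.real)]
        out.append(
            Equilibrium(state=x, z_value=float(root), stable=bool(lead.real < 0),
                        leading_eigenvalue=complex(lead))
        )
    return out


def continue_equilibria(
    p_base: ModelParameters,
    ratio_range: tuple[float, float] = (1.0, 15.0),
    n_points: int = 1000,
) -> EquilibriumBranch:
    """Sweep B (A fixed) over ``ratio_range`` of B/A and collect equilibria."""
    lo, hi = ratio_range
    if not (0 < lo < hi <= 20):
        raise ValueError("ratio_range must satisfy 0 < lo < hi <= 20")
    if n_points < 100:
        raise ValueError("n_points must be at least 100")
    ratios = np.linspace(lo, hi, n_points)
    eqs = [find_equilibria(p_base.with_gains(B=r * p_base.A)) for r in ratios]
    branch = EquilibriumBranch(ratios=ratios, equilibria=eqs, A=p_base.A, params=p_base)
    return branch


def _count_at(ratio: float, p_base: ModelParameters) -> int:
    return len(find_equilibria(p_base.with_gains(B=ratio * p_base.A)))


def _hopf_indicator(ratio: float, p_base: ModelParameters, branch_pick) -> float:
    eqs = find_equilibria(p_base.with_gains(B=ratio * p_base.A))
    if not eqs:
        return np.nan
    eq = branch_pick(eqs)
    eig = np.linalg.eigvals(jacobian(eq.state, p_base.with_gains(B=ratio * p_base.A)))
    cplx = eig[np.abs(eig.imag) > 1e-9]
    if cplx.size == 0:
        return -np.inf
    return float(cplx.real.max())


def detect_bifurcations(branch: EquilibriumBranch, refine_tol: float = 1e-4) -> list[tuple[str, float]]:
    """Locate AH, SN and SS points on a continuation branch.

    Folds are found where the equilibrium count changes between adjacent
    sweep points and refined by bisection on the count; the fold is
    labelled SN when the merging pair contains a stable point and SS when
    both merging points are unstable.  The Hopf point is found where the
    real part of the leading complex-conjugate eigenvalue pair changes sign
    along a (count-preserving) stretch of the branch, refined by bisection.
    """
    p_base = branch.params
    ratios = branch.ratios
    counts = branch.counts()
    found: list[tuple[str, float]] = []

    # --- folds: equilibrium-count changes ---
    for i in range(len(ratios) - 1):
        if counts[i] == counts[i + 1]:
            continue
        lo, hi = float(ratios[i]), float(ratios[i + 1])
        n_lo = counts[i]
        while hi - lo > refine_tol:
            mid = 0.5 * (lo + hi)
            if _count_at(mid, p_base) == n_lo:
                lo = mid
            else:
                hi = mid
        fold = 0.5 * (lo + hi)
        # classify from the merging pair on the many-root side
        many = ratios[i] if counts[i] > counts[i + 1] else ratios[i + 1]
        eqs = branch.equilibria[i if counts[i] > counts[i + 1] else i + 1]
        zs = np.array([e.z_value for e in eqs])
        order = np.argsort(zs)
        gaps = np.diff(zs[order])
        j = int(np.argmin(gaps)) if gaps.size else 0
        pair = (eqs[order[j]], eqs[order[j + 1]]) if gaps.size else tuple(eqs[:2])
        kind = "SN" if any(e.stable for e in pair) else "SS"
        found.append((kind, float(fold)))

    # --- Andronov-Hopf: eigenvalue real-part crossing along matched branches ---
    def pick_nearest(z_ref):
        return lambda eqs: min(eqs, key=lambda e: abs(e.z_value - z_ref))

    for i in range(len(ratios) - 1):
        e_lo, e_hi = branch.equilibria[i], branch.equilibria[i + 1]
        if not e_lo or not e_hi or len(e_lo) != len(e_hi):
            continue
        z_lo = sorted(e.z_value for e in e_lo)
        for z_ref, eq_a in zip(z_lo, sorted(e_lo, key=lambda e: e.z_value)):
            eq_b = min(e_hi, key=lambda e: abs(e.z_value - z_ref))
            if eq_a.stable == eq_b.stable:
                # a complex pair may turn real or shuffle order without a
                # stability change; that is not a Hopf point
                continue
            a = _pair_real(eq_a, p_base.with_gains(B=ratios[i] * p_base.A))
            b = _pair_real(eq_b, p_base.with_gains(B=ratios[i + 1] * p_base.A))
            if not (np.isfinite(a) and np.isfinite(b)) or a * b >= 0:
                continue
            lo, hi = float(ratios[i]), float(ratios[i + 1])
            pick = pick_nearest(z_ref)
            while hi - lo > refine_tol:
                mid = 0.5 * (lo + hi)
                val = _hopf_indicator(mid, p_base, pick)
                if np.sign(val) == np.sign(a):
                    lo = mid
                else:
                    hi = mid
            found.append(("AH", 0.5 * (lo + hi)))

    # deduplicate (matched-branch scan can see the same crossing twice)
    dedup: list[tuple[str, float]] = []
    for kind, r in sorted(found, key=lambda t: t[1]):
        if not any(k == kind and abs(r - r0) < 10 * refine_tol for k, r0 in dedup):
            dedup.append((kind, r))
    branch.bifurcations = dedup
    return dedup


def _pair_real(eq: Equilibrium, p: ModelParameters) -> float:
    eig = np.linalg.eigvals(jacobian(eq.state, p))
    cplx = eig[np.abs(eig.imag) > 1e-9]
    return float(cplx.real.max()) if cplx.size else -np.inf


def limit_cycle_envelope(
    p_base: ModelParameters,
    ratio_range: tuple[float, float] = (1.0, 15.0),
    n_points: int = 60,
    *,
    sim_duration: float = 10.0,
    transient: float = 5.0,
    fs: float = 480.0,
) -> dict[str, np.ndarray]:
    """Per-ratio (min, max) of z over a noise-free run after transient decay.

    Trajectories start from a small perturbation of the lowest-lying
    equilibrium so unstable points are left and any attracting cycle is
    reached; where the low equilibrium is stable the envelope collapses to
    the fixed-point value.
    """
    from dataclasses import replace

    ratios = np.linspace(*ratio_range, n_points)
    z_min = np.empty(n_points)
    z_max = np.empty(n_points)
    for i, r in enumerate(ratios):
        p = replace(p_base.with_gains(B=r * p_base.A), input_sd=0.0)
        eqs = find_equilibria(p)
        x0 = eqs[0].state + 1e-3 if eqs else np.full(N_MODEL_STATES, 1e-3)
        z, _ = simulate(
            p, sim_duration - transient, fs, seed=0, burn_in=transient, x0=x0
        )
        z_min[i] = z.samples.min()
        z_max[i] = z.samples.max()
    return {"ratio": ratios, "z_min": z_min, "z_max": z_max}
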