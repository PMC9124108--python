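"""Population metaheuristic with attacker/barrier/chaser/driver roles.

Bound-constrained minimizer used to tune the ANFIS premise (and optionally
consequent) parameters.  The four best agents take hunting roles -- attacker,
barrier, chaser, driver -- and every agent moves to the mean of four
role-guided candidates

    d_k = |c_k * x_k - m_k * x|,   x_k' = x_k - a_k * d_k,

with a_k = 2*f*r1 - f, c_k = 2*r2, and m_k a chaotic value from a logistic
map.  The driving coefficient f decays nonlinearly from 2.5 to 0 over the
run (here f(t) = 2.5 * (1 - t/T)^2, which meets both endpoints), so the
search shifts from exploration to exploitation.  With f = 0 every agent
collapses onto the mean of the four role positions in a single step.

For ANFIS tuning the default "hybrid" mode searches only the premise
parameters and refits the linear consequents by least squares inside every
objective evaluation; "full" mode searches the complete flattened parameter
vector instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anfis import ANFISModel, fit_consequents_ls, predict_f
from .exceptions import DimensionMismatchError, InvalidConfigError

__all__ = [
    "CoaConfig",
    "CoaResult",
    "ChaoticStream",
    "f_schedule",
    "chaotic_step",
    "sample_coefficients",
    "drive_chase_update",
    "role_based_update",
    "optimize",
    "tune_anfis",
    "anfis_parameter_bounds",
]


@dataclass(frozen=True)
class CoaConfig:
    """Optimizer settings: population, iteration budget T, f start, bounds, seed."""

    population: int = 20
    max_iter: int = 100
    f_start: float = 2.5
    chaotic_seed: float = 0.7
    bounds: tuple = ((0.0, 1.0),)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 4:
            raise InvalidConfigError("population must be >= 4 (one agent per role)")
        if self.max_iter < 0:
            raise InvalidConfigError("max_iter must be >= 0")
        if not 0.0 < self.chaotic_seed < 1.0:
            raise InvalidConfigError("chaotic_seed must lie in (0,1)")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise InvalidConfigError("each bound must satisfy low < high")

    @property
    def lower(self) -> np.ndarray:
        return np.array([lo for lo, _ in self.bounds], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([hi for _, hi in self.bounds], dtype=float)


@dataclass
class CoaResult:
    best_x: np.ndarray
    best_value: float
    history: list[float] = field(default_factory=list)
    f_trace: list[float] = field(default_factory=list)


def f_schedule(t: float, T: int, f_start: float = 2.5) -> float:
    """Nonlinear decay f(t) = f_start * (1 - t/T)^2; f(0)=f_start, f(T)=0."""
    if T <= 0:
        raise InvalidConfigError("iteration budget T must be positive")
    frac = min(max(t / T, 0.0), 1.0)
    return f_start * (1.0 - frac) ** 2


def chaotic_step(m: float) -> float:
    """One raw logistic-map step m' = 4 m (1 - m); maps [0,1] into [0,1]."""
    return 4.0 * m * (1.0 - m)


class ChaoticStream:
    """Logistic-map value stream that resets to its seed when the state leaves
    the open interval (0,1), where the map would get stuck at 0."""

    def __init__(self, seed: float):
        if not 0.0 < seed < 1.0:
            raise InvalidConfigError("chaotic seed must lie in (0,1)")
        self.seed = seed
        self.state = seed

    def next(self) -> float:
        if not 0.0 < self.state < 1.0:
            self.state = self.seed
        value = chaotic_step(self.state)
        self.state = value
        return value


def sample_coefficients(f: float, rng: np.random.Generator, dim: int = 1):
    """a = 2*f*r1 - f in [-f, f]^dim and c = 2*r2 in [0, 2]^dim."""
    r1 = rng.uniform(size=dim)
    r2 = rng.uniform(size=dim)
    return 2.0 * f * r1 - f, 2.0 * r2


def drive_chase_update(
    x_chimp: np.ndarray,
    x_prey: np.ndarray,
    a: np.ndarray,
    c: np.ndarray,
    m: float,
    lower: np.ndarray | None = None,
    upper: np.ndarray | None = None,
) -> np.ndarray:
    """Single prey-relative move: x' = x_prey - a * |c*x_prey - m*x_chimp|."""
    x_chimp = np.asarray(x_chimp, dtype=float)
    x_prey = np.asarray(x_prey, dtype=float)
    if x_chimp.shape != x_prey.shape:
        raise DimensionMismatchError("agent and prey vectors differ in dimension")
    d = np.abs(c * x_prey - m * x_chimp)
    x_new = x_prey - a * d
    if lower is not None:
        x_new = np.clip(x_new, lower, upper)
    return x_new


def role_based_update(
    x: np.ndarray,
    roles: list[np.ndarray],
    f: float,
    chaos: ChaoticStream,
    rng: np.random.Generator,
    lower: np.ndarray,
    upper: np.ndarray,
) -> np.ndarray:
    """Move one agent to the mean of the four role-guided candidates."""
    x = np.asarray(x, dtype=float)
    if len(roles) != 4:
        raise InvalidConfigError("four role vectors (attacker..driver) required")
    dim = x.shape[0]
    cands = np.empty((4, dim))
    for k, xk in enumerate(roles):
        xk = np.asarray(xk, dtype=float)
        if xk.shape != x.shape:
            raise DimensionMismatchError("role vector dimension mismatch")
        a_k, c_k = sample_coefficients(f, rng, dim)
        m_k = chaos.next()
        d_k = np.abs(c_k * xk - m_k * x)
        cands[k] = xk - a_k * d_k
    return np.clip(cands.mean(axis=0), lower, upper)


def _safe_eval(objective, x: np.ndarray) -> float:
    value = float(objective(x))
    return value if np.isfinite(value) else np.inf


def optimize(
    objective,
    cfg: CoaConfig,
    init: np.ndarray | None = None,
) -> CoaResult:
    """Minimize ``objective`` over the bounded box.

    ``init`` optionally supplies row vectors placed at the start of the
    otherwise uniform initial population (used for warm starts).  The returned
    history is the best-so-far objective value after each iteration and is
    monotone non-increasing by elitist bookkeeping.
    """
    lower, upper = cfg.lower, cfg.upper
    dim = len(cfg.bounds)
    rng = np.random.default_rng(cfg.seed)
    pos = rng.uniform(lower, upper, size=(cfg.population, dim))
    if init is not None:
        init = np.atleast_2d(np.asarray(init, dtype=float))
        k = min(len(init), cfg.population)
        pos[:k] = np.clip(init[:k], lower, upper)

    values = np.array([_safe_eval(objective, p) for p in pos])
    best_i = int(np.argmin(values))
    best_x, best_val = pos[best_i].copy(), float(values[best_i])
    history, f_trace = [best_val], []
    if cfg.max_iter == 0:
        return CoaResult(best_x, best_val, history, f_trace)

    streams = [ChaoticStream(cfg.chaotic_seed) for _ in range(cfg.population)]
    for t in range(cfg.max_iter):
        order = np.argsort(values, kind="stable")
        roles = [pos[order[k]].copy() for k in range(4)]
        f = f_schedule(t, cfg.max_iter, cfg.f_start)
        f_trace.append(f)
        for i in range(cfg.population):
            pos[i] = role_based_update(pos[i], roles, f, streams[i], rng, lower, upper)
        values = np.array([_safe_eval(objective, p) for p in pos])
        it_best = int(np.argmin(values))
        if values[it_best] < best_val:
            best_val = float(values[it_best])
            best_x = pos[it_best].copy()
        history.append(best_val)
    return CoaResult(best_x, best_val, history, f_trace)


def write_trace(result: CoaResult, path) -> None:
    """Dump the convergence trace as delimited text (iteration, best, f)."""
    with open(path, "w") as fh:
        fh.write("iteration\tbest_objective\tf\n")
        for i, best in enumerate(result.history):
            f_val = repr(result.f_trace[i - 1]) if 0 < i <= len(result.f_trace) else ""
            fh.write(f"{i}\t{best!r}\t{f_val}\n")


def anfis_parameter_bounds(model: ANFISModel, X: np.ndarray, mode: str) -> list[tuple]:
    """Box bounds for the flattened ANFIS parameter vector.

    Centers c range over each input's observed range +/- 1 SD; widths a over
    [1e-3, 3 * input SD]; shapes b over [0.5, 5]; consequents (full mode only)
    over [-10, 10].
    """
    X = np.asarray(X, dtype=float)
    sd = np.maximum(X.std(axis=0), 1e-3)
    lo_x, hi_x = X.min(axis=0) - sd, X.max(axis=0) + sd
    r, d = model.n_rules, model.input_dim
    bounds: list[tuple] = []
    bounds += [(1e-3, 3.0 * sd[j]) for _ in range(r) for j in range(d)]   # a
    bounds += [(0.5, 5.0)] * (r * d)                                      # b
    bounds += [(lo_x[j], hi_x[j]) for _ in range(r) for j in range(d)]    # c
    if mode == "full":
        bounds += [(-10.0, 10.0)] * (r * d)                               # p
        bounds += [(-10.0, 10.0)] * r                                     # r0
    return bounds


def _flatten(model: ANFISModel, mode: str) -> np.ndarray:
    parts = [model.a.ravel(), model.b.ravel(), model.c.ravel()]
    if mode == "full":
        parts += [model.p.ravel(), model.r0.ravel()]
    return np.concatenate(parts)


def _unflatten(vec: np.ndarray, template: ANFISModel, mode: str) -> ANFISModel:
    r, d = template.n_rules, template.input_dim
    n = r * d
    out = template.copy()
    out.a = vec[:n].reshape(r, d)
    out.b = vec[n:2 * n].reshape(r, d)
    out.c = vec[2 * n:3 * n].reshape(r, d)
    if mode == "full":
        out.p = vec[3 * n:4 * n].reshape(r, d)
        out.r0 = vec[4 * n:4 * n + r]
    return out


def tune_anfis(
    model: ANFISModel,
    X: np.ndarray,
    y: np.ndarray,
    cfg: CoaConfig | None = None,
    mode: str = "hybrid",
) -> tuple[ANFISModel, CoaResult]:
    """Tune ANFIS parameters by role-based search; objective = training MSE.

    The incumbent parameter vector seeds the initial population, so combined
    with elitist bookkeeping the tuned model's training MSE never exceeds the
    initial model's (after its own consequent refit in hybrid mode).
    """
    if mode not in ("hybrid", "full"):
        raise InvalidConfigError(f"unknown tuning mode {mode!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    bounds = anfis_parameter_bounds(model, X, mode)
    if cfg is None:
        cfg = CoaConfig(bounds=tuple(bounds))
    else:
        cfg = CoaConfig(
            population=cfg.population, max_iter=cfg.max_iter, f_start=cfg.f_start,
            chaotic_seed=cfg.chaotic_seed, bounds=tuple(bounds), seed=cfg.seed,
        )

    def objective(vec: np.ndarray) -> float:
        cand = _unflatten(np.clip(vec, cfg.lower, cfg.upper), model, mode)
        if mode == "hybrid":
            cand = fit_consequents_ls(cand, X, y)
        resid = predict_f(cand, X) - y
        return float(np.mean(resid**2))

    x0 = np.clip(_flatten(model, mode), cfg.lower, cfg.upper)
    if cfg.max_iter == 0:  # degenerate budget: keep the incumbent parameters
        result = CoaResult(best_x=x0, best_value=objective(x0), history=[objective(x0)])
    else:
        result = optimize(objective, cfg, init=x0)
    tuned = _unflatten(result.best_x, model, mode)
    if mode == "hybrid":
        tuned = fit_consequents_ls(tuned, X, y)
    return tuned, result
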