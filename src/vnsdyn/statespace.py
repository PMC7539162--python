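"""Innovations-form LTI state-space models for stimulus-response data.

The model class is the discrete-time innovations form at 1 Hz,

    x[k+1] = A x[k] + B u[k - tau] + K e[k]
    y[k]   = C x[k] + e[k]

with scalar input u (stimulus amplitude), scalar output y (normalized
biomarker), latent state x of order M, integer dead time tau in samples,
and innovation e.  The direct feedthrough D is fixed at zero: the
stimulus never acts on the biomarker instantaneously.

Estimation follows the classical two-stage recipe: a non-iterative
subspace estimate (PO-MOESP family: block-Hankel matrices, an LQ
factorization, and an SVD) provides the initialization, which
prediction-error minimization then refines over a modal (real
block-diagonal) parameterization, optionally with a ridge penalty on the
free parameter vector.  Multi-record estimation concatenates records and
resets the predictor state to zero at record boundaries — records are
rest-normalized, so zero is the shared equilibrium.

Two model-evaluation primitives are exposed: the one-step-ahead
predictor (used for the fit metric and for training) and free simulation
with the innovations ignored (used for response-signature analysis).
The fit metric is the standard-deviation-normalized RMSE score

    fit% = (1 - ||y - yhat|| / ||y - mean(y)||) * 100,

with both norms over the same samples, so the mean predictor scores
exactly 0% and a perfect predictor 100%.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, signal

from .containers import AdministrationDataset, UniformSeries

__all__ = [
    "StateSpaceParams",
    "PredictionResult",
    "EstimationError",
    "shift_input",
    "subspace_estimate",
    "pem_refine",
    "ridge_regularize",
    "predict_one_step",
    "simulate",
    "fit_percent",
    "count_parameters",
    "InnovationsStateSpace",
    "InnovationsStateSpaceResults",
]

_STABILITY_MARGIN = 1e-6
_POLE_RADIUS_MAX = 1.0 - _STABILITY_MARGIN


class EstimationError(RuntimeError):
    """Raised when a model cannot be estimated from the data provided."""


# ---------------------------------------------------------------------------
# parameter container


@dataclass
class StateSpaceParams:
    """Parameters of an innovations-form model (D fixed at 0).

    ``structure`` records the modal block layout as a tuple of block
    sizes (1 for a real pole, 2 for a complex-conjugate pair); it is
    required for the modal parameterization used by the prediction-error
    refinement.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    K: np.ndarray
    dead_time: int = 0
    form: str = "modal"
    structure: tuple = ()

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.B = np.asarray(self.B, dtype=float).reshape(-1, 1)
        self.C = np.asarray(self.C, dtype=float).reshape(1, -1)
        self.K = np.asarray(self.K, dtype=float).reshape(-1, 1)
        m = self.A.shape[0]
        if self.A.shape != (m, m) or self.B.shape[0] != m or self.C.shape[1] != m \
                or self.K.shape[0] != m:
            raise ValueError("inconsistent state-space dimensions")
        if self.dead_time < 0:
            raise ValueError("dead time must be nonnegative")

    @property
    def order(self) -> int:
        return self.A.shape[0]

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.A))))

    def predictor_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.A - self.K @ self.C))))

    def dc_gain(self) -> float:
        """Steady-state output per unit constant input (noise-free)."""
        g = self.C @ np.linalg.solve(np.eye(self.order) - self.A, self.B)
        return float(g.item())

    def copy(self) -> "StateSpaceParams":
        return StateSpaceParams(
            self.A.copy(), self.B.copy(), self.C.copy(), self.K.copy(),
            self.dead_time, self.form, tuple(self.structure),
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "A": self.A.tolist(),
            "B": self.B.ravel().tolist(),
            "C": self.C.ravel().tolist(),
            "K": self.K.ravel().tolist(),
            "dead_time_s": int(self.dead_time),
            "form": self.form,
            "structure": list(self.structure),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StateSpaceParams":
        return cls(
            np.array(d["A"]), np.array(d["B"]), np.array(d["C"]),
            np.array(d["K"]), int(d["dead_time_s"]), d.get("form", "modal"),
            tuple(d.get("structure", ())),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "StateSpaceParams":
        return cls.from_dict(json.loads(s))


@dataclass
class PredictionResult:
    """One-step-ahead prediction of a single administration dataset."""

    predicted: np.ndarray
    residuals: np.ndarray
    fit_percent: float
    rmse: float
    sigma: float


# ---------------------------------------------------------------------------
# elementary operations


def shift_input(u: np.ndarray, dead_time: int) -> np.ndarray:
    """Delay ``u`` by ``dead_time`` samples with zero head-padding.

    Realizes u[k - tau]; the stimulus is zero before onset, so zero
    padding is exact rather than an approximation.
    """
    u = np.asarray(u, dtype=float)
    if dead_time == 0:
        return u
    out = np.zeros_like(u)
    out[dead_time:] = u[:-dead_time]
    return out


def fit_percent(y_true, y_pred) -> float:
    """Standard-deviation-normalized RMSE fit score in percent.

    ``(1 - ||y - yhat||_2 / ||y - mean(y)||_2) * 100`` with both norms
    over the same samples (population normalization), so that the mean
    predictor scores exactly 0%.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size < 2:
        raise ValueError("need at least 2 samples")
    denom = np.linalg.norm(y_true - y_true.mean())
    if denom == 0:
        raise ValueError("output standard deviation is zero; fit% undefined")
    return float((1.0 - np.linalg.norm(y_true - y_pred) / denom) * 100.0)


def count_parameters(order: int, form: str = "modal") -> int:
    """Free-parameter budget of an order-M modal-form model: 5M.

    Up to 2M slots for the state matrix (diagonal plus complex-pair
    couplings) plus M each for B, C, and K; D is fixed at zero.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if form != "modal":
        raise ValueError("parameter count defined for modal form")
    return 5 * order


def _predictor_tfs(params: StateSpaceParams):
    """Transfer functions of the one-step predictor driven by (u, y)."""
    abar = params.A - params.K @ params.C
    den = np.poly(abar)
    num_u = signal.ss2tf(abar, params.B, params.C, np.zeros((1, 1)))[0].ravel()
    num_y = signal.ss2tf(abar, params.K, params.C, np.zeros((1, 1)))[0].ravel()
    return num_u, num_y, den


def predict_one_step(params: StateSpaceParams, dataset: AdministrationDataset,
                     ) -> PredictionResult:
    """One-step-ahead prediction on a single record, started from x=0.

    Runs the innovations predictor
    ``xhat[k+1] = A xhat[k] + B u[k-tau] + K (y[k] - C xhat[k])``,
    ``yhat[k] = C xhat[k]`` and scores it with :func:`fit_percent`.
    With K = 0 the predictor coincides with free simulation.
    """
    y = dataset.y
    u = shift_input(dataset.u, params.dead_time)
    num_u, num_y, den = _predictor_tfs(params)
    yhat = signal.lfilter(num_u, den, u) + signal.lfilter(num_y, den, y)
    resid = y - yhat
    sigma = float(np.std(y))
    if sigma == 0:
        raise ValueError("output standard deviation is zero; fit% undefined")
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    return PredictionResult(
        predicted=yhat, residuals=resid,
        fit_percent=float((1.0 - rmse / sigma) * 100.0),
        rmse=rmse, sigma=sigma,
    )


def simulate(params: StateSpaceParams, input_series, x0=None) -> UniformSeries:
    """Noise-free simulation: solve the difference equations forward.

    The innovation terms (Ke and e) are ignored; from a zero initial
    state under zero input the output is identically zero (the system
    starts at, and remains at, its equilibrium).
    """
    if isinstance(input_series, UniformSeries):
        u = input_series.values
        start, fs = input_series.start_time_s, input_series.fs
    else:
        u = np.asarray(input_series, dtype=float)
        start, fs = 0.0, 1.0
    if params.spectral_radius() >= 1.0:
        warnings.warn("simulating an unstable model", RuntimeWarning)
    ush = shift_input(u, params.dead_time)
    num = signal.ss2tf(params.A, params.B, params.C, np.zeros((1, 1)))[0].ravel()
    den = np.poly(params.A)
    y = signal.lfilter(num, den, ush)
    if x0 is not None:
        x0 = np.asarray(x0, dtype=float).reshape(-1)
        if np.any(x0 != 0):
            # initial-condition response added by explicit recursion
            n = len(u)
            yx = np.empty(n)
            x = x0.copy()
            for k in range(n):
                yx[k] = float((params.C @ x).item())
                x = params.A @ x
            y = y + yx
    return UniformSeries(values=y, start_time_s=start, fs=fs)


# ---------------------------------------------------------------------------
# modal parameterization

def _modal_realization(A, B, C, K):
    """Similarity-transform (A,B,C,K) to real modal (block-diagonal) form.

    Poles are sorted by descending magnitude then phase (ties broken by
    phase sign); complex pairs become 2x2 blocks [[s, w], [-w, s]].
    """
    A = np.atleast_2d(A)
    m = A.shape[0]
    lam, V = np.linalg.eig(A)
    order_idx = np.lexsort((np.sign(np.angle(lam)), np.abs(np.angle(lam)),
                            -np.abs(lam)))
    lam = lam[order_idx]
    V = V[:, order_idx]

    T = np.zeros((m, m))
    structure = []
    i = 0
    while i < m:
        if abs(lam[i].imag) < 1e-10:
            T[:, i] = V[:, i].real
            structure.append(1)
            i += 1
        else:
            # conjugate partner is adjacent after sorting
            v = V[:, i]
            T[:, i] = v.real
            T[:, i + 1] = v.imag
            structure.append(2)
            i += 2
    if np.linalg.cond(T) > 1e12:
        raise EstimationError("state matrix is numerically defective; "
                              "modal form unavailable")
    Am = np.linalg.solve(T, A @ T)
    # zero out coupling entries that are numerically spurious
    Amc = np.zeros_like(Am)
    i = 0
    for b in structure:
        Amc[i:i + b, i:i + b] = Am[i:i + b, i:i + b]
        i += b
    Bm = np.linalg.solve(T, np.asarray(B).reshape(-1, 1))
    Cm = np.asarray(C).reshape(1, -1) @ T
    Km = np.linalg.solve(T, np.asarray(K).reshape(-1, 1))
    return Amc, Bm, Cm, Km, tuple(structure)


def _pack_theta(params: StateSpaceParams) -> np.ndarray:
    th = []
    i = 0
    for b in params.structure:
        if b == 1:
            th.append(params.A[i, i])
        else:
            th.append(params.A[i, i])      # sigma
            th.append(params.A[i, i + 1])  # omega
        i += b
    th.extend(params.B.ravel())
    th.extend(params.C.ravel())
    th.extend(params.K.ravel())
    return np.array(th, dtype=float)


def _unpack_theta(theta, structure, dead_time) -> StateSpaceParams:
    m = sum(structure)
    A = np.zeros((m, m))
    j = 0
    i = 0
    for b in structure:
        if b == 1:
            a = np.clip(theta[j], -_POLE_RADIUS_MAX, _POLE_RADIUS_MAX)
            A[i, i] = a
            j += 1
        else:
            s, w = theta[j], theta[j + 1]
            r = np.hypot(s, w)
            if r > _POLE_RADIUS_MAX:
                s, w = s * _POLE_RADIUS_MAX / r, w * _POLE_RADIUS_MAX / r
            A[i, i] = A[i + 1, i + 1] = s
            A[i, i + 1] = w
            A[i + 1, i] = -w
            j += 2
        i += b
    B = theta[j:j + m]
    C = theta[j + m:j + 2 * m]
    K = theta[j + 2 * m:j + 3 * m]
    return StateSpaceParams(A, B, C, K, dead_time, "modal", tuple(structure))


# ---------------------------------------------------------------------------
# subspace identification


def _as_dataset_list(datasets):
    if isinstance(datasets, AdministrationDataset):
        return [datasets]
    return list(datasets)


def _hankel(x, n_rows, n_cols):
    idx = np.arange(n_rows)[:, None] + np.arange(n_cols)[None, :]
    return x[idx]


def subspace_estimate(datasets, order: int, dead_time: int = 0,
                      horizon: int | None = None) -> StateSpaceParams:
    """Initial model estimate by subspace identification (PO-MOESP).

    Block-Hankel matrices are built per record (after delaying the input
    by ``dead_time``) and concatenated column-wise, an LQ factorization
    isolates the part of the future outputs explained by past data, and
    the SVD of that block yields the extended observability matrix, from
    which A and C follow by shift invariance.  B is then obtained by
    linear least squares on the simulated response (with free initial
    states per record, discarded afterwards).  K is initialized at zero
    and left to the prediction-error refinement.

    Deterministic for fixed inputs.  Raises :class:`EstimationError`
    when the data do not excite the requested order.
    """
    datasets = _as_dataset_list(datasets)
    if order < 1:
        raise ValueError("order must be >= 1")
    n_total = sum(d.n_samples for d in datasets)
    n_free = count_parameters(order)
    if n_total <= 10 * n_free:
        raise EstimationError(
            f"too few samples ({n_total}) for order {order}: need more than "
            f"10x the {n_free} free parameters")

    for d in datasets:
        if np.std(shift_input(d.u, dead_time)) == 0:
            raise EstimationError(
                f"input of dataset {d.label() or '<unnamed>'} is unexcited "
                "(zero variance after the dead-time shift)")

    min_len = min(d.n_samples for d in datasets)
    i = horizon if horizon is not None else max(order + 3, 6)
    i = min(i, min_len // 3)
    if i < order + 1:
        raise EstimationError("records too short for the requested order")

    u_blocks, y_blocks = [], []
    for d in datasets:
        u = shift_input(d.u, dead_time)
        y = d.y
        n_cols = d.n_samples - 2 * i + 1
        if n_cols < 1:
            continue
        u_blocks.append(_hankel(u, 2 * i, n_cols))
        y_blocks.append(_hankel(y, 2 * i, n_cols))
    U = np.hstack(u_blocks)
    Y = np.hstack(y_blocks)
    Up, Uf = U[:i], U[i:]
    Yp, Yf = Y[:i], Y[i:]

    # LQ factorization of [Uf; Up; Yp; Yf]
    Z = np.vstack([Uf, Up, Yp, Yf])
    _, R = np.linalg.qr(Z.T)
    L = R.T  # lower triangular, 4i x 4i
    G = L[3 * i:, i:3 * i]  # future outputs vs past data, input-future removed
    sv_u, sv, _ = np.linalg.svd(G, full_matrices=False)
    if sv[0] < 1e-12:
        raise EstimationError("data carry no excitation (all singular values ~0)")
    if order > i or sv[order - 1] / sv[0] < 1e-10:
        raise EstimationError(
            f"insufficient excitation for order {order}: singular-value gap "
            f"{sv[min(order, len(sv)) - 1] / sv[0]:.2e}")
    gamma = sv_u[:, :order] * np.sqrt(sv[:order])
    C = gamma[:1, :]
    A, *_ = np.linalg.lstsq(gamma[:-1], gamma[1:], rcond=None)

    # clamp unstable subspace estimates back inside the unit disk
    eigs = np.linalg.eigvals(A)
    rho = np.max(np.abs(eigs))
    if rho >= 1.0:
        A = A * (_POLE_RADIUS_MAX / rho)

    # B (shared) and per-record x0 (discarded) by least squares on the output
    n_rec = len(datasets)
    rows_y = np.concatenate([d.y for d in datasets])
    # impulse-response basis: response to B = e_j
    obs = [C.ravel()]
    Ak = A.copy()
    max_n = max(d.n_samples for d in datasets)
    for _ in range(max_n - 1):
        obs.append((C @ Ak).ravel())
        Ak = A @ Ak
    obs = np.array(obs)  # (max_n, order): row k = C A^k
    regs = []
    for d in datasets:
        u = shift_input(d.u, dead_time)
        n = d.n_samples
        # columns for B entries: conv(u, h_j) where h_j = [0, C e_j, C A e_j, ...]
        bu = np.zeros((n, order))
        for jx in range(order):
            h = np.concatenate([[0.0], obs[: n - 1, jx]])
            bu[:, jx] = np.convolve(u, h)[:n]
        regs.append((bu, obs[:n]))
    rows = []
    for r, (bu, ob) in enumerate(regs):
        x0block = np.zeros((bu.shape[0], order * n_rec))
        x0block[:, r * order:(r + 1) * order] = ob
        rows.append(np.hstack([bu, x0block]))
    Phi = np.vstack(rows)
    sol, *_ = np.linalg.lstsq(Phi, rows_y, rcond=None)
    B = sol[:order]

    K = np.zeros(order)
    Am, Bm, Cm, Km, structure = _modal_realization(A, B, C, K)
    return StateSpaceParams(Am, Bm, Cm, Km, dead_time, "modal", structure)


# ---------------------------------------------------------------------------
# prediction-error minimization


def _stack_records(datasets, dead_time):
    us = [shift_input(d.u, dead_time) for d in datasets]
    ys = [d.y for d in datasets]
    return us, ys


def _pem_residuals(theta, structure, dead_time, us, ys, sqrt_lam):
    p = _unpack_theta(theta, structure, dead_time)
    num_u, num_y, den = _predictor_tfs(p)
    with np.errstate(over="ignore", invalid="ignore"):
        res = [y - (signal.lfilter(num_u, den, u)
                    + signal.lfilter(num_y, den, y))
               for u, y in zip(us, ys)]
        res = np.concatenate(res)
    if sqrt_lam > 0:
        res = np.concatenate([res, sqrt_lam * np.asarray(theta)])
    # a transiently unstable predictor (A - KC outside the unit disk)
    # can overflow the recursion; report a large finite residual so the
    # trust-region step is rejected rather than poisoned by NaN/inf
    return np.nan_to_num(res, nan=1e150, posinf=1e150, neginf=-1e150)


def _enforce_predictor_stability(params: StateSpaceParams) -> StateSpaceParams:
    """Shrink K toward zero until the predictor matrix A - KC is stable."""
    if params.predictor_radius() < 1.0:
        return params
    warnings.warn("unstable predictor after estimation; shrinking K",
                  RuntimeWarning)
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        trial = params.copy()
        trial.K = params.K * mid
        if trial.predictor_radius() < _POLE_RADIUS_MAX:
            lo = mid
        else:
            hi = mid
    params = params.copy()
    params.K = params.K * lo
    return params


def pem_refine(init: StateSpaceParams, datasets, ridge_lambda: float = 0.0,
               max_iter: int = 400, tol: float = 1e-9) -> StateSpaceParams:
    """Refine a model by prediction-error minimization.

    Minimizes the summed squared one-step-ahead prediction error across
    all records over the modal-form free parameters (plus an optional
    ridge penalty ``ridge_lambda * ||theta||^2``), starting from
    ``init``.  ``max_iter`` bounds the trust-region iterations.  Pole
    magnitudes are projected inside the unit disk at every evaluation;
    the predictor matrix is stabilized afterwards.  The returned model
    never has a worse penalized objective than the initialization (on
    optimizer failure the initialization is returned with a warning).
    """
    datasets = _as_dataset_list(datasets)
    if init.form != "modal" or not init.structure:
        Am, Bm, Cm, Km, structure = _modal_realization(init.A, init.B, init.C,
                                                       init.K)
        init = StateSpaceParams(Am, Bm, Cm, Km, init.dead_time, "modal",
                                structure)
    us, ys = _stack_records(datasets, init.dead_time)
    sqrt_lam = float(np.sqrt(ridge_lambda))
    theta0 = _pack_theta(init)
    args = (init.structure, init.dead_time, us, ys, sqrt_lam)
    obj0 = float(np.sum(_pem_residuals(theta0, *args) ** 2))

    # an initialization already at machine-precision fit needs no polish
    scale = sum(float(np.sum(y ** 2)) for y in ys)
    if obj0 <= 1e-14 * max(scale, 1e-300):
        return _enforce_predictor_stability(init)

    try:
        sol = optimize.least_squares(
            _pem_residuals, theta0, args=args, method="trf",
            ftol=tol, xtol=tol, gtol=tol, x_scale="jac",
            max_nfev=max_iter,
        )
        theta = sol.x
    except Exception as exc:  # pragma: no cover - optimizer failure path
        warnings.warn(f"prediction-error minimization failed ({exc}); "
                      "keeping the initialization", RuntimeWarning)
        return init

    obj1 = float(np.sum(_pem_residuals(theta, *args) ** 2))
    if not np.isfinite(obj1) or obj1 > obj0:
        warnings.warn("refinement did not improve the objective; "
                      "keeping the initialization", RuntimeWarning)
        return _enforce_predictor_stability(init)
    out = _unpack_theta(theta, init.structure, init.dead_time)
    return _enforce_predictor_stability(out)


def ridge_regularize(model: StateSpaceParams, datasets, ridge_lambda: float,
                     **kw) -> StateSpaceParams:
    """Re-solve the prediction-error objective with a ridge penalty.

    ``ridge_lambda = 0`` reproduces the unregularized model exactly; as
    the penalty grows the free parameter vector shrinks toward zero and
    the predicted output toward the rest baseline.
    """
    if ridge_lambda < 0:
        raise ValueError("ridge penalty must be nonnegative")
    if ridge_lambda == 0:
        return model.copy()
    return pem_refine(model, datasets, ridge_lambda=ridge_lambda, **kw)


# ---------------------------------------------------------------------------
# statsmodels-style model / results


class InnovationsStateSpace:
    """Innovations-form state-space model of biomarker response dynamics.

    Parameters
    ----------
    datasets : AdministrationDataset or list thereof
        Training records (input/output pairs on a shared 1 Hz grid).
    order : int
        Model order M.
    dead_time : int
        Input dead time tau in samples (seconds at 1 Hz).
    ridge : float
        Ridge penalty on the modal free-parameter vector (0 = none).

    Examples
    --------
    >>> model = InnovationsStateSpace(datasets, order=2, dead_time=15)
    >>> res = model.fit()
    >>> res.fit_percents
    """

    def __init__(self, datasets, order: int, dead_time: int = 0,
                 ridge: float = 0.0):
        self.datasets = _as_dataset_list(datasets)
        if not self.datasets:
            raise ValueError("at least one training dataset is required")
        self.order = int(order)
        self.dead_time = int(dead_time)
        self.ridge = float(ridge)

    def fit(self, refine: bool = True, **pem_kw) -> "InnovationsStateSpaceResults":
        params = subspace_estimate(self.datasets, self.order, self.dead_time)
        if refine:
            params = pem_refine(params, self.datasets, **pem_kw)
        if self.ridge > 0:
            params = ridge_regularize(params, self.datasets, self.ridge,
                                      **pem_kw)
        return InnovationsStateSpaceResults(self, params)


class InnovationsStateSpaceResults:
    """Fitted innovations-form model with training diagnostics."""

    def __init__(self, model: InnovationsStateSpace, params: StateSpaceParams):
        self.model = model
        self.params = params
        self._train = [predict_one_step(params, d) for d in model.datasets]

    @property
    def fit_percents(self) -> np.ndarray:
        """Training one-step fit% per record."""
        return np.array([t.fit_percent for t in self._train])

    @property
    def sse(self) -> float:
        """Pooled one-step squared prediction error over training records."""
        return float(sum(np.sum(t.residuals ** 2) for t in self._train))

    @property
    def n_obs(self) -> int:
        return sum(d.n_samples for d in self.model.datasets)

    @property
    def n_params(self) -> int:
        return count_parameters(self.params.order)

    def predict(self, dataset: AdministrationDataset) -> PredictionResult:
        return predict_one_step(self.params, dataset)

    def simulate(self, input_series, x0=None) -> UniformSeries:
        return simulate(self.params, input_series, x0=x0)

    def summary(self) -> str:
        p = self.params
        poles = np.linalg.eigvals(p.A)
        lines = [
            "Innovations-form state-space model",
            "=" * 44,
            f"order (M)            {p.order}",
            f"dead time (tau)      {p.dead_time} s",
            f"ridge penalty        {self.model.ridge:g}",
            f"n obs / n params     {self.n_obs} / {self.n_params}",
            f"DC gain              {p.dc_gain():+.4f}",
            f"pole magnitudes      "
            + ", ".join(f"{abs(z):.4f}" for z in poles),
            f"predictor radius     {p.predictor_radius():.4f}",
            f"train 1-step SSE     {self.sse:.4e}",
            "train fit% per record "
            + ", ".join(f"{f:.2f}" for f in self.fit_percents),
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (f"<InnovationsStateSpaceResults order={self.params.order} "
                f"tau={self.params.dead_time} sse={self.sse:.3e}>")
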