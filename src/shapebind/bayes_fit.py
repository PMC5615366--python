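"""Evidence-regularized fitting of affinity models.

The fit minimizes the regularized cost

    L = beta * LD + sum_i alpha_i * W_i**2,
    LD = 1/2 * sum_i (a * P(S_i) + b - t_i)**2

by gradient descent with Armijo backtracking, alternating with Bayesian
evidence updates of the grouped L2 hyperparameters::

    gamma_i = 1 - alpha_i * (H^-1)_ii      (effective parameter counts)
    alpha_group = gamma_group / sum_{i in group} W_i**2
    beta = (n_data - sum(gamma)) / (2 * LD)

where H is the curvature of L at the converged parameters.  The exact
Hessian is replaced by the Gauss-Newton form H = beta * G^T G +
2 * diag(alpha) (G = per-sequence prediction gradients), which is the
standard positive-semidefinite surrogate in evidence-framework
regression.  Hyperparameters are grouped: all entries of ``w`` share one
``alpha_w``; dependency weights at the same motif position share one
``alpha_d[p]``; the auxiliary parameters (mu, a, b) share ``alpha_aux``.

Fitting is two-stage: the independent model (w, mu, a, b) first, then
with w and mu frozen, the dependency correction (d or df) together with
a re-calibrated (a, b).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np

from .affinity_model import (
    AffinityModel,
    DinucCorrection,
    IndependentModel,
    ShapeCorrection,
    stable_sigmoid,
    window_code_tensor,
)
from .seq_encoding import TrainingSet
from .shape_features import ShapeFeatureTable

Stage = Literal["full", "independent", "correction"]


@dataclass
class FitConfig:
    """Optimizer and initialization constants (none are data-derived)."""

    max_outer: int = 10
    outer_tol: float = 1e-4
    max_gd_steps: int = 1500   # descent iterations per phase
    gd_tol: float = 1e-9       # relative cost-change tolerance (ftol)
    gd_grad_tol: float = 1e-10
    lbfgs_memory: int = 20
    init_alpha: float = 1e-6   # weak regularization on the first iteration
    init_beta: float = 1.0
    alpha_max: float = 1e6     # cap for degenerate (all-zero) groups
    beta_max: float = 1e12     # cap when the fit is numerically perfect
    hyper_tol: float = 1e-4
    hyper_max_iter: int = 100
    init_scale: float = 0.1    # w ~ uniform(-init_scale, init_scale) for init="random"
    seed_energy: float = 2.0   # non-consensus penalty for the enrichment seed
    seed_core: int = 8         # k-mer length used by the enrichment seed


@dataclass
class RegularizationState:
    """Grouped L2 hyperparameters and the error scale beta.

    ``alpha_w`` is shared by every entry of ``w``; ``alpha_d[p]`` is
    shared by all dependency weights at motif position ``p``;
    ``alpha_aux`` covers (mu, a, b).  ``gamma`` holds per-parameter
    effective-parameter numbers from the last evidence update, in the
    layout order of the stage it was computed for.
    """

    beta: float = 1.0
    alpha_w: float = 0.0
    alpha_d: Optional[np.ndarray] = None
    alpha_aux: float = 0.0
    gamma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.alpha_w < 0 or self.alpha_aux < 0:
            raise ValueError("alpha values must be >= 0")
        if self.alpha_d is not None:
            self.alpha_d = np.asarray(self.alpha_d, dtype=float)
            if np.any(self.alpha_d < 0):
                raise ValueError("alpha values must be >= 0")


@dataclass
class FitResult:
    """Outcome of a fitting run."""

    model: AffinityModel
    reg: RegularizationState
    trace: list[dict]
    converged: bool
    seed: int
    retained: Optional[bool] = None


# ---------------------------------------------------------------------------
# Parameter layout: mapping between model objects and flat vectors


@dataclass(frozen=True)
class ParameterLayout:
    """Blocks of the flat parameter vector and their hyperparameter groups."""

    blocks: tuple[tuple[str, tuple[int, ...]], ...]
    group_ids: np.ndarray          # per-parameter group index
    group_names: tuple[str, ...]   # group index -> name

    @property
    def n_params(self) -> int:
        return int(self.group_ids.size)

    def slices(self) -> dict[str, slice]:
        out, pos = {}, 0
        for name, shape in self.blocks:
            size = int(np.prod(shape)) if shape else 1
            out[name] = slice(pos, pos + size)
            pos += size
        return out


def _make_layout(M: int, corr_cols: int | None, stage: Stage) -> ParameterLayout:
    blocks: list[tuple[str, tuple[int, ...]]] = []
    groups: list[np.ndarray] = []
    names: list[str] = []

    def add_group(name: str) -> int:
        names.append(name)
        return len(names) - 1

    if stage in ("full", "independent"):
        blocks.append(("w", (M, 4)))
        gid = add_group("w")
        groups.append(np.full(M * 4, gid))
    if corr_cols is not None and stage in ("full", "correction"):
        blocks.append(("corr", (M - 1, corr_cols)))
        ids = np.empty((M - 1) * corr_cols, dtype=int)
        for p in range(M - 1):
            gid = add_group(f"d{p}")
            ids[p * corr_cols : (p + 1) * corr_cols] = gid
        groups.append(ids)
    aux_gid = add_group("aux")
    if stage in ("full", "independent"):
        blocks.append(("mu", ()))
        groups.append(np.array([aux_gid]))
    blocks.append(("a", ()))
    blocks.append(("b", ()))
    groups.append(np.array([aux_gid, aux_gid]))
    return ParameterLayout(
        blocks=tuple(blocks),
        group_ids=np.concatenate(groups),
        group_names=tuple(names),
    )


def parameter_layout(model: AffinityModel, stage: Stage = "full") -> ParameterLayout:
    corr_cols = None
    if isinstance(model.correction, DinucCorrection):
        corr_cols = 16
    elif isinstance(model.correction, ShapeCorrection):
        corr_cols = model.correction.table.K
    return _make_layout(model.M, corr_cols, stage)


def pack_parameters(model: AffinityModel, stage: Stage = "full") -> np.ndarray:
    parts = []
    if stage in ("full", "independent"):
        parts.append(model.independent.w.ravel())
    if model.correction is not None and stage in ("full", "correction"):
        if isinstance(model.correction, ShapeCorrection):
            parts.append(model.correction.df.ravel())
        else:
            parts.append(model.correction.d.ravel())
    if stage in ("full", "independent"):
        parts.append([model.independent.mu])
    parts.append([model.a, model.b])
    return np.concatenate([np.asarray(p, dtype=float).ravel() for p in parts])


def unpack_parameters(
    theta: np.ndarray, template: AffinityModel, stage: Stage = "full"
) -> AffinityModel:
    layout = parameter_layout(template, stage)
    sl = layout.slices()
    M = template.M
    w = template.independent.w
    mu = template.independent.mu
    if "w" in sl:
        w = theta[sl["w"]].reshape(M, 4)
    if "mu" in sl:
        mu = float(theta[sl["mu"]][0])
    correction = template.correction
    if "corr" in sl and correction is not None:
        if isinstance(correction, ShapeCorrection):
            K = correction.table.K
            correction = ShapeCorrection(
                df=theta[sl["corr"]].reshape(M - 1, K), table=correction.table
            )
        else:
            correction = DinucCorrection(d=theta[sl["corr"]].reshape(M - 1, 16))
    return AffinityModel(
        independent=IndependentModel(w=w, mu=mu),
        correction=correction,
        a=float(theta[sl["a"]][0]),
        b=float(theta[sl["b"]][0]),
        scan_both_strands=template.scan_both_strands,
    )


def _alpha_vector(reg: RegularizationState, layout: ParameterLayout) -> np.ndarray:
    per_group = np.empty(len(layout.group_names))
    for gid, name in enumerate(layout.group_names):
        if name == "w":
            per_group[gid] = reg.alpha_w
        elif name == "aux":
            per_group[gid] = reg.alpha_aux
        else:
            p = int(name[1:])
            if reg.alpha_d is None:
                raise ValueError("reg.alpha_d is required for dependency groups")
            per_group[gid] = reg.alpha_d[p]
    return per_group[layout.group_ids]


# ---------------------------------------------------------------------------
# Scan workspace: precomputed window codes and vectorized passes


class ScanWorkspace:
    """Precomputed scan-window codes of a training set for one motif size."""

    def __init__(
        self,
        data: TrainingSet,
        M: int,
        both_strands: bool = True,
        table: Optional[ShapeFeatureTable] = None,
    ):
        if data.n_data < 1:
            raise ValueError("empty training set")
        codes = data.code_matrix()
        B = window_code_tensor(codes, M, both_strands)
        self.M = M
        self.valid = (B >= 0).all(axis=-1)
        self.Bsafe = np.where(B >= 0, B, 0).astype(np.int64)
        self.dinuc = 4 * self.Bsafe[..., :-1] + self.Bsafe[..., 1:]
        self.t = data.targets
        self.n, self.nw = self.valid.shape
        self.table = table

    # -- forward ------------------------------------------------------------

    def window_energy(
        self,
        w: Optional[np.ndarray],
        d: Optional[np.ndarray],
        base: Optional[np.ndarray] = None,
    ) -> np.ndarray:
        """Window energies; ``base`` is a precomputed energy component
        (e.g., the frozen independent part during stage-2 fitting)."""
        E = np.zeros((self.n, self.nw)) if base is None else base.copy()
        if w is not None:
            for j in range(self.M):
                E += w[j, self.Bsafe[..., j]]
        if d is not None:
            for j in range(self.M - 1):
                E += d[j, self.dinuc[..., j]]
        return E

    def forward(
        self,
        w: Optional[np.ndarray],
        mu: float,
        d: Optional[np.ndarray],
        a: float,
        b: float,
        base_energy: Optional[np.ndarray] = None,
    ) -> dict:
        E = self.window_energy(w, d, base=base_energy)
        sig = stable_sigmoid(mu - E)
        sig = np.where(self.valid, sig, 0.0)
        P = sig.sum(axis=1)
        pred = a * P + b
        resid = pred - self.t
        return {
            "sig": sig,
            "P": P,
            "pred": pred,
            "resid": resid,
            "LD": 0.5 * float(resid @ resid),
        }

    # -- gradients of LD ----------------------------------------------------

    def ld_gradients(
        self, fw: dict, a: float, need_w: bool = True, need_d: bool = True
    ) -> dict:
        sig = fw["sig"]
        sigd = sig * (1.0 - sig)
        resid = fw["resid"]
        u = (-(a) * resid)[:, None] * sigd  # per-window weight for dLD/dE
        uf = u.ravel()
        grad_w = grad_d = None
        if need_w:
            grad_w = np.empty((self.M, 4))
            for j in range(self.M):
                grad_w[j] = np.bincount(
                    self.Bsafe[..., j].ravel(), weights=uf, minlength=4
                )
        if need_d:
            grad_d = np.empty((self.M - 1, 16))
            for j in range(self.M - 1):
                grad_d[j] = np.bincount(
                    self.dinuc[..., j].ravel(), weights=uf, minlength=16
                )
        return {
            "w": grad_w,
            "d": grad_d,
            "mu": float(a * (resid @ sigd.sum(axis=1))),
            "a": float(resid @ fw["P"]),
            "b": float(resid.sum()),
        }

    # -- per-sequence prediction Jacobian (for the curvature) ---------------

    def jacobian(
        self,
        fw: dict,
        a: float,
        layout: ParameterLayout,
        table: Optional[ShapeFeatureTable],
    ) -> np.ndarray:
        sig = fw["sig"]
        sigd = sig * (1.0 - sig)
        g = -a * sigd  # (n, nw): d pred / d E_window
        sl = layout.slices()
        G = np.empty((self.n, layout.n_params))
        if "w" in sl:
            Gw = np.empty((self.n, self.M * 4))
            for j in range(self.M):
                for base in range(4):
                    Gw[:, 4 * j + base] = np.where(
                        self.Bsafe[..., j] == base, g, 0.0
                    ).sum(axis=1)
            G[:, sl["w"]] = Gw
        if "corr" in sl:
            Gd = np.empty((self.n, (self.M - 1) * 16))
            for j in range(self.M - 1):
                for idx in range(16):
                    Gd[:, 16 * j + idx] = np.where(
                        self.dinuc[..., j] == idx, g, 0.0
                    ).sum(axis=1)
            if table is not None:
                # chain rule through d = df @ D
                K = table.K
                Gdf = np.empty((self.n, (self.M - 1) * K))
                for j in range(self.M - 1):
                    Gdf[:, j * K : (j + 1) * K] = (
                        Gd[:, 16 * j : 16 * (j + 1)] @ table.D.T
                    )
                G[:, sl["corr"]] = Gdf
            else:
                G[:, sl["corr"]] = Gd
        if "mu" in sl:
            G[:, sl["mu"]] = (a * sigd.sum(axis=1))[:, None]
        G[:, sl["a"]] = fw["P"][:, None]
        G[:, sl["b"]] = 1.0
        return G


def _model_arrays(model: AffinityModel):
    d = model.effective_dinuc()
    return model.independent.w, model.independent.mu, d, model.a, model.b


# ---------------------------------------------------------------------------
# Cost, gradient, curvature (public operations, full parameter set)


def data_misfit(model: AffinityModel, data: TrainingSet) -> float:
    """Half the sum of squared residuals of ``a*P + b`` against targets."""
    if data.n_data == 0:
        raise ValueError("empty training set")
    ws = ScanWorkspace(data, model.M, model.scan_both_strands)
    w, mu, d, a, b = _model_arrays(model)
    return ws.forward(w, mu, d, a, b)["LD"]


def regularized_cost(
    model: AffinityModel, data: TrainingSet, reg: RegularizationState
) -> float:
    """beta * LD + sum_i alpha_i * W_i^2 over all model parameters."""
    layout = parameter_layout(model, "full")
    theta = pack_parameters(model, "full")
    alpha = _alpha_vector(reg, layout)
    return reg.beta * data_misfit(model, data) + float(alpha @ (theta * theta))


def cost_gradient(
    model: AffinityModel, data: TrainingSet, reg: RegularizationState
) -> np.ndarray:
    """Analytic gradient of :func:`regularized_cost` over all parameters.

    Returned flat, in the order of ``parameter_layout(model, "full")``:
    w (row-major), the correction block (d or df) if present, mu, a, b.
    """
    layout = parameter_layout(model, "full")
    table = (
        model.correction.table
        if isinstance(model.correction, ShapeCorrection)
        else None
    )
    ws = ScanWorkspace(data, model.M, model.scan_both_strands, table=table)
    w, mu, d, a, b = _model_arrays(model)
    fw = ws.forward(w, mu, d, a, b)
    gld = ws.ld_gradients(fw, a, need_d=model.correction is not None)
    sl = layout.slices()
    grad = np.empty(layout.n_params)
    grad[sl["w"]] = gld["w"].ravel()
    if "corr" in sl:
        if table is not None:
            grad[sl["corr"]] = (gld["d"] @ table.D.T).ravel()
        else:
            grad[sl["corr"]] = gld["d"].ravel()
    grad[sl["mu"]] = gld["mu"]
    grad[sl["a"]] = gld["a"]
    grad[sl["b"]] = gld["b"]
    theta = pack_parameters(model, "full")
    alpha = _alpha_vector(reg, layout)
    return reg.beta * grad + 2.0 * alpha * theta


def curvature(
    model: AffinityModel, data: TrainingSet, reg: RegularizationState
) -> np.ndarray:
    """Positive-semidefinite curvature H = beta * G^T G + 2 * diag(alpha)."""
    layout = parameter_layout(model, "full")
    table = (
        model.correction.table
        if isinstance(model.correction, ShapeCorrection)
        else None
    )
    ws = ScanWorkspace(data, model.M, model.scan_both_strands, table=table)
    w, mu, d, a, b = _model_arrays(model)
    fw = ws.forward(w, mu, d, a, b)
    G = ws.jacobian(fw, a, layout, table)
    alpha = _alpha_vector(reg, layout)
    H = reg.beta * (G.T @ G) + 2.0 * np.diag(alpha)
    if not np.isfinite(H).all():
        raise ValueError("non-finite curvature")
    return H


# ---------------------------------------------------------------------------
# Evidence fixed point


@dataclass
class EvidenceResult:
    alpha_by_group: np.ndarray
    beta: float
    gamma: np.ndarray  # per parameter
    iterations: int
    converged: bool


def _robust_inverse(H: np.ndarray) -> np.ndarray:
    n = H.shape[0]
    ridge = 0.0
    scale = float(np.trace(H)) / max(n, 1) or 1.0
    for _ in range(8):
        try:
            return np.linalg.inv(H + ridge * np.eye(n))
        except np.linalg.LinAlgError:
            ridge = max(ridge * 10.0, 1e-12 * scale)
    return np.linalg.pinv(H)


def evidence_fixed_point(
    GtG: np.ndarray,
    theta: np.ndarray,
    LD: float,
    n_data: int,
    group_ids: np.ndarray,
    beta: float,
    alpha_by_group: np.ndarray,
    *,
    alpha_max: float = 1e6,
    beta_max: float = 1e12,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> EvidenceResult:
    """Iterate the evidence hyperparameter equations to a fixed point.

    With model parameters fixed, repeatedly recompute H = beta * GtG +
    2*diag(alpha), gamma_i = 1 - alpha_i * (H^-1)_ii, grouped alphas
    gamma_group / sum(W^2), and beta = (n_data - sum(gamma)) / (2*LD),
    until the maximum relative change of (alpha, beta) drops below
    ``tol``.  Groups whose parameters are all zero get ``alpha_max``.
    """
    group_ids = np.asarray(group_ids)
    n_groups = int(group_ids.max()) + 1
    W2_g = np.bincount(group_ids, weights=theta * theta, minlength=n_groups)
    alpha_g = np.asarray(alpha_by_group, dtype=float).copy()
    gamma = np.zeros_like(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        alpha_vec = alpha_g[group_ids]
        H = beta * GtG + 2.0 * np.diag(alpha_vec)
        Hinv = _robust_inverse(H)
        gamma = 1.0 - alpha_vec * np.diag(Hinv)
        gamma = np.clip(gamma, 0.0, 1.0)
        gamma_g = np.bincount(group_ids, weights=gamma, minlength=n_groups)
        new_alpha = np.where(
            W2_g > 0.0, gamma_g / np.maximum(W2_g, 1e-300), alpha_max
        )
        new_alpha = np.minimum(new_alpha, alpha_max)
        gamma_sum = float(gamma.sum())
        if n_data <= gamma_sum:
            raise ValueError(
                f"beta update rejected: n_data={n_data} <= sum(gamma)={gamma_sum:.3f}"
            )
        if LD > 0:
            new_beta = min((n_data - gamma_sum) / (2.0 * LD), beta_max)
        else:
            new_beta = beta_max
        rel = max(
            float(
                np.max(
                    np.abs(new_alpha - alpha_g) / np.maximum(np.abs(alpha_g), 1e-12)
                )
            ),
            abs(new_beta - beta) / max(abs(beta), 1e-12),
        )
        alpha_g, beta = new_alpha, new_beta
        if rel < tol:
            converged = True
            break
    return EvidenceResult(
        alpha_by_group=alpha_g,
        beta=float(beta),
        gamma=gamma,
        iterations=it,
        converged=converged,
    )


def update_hyperparameters(
    model: AffinityModel,
    data: TrainingSet,
    reg: RegularizationState,
    stage: Stage = "independent",
    config: Optional[FitConfig] = None,
) -> RegularizationState:
    """One full evidence update of (alpha, beta) at fixed model parameters."""
    config = config or FitConfig()
    layout = parameter_layout(model, stage)
    table = (
        model.correction.table
        if isinstance(model.correction, ShapeCorrection)
        else None
    )
    ws = ScanWorkspace(data, model.M, model.scan_both_strands, table=table)
    w, mu, d, a, b = _model_arrays(model)
    fw = ws.forward(w, mu, d, a, b)
    G = ws.jacobian(fw, a, layout, table)
    theta = pack_parameters(model, stage)
    alpha_vec = _alpha_vector(reg, layout)
    alpha_by_group = np.array(
        [
            alpha_vec[np.argmax(layout.group_ids == gid)]
            for gid in range(len(layout.group_names))
        ]
    )
    res = evidence_fixed_point(
        G.T @ G,
        theta,
        fw["LD"],
        data.n_data,
        layout.group_ids,
        reg.beta,
        alpha_by_group,
        alpha_max=config.alpha_max,
        beta_max=config.beta_max,
        tol=config.hyper_tol,
        max_iter=config.hyper_max_iter,
    )
    return _reg_from_groups(res, layout, model.M)


def _reg_from_groups(
    res: EvidenceResult, layout: ParameterLayout, M: int
) -> RegularizationState:
    alpha_w = 0.0
    alpha_aux = 0.0
    alpha_d: Optional[np.ndarray] = None
    for gid, name in enumerate(layout.group_names):
        if name == "w":
            alpha_w = float(res.alpha_by_group[gid])
        elif name == "aux":
            alpha_aux = float(res.alpha_by_group[gid])
        else:
            if alpha_d is None:
                alpha_d = np.zeros(M - 1)
            alpha_d[int(name[1:])] = float(res.alpha_by_group[gid])
    return RegularizationState(
        beta=res.beta,
        alpha_w=alpha_w,
        alpha_d=alpha_d,
        alpha_aux=alpha_aux,
        gamma=res.gamma,
    )


# ---------------------------------------------------------------------------
# Gradient descent with backtracking line search


def _gradient_descent(
    theta0: np.ndarray,
    cost_fn,
    grad_fn,
    config: FitConfig,
    max_steps: Optional[int] = None,
) -> tuple[np.ndarray, list[float], bool]:
    """One descent phase on the regularized cost; returns (theta, costs, converged).

    Uses limited-memory BFGS with a sufficient-decrease line search
    (scipy's L-BFGS-B, unconstrained).  The occupancy regression is
    badly conditioned -- the calibration slope multiplies a window sum
    of order 10^2 while informative motif directions are nearly flat --
    so curvature-adaptive descent is required; fixed-metric gradient
    steps stall on the plateau.  ``costs`` records the cost at the start
    and after every accepted iteration (non-increasing by the line-search
    contract).
    """
    from scipy.optimize import minimize

    theta = theta0.copy()
    c0 = cost_fn(theta)
    if not np.isfinite(c0):
        raise FloatingPointError("non-finite cost at the starting point")
    costs = [c0]

    def record(xk: np.ndarray) -> None:
        costs.append(float(cost_fn(xk)))

    res = minimize(
        cost_fn,
        theta,
        jac=grad_fn,
        method="L-BFGS-B",
        callback=record,
        options={
            "maxiter": max_steps if max_steps is not None else config.max_gd_steps,
            "ftol": config.gd_tol,
            "gtol": config.gd_grad_tol,
            "maxcor": config.lbfgs_memory,
        },
    )
    if not np.isfinite(res.fun):
        raise FloatingPointError("descent diverged to a non-finite cost")
    converged = bool(res.success) or res.status == 1  # 1 = iteration cap
    # the recorded trail can lag the final polished iterate
    if not costs or res.fun <= costs[-1]:
        costs.append(float(res.fun))
        theta = res.x
    else:
        theta = res.x
    return theta, costs, converged


class _StageProblem:
    """Cost/gradient of one fitting stage over its free parameters."""

    def __init__(
        self,
        ws: ScanWorkspace,
        template: AffinityModel,
        stage: Stage,
        reg: RegularizationState,
        table: Optional[ShapeFeatureTable],
    ):
        self.ws = ws
        self.template = template
        self.stage = stage
        self.layout = parameter_layout(template, stage)
        self.sl = self.layout.slices()
        self.table = table
        # stage 2 freezes (w, mu): cache the independent energy component
        self.base_energy = None
        if "w" not in self.sl:
            self.base_energy = ws.window_energy(template.independent.w, None)
        self.set_reg(reg)

    def set_reg(self, reg: RegularizationState) -> None:
        self.reg = reg
        self.alpha = _alpha_vector(reg, self.layout)

    def _arrays(self, theta: np.ndarray):
        sl = self.sl
        M = self.template.M
        tmpl = self.template
        w = theta[sl["w"]].reshape(M, 4) if "w" in sl else tmpl.independent.w
        mu = float(theta[sl["mu"]][0]) if "mu" in sl else tmpl.independent.mu
        d = None
        if "corr" in sl:
            corr = theta[sl["corr"]]
            if self.table is not None:
                d = corr.reshape(M - 1, self.table.K) @ self.table.D
            else:
                d = corr.reshape(M - 1, 16)
        elif tmpl.correction is not None:
            d = tmpl.effective_dinuc()
        a = float(theta[sl["a"]][0])
        b = float(theta[sl["b"]][0])
        return w, mu, d, a, b

    def _forward(self, theta: np.ndarray) -> tuple[dict, float]:
        w, mu, d, a, b = self._arrays(theta)
        if self.base_energy is not None:
            fw = self.ws.forward(None, mu, d, a, b, base_energy=self.base_energy)
        else:
            fw = self.ws.forward(w, mu, d, a, b)
        return fw, a

    def misfit(self, theta: np.ndarray) -> float:
        return self._forward(theta)[0]["LD"]

    def cost(self, theta: np.ndarray) -> float:
        return self.reg.beta * self.misfit(theta) + float(
            self.alpha @ (theta * theta)
        )

    def grad(self, theta: np.ndarray) -> np.ndarray:
        fw, a = self._forward(theta)
        gld = self.ws.ld_gradients(
            fw, a, need_w="w" in self.sl, need_d="corr" in self.sl
        )
        sl = self.sl
        g = np.empty(self.layout.n_params)
        if "w" in sl:
            g[sl["w"]] = gld["w"].ravel()
        if "corr" in sl:
            if self.table is not None:
                g[sl["corr"]] = (gld["d"] @ self.table.D.T).ravel()
            else:
                g[sl["corr"]] = gld["d"].ravel()
        if "mu" in sl:
            g[sl["mu"]] = gld["mu"]
        g[sl["a"]] = gld["a"]
        g[sl["b"]] = gld["b"]
        return self.reg.beta * g + 2.0 * self.alpha * theta

    def model(self, theta: np.ndarray) -> AffinityModel:
        w, mu, d, a, b = self._arrays(theta)
        corr = self.template.correction
        if "corr" in self.sl and corr is not None:
            M = self.template.M
            if self.table is not None:
                corr = ShapeCorrection(
                    df=theta[self.sl["corr"]].reshape(M - 1, self.table.K),
                    table=self.table,
                )
            else:
                corr = DinucCorrection(d=theta[self.sl["corr"]].reshape(M - 1, 16))
        return AffinityModel(
            independent=IndependentModel(w=w, mu=mu),
            correction=corr,
            a=a,
            b=b,
            scan_both_strands=self.template.scan_both_strands,
        )

    def evidence_update(
        self, theta: np.ndarray, n_data: int, config: FitConfig
    ) -> RegularizationState:
        fw, a = self._forward(theta)
        G = self.ws.jacobian(fw, a, self.layout, self.table)
        groups = self.layout.group_ids
        n_groups = len(self.layout.group_names)
        alpha_by_group = np.empty(n_groups)
        for gid in range(n_groups):
            alpha_by_group[gid] = self.alpha[np.argmax(groups == gid)]
        res = evidence_fixed_point(
            G.T @ G,
            theta,
            fw["LD"],
            n_data,
            groups,
            self.reg.beta,
            alpha_by_group,
            alpha_max=config.alpha_max,
            beta_max=config.beta_max,
            tol=config.hyper_tol,
            max_iter=config.hyper_max_iter,
        )
        return _reg_from_groups(res, self.layout, self.template.M)


def _outer_loop(
    problem: _StageProblem,
    theta: np.ndarray,
    n_data: int,
    config: FitConfig,
    seed: int,
) -> FitResult:
    trace: list[dict] = []
    prev_cost = None
    converged = False
    for outer in range(1, config.max_outer + 1):
        theta, costs, _gd_ok = _gradient_descent(
            theta, problem.cost, problem.grad, config
        )
        LD = problem.misfit(theta)
        trace.append(
            {
                "outer": outer,
                "L": costs[-1],
                "LD": LD,
                "beta": problem.reg.beta,
                "alpha_w": problem.reg.alpha_w,
                "alpha_aux": problem.reg.alpha_aux,
                "alpha_d": None
                if problem.reg.alpha_d is None
                else problem.reg.alpha_d.tolist(),
                "gd_steps": len(costs) - 1,
                "phase_costs": costs,
            }
        )
        # beta rescales L between rounds, so judge outer convergence on
        # the misfit itself
        if prev_cost is not None and abs(prev_cost - LD) <= config.outer_tol * max(
            1.0, abs(prev_cost)
        ):
            converged = True
            break
        prev_cost = LD
        if outer < config.max_outer:
            problem.set_reg(problem.evidence_update(theta, n_data, config))
    # the final state of the alternation is returned: it carries the
    # converged hyperparameters, which is the point of the protocol
    return FitResult(
        model=problem.model(theta),
        reg=problem.reg,
        trace=trace,
        converged=converged,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Public fitting protocol


def enrichment_seed(
    data: TrainingSet, M: int, config: Optional[FitConfig] = None
) -> np.ndarray:
    """Seed energies from the most enriched k-mer in high-signal sequences.

    Counts k-mers of length ``min(M, seed_core)`` on both strands in the
    above-median-target half of the data versus the rest, takes the one
    with the largest excess, and places its consensus centered in the
    M-bp window: consensus bases get energy 0, all other bases
    ``seed_energy``, flanking positions 0.  The occupancy cost surface
    is nearly flat around uninformative energies, so descent needs a
    starting point inside the motif's basin of attraction; k-mer
    enrichment seeding is how biophysical motif fitters usually get one.
    """
    from collections import Counter

    config = config or FitConfig()
    k = min(M, config.seed_core)
    codes = data.code_matrix()
    median = float(np.median(data.targets))
    high = data.targets > median
    if not high.any() or high.all():
        high = data.targets >= median  # degenerate target distribution

    def count(rows: np.ndarray) -> Counter:
        cnt: Counter = Counter()
        for row in rows:
            n_win = len(row) - k + 1
            for i in range(n_win):
                win = row[i : i + k]
                if win.min() < 0:
                    continue
                t = tuple(int(c) for c in win)
                cnt[t] += 1
                cnt[tuple(3 - c for c in reversed(t))] += 1
        return cnt

    c_high = count(codes[high])
    c_low = count(codes[~high])
    if not c_high:
        raise ValueError("no unambiguous k-mers in the high-signal sequences")
    best = max(sorted(c_high), key=lambda km: c_high[km] - c_low.get(km, 0))
    w0 = np.zeros((M, 4))
    offset = (M - k) // 2
    for j, base in enumerate(best):
        w0[offset + j, :] = config.seed_energy
        w0[offset + j, base] = 0.0
    return w0


def fit_independent(
    data: TrainingSet,
    M: int,
    seed: int = 0,
    init: Literal["enrichment", "random", "pwm"] = "enrichment",
    pwm_energies: Optional[np.ndarray] = None,
    config: Optional[FitConfig] = None,
    both_strands: bool = True,
) -> FitResult:
    """Fit the independent model (w, mu, a, b) by the outer protocol.

    Alternates a descent phase on the regularized cost with evidence
    updates of (alpha_w, alpha_aux, beta), up to ``config.max_outer``
    rounds or until the misfit stabilizes; returns the best-by-misfit
    state.  Deterministic given ``seed``.
    """
    config = config or FitConfig()
    if data.n_data < 10:
        raise ValueError("fitting requires at least 10 sequences")
    if data.seq_length < M:
        raise ValueError("sequences must be at least as long as the motif")
    rng = np.random.default_rng(seed)
    if init == "pwm":
        if pwm_energies is None:
            raise ValueError("init='pwm' requires pwm_energies")
        w0 = np.asarray(pwm_energies, dtype=float)
        if w0.shape != (M, 4):
            raise ValueError(f"pwm energies must be {M} x 4")
    elif init == "enrichment":
        w0 = enrichment_seed(data, M, config)
        # seeded descent is deterministic; jitter only breaks exact ties
        w0 = w0 + rng.uniform(-1e-3, 1e-3, size=(M, 4))
    elif init == "random":
        w0 = rng.uniform(-config.init_scale, config.init_scale, size=(M, 4))
    else:
        raise ValueError(f"unknown init {init!r}")
    template = AffinityModel(
        independent=IndependentModel(w=w0, mu=0.0),
        correction=None,
        a=1.0,
        b=0.0,
        scan_both_strands=both_strands,
    )
    ws = ScanWorkspace(data, M, both_strands)
    reg0 = RegularizationState(
        beta=config.init_beta,
        alpha_w=config.init_alpha,
        alpha_aux=config.init_alpha,
    )
    problem = _StageProblem(ws, template, "independent", reg0, table=None)
    theta0 = pack_parameters(template, "independent")

    # Scale-matched initial calibration: a = sd(t)/sd(P) with the sign of
    # their correlation (positive when the correlation is negligible),
    # b = mean(t) - a*mean(P).  A least-squares fit of (a, b) at a random
    # w would put a near zero -- and every model-parameter gradient
    # scales with a, so that saddle must be avoided at initialization.
    P0 = ws.forward(w0, 0.0, None, 1.0, 0.0)["P"]
    sd_P, sd_t = float(np.std(P0)), float(np.std(data.targets))
    if sd_P > 0 and sd_t > 0:
        corr = float(np.corrcoef(P0, data.targets)[0, 1])
        a0 = (sd_t / sd_P) * (-1.0 if corr < -0.1 else 1.0)
    else:
        a0 = 1.0
    sl = problem.sl
    theta0[sl["a"]] = a0
    theta0[sl["b"]] = float(np.mean(data.targets) - a0 * np.mean(P0))
    return _outer_loop(problem, theta0, data.n_data, config, seed)


def fit_correction(
    base: FitResult | AffinityModel,
    data: TrainingSet,
    kind: Literal["dinuc", "shape"],
    table: Optional[ShapeFeatureTable] = None,
    config: Optional[FitConfig] = None,
    seed: int = 0,
) -> FitResult:
    """Stage-2 fit: freeze (w, mu), fit the dependency term and (a, b).

    The correction starts at zero, so the starting point reproduces the
    base model exactly; per-position grouped alphas let the evidence
    update shut down positions where dependencies do not help.
    """
    config = config or FitConfig()
    base_model = base.model if isinstance(base, FitResult) else base
    M = base_model.M
    if kind == "shape":
        if table is None:
            raise ValueError("kind='shape' requires a shape feature table")
        correction: DinucCorrection | ShapeCorrection = ShapeCorrection(
            df=np.zeros((M - 1, table.K)), table=table
        )
    elif kind == "dinuc":
        correction = DinucCorrection(d=np.zeros((M - 1, 16)))
        table = None
    else:
        raise ValueError(f"unknown correction kind {kind!r}")
    template = AffinityModel(
        independent=base_model.independent,
        correction=correction,
        a=base_model.a,
        b=base_model.b,
        scan_both_strands=base_model.scan_both_strands,
    )
    ws = ScanWorkspace(data, M, base_model.scan_both_strands, table=table)
    reg0 = RegularizationState(
        beta=config.init_beta,
        alpha_w=0.0,
        alpha_d=np.full(M - 1, config.init_alpha),
        alpha_aux=config.init_alpha,
    )
    problem = _StageProblem(ws, template, "correction", reg0, table=table)
    theta0 = pack_parameters(template, "correction")
    return _outer_loop(problem, theta0, data.n_data, config, seed)


def passes_retention(r2: float, auc: float) -> bool:
    """Strict retention thresholds: r^2 > 0.4 and ROC AUC > 0.75."""
    return (r2 > 0.4) and (auc > 0.75)


def retain_model(result: FitResult | AffinityModel, data: TrainingSet) -> bool:
    """The model-retention filter.

    True iff the squared Pearson correlation of predicted vs target
    signal exceeds 0.4 AND the ROC AUC of occupancy for positive-signal
    vs zero-signal sequences exceeds 0.75 (both strictly).
    """
    from .evaluation import roc_auc

    model = result.model if isinstance(result, FitResult) else result
    ws = ScanWorkspace(data, model.M, model.scan_both_strands)
    w, mu, d, a, b = _model_arrays(model)
    fw = ws.forward(w, mu, d, a, b)
    labels = (data.targets > 0).astype(int)
    if labels.min() == labels.max():
        raise ValueError("retention filter needs both positive and zero-label data")
    pred = fw["pred"]
    if np.std(pred) == 0 or np.std(data.targets) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(pred, data.targets)[0, 1]) ** 2
    auc = roc_auc(fw["P"], labels)
    return passes_retention(r2, auc)


def fit_motif_sizes(
    data: TrainingSet,
    sizes: Sequence[int] = (10, 15, 20),
    seed: int = 0,
    config: Optional[FitConfig] = None,
    both_strands: bool = True,
) -> list[FitResult]:
    """Fit one independent model per motif size; attach the retention flag."""
    results = []
    for M in sizes:
        res = fit_independent(
            data, M, seed=seed, config=config, both_strands=both_strands
        )
        res = replace(res, retained=retain_model(res, data))
        results.append(res)
    return results
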