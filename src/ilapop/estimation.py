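"""Nonlinear mixed-effects estimation by FOCE-ELS (first-order conditional
estimation, extended least squares) for the compartmental infusion models.

The hierarchical model is

    y_ij = f(t_ij; P_i) * (1 + eps_ij)          (multiplicative residual)
    P_i  = P_typ * covariate multipliers * exp(eta_i),  eta_i ~ N(0, Omega)

with diagonal Omega. The marginal likelihood has no closed form; each
subject's contribution is approximated by a Laplace-type expansion at the
conditional mode eta_hat (FOCE with interaction: the residual variance is
evaluated at the conditional prediction). The approximation is exact when
the model is linear in eta with additive error, which the test suite uses
as an oracle.

Objective function convention: OFV = -2 log (approximate) marginal
likelihood, including all 2*pi constants, so that for the linear-Gaussian
degenerate case OFV equals the exact -2 log-likelihood, not merely up to a
constant. Model selection uses signed OFV differences, which are invariant
to that choice.

Public surface mirrors statsmodels: build a :class:`PopPKModel` from a
:class:`~ilapop.data.PopPKDataset`, call :meth:`~PopPKModel.fit`, get a
:class:`PopPKResults` with estimates, standard errors, empirical-Bayes
etas, shrinkage and a ``summary()`` table.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import PopPKDataset
from .structural import (HAVE_NUMBA, _conc1_batch, _conc1_masked,
                         _conc2_batch, _conc2_masked)

__all__ = [
    "CovariateEffect",
    "PopPKModel",
    "PopPKResults",
    "lrt_threshold",
    "compare_models",
    "eta_shrinkage",
    "subject_objective",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_VAR_FLOOR = 1e-12

STRUCTURAL_PARAMS = {
    "two_compartment": ("V", "Vp", "CL", "CLp"),
    "one_compartment": ("V", "CL"),
}

_DEFAULT_START = {"V": 10.0, "Vp": 10.0, "CL": 5.0, "CLp": 10.0}


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate–parameter relationship.

    ``form='continuous'`` scales the parameter by ``(value/reference)**theta``
    (reference defaults to the dataset median, recomputed at model build);
    ``form='categorical'`` scales by ``exp(theta*value)`` for a 0/1 column.
    """

    parameter: str
    covariate: str
    form: str = "continuous"
    reference: Optional[float] = None

    def __post_init__(self) -> None:
        if self.form not in ("continuous", "categorical"):
            raise ValueError(f"unknown covariate form {self.form!r}")

    @property
    def name(self) -> str:
        return f"{self.covariate}_{self.parameter}"


def lrt_threshold(alpha: float, df: int = 1) -> float:
    """Chi-square critical value for a likelihood-ratio OFV difference."""
    if not 0 < alpha < 1 or df < 1:
        raise ValueError("need 0 < alpha < 1 and df >= 1")
    return float(stats.chi2.ppf(1.0 - alpha, df))


def eta_shrinkage(ebes: np.ndarray, omega2: np.ndarray) -> np.ndarray:
    """Per-eta shrinkage, ``100 * (1 - SD(eta_hat) / omega)`` in percent.

    Returns NaN where omega^2 is zero (shrinkage undefined)."""
    ebes = np.atleast_2d(np.asarray(ebes, float))
    if ebes.shape[0] < 2:
        raise ValueError("shrinkage needs at least two subjects")
    omega2 = np.asarray(omega2, float)
    sd = ebes.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (1.0 - sd / np.sqrt(omega2))
    out = np.where(omega2 > 0, out, np.nan)
    return out


class PopPKModel:
    """Nonlinear mixed-effects model bound to a dataset.

    Parameters
    ----------
    dataset : PopPKDataset
    structural : "two_compartment" or "one_compartment"
    covariate_effects : iterable of CovariateEffect
    iiv : structural parameters carrying a random effect (diagonal Omega);
        defaults to all but CLp, whose variability is fixed to zero.
    fixed_omega2 : mapping parameter -> constant variance for parameters
        that carry an eta whose omega^2 is held fixed rather than estimated.
    residual : "multiplicative" (default), "additive", "combined", or
        "exponential" (log-normal flavour of the proportional model).
    """

    def __init__(self, dataset: PopPKDataset, structural: str = "two_compartment",
                 covariate_effects: Iterable[CovariateEffect] = (),
                 iiv: Optional[Sequence[str]] = None,
                 fixed_omega2: Optional[Mapping[str, float]] = None,
                 residual: str = "multiplicative"):
        if structural not in STRUCTURAL_PARAMS:
            raise ValueError(f"unknown structural model {structural!r}")
        if residual not in ("multiplicative", "additive", "combined", "exponential"):
            raise ValueError(f"unknown residual model {residual!r}")
        self.dataset = dataset
        self.structural = structural
        self.residual = residual
        self.struct_params = STRUCTURAL_PARAMS[structural]
        if iiv is None:
            iiv = tuple(p for p in self.struct_params if p != "CLp")
        for p in iiv:
            if p not in self.struct_params:
                raise ValueError(f"iiv parameter {p!r} not in structural model")
        self.iiv = tuple(iiv)
        self.fixed_omega2 = dict(fixed_omega2 or {})
        for p, w in self.fixed_omega2.items():
            if p not in self.iiv:
                raise ValueError(f"fixed omega^2 given for non-IIV parameter {p!r}")
            if w < 0:
                raise ValueError("fixed omega^2 must be non-negative")
        self.covariate_effects = tuple(covariate_effects)

        self._batch = dataset.padded_arrays()
        self._cov = dataset.covariate_table()
        self._n = len(self._batch["ids"])
        self._q = len(self.iiv)
        self._iiv_idx = [self.struct_params.index(p) for p in self.iiv]

        # covariate design columns, grouped by target structural parameter
        self._effect_x = []          # (N,) design value per effect, packed order
        self._effect_refs = {}
        for e in self.covariate_effects:
            if e.parameter not in self.struct_params:
                raise ValueError(f"effect targets unknown parameter {e.parameter!r}")
            if e.covariate not in self._cov.columns:
                raise ValueError(f"covariate {e.covariate!r} not in dataset")
            col = self._cov[e.covariate].to_numpy(float)
            if e.form == "continuous":
                ref = e.reference if e.reference is not None else float(np.median(col))
                if ref <= 0 or np.any(col <= 0):
                    raise ValueError(
                        f"continuous covariate {e.covariate!r} must be positive")
                self._effect_refs[e.name] = ref
                self._effect_x.append(np.log(col / ref))
            else:
                self._effect_refs[e.name] = 0.0
                self._effect_x.append(col.copy())

        self._layout = self._build_layout()
        self._tile_cache: dict[int, dict] = {}
        self._best = (None, np.inf)
        self._eta_cache = np.zeros((self._n, self._q))
        self._trace: list[tuple[int, float]] = []
        self._neval = 0

    # ------------------------------------------------------------------
    # parameter packing
    # ------------------------------------------------------------------
    def _build_layout(self):
        names, log_scale = [], []
        for p in self.struct_params:
            names.append(f"tv_{p}")
            log_scale.append(True)
        for e in self.covariate_effects:
            names.append(e.name)
            log_scale.append(False)
        self._omega_free = [p for p in self.iiv if p not in self.fixed_omega2]
        for p in self._omega_free:
            names.append(f"omega2_{p}")
            log_scale.append(True)
        if self.residual in ("multiplicative", "exponential"):
            sig = ["sigma_mult"]
        elif self.residual == "additive":
            sig = ["sigma_add"]
        else:
            sig = ["sigma_add", "sigma_mult"]
        for s in sig:
            names.append(s)
            log_scale.append(True)
        return {"names": names, "log": np.array(log_scale)}

    @property
    def param_names(self) -> list[str]:
        return list(self._layout["names"])

    @property
    def k_params(self) -> int:
        return len(self._layout["names"])

    def default_start(self) -> dict[str, float]:
        start = {}
        for p in self.struct_params:
            start[f"tv_{p}"] = _DEFAULT_START[p]
        for e in self.covariate_effects:
            start[e.name] = 0.0
        for p in self._omega_free:
            start[f"omega2_{p}"] = 0.05
        for n in self._layout["names"]:
            if n.startswith("sigma"):
                start[n] = 0.2
        return start

    def _pack(self, values: Mapping[str, float]) -> np.ndarray:
        x = np.empty(self.k_params)
        for i, (name, lg) in enumerate(zip(self._layout["names"], self._layout["log"])):
            v = float(values[name])
            if lg and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
            x[i] = np.log(v) if lg else v
        return x

    def _unpack(self, x: np.ndarray) -> dict[str, float]:
        out = {}
        for i, (name, lg) in enumerate(zip(self._layout["names"], self._layout["log"])):
            out[name] = float(np.exp(x[i])) if lg else float(x[i])
        return out

    # ------------------------------------------------------------------
    # model evaluation
    # ------------------------------------------------------------------
    def _log_base(self, values: Mapping[str, float]) -> np.ndarray:
        """Per-subject log structural parameters before eta, (N, P)."""
        logs = np.empty((self._n, len(self.struct_params)))
        for j, p in enumerate(self.struct_params):
            logs[:, j] = np.log(values[f"tv_{p}"])
        for e, x in zip(self.covariate_effects, self._effect_x):
            j = self.struct_params.index(e.parameter)
            logs[:, j] += values[e.name] * x
        return logs

    def _tiled_batch(self, K: int) -> dict:
        """Observation/dose arrays replicated K-fold along the subject axis
        (cached) for stacked evaluations."""
        cached = self._tile_cache.get(K)
        if cached is None:
            b = self._batch
            cached = {k: np.ascontiguousarray(np.tile(b[k], (K, 1)))
                      for k in ("times", "obs_mask", "amt", "start", "dur",
                                "dose_mask")}
            self._tile_cache[K] = cached
        return cached

    def _kernel(self, P: np.ndarray, batch: dict) -> np.ndarray:
        """Concentrations for per-row parameters P (M, P-dim) on the given
        (possibly tiled) batch arrays; masked cells are 0."""
        out = np.empty_like(batch["times"])
        cols = [np.ascontiguousarray(P[:, j]) for j in range(P.shape[1])]
        if HAVE_NUMBA:
            if self.structural == "two_compartment":
                _conc2_masked(cols[0], cols[1], cols[2], cols[3],
                              batch["times"], batch["obs_mask"], batch["amt"],
                              batch["start"], batch["dur"],
                              batch["dose_mask"], out)
            else:
                _conc1_masked(cols[0], cols[1], batch["times"],
                              batch["obs_mask"], batch["amt"], batch["start"],
                              batch["dur"], batch["dose_mask"], out)
            return out
        if self.structural == "two_compartment":
            f = _conc2_batch(cols[0], cols[1], cols[2], cols[3],
                             batch["times"], batch["amt"], batch["start"],
                             batch["dur"], batch["dose_mask"])
        else:
            f = _conc1_batch(cols[0], cols[1], batch["times"], batch["amt"],
                             batch["start"], batch["dur"], batch["dose_mask"])
        return np.where(batch["obs_mask"], f, 0.0)

    def _f_eta(self, logbase: np.ndarray, eta: np.ndarray) -> np.ndarray:
        logs = logbase.copy()
        if self._q:
            logs[:, self._iiv_idx] += eta
        return self._kernel(np.exp(logs), self._batch)

    def _f_eta_multi(self, logbase: np.ndarray, eta_stack: np.ndarray) -> np.ndarray:
        """Evaluate f for K eta variants at once, (K, N, q) -> (K, N, T);
        one kernel call over a stacked subject axis."""
        K = eta_stack.shape[0]
        N, T = self._batch["times"].shape
        logs = np.broadcast_to(logbase, (K,) + logbase.shape).copy()
        if self._q:
            logs[:, :, self._iiv_idx] += eta_stack
        P = np.exp(logs).reshape(K * N, -1)
        out = self._kernel(P, self._tiled_batch(K))
        return out.reshape(K, N, T)

    def _residual_parts(self, f: np.ndarray, values: Mapping[str, float]):
        """Residual r, variance v, and the eta-sensitivity factors c_r, c_v
        such that dr/deta = c_r * df/deta and dv/deta = c_v * df/deta."""
        y = self._batch["y"]
        if self.residual == "multiplicative":
            s2 = values["sigma_mult"] ** 2
            v = np.maximum(s2 * f * f, _VAR_FLOOR)
            return y - f, v, -np.ones_like(f), 2.0 * s2 * f
        if self.residual == "additive":
            s2 = values["sigma_add"] ** 2
            v = np.full_like(f, max(s2, _VAR_FLOOR))
            return y - f, v, -np.ones_like(f), np.zeros_like(f)
        if self.residual == "combined":
            sa2 = values["sigma_add"] ** 2
            sm2 = values["sigma_mult"] ** 2
            v = np.maximum(sa2 + sm2 * f * f, _VAR_FLOOR)
            return y - f, v, -np.ones_like(f), 2.0 * sm2 * f
        # exponential: log y = log f + eps
        s2 = values["sigma_mult"] ** 2
        fpos = np.maximum(f, _VAR_FLOOR)
        v = np.full_like(f, max(s2, _VAR_FLOOR))
        return np.log(np.maximum(y, _VAR_FLOOR)) - np.log(fpos), v, -1.0 / fpos, \
            np.zeros_like(f)

    def _gvec(self, f: np.ndarray, eta: np.ndarray, oinv_diag: np.ndarray,
              logdet_omega: float, values: Mapping[str, float]) -> np.ndarray:
        """Per-subject -2 log joint density of (y_i, eta_i)."""
        m = self._batch["obs_mask"]
        r, v, _, _ = self._residual_parts(f, values)
        term = np.sum(np.where(m, r * r / v + np.log(v) + _LOG2PI, 0.0), axis=1)
        if self._q:
            term = term + np.einsum("nq,q,nq->n", eta, oinv_diag, eta) \
                + logdet_omega + self._q * _LOG2PI
        return term

    # ------------------------------------------------------------------
    # inner problem: conditional modes
    # ------------------------------------------------------------------
    def _jacobian(self, logbase, eta, h=1e-4):
        """df/deta by central differences, (N, T, q); all perturbations are
        evaluated in a single batched kernel call."""
        q = self._q
        stack = np.repeat(eta[None, :, :], 2 * q, axis=0)
        for k in range(q):
            stack[2 * k, :, k] += h
            stack[2 * k + 1, :, k] -= h
        fs = self._f_eta_multi(logbase, stack)
        G = np.stack([(fs[2 * k] - fs[2 * k + 1]) / (2 * h) for k in range(q)],
                     axis=-1)
        return G

    def _inner_solve(self, logbase, values, oinv_diag, logdet_omega,
                     eta0, tol=1e-10, maxit=60):
        """Batched damped Gauss–Newton for the conditional modes eta_hat."""
        m = self._batch["obs_mask"]
        # robust start: per subject, the better of the warm-start eta and 0
        # (a poisoned cache entry would otherwise trap the Newton search)
        eta = eta0.copy()
        f = self._f_eta(logbase, eta)
        g = self._gvec(f, eta, oinv_diag, logdet_omega, values)
        if np.any(eta0):
            f0 = self._f_eta(logbase, np.zeros_like(eta))
            g0 = self._gvec(f0, np.zeros_like(eta), oinv_diag, logdet_omega,
                            values)
            use0 = ~(g <= g0)          # catches NaN/inf g as well
            eta[use0] = 0.0
            g[use0] = g0[use0]
            f = np.where(use0[:, None], f0, f)
        eye = np.eye(self._q)
        converged = np.zeros(self._n, bool)
        G = None
        at_mode = False
        for _ in range(maxit):
            G = self._jacobian(logbase, eta)
            at_mode = True
            r, v, c_r, c_v = self._residual_parts(f, values)
            w = np.where(m, 1.0 / v, 0.0)
            # gradient of the per-subject -2 log joint
            resid_part = np.where(m, 2.0 * r * c_r * w
                                  + (w - r * r * w * w) * c_v, 0.0)
            grad = np.einsum("nt,ntq->nq", resid_part, G) + 2.0 * eta * oinv_diag
            # Gauss-Newton curvature (positive definite via the Omega prior)
            GW = G * (np.where(m, c_r * c_r * w, 0.0))[:, :, None]
            H = 2.0 * (np.einsum("ntq,ntk->nqk", GW, G) + oinv_diag * eye)
            try:
                d = -np.linalg.solve(H, grad[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                d = -grad / np.maximum(np.diagonal(H, axis1=1, axis2=2), 1e-8)
            # Newton decrement: predicted decrease of the quadratic model
            decrement = -0.5 * np.einsum("nq,nq->n", grad, d)
            converged |= (decrement < tol) | ~np.isfinite(decrement)
            if converged.all():
                break
            at_mode = False
            step = np.ones(self._n)
            active = ~converged
            for _bt in range(15):
                trial = eta + np.where(active, step, 0.0)[:, None] * d
                f_t = self._f_eta(logbase, trial)
                g_t = self._gvec(f_t, trial, oinv_diag, logdet_omega, values)
                better = active & (g_t <= g)
                eta[better] = trial[better]
                g[better] = g_t[better]
                if better.any():
                    f = np.where(better[:, None], f_t, f)
                active &= ~better
                if not active.any():
                    break
                step[active] *= 0.5
            # subjects that cannot improve along d are at their mode
            converged |= active
        if G is None or not at_mode:
            G = self._jacobian(logbase, eta)
        return eta, f, g, G

    # ------------------------------------------------------------------
    # objective
    # ------------------------------------------------------------------
    def _omega_values(self, values: Mapping[str, float]) -> np.ndarray:
        w = np.empty(self._q)
        for k, p in enumerate(self.iiv):
            w[k] = self.fixed_omega2.get(p, values.get(f"omega2_{p}", 0.0))
        return w

    def ofv(self, values: Mapping[str, float], eta0: Optional[np.ndarray] = None,
            inner_tol: float = 1e-10, update_cache: bool = True) -> float:
        """FOCE-ELS objective (-2 log approximate marginal likelihood) at the
        given parameter values. Deterministic given inputs; the conditional
        modes are re-solved from ``eta0`` (zeros by default)."""
        with np.errstate(all="ignore"):
            logbase = self._log_base(values)
            if self._q == 0:
                f = self._f_eta(logbase, np.zeros((self._n, 0)))
                g = self._gvec(f, np.zeros((self._n, 0)), np.zeros(0), 0.0, values)
                return float(np.sum(g))
            omega2 = self._omega_values(values)
            if np.any(omega2 <= 0):
                raise ValueError("omega^2 must be positive for active etas; "
                                 "drop the parameter from iiv to fix it at zero")
            oinv = 1.0 / omega2
            logdet = float(np.sum(np.log(omega2)))
            if eta0 is None:
                eta0 = self._eta_cache if update_cache else np.zeros((self._n, self._q))
            eta, f, g, G = self._inner_solve(logbase, values, oinv, logdet, eta0,
                                             tol=inner_tol)
            if update_cache:
                self._eta_cache = eta.copy()
            # Laplace log-determinant with the FOCE(-I) Gauss-Newton Hessian
            r, v, c_r, c_v = self._residual_parts(f, values)
            w = np.where(self._batch["obs_mask"], c_r * c_r / v, 0.0)
            H = (np.einsum("ntq,ntk->nqk", G * w[:, :, None], G)
                 + np.diag(oinv)[None, :, :])
            sign, logdetH = np.linalg.slogdet(H)
            if np.any(sign <= 0):
                return float(np.inf)
            ofv = np.sum(g) - self._n * self._q * _LOG2PI + np.sum(logdetH)
            return float(ofv)

    def _ofv_packed(self, x: np.ndarray) -> float:
        try:
            val = self.ofv(self._unpack(x))
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            val = np.inf
        if not np.isfinite(val):
            val = np.inf
        self._neval += 1
        self._trace.append((self._neval, val))
        if val < self._best[1]:
            self._best = (x.copy(), val)
        return val

    # ------------------------------------------------------------------
    # fitting
    # ------------------------------------------------------------------
    def fit(self, start: Optional[Mapping[str, float]] = None,
            preset: str = "default", maxiter: Optional[int] = None,
            compute_se: bool = True) -> "PopPKResults":
        """Maximise the FOCE-ELS marginal likelihood.

        The outer search runs on transformed coordinates (log for positive
        quantities, identity for covariate effects) with L-BFGS-B and
        finite-difference gradients. ``preset='fast'`` loosens the outer
        tolerance for replicate-heavy work (bootstrap, stepwise screens).
        """
        values = self.default_start()
        if start:
            values.update({k: float(v) for k, v in start.items()})
        x0 = self._pack(values)
        if preset == "fast":
            opts = dict(maxiter=maxiter or 120, ftol=1e-8, gtol=1e-3, eps=1e-5)
        else:
            opts = dict(maxiter=maxiter or 400, ftol=2e-9, gtol=1e-4, eps=1e-5)
        self._eta_cache = np.zeros((self._n, self._q))
        self._trace = []
        self._neval = 0
        self._best = (x0.copy(), np.inf)
        t0 = time.perf_counter()
        res = optimize.minimize(self._ofv_packed, x0, method="L-BFGS-B",
                                options=opts)
        elapsed = time.perf_counter() - t0
        # guard against a line search ending in a bad region: fall back to
        # the best parameter vector seen during the search
        final_val = self._ofv_packed(res.x)
        x_hat = res.x if final_val <= self._best[1] else self._best[0]
        est = self._unpack(x_hat)
        ofv = self.ofv(est, inner_tol=1e-12)
        ebes = self._eta_cache.copy()
        omega2 = self._omega_values(est)
        shrink = eta_shrinkage(ebes, omega2) if (self._q and self._n > 1) else \
            np.zeros(0)

        se = rse = None
        if compute_se:
            se, rse = self._standard_errors(est)

        return PopPKResults(
            model=self, params=est, start=dict(values), ofv=ofv,
            converged=bool(res.success), message=str(res.message),
            n_outer_evals=self._neval, elapsed=elapsed,
            ebes=pd.DataFrame(ebes, index=pd.Index(self._batch["ids"], name="ID"),
                              columns=[f"eta_{p}" for p in self.iiv]),
            shrinkage={p: float(s) for p, s in zip(self.iiv, shrink)},
            se=se, rse=rse, trace=list(self._trace))

    def evaluate(self, values: Mapping[str, float],
                 compute_se: bool = False) -> "PopPKResults":
        """Results object at fixed parameter values (no optimization):
        OFV, empirical-Bayes etas and shrinkage evaluated as-is. Useful for
        diagnostics at known simulation truth or at externally fitted
        estimates."""
        full = self.default_start()
        full.update({k: float(v) for k, v in values.items()})
        self._eta_cache = np.zeros((self._n, self._q))
        ofv = self.ofv(full, inner_tol=1e-12)
        ebes = self._eta_cache.copy()
        omega2 = self._omega_values(full)
        shrink = eta_shrinkage(ebes, omega2) if (self._q and self._n > 1) \
            else np.zeros(0)
        se = rse = None
        if compute_se:
            se, rse = self._standard_errors(full)
        return PopPKResults(
            model=self, params=full, start=dict(full), ofv=ofv,
            converged=True, message="evaluated at fixed parameters",
            n_outer_evals=1, elapsed=0.0,
            ebes=pd.DataFrame(ebes, index=pd.Index(self._batch["ids"], name="ID"),
                              columns=[f"eta_{p}" for p in self.iiv]),
            shrinkage={p: float(s) for p, s in zip(self.iiv, shrink)},
            se=se, rse=rse, trace=[])

    def _standard_errors(self, est: Mapping[str, float], step: float = 2e-3):
        """SEs from the central finite-difference Hessian of the OFV.

        The Hessian is taken on the transformed (log/identity) coordinates,
        where all parameters are O(1) and a uniform absolute step is
        well-scaled, then mapped to the natural scale by the delta method
        (SE_P = P * SE_logP for log-parameterised P). Covariance = 2 H^-1
        since OFV = -2 log L."""
        x = self._pack(est)
        p = len(x)
        fx = self._ofv_packed_quiet
        f0 = fx(x)
        H = np.empty((p, p))
        fplus = np.empty(p)
        fminus = np.empty(p)
        h = np.full(p, step)
        for i in range(p):
            xp = x.copy(); xp[i] += h[i]
            xm = x.copy(); xm[i] -= h[i]
            fplus[i], fminus[i] = fx(xp), fx(xm)
            H[i, i] = (fplus[i] - 2 * f0 + fminus[i]) / h[i] ** 2
        for i in range(p):
            for j in range(i + 1, p):
                xpp = x.copy(); xpp[[i, j]] += h[[i, j]]
                xmm = x.copy(); xmm[[i, j]] -= h[[i, j]]
                H[i, j] = H[j, i] = (
                    fx(xpp) - fplus[i] - fplus[j] + 2 * f0
                    - fminus[i] - fminus[j] + fx(xmm)) / (2 * h[i] * h[j])
        # guard indefinite numerical Hessians: clip tiny/negative eigenvalues
        w, U = np.linalg.eigh((H + H.T) / 2)
        w = np.where(w > 1e-10, w, np.nan)
        with np.errstate(invalid="ignore"):
            cov = 2.0 * (U * (1.0 / w)) @ U.T
            se_t = np.sqrt(np.diag(cov))
        names = self.param_names
        se, rse = {}, {}
        for i, (name, lg) in enumerate(zip(names, self._layout["log"])):
            s = se_t[i] * (abs(est[name]) if lg else 1.0)
            se[name] = float(s)
            rse[name] = float(100.0 * s / abs(est[name])) if est[name] != 0 else np.nan
        return se, rse

    def _ofv_packed_quiet(self, x: np.ndarray) -> float:
        try:
            v = self.ofv(self._unpack(x))
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            v = np.inf
        return v

    # ------------------------------------------------------------------
    # simulation under the model (shared by VPC / synthetic refits)
    # ------------------------------------------------------------------
    def simulate_observations(self, values: Mapping[str, float],
                              rng: np.random.Generator) -> np.ndarray:
        """Draw one replicate of the observation array (N, T): new etas from
        N(0, Omega) and residuals from the fitted error model. Padded cells
        (no observation) are left at NaN."""
        logbase = self._log_base(values)
        omega2 = self._omega_values(values)
        eta = rng.normal(0.0, np.sqrt(omega2), size=(self._n, self._q)) \
            if self._q else np.zeros((self._n, 0))
        f = self._f_eta(logbase, eta)
        if self.residual == "multiplicative":
            dv = f * (1.0 + rng.normal(0.0, values["sigma_mult"], f.shape))
        elif self.residual == "additive":
            dv = f + rng.normal(0.0, values["sigma_add"], f.shape)
        elif self.residual == "combined":
            dv = f * (1.0 + rng.normal(0.0, values["sigma_mult"], f.shape)) \
                + rng.normal(0.0, values["sigma_add"], f.shape)
        else:
            dv = f * np.exp(rng.normal(0.0, values["sigma_mult"], f.shape))
        dv = np.maximum(dv, 0.0)
        return np.where(self._batch["obs_mask"], dv, np.nan)


class PopPKResults:
    """Fit output: estimates, uncertainty, diagnostics hooks.

    Attributes
    ----------
    params : dict of estimates on natural scale (tv_* in L or L/h, covariate
        effects dimensionless, omega2_* variances, sigma_* residual scale).
    ofv, aic, bic : model-fit metrics (-2 log approx. marginal likelihood;
        AIC = OFV + 2p; BIC = OFV + p ln n_obs).
    se, rse : standard errors and relative standard errors (percent), from
        the finite-difference Hessian; None when not requested.
    ebes : DataFrame of empirical-Bayes eta estimates per subject.
    shrinkage : dict parameter -> eta-shrinkage percent.
    """

    def __init__(self, model, params, start, ofv, converged, message,
                 n_outer_evals, elapsed, ebes, shrinkage, se, rse, trace):
        self.model = model
        self.params = params
        self.start = start
        self.ofv = ofv
        self.converged = converged
        self.message = message
        self.n_outer_evals = n_outer_evals
        self.elapsed = elapsed
        self.ebes = ebes
        self.shrinkage = shrinkage
        self.se = se
        self.rse = rse
        self.trace = trace

    @property
    def k_params(self) -> int:
        return self.model.k_params

    @property
    def n_obs(self) -> int:
        return self.model.dataset.n_obs

    @property
    def aic(self) -> float:
        return self.ofv + 2.0 * self.k_params

    @property
    def bic(self) -> float:
        return self.ofv + self.k_params * float(np.log(self.n_obs))

    def compare(self, other: "PopPKResults") -> tuple[float, float, float]:
        return compare_models(self, other)

    def summary(self) -> str:
        lines = [
            "Population PK model fit (FOCE-ELS)",
            "=" * 58,
            f"structural: {self.model.structural}   residual: {self.model.residual}",
            f"subjects: {self.model.dataset.n_subjects}   observations: {self.n_obs}",
            f"OFV: {self.ofv:.3f}   AIC: {self.aic:.3f}   BIC: {self.bic:.3f}",
            f"converged: {self.converged}   outer evals: {self.n_outer_evals}"
            f"   time: {self.elapsed:.1f} s",
            "-" * 58,
            f"{'parameter':<16}{'estimate':>12}{'SE':>12}{'RSE%':>10}",
        ]
        for name in self.model.param_names:
            se = self.se.get(name) if self.se else None
            rse = self.rse.get(name) if self.rse else None
            lines.append(
                f"{name:<16}{self.params[name]:>12.4g}"
                f"{(f'{se:.4g}' if se is not None and np.isfinite(se) else '-'):>12}"
                f"{(f'{rse:.1f}' if rse is not None and np.isfinite(rse) else '-'):>10}")
        if self.shrinkage:
            lines.append("-" * 58)
            shr = "   ".join(f"eta_{p}: {s:.1f}%" for p, s in self.shrinkage.items())
            lines.append(f"eta-shrinkage  {shr}")
        return "\n".join(lines)

    def run_log(self) -> str:
        """Plain-text iteration trace of the outer objective."""
        lines = [f"{'eval':>6}  {'OFV':>14}"]
        for n, v in self.trace:
            lines.append(f"{n:>6}  {v:>14.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serialisable report."""
        return {
            "structural": self.model.structural,
            "residual": self.model.residual,
            "covariate_effects": [
                {"parameter": e.parameter, "covariate": e.covariate,
                 "form": e.form,
                 "reference": self.model._effect_refs.get(e.name)}
                for e in self.model.covariate_effects],
            "params": self.params,
            "se": self.se, "rse": self.rse,
            "ofv": self.ofv, "aic": self.aic, "bic": self.bic,
            "n_obs": self.n_obs, "n_subjects": self.model.dataset.n_subjects,
            "converged": self.converged,
            "shrinkage": self.shrinkage,
            "ebes": {str(i): list(map(float, row))
                     for i, row in self.ebes.iterrows()},
        }


def compare_models(fit_a: PopPKResults, fit_b: PopPKResults) -> tuple[float, float, float]:
    """Signed (OFV, AIC, BIC) differences, fit_a minus fit_b.

    Both fits must be on the same dataset (same subjects and observation
    count), otherwise the differences are meaningless."""
    da, db = fit_a.model.dataset, fit_b.model.dataset
    if da.subject_ids != db.subject_ids or da.n_obs != db.n_obs:
        raise ValueError("model comparison requires the same dataset")
    return (fit_a.ofv - fit_b.ofv, fit_a.aic - fit_b.aic, fit_a.bic - fit_b.bic)


def subject_objective(model: PopPKModel, subject, values: Mapping[str, float],
                      eta: np.ndarray) -> float:
    """Extended-least-squares conditional objective for one subject:
    ``sum_j [r_j^2/v_j + ln v_j + ln 2pi] + eta' Omega^-1 eta + ln|2pi Omega|``
    — the -2 log joint density of (y_i, eta_i) evaluated at ``eta``."""
    ids = model._batch["ids"]
    i = ids.index(subject)
    eta = np.asarray(eta, float).reshape(1, -1)
    if eta.shape[1] != model._q:
        raise ValueError(f"eta must have length {model._q}")
    logbase = model._log_base(values)
    full_eta = np.zeros((model._n, model._q))
    full_eta[i] = eta[0]
    f = model._f_eta(logbase, full_eta)
    if model._q:
        omega2 = model._omega_values(values)
        oinv = 1.0 / omega2
        logdet = float(np.sum(np.log(omega2)))
    else:
        oinv, logdet = np.zeros(0), 0.0
    g = model._gvec(f, full_eta, oinv, logdet, values)
    return float(g[i])
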