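"""Logistic mixed models: Laplace fits, bootstrap CIs, parametric-bootstrap LRTs.

Fits ``accuracy ~ knowledge + (knowledge | group) + ...`` with a logistic
link by maximum likelihood under the Laplace approximation, the same scheme
as lme4's ``glmer`` at ``nAGQ = 1``: an inner penalized Newton (PIRLS) solves
jointly for the fixed effects and the conditional modes of the spherical
random effects, and an outer derivative-free optimization runs over the
relative-covariance Cholesky parameters (theta).  The Laplace deviance is

    pdev(beta_hat, v_hat) + log det(Lambda' Z' W Z Lambda + I),

where ``pdev`` is the binomial deviance plus the ``||v||^2`` penalty.

Random-effect terms are correlated intercept + slope pairs by default; when a
fit fails to converge or its covariance is singular, terms are simplified in
a fixed order (drop the intercept-slope correlation, then the slope, then the
term; groups attempted smallest-expected-variance first).

The model-comparison machinery mirrors the validation design: odds-ratio
confidence intervals from a nonparametric bootstrap over rows, and p-values
for the knowledge effect from a parametric bootstrap of the likelihood-ratio
statistic (simulate from the fitted null, refit both models, count
exceedances, ``p = (r + 1) / (n + 1)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "RandomTerm",
    "GLMMSpec",
    "GLMMFit",
    "GLMMResult",
    "ConvergenceError",
    "fit_glmm",
    "odds_ratio_ci",
    "bootstrap_lrt",
]

_SINGULAR_TOL = 1e-4
_ETA_CLIP = 30.0


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class RandomTerm:
    """One random-effects term: ``(knowledge | group)`` or ``(1 | group)``."""

    group: str
    slope: bool = True
    correlated: bool = True

    @property
    def q(self) -> int:
        return 2 if self.slope else 1

    @property
    def n_theta(self) -> int:
        if not self.slope:
            return 1
        return 3 if self.correlated else 2

    def label(self) -> str:
        if not self.slope:
            return f"(1 | {self.group})"
        sep = "|" if self.correlated else "||"
        return f"(knowledge {sep} {self.group})"


@dataclass(frozen=True)
class GLMMSpec:
    """Model specification.

    ``random`` lists the grouping terms; question identifiers are expected to
    be globally unique, so a question grouping is implicitly nested within a
    lecture grouping without explicit nesting syntax.  ``simplification_order``
    gives the order in which groups lose structure when a maximal fit does
    not converge (default: smallest expected variance first).
    """

    response: str = "accuracy"
    predictor: str | None = "knowledge"  # None for the null (intercept-only) model
    random: tuple[RandomTerm, ...] = (
        RandomTerm("participant"),
        RandomTerm("qid"),
    )
    simplification_order: tuple[str, ...] = ("lecture", "qid", "participant")

    def null_spec(self) -> "GLMMSpec":
        """Same random structure with the fixed predictor removed."""
        return replace(self, predictor=None)

    def formula(self) -> str:
        fixed = self.predictor if self.predictor else "1"
        terms = " + ".join(t.label() for t in self.random)
        rhs = f"{fixed} + {terms}" if terms else fixed
        return f"{self.response} ~ {rhs}"


# --------------------------------------------------------------------------- #
# internal design / fitting machinery
# --------------------------------------------------------------------------- #


class _TermDesign:
    """Per-term grouping codes and raw covariates."""

    def __init__(self, term: RandomTerm, table: pd.DataFrame, x: np.ndarray):
        self.term = term
        codes, levels = pd.factorize(table[term.group].to_numpy(), sort=True)
        self.g = codes.astype(np.intp)
        self.levels = levels
        self.n_levels = len(levels)
        if term.slope:
            self.U = np.column_stack([np.ones_like(x), x])  # (n, 2)
        else:
            self.U = np.ones((len(x), 1))
        self.q = term.q
        self.dim = self.n_levels * self.q

    def cholesky(self, theta_part: np.ndarray) -> np.ndarray:
        """Lower Cholesky factor of the relative covariance (q x q)."""
        if not self.term.slope:
            return np.array([[theta_part[0]]])
        if self.term.correlated:
            return np.array([[theta_part[0], 0.0], [theta_part[1], theta_part[2]]])
        return np.array([[theta_part[0], 0.0], [0.0, theta_part[1]]])


class _Design:
    def __init__(self, table: pd.DataFrame, spec: GLMMSpec):
        self.spec = spec
        y = table[spec.response].to_numpy(dtype=np.float64)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError(f"response {spec.response!r} must be binary 0/1")
        self.y = y
        self.n = len(y)
        if spec.predictor is not None:
            x = table[spec.predictor].to_numpy(dtype=np.float64)
            if np.ptp(x) == 0:
                raise ValueError(
                    f"predictor {spec.predictor!r} is constant; the slope is "
                    "not identifiable"
                )
            self.X = np.column_stack([np.ones(self.n), x])
            self._x = x
        else:
            # slopes in random terms still need the covariate if present
            self._x = (
                table["knowledge"].to_numpy(dtype=np.float64)
                if "knowledge" in table.columns
                else np.zeros(self.n)
            )
            self.X = np.ones((self.n, 1))
        self.p = self.X.shape[1]
        self.terms = [_TermDesign(t, table, self._x) for t in spec.random]
        self.v_dim = sum(t.dim for t in self.terms)
        self.dim = self.p + self.v_dim
        self.offsets = []
        off = self.p
        for t in self.terms:
            self.offsets.append(off)
            off += t.dim
        self.n_theta = sum(t.term.n_theta for t in self.terms)

    # -- theta packing ----------------------------------------------------- #

    def theta0(self) -> np.ndarray:
        out = []
        for t in self.terms:
            if not t.term.slope:
                out += [1.0]
            elif t.term.correlated:
                out += [1.0, 0.0, 1.0]
            else:
                out += [1.0, 1.0]
        return np.array(out)

    def theta_bounds(self) -> list[tuple[float | None, float | None]]:
        bounds: list[tuple[float | None, float | None]] = []
        for t in self.terms:
            if not t.term.slope:
                bounds.append((0.0, None))
            elif t.term.correlated:
                bounds += [(0.0, None), (None, None), (0.0, None)]
            else:
                bounds += [(0.0, None), (0.0, None)]
        return bounds

    def split_theta(self, theta: np.ndarray) -> list[np.ndarray]:
        parts = []
        i = 0
        for t in self.terms:
            parts.append(np.asarray(theta[i : i + t.term.n_theta], dtype=np.float64))
            i += t.term.n_theta
        return parts

    # -- penalized iteratively reweighted least squares -------------------- #

    def _linpred(self, beta: np.ndarray, V: list[np.ndarray], C: list[np.ndarray]) -> np.ndarray:
        eta = self.X @ beta
        for t, Vt, Ct in zip(self.terms, V, C):
            eta += np.einsum("ij,ij->i", Ct, Vt[t.g])
        return eta

    def _pdev(self, eta: np.ndarray, v: np.ndarray) -> float:
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        # -2 log-likelihood of the Bernoulli observations, numerically stable
        ll = self.y * eta - np.logaddexp(0.0, eta)
        return float(-2.0 * ll.sum() + v @ v)

    def _assemble(
        self,
        w: np.ndarray,
        C: list[np.ndarray],
    ) -> np.ndarray:
        """Dense penalized Hessian: [X, ZLambda]' W [X, ZLambda] + diag(0, I)."""
        H = np.zeros((self.dim, self.dim))
        Xw = self.X * w[:, None]
        H[: self.p, : self.p] = Xw.T @ self.X
        for s, (ts, Cs) in enumerate(zip(self.terms, C)):
            offs = self.offsets[s]
            # X' W C_s block
            for a in range(ts.q):
                for b in range(self.p):
                    vals = np.bincount(
                        ts.g, weights=w * Cs[:, a] * self.X[:, b], minlength=ts.n_levels
                    )
                    H[b, offs + a :: ts.q][: ts.n_levels] = vals
            # diagonal block of term s (block-diagonal per level) + identity
            for a in range(ts.q):
                for b in range(ts.q):
                    vals = np.bincount(
                        ts.g, weights=w * Cs[:, a] * Cs[:, b], minlength=ts.n_levels
                    )
                    rows = offs + np.arange(ts.n_levels) * ts.q + a
                    cols = offs + np.arange(ts.n_levels) * ts.q + b
                    H[rows, cols] = vals
            # cross blocks with later terms
            for t_idx in range(s + 1, len(self.terms)):
                tt, Ct = self.terms[t_idx], C[t_idx]
                offt = self.offsets[t_idx]
                combined = ts.g * tt.n_levels + tt.g
                for a in range(ts.q):
                    rows = offs + np.arange(ts.n_levels) * ts.q + a
                    for b in range(tt.q):
                        M = np.bincount(
                            combined,
                            weights=w * Cs[:, a] * Ct[:, b],
                            minlength=ts.n_levels * tt.n_levels,
                        ).reshape(ts.n_levels, tt.n_levels)
                        cols = offt + np.arange(tt.n_levels) * tt.q + b
                        H[np.ix_(rows, cols)] = M
        # only the upper triangle was filled for cross blocks; mirror it
        H = np.triu(H) + np.triu(H, 1).T
        idx = np.arange(self.p, self.dim)
        H[idx, idx] += 1.0
        return H

    def pirls(
        self,
        theta: np.ndarray,
        start: tuple[np.ndarray, np.ndarray] | None = None,
        max_iter: int = 60,
        tol: float = 1e-9,
        fixed_beta: np.ndarray | None = None,
    ) -> dict:
        """Inner penalized Newton at fixed theta.

        With ``fixed_beta=None`` the solve is joint over (beta, v) -- beta is
        profiled at the penalized mode, glmer's nAGQ=0 scheme, used to locate
        good starting values.  With ``fixed_beta`` given, only the random
        modes v are solved, which is what evaluating the true Laplace
        objective at (theta, beta) requires.
        """
        L = [t.cholesky(part) for t, part in zip(self.terms, self.split_theta(theta))]
        C = [t.U @ Ls for t, Ls in zip(self.terms, L)]  # (n, q) per-row effects design
        profile = fixed_beta is None
        if profile:
            beta = start[0].copy() if start is not None else np.zeros(self.p)
        else:
            beta = np.asarray(fixed_beta, dtype=np.float64)
        v = start[1].copy() if start is not None else np.zeros(self.v_dim)
        V = self._split_v(v)
        eta = self._linpred(beta, V, C)
        pdev = self._pdev(eta, v)
        for _ in range(max_iter):
            mu = expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
            w = np.maximum(mu * (1.0 - mu), 1e-10)
            resid = self.y - mu
            grad = np.empty(self.dim)
            grad[: self.p] = self.X.T @ resid
            for t, Ct, off in zip(self.terms, C, self.offsets):
                for a in range(t.q):
                    grad[off + a :: t.q][: t.n_levels] = np.bincount(
                        t.g, weights=resid * Ct[:, a], minlength=t.n_levels
                    )
            grad[self.p :] -= v
            H = self._assemble(w, C)
            try:
                if profile:
                    step = np.linalg.solve(H, grad)
                    step_beta, step_v = step[: self.p], step[self.p :]
                else:
                    step_beta = np.zeros(self.p)
                    step_v = np.linalg.solve(H[self.p :, self.p :], grad[self.p :])
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(f"singular penalized Hessian: {exc}") from exc
            # step-halving line search on the penalized deviance
            scale = 1.0
            for _ in range(25):
                beta_new = beta + scale * step_beta
                v_new = v + scale * step_v
                V_new = self._split_v(v_new)
                eta_new = self._linpred(beta_new, V_new, C)
                pdev_new = self._pdev(eta_new, v_new)
                if pdev_new <= pdev + 1e-12:
                    break
                scale *= 0.5
            else:
                break  # no descent possible: treat current point as converged
            delta = pdev - pdev_new
            beta, v, V, eta, pdev = beta_new, v_new, V_new, eta_new, pdev_new
            if delta < tol:
                break
        mu = expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        H = self._assemble(w, C)
        if self.v_dim:
            sign, logdet = np.linalg.slogdet(H[self.p :, self.p :])
            if sign <= 0:
                raise ConvergenceError("non-positive-definite random-effects Hessian")
        else:
            logdet = 0.0
        return {
            "deviance": pdev + logdet,
            "pdev": pdev,
            "beta": beta,
            "v": v,
            "L": L,
            "theta": np.asarray(theta, dtype=np.float64),
        }

    def _split_v(self, v: np.ndarray) -> list[np.ndarray]:
        out = []
        i = 0
        for t in self.terms:
            out.append(v[i : i + t.dim].reshape(t.n_levels, t.q))
            i += t.dim
        return out


@dataclass
class GLMMFit:
    """A converged Laplace fit."""

    spec: GLMMSpec
    beta: np.ndarray
    theta: np.ndarray
    deviance: float
    v: np.ndarray
    n_obs: int
    design: _Design = field(repr=False)
    simplified_from: GLMMSpec | None = None

    @property
    def loglik(self) -> float:
        return -0.5 * self.deviance

    @property
    def beta_knowledge(self) -> float | None:
        if self.spec.predictor is None:
            return None
        return float(self.beta[1])

    @property
    def odds_ratio(self) -> float | None:
        b = self.beta_knowledge
        return None if b is None else float(np.exp(b))

    def covariances(self) -> dict[str, np.ndarray]:
        """Random-effect covariance matrix per group (on the logit scale)."""
        out = {}
        for t, part in zip(self.design.terms, self.design.split_theta(self.theta)):
            L = t.cholesky(part)
            out[t.term.group] = L @ L.T
        return out

    def is_singular(self, tol: float = _SINGULAR_TOL) -> bool:
        for t, part in zip(self.design.terms, self.design.split_theta(self.theta)):
            L = t.cholesky(part)
            if np.any(np.abs(np.diag(L)) < tol):
                return True
        return False

    def simulate(self, rng: np.random.Generator) -> np.ndarray:
        """Draw a response vector from the fitted model (new random effects)."""
        d = self.design
        parts = d.split_theta(self.theta)
        eta = d.X @ self.beta
        for t, part in zip(d.terms, parts):
            L = t.cholesky(part)
            u = rng.standard_normal((t.n_levels, t.q)) @ L.T
            eta += np.einsum("ij,ij->i", t.U, u[t.g])
        p = expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        return (rng.random(d.n) < p).astype(np.float64)


def _simplify_once(spec: GLMMSpec) -> GLMMSpec | None:
    """Remove one unit of random-effects structure, or None if nothing left."""
    for group in spec.simplification_order + tuple(
        t.group for t in spec.random if t.group not in spec.simplification_order
    ):
        for i, term in enumerate(spec.random):
            if term.group != group:
                continue
            if term.slope and term.correlated:
                new = replace(term, correlated=False)
            elif term.slope:
                new = replace(term, slope=False)
            else:
                new = None
            random = list(spec.random)
            if new is None:
                random.pop(i)
            else:
                random[i] = new
            return replace(spec, random=tuple(random))
    return None


def fit_glmm(
    table: pd.DataFrame,
    spec: GLMMSpec | None = None,
    simplify: bool = True,
    start: dict | None = None,
    xatol: float = 1e-4,
    fatol: float = 1e-7,
    maxfev: int | None = None,
    method: str = "laplace",
) -> GLMMFit:
    """Maximum-likelihood Laplace fit of the logistic mixed model.

    Parameters
    ----------
    table:
        One row per (participant, quiz, question) with the response and
        predictor columns named in ``spec`` plus every grouping column.
    spec:
        Model structure; defaults to correlated intercept + slope terms for
        participant and question.
    simplify:
        Iteratively remove random-effects structure (correlation, slope,
        term) when a fit fails or is singular, re-fitting until a full-rank
        converged model is found.
    start:
        Optional warm start: ``{"theta": ..., "beta": ..., "v": ...}``.
    xatol, fatol, maxfev:
        Tolerances of the outer Nelder-Mead optimization over theta.
    method:
        ``"laplace"`` (default): true Laplace objective, outer optimization
        over (theta, beta) with the random modes profiled -- matches glmer
        at nAGQ = 1.  ``"nagq0"``: beta profiled jointly with the random
        modes in the inner Newton, outer over theta only -- glmer's nAGQ = 0
        scheme, several-fold faster and used for the internally consistent
        deviance comparisons of the parametric bootstrap.
    """
    if spec is None:
        spec = GLMMSpec()
    if table[spec.response].nunique() < 2:
        raise ValueError(f"response {spec.response!r} has no variation")
    if method not in ("laplace", "nagq0"):
        raise ValueError(f"unknown method {method!r}")
    attempted = spec
    original = spec
    while True:
        try:
            fit = _fit_fixed_structure(table, attempted, start, xatol, fatol, maxfev, method)
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            simpler = _simplify_once(attempted) if simplify else None
            if simpler is None:
                raise ConvergenceError(
                    f"model {attempted.formula()!r} failed to converge: {exc}"
                ) from exc
            attempted = simpler
            start = None
            continue
        if simplify and fit.is_singular():
            simpler = _simplify_once(attempted)
            if simpler is not None:
                attempted = simpler
                start = None
                continue
        if attempted is not original:
            fit.simplified_from = original
        return fit


def _fit_fixed_structure(
    table: pd.DataFrame,
    spec: GLMMSpec,
    start: dict | None,
    xatol: float,
    fatol: float,
    maxfev: int,
    method: str = "laplace",
) -> GLMMFit:
    design = _Design(table, spec)
    if maxfev is None:
        maxfev = 300 * (design.n_theta + design.p + 1)
    if design.v_dim == 0:
        # plain logistic regression: the joint Newton is exact ML
        res = design.pirls(np.empty(0))
        return _finalize(design, spec, res)

    warm: dict = {"beta": None, "v": None}
    have_start = False
    theta0 = design.theta0()
    beta0 = None
    if start:
        if start.get("beta") is not None and len(start["beta"]) == design.p:
            beta0 = np.asarray(start["beta"], dtype=np.float64)
        if start.get("v") is not None and len(start["v"]) == design.v_dim:
            warm["v"] = np.asarray(start["v"], dtype=np.float64)
        if start.get("theta") is not None and len(start["theta"]) == design.n_theta:
            theta0 = np.asarray(start["theta"], dtype=np.float64)
            have_start = beta0 is not None
        warm["beta"] = beta0

    if not have_start or method == "nagq0":
        # stage 1: profile beta in the inner solve (nAGQ=0) to locate theta
        best0: dict = {}

        def objective0(theta: np.ndarray) -> float:
            st = None
            if warm["beta"] is not None and warm["v"] is not None:
                st = (warm["beta"], warm["v"])
            try:
                res = design.pirls(theta, start=st)
            except ConvergenceError:
                return 1e10
            warm["beta"], warm["v"] = res["beta"], res["v"]
            if not best0 or res["deviance"] < best0["deviance"]:
                best0.clear()
                best0.update(res)
            return res["deviance"]

        res0 = minimize(
            objective0,
            theta0,
            method="Nelder-Mead",
            bounds=design.theta_bounds(),
            options={"xatol": xatol, "fatol": fatol, "maxfev": maxfev},
        )
        if not best0:
            raise ConvergenceError(f"all theta evaluations failed for {spec.formula()!r}")
        if method == "nagq0":
            if not res0.success and res0.nfev >= maxfev:
                raise ConvergenceError(
                    f"outer optimization did not converge for {spec.formula()!r}"
                )
            return _finalize(design, spec, best0)
        theta0 = best0["theta"]
        beta0 = best0["beta"]
        warm["v"] = best0["v"]

    # stage 2: true Laplace -- outer optimization over (theta, beta) with the
    # random modes v solved in the inner Newton
    best: dict = {}
    n_theta = design.n_theta

    def objective(params: np.ndarray) -> float:
        theta = params[:n_theta]
        beta = params[n_theta:]
        st = (beta, warm["v"]) if warm["v"] is not None else None
        try:
            res = design.pirls(theta, start=st, fixed_beta=beta)
        except ConvergenceError:
            return 1e10
        warm["v"] = res["v"]
        if not best or res["deviance"] < best["deviance"]:
            best.clear()
            best.update(res)
        return res["deviance"]

    params0 = np.concatenate([theta0, beta0])
    bounds = design.theta_bounds() + [(None, None)] * design.p
    result = minimize(
        objective,
        params0,
        method="Nelder-Mead",
        bounds=bounds,
        options={"xatol": xatol, "fatol": fatol, "maxfev": maxfev},
    )
    if not best:
        raise ConvergenceError(f"all Laplace evaluations failed for {spec.formula()!r}")
    if not result.success and result.nfev >= maxfev:
        raise ConvergenceError(
            f"outer optimization did not converge for {spec.formula()!r}"
        )
    return _finalize(design, spec, best)


def _finalize(design: _Design, spec: GLMMSpec, res: dict) -> GLMMFit:
    beta = res["beta"]
    if not np.all(np.isfinite(beta)) or np.any(np.abs(beta) > 1e3):
        groups = ", ".join(t.term.group for t in design.terms) or "none"
        raise ConvergenceError(
            f"diverging fixed effects (possible separation); groupings: {groups}"
        )
    return GLMMFit(
        spec=spec,
        beta=beta,
        theta=res["theta"],
        deviance=res["deviance"],
        v=res["v"],
        n_obs=design.n,
        design=design,
    )


# --------------------------------------------------------------------------- #
# bootstrap machinery
# --------------------------------------------------------------------------- #


#: Outer-optimization tolerances for warm-started bootstrap refits.  The
#: resample distributions (percentile CIs, simulated LRT statistics) are far
#: wider than 1e-3 in theta, so the tight point-estimate tolerances would
#: only burn Nelder-Mead evaluations.
_BOOT_TOL = {"xatol": 1e-3, "fatol": 1e-4}


def odds_ratio_ci(
    table: pd.DataFrame,
    spec: GLMMSpec | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
    max_failure_rate: float = 0.1,
) -> tuple[float, tuple[float, float]]:
    """Odds ratio with a percentile bootstrap 95% CI.

    Rows are resampled with replacement (full size); the model is refit to
    each resample and ``exp(beta_knowledge)`` collected.  Failed refits are
    dropped; more than ``max_failure_rate`` failures aborts.
    """
    if spec is None:
        spec = GLMMSpec()
    if spec.predictor is None:
        raise ValueError("odds_ratio_ci requires a model with a fixed predictor")
    table = table.loc[np.isfinite(table[spec.predictor].to_numpy(dtype=np.float64))]
    table = table.reset_index(drop=True)
    fit = fit_glmm(table, spec)
    spec_final = fit.spec
    rng = np.random.default_rng(seed)
    ors = []
    failures = 0
    n = len(table)
    warm = {"theta": fit.theta, "beta": fit.beta, "v": None}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = table.iloc[idx].reset_index(drop=True)
        try:
            bfit = fit_glmm(sample, spec_final, simplify=False, start=warm,
                            method="nagq0", **_BOOT_TOL)
            ors.append(bfit.odds_ratio)
        except (ConvergenceError, np.linalg.LinAlgError, ValueError):
            failures += 1
    if failures > max_failure_rate * n_boot:
        raise ConvergenceError(
            f"{failures}/{n_boot} bootstrap refits failed; data too unstable"
        )
    lo, hi = np.percentile(ors, [2.5, 97.5])
    return fit.odds_ratio, (float(lo), float(hi))


@dataclass(frozen=True)
class GLMMResult:
    """Summary of the knowledge-effect test for one model cell."""

    beta_knowledge: float
    OR: float
    OR_CI: tuple[float, float] | None
    lambda_LR: float
    p_boot: float
    boot_counts: tuple[int, int]  # (exceedances r, completed simulations n)
    converged_structure: tuple[RandomTerm, ...]

    def __post_init__(self) -> None:
        r, n = self.boot_counts
        expected = (r + 1) / (n + 1)
        if abs(self.p_boot - expected) > 1e-12:
            raise ValueError("p_boot must equal (r + 1) / (n + 1)")
        if self.lambda_LR < 0:
            raise ValueError("lambda_LR must be non-negative")


def bootstrap_lrt(
    table: pd.DataFrame,
    spec: GLMMSpec | None = None,
    n_sim: int = 10_000,
    seed: int = 0,
    n_boot_or: int | None = None,
    max_failure_rate: float = 0.1,
    regenerate=None,
) -> GLMMResult:
    """Parametric-bootstrap likelihood-ratio test of the knowledge effect.

    The full model is compared with the nested null (same random structure,
    fixed predictor removed).  ``n_sim`` response vectors are simulated from
    the fitted null model (sampling new random effects), both models are
    refit to each, and the observed statistic's exceedance count gives
    ``p = (r + 1) / (n_sim + 1)``.  When ``n_boot_or`` is set, a row-resample
    bootstrap CI for the odds ratio is computed as well.

    ``regenerate`` hooks in the full-pipeline null simulation: because the
    knowledge predictor is itself computed from the quiz responses, a null
    simulation that redraws responses but freezes the predictor fails to
    reproduce the predictor-response coupling of the real data-generating
    process, which anti-conservatively biases the test.  Passing a callable
    ``accuracy_vector -> knowledge_vector`` (NaN marks rows excluded for the
    simulated labels; see
    :meth:`knowmap.knowledge.HeldoutEstimator.recompute`) recomputes the
    predictor inside every simulation.  Rows with NaN knowledge (observed or
    simulated) are dropped from the corresponding fits.
    """
    if spec is None:
        spec = GLMMSpec()
    if spec.predictor is None:
        raise ValueError("bootstrap_lrt requires a model with a fixed predictor")
    knowledge = table[spec.predictor].to_numpy(dtype=np.float64)
    valid = np.isfinite(knowledge)
    obs_table = table.loc[valid].reset_index(drop=True)
    # point estimates (OR, beta) from the full Laplace fit; the deviance
    # comparisons of the LRT chain use the faster profiled-beta scheme,
    # identically for the observed statistic and every simulated one
    full = fit_glmm(obs_table, spec)
    spec_final = full.spec
    full_fast = fit_glmm(
        obs_table, spec_final, simplify=False, method="nagq0",
        start={"theta": full.theta, "beta": full.beta, "v": full.v}, **_BOOT_TOL,
    )
    null = fit_glmm(
        obs_table, spec_final.null_spec(), simplify=False, method="nagq0",
        start={"theta": full.theta}, **_BOOT_TOL,
    )
    lam = max(0.0, null.deviance - full_fast.deviance)

    rng = np.random.default_rng(seed)
    y_obs_full = table[spec.response].to_numpy(dtype=np.float64)
    exceed = 0
    completed = 0
    failures = 0
    warm_null = {"theta": null.theta, "beta": null.beta, "v": None}
    warm_full = {"theta": full_fast.theta, "beta": full_fast.beta, "v": None}
    for _ in range(n_sim):
        y_sim_valid = null.simulate(rng)
        if regenerate is None:
            sim_table = obs_table.copy()
            sim_table[spec.response] = y_sim_valid
        else:
            # rows excluded at the observed labels keep their observed
            # responses; they sit outside the fitted design
            y_full = y_obs_full.copy()
            y_full[valid] = y_sim_valid
            k_sim = np.asarray(regenerate(y_full), dtype=np.float64)
            keep = np.isfinite(k_sim)
            sim_table = table.loc[keep].reset_index(drop=True)
            sim_table[spec.predictor] = k_sim[keep]
            sim_table[spec.response] = y_full[keep]
        try:
            nfit = fit_glmm(
                sim_table, spec_final.null_spec(), simplify=False,
                start=warm_null, method="nagq0", **_BOOT_TOL,
            )
            ffit = fit_glmm(
                sim_table, spec_final, simplify=False,
                start=warm_full, method="nagq0", **_BOOT_TOL,
            )
        except (ConvergenceError, np.linalg.LinAlgError, ValueError):
            failures += 1
            continue
        lam_sim = max(0.0, nfit.deviance - ffit.deviance)
        completed += 1
        if lam_sim > lam:
            exceed += 1
    if completed == 0 or failures > max_failure_rate * n_sim:
        raise ConvergenceError(
            f"{failures}/{n_sim} simulated refits failed; aborting the LRT"
        )
    p = (exceed + 1) / (completed + 1)

    or_ci: tuple[float, float] | None = None
    if n_boot_or:
        _, or_ci = odds_ratio_ci(table, spec_final, n_boot=n_boot_or, seed=seed + 1)
    return GLMMResult(
        beta_knowledge=float(full.beta[1]),
        OR=float(np.exp(full.beta[1])),
        OR_CI=or_ci,
        lambda_LR=float(lam),
        p_boot=p,
        boot_counts=(exceed, completed),
        converged_structure=spec_final.random,
    )
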