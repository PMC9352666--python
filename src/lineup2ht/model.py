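"""Model and results classes for fitting the 2-HT lineup model.

`TwoHTModel` binds a model specification to a set of per-condition
frequency tables; `fit` maximises the product-multinomial likelihood by
expectation-maximisation (with a quasi-Newton cross-check on the logit
scale) and returns a `TwoHTResults` carrying the estimates, standard
errors, expected frequencies, the G² goodness-of-fit statistic and
convergence diagnostics.  Nested models are compared with
`likelihood_ratio_test`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import chi2

from ._em import CompiledModel
from .spec import ModelSpec, degrees_of_freedom, saturated_spec
from .trees import CA_CATEGORIES, CP_CATEGORIES, PARAM_NAMES, LineupCounts

__all__ = [
    "TwoHTModel",
    "TwoHTResults",
    "LRTestResult",
    "NotNestedError",
    "g_squared",
    "likelihood_ratio_test",
]


def g_squared(observed, expected) -> float:
    """Log-likelihood-ratio statistic G² = 2 Σ O ln(O/E).

    Categories with O = 0 contribute nothing.  A category with O > 0 but
    E = 0 cannot be fit at all and yields ``inf``.
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must have matching shapes")
    mask = observed > 0
    if np.any(expected[mask] <= 0.0):
        return float("inf")
    return float(2.0 * np.sum(observed[mask] * np.log(observed[mask] / expected[mask])))

_HEURISTIC_START = {"dP": 0.5, "b": 0.1, "g": 0.5, "dA": 0.1}
_BOUNDARY_TOL = 1e-4


class NotNestedError(ValueError):
    """Raised when a likelihood-ratio comparison is structurally invalid."""


def _chi2_sf(stat: float, df: int) -> float:
    if df == 0:
        # degenerate chi-square: all mass at zero
        return 1.0 if stat <= 1e-8 else 0.0
    return float(chi2.sf(stat, df))


class TwoHTModel:
    """The 2-HT lineup identification model bound to observed data.

    Parameters
    ----------
    data
        One `LineupCounts` per condition, in the order of the spec.
    spec
        Parameter-binding specification.  ``None`` selects the saturated
        per-condition model (four free parameters per condition).
    """

    def __init__(self, data: Sequence[LineupCounts], spec: ModelSpec | None = None):
        self.data = list(data)
        if spec is None:
            spec = saturated_spec([d.condition_id for d in self.data])
        self.spec = spec
        self._compiled = CompiledModel(spec, self.data)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, spec: ModelSpec | None = None
    ) -> "TwoHTModel":
        """Build from a data frame with the standard count columns."""
        from .io import counts_from_dataframe

        return cls(counts_from_dataframe(frame), spec=spec)

    @classmethod
    def from_csv(cls, path, spec: ModelSpec | None = None) -> "TwoHTModel":
        from .io import read_counts_csv

        return cls(read_counts_csv(path), spec=spec)

    # -- likelihood surface -------------------------------------------------

    @property
    def free_parameters(self) -> tuple[str, ...]:
        return self.spec.free_parameters

    def loglike(self, params: np.ndarray) -> float:
        """Product-multinomial log-likelihood kernel at ``params``."""
        return self._compiled.loglike(np.asarray(params, dtype=float))

    def score(self, params: np.ndarray) -> np.ndarray:
        return self._compiled.score(np.asarray(params, dtype=float))

    def g_squared(self, params: np.ndarray) -> float:
        """G² = 2 Σ O ln(O/E) at ``params`` (terms with O = 0 vanish)."""
        return self._compiled.g_squared(np.asarray(params, dtype=float))

    def expected(self, params: np.ndarray) -> np.ndarray:
        return self._compiled.expected(np.asarray(params, dtype=float))

    def category_probs(self, params: np.ndarray) -> np.ndarray:
        return self._compiled.category_probs(np.asarray(params, dtype=float))

    def degrees_of_freedom(self, strict_df: bool = False) -> int:
        return degrees_of_freedom(self.spec, self.data, strict_df=strict_df)

    # -- starting values ----------------------------------------------------

    def _heuristic_start(self) -> np.ndarray:
        start = np.empty(self.spec.n_free)
        slot_params: dict[str, set[str]] = {name: set() for name in self.free_parameters}
        for (cond, param), name in self.spec.bind.items():
            slot_params[name].add(param)
        for j, name in enumerate(self.free_parameters):
            kinds = slot_params[name]
            if len(kinds) == 1:
                start[j] = _HEURISTIC_START[next(iter(kinds))]
            else:
                start[j] = 0.5
        return start

    def _starts(self, n_restarts: int, seed: int | None) -> list[np.ndarray]:
        rng = np.random.default_rng(seed)
        starts = [self._heuristic_start()]
        for _ in range(n_restarts):
            starts.append(rng.uniform(0.02, 0.98, self.spec.n_free))
        return starts

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        *,
        method: str = "em",
        n_restarts: int = 10,
        seed: int | None = 20220804,
        tol: float = 1e-10,
        max_iter: int = 100_000,
        cross_check: bool = True,
        strict_df: bool = False,
        compute_se: bool = True,
    ) -> "TwoHTResults":
        """Maximise the likelihood and assemble a results object.

        ``method`` is ``"em"`` (default) or ``"optimizer"`` (quasi-Newton on
        logit-transformed parameters only).  ``n_restarts`` uniform-random
        starting vectors are used in addition to a heuristic start; the
        solution with the best likelihood wins, first found winning ties
        within 1e-9 of G².
        """
        starts = self._starts(n_restarts, seed)
        solutions: list[tuple[np.ndarray, float, bool]] = []
        if method == "em":
            for s in starts:
                theta, ll, conv, _, _ = self._compiled.run_em(s, tol=tol, max_iter=max_iter)
                solutions.append((theta, ll, conv))
        elif method == "optimizer":
            for s in starts:
                theta, ll = self._optimize_logit(s)
                solutions.append((theta, ll, True))
        else:
            raise ValueError(f"unknown method {method!r}")

        best_i = 0
        for i, (_, ll, _) in enumerate(solutions):
            if ll > solutions[best_i][1] + 1e-9:
                best_i = i
        theta, ll, converged = solutions[best_i]
        g2 = self._compiled.g_squared(theta)
        g2_all = [self._compiled.g_squared(t) for t, _, _ in solutions]
        n_agree = sum(1 for g in g2_all if abs(g - g2) <= 1e-3)
        diagnostics: dict = {
            "method": method,
            "n_starts": len(starts),
            "n_restarts_agreeing": n_agree,
            "restart_g_squared": g2_all,
        }
        if n_agree < len(starts):
            diagnostics["multimodality_warning"] = (
                f"{len(starts) - n_agree} of {len(starts)} starts ended more than "
                "1e-3 above the best G²; the likelihood may be multimodal"
            )
        if not converged:
            warnings.warn(
                f"fit did not converge within {max_iter} iterations", RuntimeWarning
            )
        if not np.isfinite(g2):
            diagnostics["nonfit"] = (
                "a category with positive observed count has expected count 0; "
                "G² is infinite"
            )

        if cross_check and method == "em":
            theta_qn, ll_qn = self._optimize_logit(theta)
            for s in starts[: min(3, len(starts))]:
                t2, l2 = self._optimize_logit(s)
                if l2 > ll_qn:
                    theta_qn, ll_qn = t2, l2
            g2_qn = self._compiled.g_squared(theta_qn)
            diagnostics["optimizer_g_squared"] = g2_qn
            diagnostics["em_optimizer_gap"] = abs(g2 - g2_qn)
            if g2_qn < g2 - 1e-4:
                warnings.warn(
                    "quasi-Newton cross-check found a better optimum than EM "
                    f"(gap {g2 - g2_qn:.3g})",
                    RuntimeWarning,
                )
            if ll_qn > ll:
                # the quasi-Newton polish sharpens the flat tail of EM
                # convergence; keep whichever solution is better
                theta, ll, g2 = theta_qn, ll_qn, g2_qn

        df = self.degrees_of_freedom(strict_df=strict_df)
        result = TwoHTResults(
            model=self,
            params=theta,
            llf=ll,
            g_squared=g2,
            df=df,
            p_value=_chi2_sf(g2, df),
            converged=converged,
            n_restarts_agreeing=n_agree,
            diagnostics=diagnostics,
            strict_df=strict_df,
        )
        if compute_se:
            result._compute_standard_errors()
        return result

    def _optimize_logit(self, start: np.ndarray) -> tuple[np.ndarray, float]:
        """Quasi-Newton maximisation on logit-transformed parameters."""
        x0 = logit(np.clip(start, 1e-9, 1 - 1e-9))

        def negll(x: np.ndarray) -> tuple[float, np.ndarray]:
            theta = expit(x)
            ll = self._compiled.loglike(theta)
            if not np.isfinite(ll):
                return 1e12, np.zeros_like(x)
            grad_theta = self._compiled.score(theta)
            grad_x = grad_theta * theta * (1.0 - theta)  # chain rule
            return -ll, -grad_x

        res = minimize(
            negll,
            np.clip(x0, -30, 30),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-10},
        )
        theta = expit(res.x)
        return theta, self._compiled.loglike(theta)

    # -- inference helpers ---------------------------------------------------

    def observed_information(self, params: np.ndarray, h: float = 1e-4) -> np.ndarray:
        """Observed Fisher information (negative Hessian of the log-likelihood).

        Central finite differences of the analytic score.  The category
        probabilities are polynomials in the parameters, so evaluation a
        half-step outside [0, 1] at boundary estimates is well defined as
        long as all fitted probabilities stay positive.
        """
        params = np.asarray(params, dtype=float)
        n = len(params)
        hess = np.zeros((n, n))
        for j in range(n):
            step = np.zeros(n)
            step[j] = h
            g_plus = self._compiled.score(params + step)
            g_minus = self._compiled.score(params - step)
            hess[:, j] = (g_plus - g_minus) / (2.0 * h)
        hess = 0.5 * (hess + hess.T)
        return -hess

    def probability_jacobian(self, params: np.ndarray, h: float = 1e-6) -> np.ndarray:
        """Jacobian of the independent category probabilities.

        Rows are the first two categories of every tree with a positive
        total (the third is redundant); columns are the free parameters.
        """
        params = np.asarray(params, dtype=float)
        keep = []
        for ci, d in enumerate(self.data):
            if d.n_cp > 0:
                keep.extend([6 * ci, 6 * ci + 1])
            if d.n_ca > 0:
                keep.extend([6 * ci + 3, 6 * ci + 4])
        keep = np.array(keep)
        jac = np.zeros((len(keep), len(params)))
        for j in range(len(params)):
            step = np.zeros(len(params))
            step[j] = h
            p_plus = self._compiled.category_probs(params + step)[keep]
            p_minus = self._compiled.category_probs(params - step)[keep]
            jac[:, j] = (p_plus - p_minus) / (2.0 * h)
        return jac

    def identifiability_check(self, params: np.ndarray) -> dict:
        """Local identifiability via the rank of the probability Jacobian.

        Boundary estimates are perturbed inward by 1e-3 before
        differentiation.  Rank deficiency flags the model as not locally
        identifiable at the solution.
        """
        theta = np.clip(np.asarray(params, dtype=float), 1e-3, 1.0 - 1e-3)
        jac = self.probability_jacobian(theta)
        sv = np.linalg.svd(jac, compute_uv=False)
        tol = max(jac.shape) * np.finfo(float).eps * (sv[0] if len(sv) else 0.0)
        tol = max(tol, 1e-10)
        rank = int(np.sum(sv > tol))
        return {
            "rank": rank,
            "n_free": self.spec.n_free,
            "identifiable": rank == self.spec.n_free,
            "singular_values": sv.tolist(),
        }


@dataclass
class LRTestResult:
    """Nested likelihood-ratio (ΔG²) comparison of two fits."""

    delta_g_squared: float
    delta_df: int
    p_value: float
    restricted_description: str = ""
    general_description: str = ""

    def __str__(self) -> str:
        return (
            f"dG2({self.delta_df}) = {self.delta_g_squared:.2f}, "
            f"p = {self.p_value:.3f}"
        )


@dataclass
class TwoHTResults:
    """Estimates, uncertainties and diagnostics of one fitted 2-HT model."""

    model: TwoHTModel
    params: np.ndarray
    llf: float
    g_squared: float
    df: int
    p_value: float
    converged: bool
    n_restarts_agreeing: int
    diagnostics: dict = field(default_factory=dict)
    strict_df: bool = False
    standard_errors: dict = field(default_factory=dict)
    boundary: dict = field(default_factory=dict)

    # -- derived quantities --------------------------------------------------

    @property
    def estimates(self) -> dict[str, float]:
        return dict(zip(self.model.free_parameters, map(float, self.params)))

    @property
    def bse(self) -> dict[str, float]:
        return dict(self.standard_errors)

    def expected(self) -> dict[str, np.ndarray]:
        """Expected frequencies per condition (six categories each)."""
        flat = self.model.expected(self.params)
        return {
            d.condition_id: flat[6 * i : 6 * i + 6]
            for i, d in enumerate(self.model.data)
        }

    def expected_frame(self) -> pd.DataFrame:
        """Observed and expected counts side by side."""
        rows = []
        flat_exp = self.model.expected(self.params)
        for i, d in enumerate(self.model.data):
            obs = d.observed()
            for j, cat in enumerate(CP_CATEGORIES + CA_CATEGORIES):
                rows.append(
                    {
                        "condition": d.condition_id,
                        "category": cat,
                        "observed": obs[j],
                        "expected": flat_exp[6 * i + j],
                    }
                )
        return pd.DataFrame(rows)

    def condition_parameters(self) -> pd.DataFrame:
        """Per-condition values of dP, b, g, dA implied by the binding."""
        est = self.estimates
        rows = []
        for d in self.model.data:
            row = {"condition": d.condition_id}
            for p in PARAM_NAMES:
                assignment = self.model.spec.assignment((d.condition_id, p))
                row[p] = est[assignment] if isinstance(assignment, str) else assignment
            rows.append(row)
        return pd.DataFrame(rows).set_index("condition")

    def identifiability(self) -> dict:
        return self.model.identifiability_check(self.params)

    # -- standard errors -----------------------------------------------------

    def _compute_standard_errors(self) -> None:
        names = self.model.free_parameters
        self.boundary = {
            name: bool(v < _BOUNDARY_TOL or v > 1.0 - _BOUNDARY_TOL)
            for name, v in zip(names, self.params)
        }
        info = self.model.observed_information(self.params)
        try:
            cov = np.linalg.inv(info)
            diag = np.diag(cov)
            if np.any(diag < 0) or not np.all(np.isfinite(diag)):
                raise np.linalg.LinAlgError("non-positive information diagonal")
            ses = np.sqrt(diag)
        except np.linalg.LinAlgError:
            self.standard_errors = {name: float("nan") for name in names}
            self.diagnostics["se_warning"] = (
                "observed information is singular or indefinite at the "
                "estimates; standard errors are undefined (possible "
                "identifiability problem)"
            )
            return
        self.standard_errors = dict(zip(names, map(float, ses)))

    # -- plotting ------------------------------------------------------------

    def plot_estimates(self, ax=None):
        """Bar chart of the free-parameter estimates with SE error bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        names = list(self.model.free_parameters)
        values = [self.estimates[n] for n in names]
        errors = [self.standard_errors.get(n, 0.0) for n in names]
        ax.bar(names, values, yerr=errors, capsize=3, color="0.6")
        ax.set_ylim(0, 1)
        ax.set_ylabel("probability estimate")
        ax.tick_params(axis="x", rotation=45)
        return ax

    # -- comparison ----------------------------------------------------------

    def lr_test(self, general: "TwoHTResults") -> LRTestResult:
        """Test this (restricted) model against a more general one."""
        return likelihood_ratio_test(self, general)

    # -- reporting -----------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "standard_errors": self.standard_errors,
            "boundary": self.boundary,
            "g_squared": float(self.g_squared),
            "df": int(self.df),
            "p_value": float(self.p_value),
            "log_likelihood": float(self.llf),
            "converged": bool(self.converged),
            "n_restarts_agreeing": int(self.n_restarts_agreeing),
            "expected": {c: list(map(float, e)) for c, e in self.expected().items()},
            "diagnostics": {
                k: v for k, v in self.diagnostics.items() if k != "restart_g_squared"
            },
            "spec": self.model.spec.to_dict(),
        }

    def summary(self) -> str:
        lines = []
        desc = self.model.spec.description or "2-HT lineup identification model"
        lines.append(desc)
        lines.append("=" * max(40, len(desc)))
        lines.append(
            f"G2({self.df}) = {self.g_squared:.2f}, p = {self.p_value:.3f}   "
            f"logL = {self.llf:.4f}"
        )
        lines.append(
            f"converged: {self.converged}   starts agreeing: "
            f"{self.n_restarts_agreeing}/{self.diagnostics.get('n_starts', '?')}"
        )
        if "em_optimizer_gap" in self.diagnostics:
            lines.append(
                f"EM vs quasi-Newton G2 gap: {self.diagnostics['em_optimizer_gap']:.2e}"
            )
        lines.append("")
        lines.append(f"{'parameter':<16}{'estimate':>10}{'std err':>10}  note")
        lines.append("-" * 44)
        for name in self.model.free_parameters:
            est = self.estimates[name]
            se = self.standard_errors.get(name, float("nan"))
            note = "at boundary" if self.boundary.get(name) else ""
            lines.append(f"{name:<16}{est:>10.2f}{se:>10.2f}  {note}")
        lines.append("")
        lines.append("observed vs expected frequencies")
        lines.append("-" * 44)
        frame = self.expected_frame()
        for cond, grp in frame.groupby("condition", sort=False):
            obs = " ".join(f"{v:6.0f}" for v in grp["observed"])
            exp = " ".join(f"{v:6.1f}" for v in grp["expected"])
            lines.append(f"{cond}")
            lines.append(f"  observed: {obs}")
            lines.append(f"  expected: {exp}")
        return "\n".join(lines)


def likelihood_ratio_test(
    restricted: TwoHTResults, general: TwoHTResults
) -> LRTestResult:
    """ΔG² test of a nested (restricted) model against a general model.

    The restriction is rejected when the restricted model fits
    significantly worse, i.e. when ΔG² = G²_restricted − G²_general exceeds
    the upper χ²(Δdf) quantile.
    """
    if restricted.model.data != general.model.data:
        raise ValueError("likelihood-ratio test requires identical data sets")
    if not restricted.model.spec.is_nested_in(general.model.spec):
        raise NotNestedError(
            "restricted spec is not a coarsening of the general spec"
        )
    delta_df = restricted.df - general.df
    if delta_df <= 0:
        raise NotNestedError(f"not nested (ddf={delta_df}); ddf must be positive")
    delta = restricted.g_squared - general.g_squared
    if delta < -1e-6:
        warnings.warn(
            f"restricted model fits better than the general model by {-delta:.3g}; "
            "check convergence",
            RuntimeWarning,
        )
    delta = max(delta, 0.0)
    return LRTestResult(
        delta_g_squared=float(delta),
        delta_df=int(delta_df),
        p_value=_chi2_sf(delta, delta_df),
        restricted_description=restricted.model.spec.description,
        general_description=general.model.spec.description,
    )
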