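"""Likelihood machinery for the multi-condition 2-HT model.

The product-multinomial likelihood is compiled into flat branch arrays so
that category probabilities, the log-likelihood kernel, the analytic score
and one EM step are all cheap vectorised operations.  The EM scheme is the
classic one for MPT models: the E-step distributes each observed category
count over the root-to-leaf branches that end in that category in
proportion to the branch probabilities, and the M-step updates each free
parameter as (expected successes) / (expected trials) aggregated over all
branches in which that parameter appears, with the structural ``1/k``
weights held constant.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

import numpy as np

from .spec import ModelSpec
from .trees import LineupCounts

__all__ = ["CompiledModel"]

# branch tables: (category offset within condition, factors, weight)
# a factor is (param name, success flag); category offsets follow
# (cp_culprit, cp_filler, cp_reject, ca_suspect, ca_filler, ca_reject).


def _branches(k: int):
    w1 = float(Fraction(1, k))
    wk = float(Fraction(k - 1, k))
    return [
        (0, [("dP", True)], 1.0),
        (0, [("dP", False), ("b", True)], 1.0),
        (0, [("dP", False), ("b", False), ("g", True)], w1),
        (1, [("dP", False), ("b", False), ("g", True)], wk),
        (2, [("dP", False), ("b", False), ("g", False)], 1.0),
        (5, [("dA", True)], 1.0),
        (3, [("dA", False), ("b", True)], 1.0),
        (3, [("dA", False), ("b", False), ("g", True)], w1),
        (4, [("dA", False), ("b", False), ("g", True)], wk),
        (5, [("dA", False), ("b", False), ("g", False)], 1.0),
    ]


class CompiledModel:
    """Branch-matrix representation of one spec bound to one data set."""

    def __init__(self, spec: ModelSpec, data: Sequence[LineupCounts]):
        if list(spec.conditions) != [d.condition_id for d in data]:
            raise ValueError("spec conditions do not match data conditions")
        self.spec = spec
        self.data = list(data)
        self.n_free = spec.n_free
        self._index = {name: j for j, name in enumerate(spec.free_parameters)}

        rows_a, rows_c, consts, cats = [], [], [], []
        for ci, d in enumerate(self.data):
            for offset, factors, weight in _branches(d.lineup_size):
                a = np.zeros(self.n_free)
                c = np.zeros(self.n_free)
                const = weight
                for param, success in factors:
                    assignment = spec.assignment((d.condition_id, param))
                    if isinstance(assignment, str):
                        j = self._index[assignment]
                        if success:
                            a[j] += 1.0
                        else:
                            c[j] += 1.0
                    else:
                        const *= assignment if success else 1.0 - assignment
                rows_a.append(a)
                rows_c.append(c)
                consts.append(const)
                cats.append(6 * ci + offset)
        self._A = np.array(rows_a)  # (n_branches, n_free) success exponents
        self._C = np.array(rows_c)  # failure exponents
        self._const = np.array(consts)
        self._cat = np.array(cats)

        self.observed = np.concatenate([d.observed() for d in self.data])
        totals = []
        for d in self.data:
            totals.extend([d.n_cp] * 3 + [d.n_ca] * 3)
        self.totals = np.array(totals, dtype=float)
        self._n_cat = len(self.observed)
        self._obs_pos = self.observed > 0
        # constant term of G^2: 2 * sum O log(O / N) over observed categories
        o = self.observed[self._obs_pos]
        n = self.totals[self._obs_pos]
        self._g2_const = 2.0 * np.sum(o * np.log(o / n))

    # -- probabilities and objectives --------------------------------------

    def branch_probs(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        # exponents are 0/1, so power is exact; guard 0**0 == 1 holds in numpy
        return (
            self._const
            * np.prod(theta ** self._A, axis=1)
            * np.prod((1.0 - theta) ** self._C, axis=1)
        )

    def category_probs(self, theta: np.ndarray) -> np.ndarray:
        p = np.zeros(self._n_cat)
        np.add.at(p, self._cat, self.branch_probs(theta))
        return p

    def expected(self, theta: np.ndarray) -> np.ndarray:
        return self.totals * self.category_probs(theta)

    def loglike(self, theta: np.ndarray) -> float:
        """Product-multinomial log-likelihood kernel: sum O log p."""
        p = self.category_probs(theta)[self._obs_pos]
        if np.any(p <= 0.0):
            return -np.inf
        return float(np.sum(self.observed[self._obs_pos] * np.log(p)))

    def g_squared(self, theta: np.ndarray) -> float:
        return self._g2_const - 2.0 * self.loglike(theta)

    def score(self, theta: np.ndarray) -> np.ndarray:
        """Analytic gradient of the log-likelihood kernel."""
        theta = np.asarray(theta, dtype=float)
        pb = self.branch_probs(theta)
        p = np.zeros(self._n_cat)
        np.add.at(p, self._cat, pb)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(p > 0, self.observed / np.where(p > 0, p, 1.0), 0.0)
        grad = np.zeros(self.n_free)
        for j in range(self.n_free):
            with np.errstate(divide="ignore", invalid="ignore"):
                dlog = self._A[:, j] / theta[j] - self._C[:, j] / (1.0 - theta[j])
            dlog = np.where(np.isfinite(dlog), dlog, 0.0)
            dp = np.zeros(self._n_cat)
            np.add.at(dp, self._cat, pb * dlog)
            grad[j] = np.sum(ratio * dp)
        return grad

    # -- EM ----------------------------------------------------------------

    def em_step(self, theta: np.ndarray) -> np.ndarray:
        pb = self.branch_probs(theta)
        p = np.zeros(self._n_cat)
        np.add.at(p, self._cat, pb)
        with np.errstate(divide="ignore", invalid="ignore"):
            share = np.where(p[self._cat] > 0, self.observed[self._cat] / p[self._cat], 0.0)
        m = pb * share  # expected branch counts
        succ = m @ self._A
        trials = m @ (self._A + self._C)
        new = theta.copy()
        mask = trials > 0
        new[mask] = succ[mask] / trials[mask]
        # keep strictly inside (0, 1) so branch probabilities stay defined
        return np.clip(new, 1e-12, 1.0 - 1e-12)

    def run_em(
        self,
        start: np.ndarray,
        tol: float = 1e-10,
        max_iter: int = 100_000,
        trace: bool = False,
    ) -> tuple[np.ndarray, float, bool, int, list[float]]:
        """Iterate EM to convergence in the log-likelihood.

        Returns (theta, loglik, converged, n_iter, trajectory).
        """
        theta = np.clip(np.asarray(start, dtype=float), 1e-12, 1.0 - 1e-12)
        ll = self.loglike(theta)
        trajectory = [ll] if trace else []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            theta = self.em_step(theta)
            ll_new = self.loglike(theta)
            if trace:
                trajectory.append(ll_new)
            if ll_new - ll < tol and np.isfinite(ll_new):
                ll = ll_new
                converged = True
                break
            ll = ll_new
        return theta, ll, converged, it, trajectory
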