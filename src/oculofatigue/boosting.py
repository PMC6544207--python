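"""Label-noise-robust boosting of depth-limited decision trees.

``RobustBoostClassifier`` follows the boost-by-majority family: boosting
runs on a virtual time axis t in [0, 1] and each example is weighted by
a Gaussian potential of its margin,

    w_i  ~  exp(-(m_i - mu(t))^2 / (2 sigma(t)^2)),

with the drift/width schedules

    sigma(t)^2 = (sigma_f^2 + 1) e^{2(1-t)} - 1,
    mu(t)      = (theta - 2 rho) e^{1-t} + 2 rho,

where ``theta`` is the target margin (``max_margin``) and ``rho`` is
calibrated so that the initial average potential equals the error goal
``epsilon``.  Unlike exponential-loss boosting, the weight of an example
with a very negative margin *decays*, which is what confers robustness
to mislabeled training points.

Each round fits a weighted tree (at most ``max_splits`` splits), then
advances the virtual time by the largest step for which the line-search
optimal vote weight ``alpha`` keeps the average potential from rising
(capped at twice the uniform per-round budget so easy problems still
spread over the ensemble).  On clean data the clock reaches 1 and the
final weight distribution concentrates around the target margin; on
noisy data the feasible step shrinks, the clock stalls before the
concentration phase, and persistently misclassified (mislabeled)
points are given up on instead of dominating the fit — the source of
the label-noise robustness.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import erfc, erfinv
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier

from oculofatigue.errors import ValidationError


def _sigma_sq(t: np.ndarray | float, sigma_f: float) -> np.ndarray | float:
    return (sigma_f**2 + 1.0) * np.exp(2.0 * (1.0 - t)) - 1.0


def _mu(t: np.ndarray | float, theta: float, rho: float) -> np.ndarray | float:
    return (theta - 2.0 * rho) * np.exp(1.0 - t) + 2.0 * rho


def _calibrate_rho(error_goal: float, theta: float, sigma_f: float) -> float:
    """rho such that the potential of a zero-margin example at t=0 is the error goal."""
    sigma0 = float(np.sqrt(_sigma_sq(0.0, sigma_f)))
    mu0 = -np.sqrt(2.0) * sigma0 * float(erfinv(1.0 - 2.0 * error_goal))
    e = np.e
    return float((mu0 - theta * e) / (2.0 * (1.0 - e)))


class RobustBoostClassifier(BaseEstimator, ClassifierMixin):
    """Boosted depth-limited trees with a noise-robust weight schedule.

    Parameters mirror the deployed configuration: 50 learners, at most
    5 splits per tree, error goal 0.25, max margin 1.
    """

    def __init__(
        self,
        n_learners: int = 50,
        max_splits: int = 5,
        error_goal: float = 0.25,
        max_margin: float = 1.0,
        margin_sigma: float = 0.1,
        max_vote_weight: float = 0.3,
        random_state: int | None = None,
    ):
        self.n_learners = n_learners
        self.max_splits = max_splits
        self.error_goal = error_goal
        self.max_margin = max_margin
        self.margin_sigma = margin_sigma
        # small per-round votes are essential: one large-vote tree could
        # hand mislabeled points a positive margin before the weight
        # schedule has had a chance to abandon them
        self.max_vote_weight = max_vote_weight
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _weights(self, margins: np.ndarray, t: float) -> np.ndarray:
        s2 = _sigma_sq(t, self.margin_sigma)
        w = np.exp(-((margins - _mu(t, self.max_margin, self._rho)) ** 2) / (2.0 * s2))
        total = w.sum()
        if total <= 0 or not np.isfinite(total):
            w = np.ones_like(w)
            total = w.sum()
        return w / total

    def _potential(self, margins: np.ndarray, t: float) -> float:
        s = np.sqrt(_sigma_sq(t, self.margin_sigma))
        z = (margins - _mu(t, self.max_margin, self._rho)) / (np.sqrt(2.0) * s)
        return float(np.mean(0.5 * erfc(z)))

    def fit(self, X, y, sample_weight=None) -> "RobustBoostClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValidationError(
                f"need exactly 2 classes, got {self.classes_.size}"
            )
        if not 0.0 < self.error_goal < 0.5:
            raise ValidationError("error_goal must be in (0, 0.5)")
        ysign = np.where(y == self.classes_[1], 1.0, -1.0)
        base_w = (np.ones(len(y)) if sample_weight is None
                  else np.asarray(sample_weight, dtype=float))
        self._rho = _calibrate_rho(self.error_goal, self.max_margin, self.margin_sigma)
        rng = np.random.RandomState(self.random_state)

        margins = np.zeros(len(y))
        t = 0.0
        self.estimators_: list[DecisionTreeClassifier] = []
        self.alphas_: list[float] = []
        for _ in range(self.n_learners):
            if t >= 1.0 - 1e-9:
                break
            w = self._weights(margins, t) * base_w
            if w.sum() <= 0:
                break
            tree = DecisionTreeClassifier(
                max_leaf_nodes=self.max_splits + 1,
                random_state=rng.randint(0, 2**31 - 1),
            )
            tree.fit(X, ysign, sample_weight=w / w.sum())
            h = np.sign(tree.predict(X))
            h[h == 0] = 1.0

            alpha, dt = self._solve_step(margins, ysign * h, t)
            if alpha <= 1e-6:
                continue  # learner no better than chance under current weights
            margins = margins + alpha * ysign * h
            t = min(1.0, t + dt)
            self.estimators_.append(tree)
            self.alphas_.append(alpha)
        if not self.estimators_:
            # degenerate: fall back to a single unweighted tree
            tree = DecisionTreeClassifier(
                max_leaf_nodes=self.max_splits + 1,
                random_state=rng.randint(0, 2**31 - 1),
            )
            tree.fit(X, ysign, sample_weight=base_w / base_w.sum())
            self.estimators_ = [tree]
            self.alphas_ = [1.0]
        self.final_time_ = t
        return self

    def _solve_step(self, margins: np.ndarray, agree: np.ndarray, t: float):
        """Vote weight + largest time step that keeps the potential conserved.

        For a candidate step dt, the optimal alpha minimizes the average
        potential at t+dt (equivalently, decorrelates the new weights
        from the weak hypothesis).  The step taken is the largest dt, up
        to a cap of two uniform per-round budgets, at which that
        minimized potential does not exceed the current one.
        """
        phi_now = self._potential(margins, t)
        cap = min(1.0 - t, 2.0 / self.n_learners)

        def best(dt: float) -> tuple[float, float]:
            res = minimize_scalar(
                lambda a: self._potential(margins + a * agree, t + dt),
                bounds=(0.0, self.max_vote_weight), method="bounded",
                options={"xatol": 1e-4},
            )
            return float(res.x), float(res.fun)

        a_cap, f_cap = best(cap)
        if f_cap <= phi_now + 1e-12:
            return a_cap, cap
        lo = cap * 1e-3
        alpha, f_lo = best(lo)
        if f_lo > phi_now + 1e-12:
            return alpha, lo          # can barely move; crawl forward
        hi = cap
        dt = lo
        for _ in range(16):
            mid = 0.5 * (lo + hi)
            a_mid, f_mid = best(mid)
            if f_mid <= phi_now + 1e-12:
                lo, alpha, dt = mid, a_mid, mid
            else:
                hi = mid
        return alpha, dt

    # -- prediction --------------------------------------------------------

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        total = np.zeros(len(X))
        for alpha, tree in zip(self.alphas_, self.estimators_):
            total += alpha * np.sign(tree.predict(X))
        norm = sum(self.alphas_)
        return total / norm if norm > 0 else total

    def predict_proba(self, X) -> np.ndarray:
        score = self.decision_function(X)          # in [-1, 1]
        p1 = np.clip((score + 1.0) / 2.0, 0.0, 1.0)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        p1 = self.predict_proba(X)[:, 1]
        return np.where(p1 >= 0.5, self.classes_[1], self.classes_[0])
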