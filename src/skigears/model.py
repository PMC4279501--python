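"""Markov-Gaussian gear models: estimation, likelihood and classification.

Each gear is modeled generatively as a first-order Markov chain of
multivariate Gaussian distributions over the 100-step normalized cycle
trajectory: the first step is Gaussian, v_1 ~ N(mu1, S1), and every
subsequent step depends linearly on its predecessor,

    p(v_t | v_{t-1}) = N(A_t v_{t-1} + b_t, Q_t),    t = 2..n_steps,

with v_t the 3-vector of accelerations at step t.  This keeps under 2k
parameters per class — far fewer than a full 300×300 covariance —
while still capturing the sequential correlation along the trajectory,
and it operates on continuous observations (no discretization).  A cycle
is classified by evaluating its log-likelihood under each of the five
gear models and taking the argmax (equal class priors; exact ties go to
the earlier gear in canonical order).

The estimator is plain conditional least squares: (A_t, b_t) is the
least-squares linear map from step t−1 to step t across training cycles,
Q_t the residual covariance; mu1/S1 are the first-step sample mean and
covariance.  Every covariance gets ``ridge``·I added, guaranteeing
positive definiteness even for degenerate training sets.

Following statsmodels conventions, :class:`GearMarkovModel` is the model
specification built from data and its :meth:`~GearMarkovModel.fit`
returns a :class:`GearClassifier` results object that carries the
estimates, diagnostics, a ``summary()`` table and the prediction and
serialization methods.  The module-level functions
(:func:`fit_markov_gaussian`, :func:`train_classifier`, ...) are thin
functional entry points over the same code.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import solve_triangular

from .exceptions import (CoverageError, InsufficientDataError,
                         ModelIntegrityError, ValidationError)
from .gears import GEARS, check_gear
from .io import AccelerometerStream, LabelInterval
from .preprocess import (CycleSegment, NormalizedCycle, PreprocessConfig,
                         extract_cycles, segment_cycles, normalize_cycle)

DEFAULT_RIDGE = 1e-3  # (m/s²)², added as ridge·I to every covariance

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class GearClassModel:
    """Fitted Markov-Gaussian parameters for one gear.

    ``A``, ``b``, ``Q`` stack the n_steps−1 conditional blocks:
    shapes (T−1, 3, 3), (T−1, 3) and (T−1, 3, 3).
    """

    gear: str
    mu1: np.ndarray
    S1: np.ndarray
    A: np.ndarray
    b: np.ndarray
    Q: np.ndarray
    ridge: float = DEFAULT_RIDGE
    n_train: int = 0
    _chol_S1: np.ndarray | None = field(default=None, repr=False, compare=False)
    _chol_Q: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        check_gear(self.gear)
        self.mu1 = np.asarray(self.mu1, float).reshape(3)
        self.S1 = np.asarray(self.S1, float).reshape(3, 3)
        self.A = np.asarray(self.A, float)
        self.b = np.asarray(self.b, float)
        self.Q = np.asarray(self.Q, float)
        T1 = self.A.shape[0]
        if self.A.shape != (T1, 3, 3) or self.b.shape != (T1, 3) \
                or self.Q.shape != (T1, 3, 3):
            raise ValidationError("inconsistent conditional block shapes")

    @property
    def n_steps(self) -> int:
        return self.A.shape[0] + 1

    @property
    def n_parameters(self) -> int:
        """Free parameters: 3+6 for the first step, 9+3+6 per transition."""
        return 9 + (self.n_steps - 1) * 18

    def _factorize(self) -> None:
        if self._chol_S1 is not None:
            return
        try:
            self._chol_S1 = np.linalg.cholesky(self.S1)
            self._chol_Q = np.linalg.cholesky(self.Q)
        except np.linalg.LinAlgError as exc:
            raise ModelIntegrityError(
                f"covariance for gear {self.gear} is not positive definite"
            ) from exc

    def log_likelihood_many(self, values: np.ndarray) -> np.ndarray:
        """Log-density of each cycle in ``values`` (N, n_steps, 3)."""
        V = np.asarray(values, float)
        if V.ndim == 2:
            V = V[None]
        if V.shape[1:] != (self.n_steps, 3):
            raise ValidationError(
                f"cycles have shape {V.shape[1:]}, model expects "
                f"({self.n_steps}, 3)"
            )
        self._factorize()
        L1, LQ = self._chol_S1, self._chol_Q
        # first step
        r1 = V[:, 0, :] - self.mu1                      # (N, 3)
        x1 = solve_triangular(L1, r1.T, lower=True).T   # (N, 3)
        maha = (x1 * x1).sum(axis=1)
        logdet = 2.0 * np.log(np.diag(L1)).sum()
        # transitions, vectorized over cycles per step
        pred = np.einsum("tij,ntj->nti", self.A, V[:, :-1, :]) + self.b
        resid = V[:, 1:, :] - pred                      # (N, T-1, 3)
        # solve L_t x = r for every step/cycle via precomputed inverses
        Linv = np.linalg.inv(LQ)                        # (T-1, 3, 3)
        x = np.einsum("tij,ntj->nti", Linv, resid)
        maha = maha + (x * x).sum(axis=(1, 2))
        logdet += 2.0 * np.log(np.diagonal(LQ, axis1=1, axis2=2)).sum()
        const = 3 * self.n_steps * _LOG_2PI
        return -0.5 * (maha + logdet + const)

    def log_likelihood(self, cycle: NormalizedCycle | np.ndarray) -> float:
        """Chain-factorized log-likelihood of a single cycle."""
        values = cycle.values if isinstance(cycle, NormalizedCycle) else cycle
        return float(self.log_likelihood_many(np.asarray(values)[None])[0])

    def to_dict(self) -> dict:
        return {
            "mu1": self.mu1.tolist(),
            "S1": self.S1.tolist(),
            "A": self.A.tolist(),
            "b": self.b.tolist(),
            "Q": self.Q.tolist(),
            "ridge": self.ridge,
            "n_train": self.n_train,
        }

    @classmethod
    def from_dict(cls, gear: str, d: dict) -> "GearClassModel":
        return cls(gear=gear, mu1=np.array(d["mu1"]), S1=np.array(d["S1"]),
                   A=np.array(d["A"]), b=np.array(d["b"]), Q=np.array(d["Q"]),
                   ridge=float(d.get("ridge", DEFAULT_RIDGE)),
                   n_train=int(d.get("n_train", 0)))


@dataclass(frozen=True)
class GearPrediction:
    """Predicted gear for one cycle, with per-gear log-likelihoods."""

    segment: CycleSegment
    gear: str
    loglik: dict[str, float]


def _stack_cycles(cycles: Sequence[NormalizedCycle | np.ndarray]) -> np.ndarray:
    arrs = [c.values if isinstance(c, NormalizedCycle) else np.asarray(c, float)
            for c in cycles]
    steps = {a.shape[0] for a in arrs}
    if len(steps) > 1:
        raise ValidationError(f"cycles disagree on n_steps: {sorted(steps)}")
    return np.stack(arrs)


def fit_markov_gaussian(cycles: Sequence[NormalizedCycle], gear: str,
                        ridge: float = DEFAULT_RIDGE) -> GearClassModel:
    """Estimate one gear's Markov-Gaussian model from normalized cycles.

    Requires at least two cycles with identical ``n_steps``.  The
    first-step covariance uses the unbiased sample covariance; each Q_t
    is the mean squared residual of the per-step least-squares fit.
    Both get ``ridge``·I added.
    """
    check_gear(gear)
    if len(cycles) < 2:
        raise InsufficientDataError(
            f"gear {gear}: need at least 2 cycles, got {len(cycles)}"
        )
    V = _stack_cycles(cycles)               # (N, T, 3)
    N, T, _ = V.shape
    eye = np.eye(3)
    mu1 = V[:, 0, :].mean(axis=0)
    dev = V[:, 0, :] - mu1
    S1 = dev.T @ dev / (N - 1) + ridge * eye
    A = np.empty((T - 1, 3, 3))
    b = np.empty((T - 1, 3))
    Q = np.empty((T - 1, 3, 3))
    ones = np.ones((N, 1))
    for t in range(1, T):
        D = np.hstack([V[:, t - 1, :], ones])           # (N, 4)
        coef, *_ = np.linalg.lstsq(D, V[:, t, :], rcond=None)
        A[t - 1] = coef[:3].T
        b[t - 1] = coef[3]
        resid = V[:, t, :] - D @ coef
        Q[t - 1] = resid.T @ resid / N + ridge * eye
    return GearClassModel(gear=gear, mu1=mu1, S1=S1, A=A, b=b, Q=Q,
                          ridge=ridge, n_train=N)


def log_likelihood(model: GearClassModel,
                   cycle: NormalizedCycle | np.ndarray) -> float:
    """Log-likelihood of a cycle under a fitted gear model."""
    return model.log_likelihood(cycle)


class GearMarkovModel:
    """Five-gear Markov-Gaussian classification model, built from data.

    Parameters
    ----------
    cycles_by_gear : mapping gear -> sequence of NormalizedCycle
        Training cycles; all five gears must be present with >= 2
        cycles each.
    preprocess_config : PreprocessConfig, optional
        The configuration used to produce the cycles; embedded in the
        fitted classifier so streams are preprocessed consistently.
    ridge : float
        Covariance regularization weight (added as ridge·I).
    regime : {"collective", "individual"}
        Whether the training corpus pools several sources or comes from
        a single skier's calibration trial.
    """

    def __init__(self, cycles_by_gear: Mapping[str, Sequence[NormalizedCycle]],
                 preprocess_config: PreprocessConfig | None = None,
                 ridge: float = DEFAULT_RIDGE,
                 regime: str = "collective") -> None:
        missing = [g for g in GEARS
                   if g not in cycles_by_gear or len(cycles_by_gear[g]) < 2]
        if missing:
            raise CoverageError(
                "training data must cover all five gears with >= 2 cycles "
                f"each; missing or insufficient: {', '.join(missing)}"
            )
        unknown = set(cycles_by_gear) - set(GEARS)
        if unknown:
            raise CoverageError(f"unknown gear labels in training data: "
                                f"{sorted(unknown)}")
        if regime not in ("collective", "individual"):
            raise ValidationError("regime must be 'collective' or 'individual'")
        self.cycles_by_gear = {g: list(cycles_by_gear[g]) for g in GEARS}
        self.preprocess_config = preprocess_config or PreprocessConfig()
        self.ridge = float(ridge)
        self.regime = regime

    @classmethod
    def from_trials(cls,
                    trials: Sequence[tuple[AccelerometerStream,
                                           Sequence[LabelInterval]]],
                    preprocess_config: PreprocessConfig | None = None,
                    ridge: float = DEFAULT_RIDGE,
                    regime: str | None = None) -> "GearMarkovModel":
        """Build the model from (stream, label intervals) trial pairs.

        Cycles are extracted from each stream and labeled by majority
        overlap with the intervals.  The regime defaults to
        ``individual`` for a single trial and ``collective`` otherwise.
        """
        from .evaluation import align_labels

        cfg = preprocess_config or PreprocessConfig()
        by_gear: dict[str, list[NormalizedCycle]] = {g: [] for g in GEARS}
        for stream, intervals in trials:
            segments = segment_cycles(stream, cfg)
            labels = align_labels(list(intervals), segments)
            for seg, lab in zip(segments, labels):
                if lab is not None:
                    by_gear[lab].append(normalize_cycle(stream, seg, cfg))
        if regime is None:
            regime = "individual" if len(trials) == 1 else "collective"
        return cls({g: cyc for g, cyc in by_gear.items() if cyc},
                   preprocess_config=cfg, ridge=ridge, regime=regime)

    def fit(self) -> "GearClassifier":
        """Estimate all five gear models; deterministic given the input."""
        models = {g: fit_markov_gaussian(self.cycles_by_gear[g], g, self.ridge)
                  for g in GEARS}
        train_loglik = {
            g: float(np.mean(models[g].log_likelihood_many(
                _stack_cycles(self.cycles_by_gear[g]))))
            for g in GEARS
        }
        return GearClassifier(models=models,
                              preprocess_config=self.preprocess_config,
                              regime=self.regime, ridge=self.ridge,
                              train_loglik=train_loglik)


class GearClassifier:
    """Fitted five-gear classifier (results object).

    Carries one :class:`GearClassModel` per gear in canonical order, the
    preprocessing configuration used at training time, and training
    diagnostics.  Classification is maximum likelihood with equal class
    priors; exact likelihood ties resolve to the earlier gear in
    canonical order.
    """

    def __init__(self, models: Mapping[str, GearClassModel],
                 preprocess_config: PreprocessConfig,
                 regime: str = "collective", ridge: float = DEFAULT_RIDGE,
                 train_loglik: Mapping[str, float] | None = None) -> None:
        if set(models) != set(GEARS):
            raise CoverageError(
                f"classifier requires exactly the gears {GEARS}; "
                f"got {sorted(models)}"
            )
        steps = {m.n_steps for m in models.values()}
        if len(steps) > 1:
            raise ValidationError(f"models disagree on n_steps: {sorted(steps)}")
        self.models = {g: models[g] for g in GEARS}
        self.preprocess_config = preprocess_config
        self.regime = regime
        self.ridge = ridge
        self.train_loglik = dict(train_loglik or {})

    @property
    def n_steps(self) -> int:
        return next(iter(self.models.values())).n_steps

    def log_likelihoods(self, cycles: Sequence[NormalizedCycle]) -> np.ndarray:
        """(n_cycles, 5) log-likelihood matrix, columns in canonical order."""
        V = _stack_cycles(cycles)
        return np.column_stack(
            [self.models[g].log_likelihood_many(V) for g in GEARS]
        )

    def classify_cycle(self, cycle: NormalizedCycle) -> GearPrediction:
        """Maximum-likelihood gear for one normalized cycle."""
        ll = self.log_likelihoods([cycle])[0]
        best = int(np.argmax(ll))  # first max -> earlier canonical gear
        return GearPrediction(segment=cycle.segment, gear=GEARS[best],
                              loglik={g: float(v) for g, v in zip(GEARS, ll)})

    def classify_cycles(self,
                        cycles: Sequence[NormalizedCycle]) -> list[GearPrediction]:
        if not cycles:
            return []
        LL = self.log_likelihoods(cycles)
        out = []
        for cyc, ll in zip(cycles, LL):
            best = int(np.argmax(ll))
            out.append(GearPrediction(segment=cyc.segment, gear=GEARS[best],
                                      loglik={g: float(v)
                                              for g, v in zip(GEARS, ll)}))
        return out

    def classify_stream(self, stream: AccelerometerStream,
                        cfg: PreprocessConfig | None = None
                        ) -> list[GearPrediction]:
        """Segment, normalize and classify every cycle of a raw stream."""
        cfg = cfg or self.preprocess_config
        return self.classify_cycles(extract_cycles(stream, cfg))

    # -- reporting and persistence ------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary, one row per gear."""
        lines = [
            "Markov-Gaussian gear classifier",
            f"  regime: {self.regime}   n_steps: {self.n_steps}   "
            f"dimension: {3 * self.n_steps}   ridge: {self.ridge:g}",
            "",
            f"  {'gear':<6}{'n_train':>8}{'n_params':>10}"
            f"{'mean train loglik':>20}",
        ]
        for g in GEARS:
            m = self.models[g]
            tl = self.train_loglik.get(g)
            tl_s = f"{tl:.1f}" if tl is not None else "-"
            lines.append(f"  {g:<6}{m.n_train:>8}{m.n_parameters:>10}{tl_s:>20}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "preprocess": self.preprocess_config.to_dict(),
            "regime": self.regime,
            "ridge": self.ridge,
            "train_loglik": {g: self.train_loglik[g]
                             for g in GEARS if g in self.train_loglik},
            "models": {g: self.models[g].to_dict() for g in GEARS},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GearClassifier":
        models = {g: GearClassModel.from_dict(g, md)
                  for g, md in d["models"].items()}
        return cls(models=models,
                   preprocess_config=PreprocessConfig.from_dict(d["preprocess"]),
                   regime=d.get("regime", "collective"),
                   ridge=float(d.get("ridge", DEFAULT_RIDGE)),
                   train_loglik=d.get("train_loglik"))

    def save(self, path: str | os.PathLike) -> None:
        """Serialize to JSON (nested arrays, canonical gear order)."""
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | os.PathLike) -> "GearClassifier":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def train_classifier(labeled_cycles: Mapping[str, Sequence[NormalizedCycle]],
                     ridge: float = DEFAULT_RIDGE,
                     preprocess_config: PreprocessConfig | None = None,
                     regime: str = "collective") -> GearClassifier:
    """Fit the five-gear classifier from labeled normalized cycles."""
    return GearMarkovModel(labeled_cycles, preprocess_config=preprocess_config,
                           ridge=ridge, regime=regime).fit()


def classify_cycle(classifier: GearClassifier,
                   cycle: NormalizedCycle) -> GearPrediction:
    return classifier.classify_cycle(cycle)


def classify_stream(classifier: GearClassifier, stream: AccelerometerStream,
                    cfg: PreprocessConfig | None = None) -> list[GearPrediction]:
    return classifier.classify_stream(stream, cfg)
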