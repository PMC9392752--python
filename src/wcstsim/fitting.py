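"""Group simulation and MSE-based parameter search.

The fitting procedure mirrors how the agent's four free parameters are
matched to a behavioural profile: draw many parameter configurations at
random, simulate a group of sessions for each, and rank configurations by
the mean squared error between simulated and target index means

    MSE = (1/4) Σ_k (mean_model,k − mean_target,k)²   over k ∈ {CC, PE, NPE, FMS}.

Every configuration is evaluated on the same bank of session random
streams (common random numbers), which makes the ranking a deterministic
function of ``(target, n_configs, n_runs, bounds, seed)`` and sharpens
between-configuration comparisons.

:class:`WCSTProfileFitter` packages the search as a scikit-learn style
estimator; :func:`random_search` is the thin functional wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import _engine
from .cognitive_agent import AgentParams, validate_params

__all__ = [
    "INDEX_NAMES",
    "GroupProfile",
    "FitResult",
    "DEFAULT_BOUNDS",
    "simulate_group",
    "simulate_sessions",
    "fit_mse",
    "random_search",
    "WCSTProfileFitter",
]

INDEX_NAMES = ("cc", "pe", "npe", "fms")

#: Uniform sampling box for (μ, φ, τ, λ); τ bounded away from zero.
DEFAULT_BOUNDS = ((0.0, 1.0), (0.0, 1.0), (0.01, 1.0), (0.0, 1.0))


@dataclass(frozen=True, eq=False)
class GroupProfile:
    """Mean and SD of the four indices over a group of sessions."""

    mean: np.ndarray  # (4,) cc, pe, npe, fms
    sd: np.ndarray  # (4,) population SD
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if self.mean.shape != (4,) or self.sd.shape != (4,):
            raise ValueError("mean and sd must have shape (4,)")
        if (self.sd < 0).any():
            raise ValueError("sd must be non-negative")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    def __eq__(self, other) -> bool:
        if not isinstance(other, GroupProfile):
            return NotImplemented
        return (
            self.n == other.n
            and np.array_equal(self.mean, other.mean)
            and np.array_equal(self.sd, other.sd)
        )

    @classmethod
    def from_sessions(cls, profiles: np.ndarray) -> "GroupProfile":
        """Summarise an ``(n, 4)`` array of per-session profiles."""
        profiles = np.asarray(profiles, dtype=float)
        return cls(mean=profiles.mean(axis=0), sd=profiles.std(axis=0), n=len(profiles))

    @classmethod
    def from_dict(cls, d: dict) -> "GroupProfile":
        mean = np.array([d["mean"][k] for k in INDEX_NAMES], dtype=float)
        sd = np.array([d["sd"][k] for k in INDEX_NAMES], dtype=float)
        return cls(mean=mean, sd=sd, n=int(d["n"]))

    def as_dict(self) -> dict:
        return {
            "mean": dict(zip(INDEX_NAMES, self.mean.tolist())),
            "sd": dict(zip(INDEX_NAMES, self.sd.tolist())),
            "n": self.n,
        }


@dataclass(frozen=True)
class FitResult:
    params: AgentParams
    mse: float
    n_runs: int
    seed: int


def _session_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-session integer seeds derived from a master seed."""
    return np.random.SeedSequence(seed).generate_state(n)


def simulate_sessions(params: AgentParams, n: int, seed: int) -> np.ndarray:
    """Per-session profiles, shape ``(n, 4)``, for one parameter set."""
    if n < 1:
        raise ValueError("n must be >= 1")
    seeds = _session_seeds(seed, n)
    return _engine.simulate_profiles(*params.as_tuple(), seeds)


def simulate_group(params: AgentParams, n: int, seed: int) -> GroupProfile:
    """Simulate ``n`` sessions and summarise them (population SD)."""
    return GroupProfile.from_sessions(simulate_sessions(params, n, seed))


def fit_mse(model: GroupProfile, target: GroupProfile) -> float:
    """Mean over the four indices of the squared difference of means."""
    d = model.mean - target.mean
    return float(np.mean(d * d))


class WCSTProfileFitter(BaseEstimator):
    """Random-search fit of the agent's four parameters to a group profile.

    Parameters
    ----------
    n_configs : int
        Number of parameter configurations sampled uniformly in ``bounds``.
    n_runs : int or None
        Sessions simulated per configuration; ``None`` uses the target
        profile's own ``n``.
    bounds : sequence of four (low, high) pairs
        Sampling box for (μ, φ, τ, λ).
    random_state : int
        Master seed; sampling and all simulation seeds derive from it.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per evaluated configuration (mu, phi, tau, lam, mse),
        sorted ascending by MSE with ties broken by sampling order.
    best_params_ : AgentParams
    best_mse_ : float
    fit_results_ : list of FitResult, ranked.
    """

    def __init__(
        self,
        n_configs: int = 2000,
        n_runs: int | None = None,
        bounds=DEFAULT_BOUNDS,
        random_state: int = 0,
    ):
        self.n_configs = n_configs
        self.n_runs = n_runs
        self.bounds = bounds
        self.random_state = random_state

    def fit(self, target: GroupProfile, y=None) -> "WCSTProfileFitter":
        if self.n_configs < 1:
            raise ValueError("n_configs must be >= 1")
        bounds = np.asarray(self.bounds, dtype=float)
        if bounds.shape != (4, 2):
            raise ValueError("bounds must be four (low, high) pairs")
        if (bounds[:, 1] < bounds[:, 0]).any():
            raise ValueError("empty bounds interval")
        lo, hi = bounds[:, 0], bounds[:, 1]
        validate_params(*lo)
        validate_params(*np.maximum(hi, [0, 0, 1e-9, 0]))

        n_runs = int(target.n if self.n_runs is None else self.n_runs)
        if n_runs < 1:
            raise ValueError("n_runs must be >= 1")

        ss = np.random.SeedSequence(self.random_state)
        sample_ss, eval_ss = ss.spawn(2)
        rng = np.random.default_rng(sample_ss)
        configs = lo + rng.random((self.n_configs, 4)) * (hi - lo)
        eval_seed = int(eval_ss.generate_state(1)[0])

        # one shared bank of session streams for every configuration
        seeds = _session_seeds(eval_seed, n_runs)
        attrs, uniforms = _engine.session_streams(seeds)
        out = np.empty((n_runs, 4), dtype=np.int64)

        mses = np.empty(self.n_configs)
        for k in range(self.n_configs):
            mu, phi, tau, lam = configs[k]
            _engine._simulate_kernel(mu, phi, tau, lam, attrs, uniforms, out)
            d = out.mean(axis=0) - target.mean
            mses[k] = np.mean(d * d)

        order = np.argsort(mses, kind="stable")
        self.results_ = pd.DataFrame(
            {
                "mu": configs[order, 0],
                "phi": configs[order, 1],
                "tau": configs[order, 2],
                "lam": configs[order, 3],
                "mse": mses[order],
            }
        ).reset_index(drop=True)
        self.fit_results_ = [
            FitResult(
                params=AgentParams(*configs[i]),
                mse=float(mses[i]),
                n_runs=n_runs,
                seed=eval_seed,
            )
            for i in order
        ]
        self.best_params_ = self.fit_results_[0].params
        self.best_mse_ = self.fit_results_[0].mse
        self.n_runs_ = n_runs
        return self


def random_search(
    target: GroupProfile,
    n_configs: int = 2000,
    n_runs: int | None = None,
    bounds=DEFAULT_BOUNDS,
    seed: int = 0,
) -> list[FitResult]:
    """Ranked parameter search; thin wrapper over :class:`WCSTProfileFitter`."""
    fitter = WCSTProfileFitter(
        n_configs=n_configs, n_runs=n_runs, bounds=bounds, random_state=seed
    )
    fitter.fit(target)
    return fitter.fit_results_
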