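"""Batch simulation engine.

Runs many sessions with the same trial-level arithmetic as
:mod:`wcstsim.cognitive_agent`, but over pre-drawn random streams and a
compiled inner loop, so that parameter searches (thousands of
configurations × tens of sessions) stay cheap. For a given session seed
the engine and the object-level reference path consume the same stream
(two 64-card permutations, then 128 uniforms) and perform the same
floating-point operations in the same order, so their profiles agree
bit-exactly — a property the test suite asserts.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap

from .cognitive_agent import BASELINE, REWARD_GAIN

__all__ = ["session_streams", "simulate_profiles", "simulate_batch"]

_N_TRIALS = 128
_CRITERION = 10
_FMS_RUN = 5
_N_CATS = 6


def session_streams(seeds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Card attributes and selection uniforms for a batch of sessions.

    Returns ``(attrs, uniforms)`` with shapes ``(n, 128, 3)`` (attribute
    value per category for each dealt card) and ``(n, 128)``.
    """
    n = len(seeds)
    attrs = np.empty((n, _N_TRIALS, 3), dtype=np.int64)
    uniforms = np.empty((n, _N_TRIALS), dtype=np.float64)
    for i, s in enumerate(seeds):
        rng = np.random.default_rng(int(s))
        order = np.concatenate([rng.permutation(64), rng.permutation(64)])
        attrs[i, :, 0] = order // 16
        attrs[i, :, 1] = (order // 4) % 4
        attrs[i, :, 2] = order % 4
        uniforms[i] = rng.random(_N_TRIALS)
    return attrs, uniforms


@njit(cache=False)
def _simulate_kernel(mu, phi, tau, lam, attrs, uniforms, out):  # pragma: no cover
    n = attrs.shape[0]
    for i in range(n):
        p0 = BASELINE
        p1 = BASELINE
        p2 = BASELINE
        rule = 0
        cons = 0
        cc = 0
        pe = 0
        npe = 0
        fms = 0
        prin_run = 0
        prev_sel = -1
        sig_rule = -1
        sig_val = 0
        for t in range(_N_TRIALS):
            # decay toward baseline
            p0 += phi * (BASELINE - p0)
            p1 += phi * (BASELINE - p1)
            p2 += phi * (BASELINE - p2)
            # inner-speech rehearsal of the last evaluated rule
            if sig_rule == 0:
                p0 = min(1.0, max(0.0, p0 + lam * sig_val))
            elif sig_rule == 1:
                p1 = min(1.0, max(0.0, p1 + lam * sig_val))
            elif sig_rule == 2:
                p2 = min(1.0, max(0.0, p2 + lam * sig_val))
            # softmax selection (same op order as the reference path)
            l0 = p0 / tau
            l1 = p1 / tau
            l2 = p2 / tau
            m = l0
            if l1 > m:
                m = l1
            if l2 > m:
                m = l2
            e0 = np.exp(l0 - m)
            e1 = np.exp(l1 - m)
            e2 = np.exp(l2 - m)
            s = e0 + e1 + e2
            u = uniforms[i, t]
            sel = 2
            acc = e0 / s
            if u < acc:
                sel = 0
            else:
                acc += e1 / s
                if u < acc:
                    sel = 1
            # feedback: positive iff the chosen target (unique target with
            # the card's attribute on the selected rule) matches the rule's
            pos = attrs[i, t, sel] == attrs[i, t, rule]
            # motivational RL update of the selected priority
            if sel == 0:
                p0 = min(1.0, p0 + REWARD_GAIN * (1.0 - p0)) if pos else max(0.0, p0 - mu * p0)
            elif sel == 1:
                p1 = min(1.0, p1 + REWARD_GAIN * (1.0 - p1)) if pos else max(0.0, p1 - mu * p1)
            else:
                p2 = min(1.0, p2 + REWARD_GAIN * (1.0 - p2)) if pos else max(0.0, p2 - mu * p2)
            sig_rule = sel
            sig_val = 1 if pos else -1
            # scoring and task bookkeeping
            if pos:
                cons += 1
                if sel == rule:
                    prin_run += 1
                else:
                    prin_run = 0
                if cons == _CRITERION:
                    cc += 1
                    rule = (rule + 1) % 3
                    cons = 0
                    prin_run = 0
                    if cc == _N_CATS:
                        prev_sel = sel
                        break
            else:
                if prev_sel == sel:
                    pe += 1
                else:
                    npe += 1
                if prin_run >= _FMS_RUN:
                    fms += 1
                cons = 0
                prin_run = 0
            prev_sel = sel
        out[i, 0] = cc
        out[i, 1] = pe
        out[i, 2] = npe
        out[i, 3] = fms


def simulate_profiles(
    mu: float, phi: float, tau: float, lam: float, seeds: np.ndarray
) -> np.ndarray:
    """Profiles (cc, pe, npe, fms) for one parameter set over many seeds."""
    attrs, uniforms = session_streams(np.asarray(seeds))
    out = np.empty((len(seeds), 4), dtype=np.int64)
    _simulate_kernel(float(mu), float(phi), float(tau), float(lam), attrs, uniforms, out)
    return out


def simulate_batch(param_sets: np.ndarray, seeds_per_set: np.ndarray) -> np.ndarray:
    """Profiles for many parameter sets; ``seeds_per_set[k]`` seeds set k."""
    n_sets = len(param_sets)
    n = seeds_per_set.shape[1]
    out = np.empty((n_sets, n, 4), dtype=np.int64)
    for k in range(n_sets):
        mu, phi, tau, lam = param_sets[k]
        out[k] = simulate_profiles(mu, phi, tau, lam, seeds_per_set[k])
    return out
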