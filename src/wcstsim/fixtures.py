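"""Published constants for the eight simulated groups.

Eight groups — {control, ASC} × {children, teenagers, young adults,
middle adults} — each with its fitted parameter quadruple (μ, φ, τ, λ),
its human sample size, and the behavioural reference profile (mean and SD
of CC, PE, NPE, FMS) the parameters were fitted to. Values are shipped as
a versioned JSON file inside the package and guarded by checksums against
transcription drift.

The control-children sample size is reported inconsistently in the source
material (52 in the text, 42 in the demographics table); 52 is stored as
primary with 42 kept as an annotated alternate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .cognitive_agent import AgentParams
from .fitting import GroupProfile, simulate_group

__all__ = [
    "GroupSpec",
    "GROUP_LABELS",
    "group_specs",
    "table2_params",
    "table3_profiles",
    "group_sizes",
    "make_synthetic_target",
]

GROUP_LABELS = (
    "control_children",
    "control_teenagers",
    "control_young_adults",
    "control_middle_adults",
    "asc_children",
    "asc_teenagers",
    "asc_young_adults",
    "asc_middle_adults",
)

# Guard totals over all shipped numbers (params; profile means + SDs).
_PARAMS_CHECKSUM = 7.19
_PROFILE_CHECKSUM = 375.4


@dataclass(frozen=True)
class GroupSpec:
    label: str
    condition: str  # "control" | "asc"
    age: str
    params: AgentParams
    n: int
    reference_profile: GroupProfile
    n_alternate: int | None = None


@lru_cache(maxsize=1)
def _raw() -> dict:
    with resources.files("wcstsim.data").joinpath("groups.json").open() as fh:
        data = json.load(fh)
    params_total = sum(sum(g["params"].values()) for g in data["groups"].values())
    profile_total = sum(
        sum(g["profile"]["mean"].values()) + sum(g["profile"]["sd"].values())
        for g in data["groups"].values()
    )
    if round(params_total, 6) != _PARAMS_CHECKSUM:
        raise RuntimeError("fixture parameter checksum mismatch")
    if round(profile_total, 6) != _PROFILE_CHECKSUM:
        raise RuntimeError("fixture profile checksum mismatch")
    return data


@lru_cache(maxsize=1)
def group_specs() -> dict[str, GroupSpec]:
    """All eight groups, keyed by label, in canonical order."""
    data = _raw()
    out: dict[str, GroupSpec] = {}
    for label in GROUP_LABELS:
        g = data["groups"][label]
        mean = [g["profile"]["mean"][k] for k in ("cc", "pe", "npe", "fms")]
        sd = [g["profile"]["sd"][k] for k in ("cc", "pe", "npe", "fms")]
        out[label] = GroupSpec(
            label=label,
            condition=g["condition"],
            age=g["age"],
            params=AgentParams(**g["params"]),
            n=g["n"],
            reference_profile=GroupProfile(mean=mean, sd=sd, n=g["n"]),
            n_alternate=g.get("n_alternate"),
        )
    return out


def table2_params() -> dict[str, AgentParams]:
    """The eight fitted parameter quadruples."""
    return {label: spec.params for label, spec in group_specs().items()}


def table3_profiles() -> dict[str, GroupProfile]:
    """The eight behavioural reference profiles (mean, SD, n)."""
    return {label: spec.reference_profile for label, spec in group_specs().items()}


def group_sizes() -> dict[str, int]:
    return {label: spec.n for label, spec in group_specs().items()}


def make_synthetic_target(
    params: AgentParams, n: int, seed: int
) -> tuple[GroupProfile, AgentParams]:
    """Ground-truth target for parameter-recovery experiments.

    Wraps :func:`wcstsim.fitting.simulate_group` and returns the profile
    together with the generating parameters, so recovery error is
    measurable.
    """
    return simulate_group(params, n, seed), params
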