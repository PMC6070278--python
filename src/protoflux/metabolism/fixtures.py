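"""Built-in reaction networks.

Seven architectures are provided, with default parameters taken from
the published experiments:

- ``keystone_recycler`` and the ``_near`` / ``_far`` boundary variants
  (near: kcat_beta=2, cm_beta=1.5; far: cw_alpha=2 with cm_beta=2
  solved so both variants share the same maximum flux 5N/3),
- ``serial3`` / ``parallel3`` (all kcat 1, cm_beta=cm_gamma=4),
- ``bimolecular3`` (cm_alpha=cm_beta=2.5, cm_gamma=4),
- ``serial4`` / ``parallel4`` / ``bimolecular4``
  (cm_beta=cm_gamma=cm_theta=6; the unbalanced variant uses cm_theta=10).
"""

from __future__ import annotations

from typing import Callable

from protoflux.metabolism.network import (
    CRITICAL_OUTPUT,
    ENVIRONMENTAL_INPUT,
    INTERMEDIATE,
    CatalystSpec,
    MetaboliteSpec,
    NetworkSpec,
)

__all__ = ["FIXTURES", "get_fixture", "list_fixtures", "FIXTURE_NOTES"]


def _env(mid: str) -> MetaboliteSpec:
    return MetaboliteSpec(mid, ENVIRONMENTAL_INPUT)


def _waste(mid: str, delta: float) -> MetaboliteSpec:
    return MetaboliteSpec(mid, INTERMEDIATE, permeability=delta)


def _crit() -> MetaboliteSpec:
    return MetaboliteSpec("M", CRITICAL_OUTPUT)


def keystone_only(kcat_alpha: float = 1.0, cw_alpha: float = 1.0, delta: float = 0.0, Km: float = 1.0) -> NetworkSpec:
    """Single saturated keystone; the no-recycler reference network."""
    return NetworkSpec(
        name="keystone_only",
        metabolites=[_env("A"), _waste("W", delta), _crit()],
        catalysts=[
            CatalystSpec("alpha", kcat_alpha, ("A",), {"M": 1.0, "W": cw_alpha}, Km=Km, saturated=True),
        ],
    )


def keystone_recycler(
    kcat_alpha: float = 1.0,
    kcat_beta: float = 1.0,
    cw_alpha: float = 1.0,
    cm_beta: float = 2.0,
    delta: float = 0.0,
    Km: float = 1.0,
) -> NetworkSpec:
    """Keystone alpha feeds waste W to recycler beta:
    ``Phi = kcat_a*a + cm_beta*min(cw_alpha*kcat_a*a, kcat_b*b)``."""
    return NetworkSpec(
        name="keystone_recycler",
        metabolites=[_env("A"), _waste("W", delta), _crit()],
        catalysts=[
            CatalystSpec("alpha", kcat_alpha, ("A",), {"M": 1.0, "W": cw_alpha}, Km=Km, saturated=True),
            CatalystSpec("beta", kcat_beta, ("W",), {"M": cm_beta}, Km=Km),
        ],
    )


def keystone_recycler_near(**kw) -> NetworkSpec:
    """Flux maximum close to the no-recycler boundary (faster recycler)."""
    kw.setdefault("kcat_beta", 2.0)
    kw.setdefault("cm_beta", 1.5)
    net = keystone_recycler(**kw)
    net.name = "keystone_recycler_near"
    return net


def keystone_recycler_far(**kw) -> NetworkSpec:
    """Flux maximum far from the boundary (double waste output); cm_beta
    chosen so the maximum flux equals the near variant's (5N/3)."""
    kw.setdefault("cw_alpha", 2.0)
    kw.setdefault("cm_beta", 2.0)
    net = keystone_recycler(**kw)
    net.name = "keystone_recycler_far"
    return net


def serial3(
    kcat_alpha: float = 1.0,
    kcat_beta: float = 1.0,
    kcat_gamma: float = 1.0,
    cm_beta: float = 4.0,
    cm_gamma: float = 4.0,
    delta: float = 0.0,
    Km: float = 1.0,
) -> NetworkSpec:
    """Recyclers in series (gamma downstream of beta):
    ``Phi = a + cm_b*min(a, b) + cm_g*min(a, b, c)`` at unit kcat."""
    return NetworkSpec(
        name="serial3",
        metabolites=[_env("A"), _waste("W1", delta), _waste("W2", delta), _crit()],
        catalysts=[
            CatalystSpec("alpha", kcat_alpha, ("A",), {"M": 1.0, "W1": 1.0}, Km=Km, saturated=True),
            CatalystSpec("beta", kcat_beta, ("W1",), {"M": cm_beta, "W2": 1.0}, Km=Km),
            CatalystSpec("gamma", kcat_gamma, ("W2",), {"M": cm_gamma}, Km=Km),
        ],
    )


def parallel3(
    kcat_alpha: float = 1.0,
    kcat_beta: float = 1.0,
    kcat_gamma: float = 1.0,
    cm_beta: float = 4.0,
    cm_gamma: float = 4.0,
    delta: float = 0.0,
    Km: float = 1.0,
) -> NetworkSpec:
    """Recyclers in parallel on two non-competing wastes:
    ``Phi = a + cm_b*min(a, b) + cm_g*min(a, c)`` at unit kcat."""
    return NetworkSpec(
        name="parallel3",
        metabolites=[_env("A"), _waste("W1", delta), _waste("W2", delta), _crit()],
        catalysts=[
            CatalystSpec("alpha", kcat_alpha, ("A",), {"M": 1.0, "W1": 1.0, "W2": 1.0}, Km=Km, saturated=True),
            CatalystSpec("beta", kcat_beta, ("W1",), {"M": cm_beta}, Km=Km),
            CatalystSpec("gamma", kcat_gamma, ("W2",), {"M": cm_gamma}, Km=Km),
        ],
    )


def bimolecular3(
    kcat_alpha: float = 1.0,
    kcat_beta: float = 1.0,
    kcat_gamma: float = 1.0,
    cm_alpha: float = 2.5,
    cm_beta: float = 2.5,
    cm_gamma: float = 4.0,
    delta: float = 0.0,
    Km: float = 1.0,
    a1: float = 1.0,
    a2: float = 1.0,
) -> NetworkSpec:
    """Two keystones feeding a bimolecular recycler:
    ``Phi = cm_a*a + cm_b*b + cm_g*min(a, b, c)`` at unit kcat."""
    return NetworkSpec(
        name="bimolecular3",
        metabolites=[_env("A1"), _env("A2"), _waste("W1", delta), _waste("W2", delta), _crit()],
        catalysts=[
            CatalystSpec("alpha", kcat_alpha, ("A1",), {"M": cm_alpha, "W1": 1.0}, Km=Km, saturated=True),
            CatalystSpec("beta", kcat_beta, ("A2",), {"M": cm_beta, "W2": 1.0}, Km=Km, saturated=True),
            CatalystSpec("gamma", kcat_gamma, ("W1", "W2"), {"M": cm_gamma}, Km=Km, a1=a1, a2=a2),
        ],
    )


def serial4(
    cm_beta: float = 6.0,
    cm_gamma: float = 6.0,
    cm_theta: float = 6.0,
    delta: float = 0.0,
    Km: float = 1.0,
) -> NetworkSpec:
    """Chain of three recyclers:
    ``Phi = a + cm_b*min(a,b) + cm_g*min(a,b,c) + cm_t*min(a,b,c,d)``."""
    return NetworkSpec(
        name="serial4",
        metabolites=[_env("A"), _waste("W1", delta), _waste("W2", delta), _waste("W3", delta), _crit()],
        catalysts=[
            CatalystSpec("alpha", 1.0, ("A",), {"M": 1.0, "W1": 1.0}, Km=Km, saturated=True),
            CatalystSpec("beta", 1.0, ("W1",), {"M": cm_beta, "W2": 1.0}, Km=Km),
            CatalystSpec("gamma", 1.0, ("W2",), {"M": cm_gamma, "W3": 1.0}, Km=Km),
            CatalystSpec("theta", 1.0, ("W3",), {"M": cm_theta}, Km=Km),
        ],
    )


def parallel4(
    cm_beta: float = 6.0,
    cm_gamma: float = 6.0,
    cm_theta: float = 6.0,
    delta: float = 0.0,
    Km: float = 1.0,
) -> NetworkSpec:
    """Three parallel recyclers on non-competing wastes:
    ``Phi = a + cm_b*min(a,b) + cm_g*min(a,c) + cm_t*min(a,d)``."""
    return NetworkSpec(
        name="parallel4",
        metabolites=[_env("A"), _waste("W1", delta), _waste("W2", delta), _waste("W3", delta), _crit()],
        catalysts=[
            CatalystSpec("alpha", 1.0, ("A",), {"M": 1.0, "W1": 1.0, "W2": 1.0, "W3": 1.0}, Km=Km, saturated=True),
            CatalystSpec("beta", 1.0, ("W1",), {"M": cm_beta}, Km=Km),
            CatalystSpec("gamma", 1.0, ("W2",), {"M": cm_gamma}, Km=Km),
            CatalystSpec("theta", 1.0, ("W3",), {"M": cm_theta}, Km=Km),
        ],
    )


def bimolecular4(
    cm_beta: float = 6.0,
    cm_gamma: float = 6.0,
    cm_theta: float = 6.0,
    delta: float = 0.0,
    Km: float = 1.0,
    a1: float = 1.0,
    a2: float = 1.0,
) -> NetworkSpec:
    """Parallel recyclers whose wastes feed a terminal bimolecular
    recycler (bow-tie):
    ``Phi = a + cm_b*min(a,b) + cm_g*min(a,c) + cm_t*min(a,b,c,d)``."""
    return NetworkSpec(
        name="bimolecular4",
        metabolites=[
            _env("A"),
            _waste("W1", delta),
            _waste("W2", delta),
            _waste("W3", delta),
            _waste("W4", delta),
            _crit(),
        ],
        catalysts=[
            CatalystSpec("alpha", 1.0, ("A",), {"M": 1.0, "W1": 1.0, "W2": 1.0}, Km=Km, saturated=True),
            CatalystSpec("beta", 1.0, ("W1",), {"M": cm_beta, "W3": 1.0}, Km=Km),
            CatalystSpec("gamma", 1.0, ("W2",), {"M": cm_gamma, "W4": 1.0}, Km=Km),
            CatalystSpec("theta", 1.0, ("W3", "W4"), {"M": cm_theta}, Km=Km, a1=a1, a2=a2),
        ],
    )


FIXTURES: dict[str, Callable[..., NetworkSpec]] = {
    "keystone_recycler": keystone_recycler,
    "keystone_recycler_near": keystone_recycler_near,
    "keystone_recycler_far": keystone_recycler_far,
    "serial3": serial3,
    "parallel3": parallel3,
    "bimolecular3": bimolecular3,
    "serial4": serial4,
    "parallel4": parallel4,
    "bimolecular4": bimolecular4,
}

FIXTURE_NOTES: dict[str, str] = {
    "keystone_recycler": "keystone + single waste recycler (defaults: unit kcat, cw_alpha=1, cm_beta=2)",
    "keystone_recycler_near": "flux maximum near the no-recycler boundary: kcat_beta=2, cm_beta=1.5",
    "keystone_recycler_far": "flux maximum far from the boundary: cw_alpha=2, cm_beta=2 (equal maximum flux)",
    "serial3": "two recyclers in series; all kcat 1, cm_beta=cm_gamma=4",
    "parallel3": "two recyclers in parallel; all kcat 1, cm_beta=cm_gamma=4",
    "bimolecular3": "two keystones + bimolecular recycler; cm_alpha=cm_beta=2.5, cm_gamma=4",
    "serial4": "three recyclers in series; cm_beta=cm_gamma=cm_theta=6 (cm_theta=10 unbalanced variant)",
    "parallel4": "three parallel recyclers; cm_beta=cm_gamma=cm_theta=6 (cm_theta=10 unbalanced variant)",
    "bimolecular4": "parallel recyclers feeding a terminal bimolecular recycler; same defaults",
}


def list_fixtures() -> dict[str, str]:
    """Fixture names with a one-line description of their defaults."""
    return dict(FIXTURE_NOTES)


def get_fixture(name: str, **overrides) -> NetworkSpec:
    """Build a named fixture, optionally overriding kinetic or
    stoichiometric parameters (e.g. ``cm_theta=10``)."""
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(FIXTURES))}"
        ) from None
    return builder(**overrides)
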