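"""Closed-form one-compartment parent/metabolite kinetics.

The model is a linear cascade

    gut --ka--> parent --fm*ke--> metabolite --km--> out
                  |--(1-fm)*ke--> other routes

with first-order rates throughout.  For a single oral dose the salivary
parent concentration is the Bateman function and the metabolite follows a
triple-exponential cascade solution; both are scaled by apparent dilution
volumes that fold the saliva:plasma partitioning into a single mg -> ug/ml
factor.  Everything downstream (multi-dose superposition, NCA) builds on
these two functions.

Concentrations are in ug/ml, times in hours, doses in mg, rates in 1/h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PKParameters", "parent_conc", "metabolite_conc", "InvalidParameterError"]

#: relative difference below which two rate constants are treated as equal
#: and the analytic limit form is used instead of the generic formula
RATE_TOL = 1e-8


class InvalidParameterError(ValueError):
    """Raised for non-physical kinetic parameters (non-positive rates etc.)."""


@dataclass(frozen=True)
class PKParameters:
    """Kinetic parameters of the parent–metabolite model for one subject.

    Parameters
    ----------
    ka
        First-order absorption rate constant (1/h).  Caffeine is almost
        completely absorbed within ~45 min, so the default used elsewhere
        is fast (3.0/h).
    ke
        Parent (caffeine) elimination rate constant K_el (1/h).
    km
        Metabolite (paraxanthine) elimination rate constant (1/h).
    fm
        Fraction of the parent dose converted to the metabolite
        (dimensionless, 0–1; ~0.84 for caffeine -> paraxanthine via CYP1A2).
    v_parent, v_metab
        Apparent dilution volumes (L) mapping an oral mg dose to a salivary
        ug/ml concentration; they absorb bioavailability and the
        saliva:plasma ratio, which are not modelled separately.
    lloq_parent, lloq_metab
        Lower limits of quantification (ug/ml); samples below them are
        censored downstream.
    """

    ka: float
    ke: float
    km: float
    fm: float = 0.84
    v_parent: float = 43.1
    v_metab: float = 19.6
    lloq_parent: float = 0.04
    lloq_metab: float = 0.02

    def __post_init__(self) -> None:
        for name in ("ka", "ke", "km"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be a positive finite rate, got {getattr(self, name)!r}")
        if not 0.0 <= self.fm <= 1.0:
            raise InvalidParameterError(f"fm must lie in [0, 1], got {self.fm!r}")
        for name in ("v_parent", "v_metab"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive, got {getattr(self, name)!r}")
        for name in ("lloq_parent", "lloq_metab"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative, got {getattr(self, name)!r}")


def _close(a: float, b: float) -> bool:
    return abs(a - b) <= RATE_TOL * max(abs(a), abs(b))


def parent_conc(t, dose: float, params: PKParameters):
    """Salivary parent concentration after a single oral dose (Bateman).

    C(t) = (dose / v_parent) * ka/(ka-ke) * (exp(-ke t) - exp(-ka t))

    with the L'Hopital limit (dose/v) * ka * t * exp(-ka t) when ka ~= ke.
    Returns 0 for t <= 0.  Accepts scalar or array ``t``; the return type
    follows the input.
    """
    if dose < 0:
        raise ValueError(f"dose must be non-negative, got {dose!r}")
    t_arr = np.asarray(t, dtype=float)
    ka, ke, v = params.ka, params.ke, params.v_parent
    tp = np.where(t_arr > 0, t_arr, 0.0)
    if _close(ka, ke):
        k = 0.5 * (ka + ke)
        c = (dose / v) * k * tp * np.exp(-k * tp)
    else:
        c = (dose / v) * ka / (ka - ke) * (np.exp(-ke * tp) - np.exp(-ka * tp))
    c = np.where(t_arr > 0, c, 0.0)
    return c if np.ndim(t) else float(c)


def _exp_divdiff3(k1: float, k2: float, k3: float, t: np.ndarray) -> np.ndarray:
    # Third-order divided difference of g(x) = exp(-x t) over the nodes
    # (k1, k2, k3); equals sum_i exp(-k_i t) / prod_{j != i} (k_j - k_i) and
    # is strictly positive for t > 0.  Coincident nodes fall back to the
    # confluent (derivative) forms, which is the analytic limit.
    ks = sorted((k1, k2, k3))
    a, b, c = ks
    ab, bc, ac = _close(a, b), _close(b, c), _close(a, c)
    if ab and bc:
        k = (a + b + c) / 3.0
        return 0.5 * t * t * np.exp(-k * t)
    if ab or bc:
        # one coincident pair (x, x, y): g[x,x,y] = (g'(x) - g[x,y])/(x - y)
        if ab:
            x, y = 0.5 * (a + b), c
        else:
            x, y = 0.5 * (b + c), a
        g_xy = (np.exp(-x * t) - np.exp(-y * t)) / (x - y)
        return (-t * np.exp(-x * t) - g_xy) / (x - y)
    return (
        np.exp(-a * t) / ((b - a) * (c - a))
        + np.exp(-b * t) / ((a - b) * (c - b))
        + np.exp(-c * t) / ((a - c) * (b - c))
    )


def metabolite_conc(t, dose: float, params: PKParameters):
    """Salivary metabolite concentration after a single oral parent dose.

    Triple-exponential cascade solution

    C_m(t) = fm * dose * ka * ke / v_metab
             * [ e^{-ka t}/((ke-ka)(km-ka)) + e^{-ke t}/((ka-ke)(km-ke))
               + e^{-km t}/((ka-km)(ke-km)) ],

    evaluated through a divided-difference form that remains finite and
    continuous when any of the rate constants (nearly) coincide.  The
    terminal decline is governed by min(ke, km) — with km < ke the
    metabolite outlives the parent ("flip-flop" kinetics).
    """
    if dose < 0:
        raise ValueError(f"dose must be non-negative, got {dose!r}")
    t_arr = np.asarray(t, dtype=float)
    tp = np.where(t_arr > 0, t_arr, 0.0)
    scale = params.fm * dose * params.ka * params.ke / params.v_metab
    c = scale * _exp_divdiff3(params.ka, params.ke, params.km, tp)
    c = np.where(t_arr > 0, c, 0.0)
    return c if np.ndim(t) else float(c)
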