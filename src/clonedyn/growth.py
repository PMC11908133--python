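"""Deterministic clone growth and VAF models for clonal hematopoiesis.

A mutant clone acquired at age ``atma`` (Age at the Time of Mutation
Acquisition) with net fitness advantage ``s`` (per year) grows
exponentially from a single cell,

    x(t) = exp(s * (t - atma)),   t >= atma,

against a fixed pool of ``N`` wild-type hematopoietic stem cells.  For a
heterozygous mutation in a diploid genome the variant allele frequency of
variant *j* under the context-aware model is

    VAF_j(t) = x_j(t) / (2 * (N + sum_i x_i^lead(t)))

where the sum runs over the host's clones and ``x_i^lead`` is the size of
each clone's lead variant (the highest-VAF mutation of that clone).  A
clone growing alone saturates at VAF 1/2.  The growth-potential metric

    MACS120 = exp(s * (120 - atma))

is the predicted clone size at age 120, the assumed maximum human life
span.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GrowthModelParams",
    "clone_size",
    "isolated_vaf",
    "context_vaf",
    "macs120",
]


@dataclass(frozen=True)
class GrowthModelParams:
    """Parameters of the deterministic growth / VAF model.

    Attributes
    ----------
    n_wildtype:
        Number of wild-type stem cells ``N`` sharing the hematopoietic
        compartment (default 100,000).
    max_age:
        Horizon age for growth-potential metrics, in years (default 120).
    diploid_factor:
        Multiplier in the VAF denominator; 2 for a heterozygous mutation
        in a diploid genome, so that a dominating clone saturates at
        VAF 0.5.
    error_floor:
        Sequencing-error floor applied to model VAFs in emission
        likelihoods; observations predating acquisition are scored at
        this VAF rather than zero.
    """

    n_wildtype: float = 100_000.0
    max_age: float = 120.0
    diploid_factor: float = 2.0
    error_floor: float = 1e-4

    def __post_init__(self) -> None:
        if self.n_wildtype < 1:
            raise ValueError("n_wildtype must be >= 1")
        if self.max_age <= 0:
            raise ValueError("max_age must be positive")


def clone_size(s: float, atma: float, t):
    """Deterministic clone size ``exp(s*(t-atma))``, zero before acquisition.

    ``t`` may be a scalar or array of ages (years).
    """
    if s < 0:
        raise ValueError(f"fitness must be non-negative, got {s}")
    t = np.asarray(t, dtype=float)
    x = np.where(t >= atma, np.exp(s * (t - atma)), 0.0)
    return x if x.ndim else float(x)


def isolated_vaf(s: float, atma: float, t, params: GrowthModelParams | None = None):
    """VAF of a clone growing alone: x / (diploid_factor * (N + x)).

    Monotone non-decreasing in ``t`` with supremum ``1/diploid_factor``;
    zero before acquisition.
    """
    params = params or GrowthModelParams()
    x = np.asarray(clone_size(s, atma, t), dtype=float)
    v = x / (params.diploid_factor * (params.n_wildtype + x))
    return v if v.ndim else float(v)


def context_vaf(x, total_lead, params: GrowthModelParams | None = None):
    """VAF of a variant of size ``x`` given the summed lead sizes of all clones.

    ``total_lead`` must include the lead of the variant's own clone.
    """
    params = params or GrowthModelParams()
    x = np.asarray(x, dtype=float)
    v = x / (params.diploid_factor * (params.n_wildtype + np.asarray(total_lead, dtype=float)))
    return v if v.ndim else float(v)


def macs120(s: float, atma: float, params: GrowthModelParams | None = None):
    """Predicted clone size at the horizon age (default 120).

    Returns ``(value, log_value)`` with ``log_value = s * (horizon - atma)``
    for numerically safe downstream use.  An acquisition age past the
    horizon yields a value below 1 and a warning.
    """
    params = params or GrowthModelParams()
    if s < 0:
        raise ValueError(f"fitness must be non-negative, got {s}")
    if atma > params.max_age:
        warnings.warn(
            f"acquisition age {atma} is past the horizon {params.max_age}; "
            "MACS will be < 1",
            stacklevel=2,
        )
    log_value = s * (params.max_age - atma)
    return math.exp(log_value), log_value
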