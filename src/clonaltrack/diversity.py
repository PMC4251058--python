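"""Clonal-diversity measures over a sample's variant set.

Each filtered variant is treated as a molecular species with weight w(i)
(by default its abundance VAF x DP x CN); normalized weights
p(i) = w(i) / sum w define a distribution over species and the Shannon
diversity index is the entropy

    SDI = -sum_i p(i) ln p(i)        (natural log; nats)

SDI grows both with the number of species and with the evenness of their
weights, and is bounded by ln N with equality iff all weights are equal.
Simpson's index 1 - sum p(i)^2 is offered as a companion measure that is
dominated more by the most frequent species.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError
from .quantify import QuantifiedVariant

logger = logging.getLogger(__name__)

WEIGHT_MODES = ("abundance", "cell_frequency", "uniform")


@dataclass(frozen=True)
class DiversityReport:
    """Summary of a sample's clonal diversity.

    ``evenness`` is shannon / ln(N) (a value in [0, 1]); it is undefined for
    N < 2 and reported as ``None`` there.
    """

    n_variants: int
    shannon: float
    simpson: float
    max_entropy: float
    evenness: float | None
    weight_mode: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def normalize_abundances(
    variants: Iterable[QuantifiedVariant], weight_mode: str = "abundance"
) -> np.ndarray:
    """Species probabilities p(i) = w(i) / sum w.

    Zero-weight variants are excluded before normalization (they carry no
    probability mass and would only produce 0*ln 0 terms); the count of
    exclusions is logged.
    """
    if weight_mode not in WEIGHT_MODES:
        raise DomainError(f"weight_mode must be one of {WEIGHT_MODES}, got {weight_mode!r}")
    vs = list(variants)
    if weight_mode == "uniform":
        w = np.ones(len(vs))
    elif weight_mode == "abundance":
        w = np.array([v.abundance for v in vs], dtype=float)
    else:
        w = np.array([v.cell_frequency for v in vs], dtype=float)
    n_zero = int(np.sum(w == 0))
    if n_zero:
        logger.info("dropping %d zero-weight variants before normalization", n_zero)
        w = w[w > 0]
    if w.size == 0 or w.sum() <= 0:
        raise DomainError("all species weights are zero; diversity undefined")
    return w / w.sum()


def shannon_index(p: Sequence[float] | np.ndarray) -> float:
    """Shannon diversity -sum p ln p in nats, with 0*ln 0 = 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise DomainError("negative probability in species distribution")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise DomainError(f"species probabilities sum to {p.sum()}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def simpson_index(p: Sequence[float] | np.ndarray) -> float:
    """Simpson's diversity 1 - sum p^2 (probability two draws differ)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise DomainError("negative probability in species distribution")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise DomainError(f"species probabilities sum to {p.sum()}, not 1")
    return float(1.0 - (p ** 2).sum())


def diversity_report(
    variants: Iterable[QuantifiedVariant], weight_mode: str = "abundance"
) -> DiversityReport:
    """Shannon and Simpson diversity of a sample's variant set.

    N counts the species entering the calculation (zero-weight variants are
    excluded, matching :func:`normalize_abundances`).
    """
    vs = list(variants)
    if not vs:
        raise DomainError("diversity undefined for an empty variant set")
    p = normalize_abundances(vs, weight_mode)
    n = int(p.size)
    sdi = shannon_index(p)
    max_h = float(np.log(n)) if n >= 1 else 0.0
    assert sdi <= max_h + 1e-9, "entropy exceeded ln(N)"
    return DiversityReport(
        n_variants=n,
        shannon=sdi,
        simpson=simpson_index(p),
        max_entropy=max_h,
        evenness=(sdi / max_h) if n >= 2 else None,
        weight_mode=weight_mode,
    )
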