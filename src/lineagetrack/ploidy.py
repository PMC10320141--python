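"""Automated ploidy classification from allele-frequency spectra.

A clonal isolate's genome-wide allele-frequency spectrum is multimodal:
diploids peak at 0, 1/2 and 1; triploids at 0, 1/3, 2/3 and 1.  The
classifier compares equal-weight binomial mixture log-likelihoods over
those peak locations, with each peak's success probability
error-adjusted as p' = g(1-e) + (1-g)e for per-read error rate e.

Only intermediate-frequency sites (0 < x < d) enter the comparison —
strictly homozygous observations carry no ploidy signal — but the 0 and
1 components stay in both mixtures: sequencing error leaks a tail of
homozygous sites into 0 < x < d, and the shared boundary components
absorb that leakage identically under both models instead of letting it
masquerade as a 1/3 peak.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom

from .io_formats import VariantMatrix

DEFAULT_MIN_DEPTH = 10
DEFAULT_MIN_SITES = 50
DEFAULT_ERROR_RATE = 0.005
DEFAULT_CONFIDENCE_THRESHOLD = 10.0


class InsufficientDataError(ValueError):
    """Too few informative sites to call ploidy."""


@dataclasses.dataclass
class AlleleFrequencySpectrum:
    """Intermediate-frequency (0 < x < d) sites of one clone."""

    clone: str
    x: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int64)
        self.d = np.asarray(self.d, dtype=np.int64)
        if np.any(self.x <= 0) or np.any(self.x >= self.d):
            raise ValueError("spectrum sites must satisfy 0 < x < d")

    @property
    def n_sites(self) -> int:
        return len(self.x)


@dataclasses.dataclass
class PloidyCall:
    clone: str
    ploidy: int | None  # 2, 3 or None for unknown
    delta_loglik: float  # diploid minus triploid
    n_sites: int
    low_confidence: bool
    reason: str = ""


def build_spectrum(
    vm: VariantMatrix, clone: str, min_depth: int = DEFAULT_MIN_DEPTH
) -> AlleleFrequencySpectrum:
    """Extract the informative sites of one clone.

    Homozygous sites (x=0 or x=d) are excluded because the peaks at 0 and
    1 carry no ploidy signal; sites below min_depth are excluded as too
    noisy to localize a peak.
    """
    x, d = vm.column(clone)
    keep = (d >= min_depth) & (x > 0) & (x < d)
    return AlleleFrequencySpectrum(clone, x[keep], d[keep])


def _error_adjusted(g: float, e: float) -> float:
    return g * (1.0 - e) + (1.0 - g) * e


def _model_loglik(x: np.ndarray, d: np.ndarray, fractions: list[float], e: float) -> float:
    """Log-likelihood of an equal-weight binomial mixture over peak fractions."""
    per_component = np.stack(
        [binom.logpmf(x, d, _error_adjusted(g, e)) for g in fractions]
    )
    return float(np.sum(logsumexp(per_component, axis=0) - np.log(len(fractions))))


def classify_ploidy(
    spectrum: AlleleFrequencySpectrum,
    error_rate: float = DEFAULT_ERROR_RATE,
    min_sites: int = DEFAULT_MIN_SITES,
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> PloidyCall:
    """Call 2n versus 3n by summed log-likelihood over informative sites.

    Raises InsufficientDataError below ``min_sites`` — the call is then
    "unknown", never a guess.  The low-confidence flag is set when the
    log-likelihood difference is smaller in magnitude than
    ``confidence_threshold`` (e.g. for out-of-model higher ploidies).
    """
    if spectrum.n_sites < min_sites:
        raise InsufficientDataError(
            f"{spectrum.clone}: {spectrum.n_sites} informative sites < {min_sites}"
        )
    ll_dip = _model_loglik(spectrum.x, spectrum.d, [0.0, 0.5, 1.0], error_rate)
    ll_tri = _model_loglik(
        spectrum.x, spectrum.d, [0.0, 1 / 3, 2 / 3, 1.0], error_rate
    )
    delta = ll_dip - ll_tri
    return PloidyCall(
        clone=spectrum.clone,
        ploidy=2 if delta > 0 else 3,
        delta_loglik=delta,
        n_sites=spectrum.n_sites,
        low_confidence=abs(delta) < confidence_threshold,
    )


def call_all_ploidies(
    vm: VariantMatrix,
    clones: list[str],
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_sites: int = DEFAULT_MIN_SITES,
    error_rate: float = DEFAULT_ERROR_RATE,
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> list[PloidyCall]:
    """One call per clone, order preserved; per-clone failures become
    unknown calls with a reason rather than aborting the batch."""
    calls = []
    for clone in clones:
        try:
            spec = build_spectrum(vm, clone, min_depth=min_depth)
            calls.append(
                classify_ploidy(
                    spec,
                    error_rate=error_rate,
                    min_sites=min_sites,
                    confidence_threshold=confidence_threshold,
                )
            )
        except InsufficientDataError:
            calls.append(
                PloidyCall(clone, None, 0.0, 0, True, reason="insufficient data")
            )
    return calls
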