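"""Chance-level model for response-polarity classes of cortical boutons.

Observed bouton-odorant responses fall into three categories with overall
probabilities (nonresponsive, enhanced, suppressed).  Under the null
hypothesis that a bouton's 16 odorant responses are drawn independently from
that distribution, how many boutons would look purely enhanced (at least one
enhanced response and no suppressed one), purely suppressed, or mixed?

Both a Monte-Carlo simulation (the published procedure: many simulated
boutons, each drawing ``n_odors`` i.i.d. labels) and the exact closed form
are provided; the closed form serves as an independent oracle:

    P(silent)          = p_N^n
    P(pure enhanced)   = (p_N + p_E)^n − p_N^n
    P(pure suppressed) = (p_N + p_S)^n − p_N^n
    P(mixed)           = 1 − the rest
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PolarityProbabilities",
    "PolarityNullResult",
    "analytic_polarity_null",
    "simulate_polarity_null",
    "OBSERVED_PROBS",
]

CATEGORIES = ("pure_enhanced", "pure_suppressed", "mixed", "silent")
Z_99 = 2.5758293035489004  # two-sided 99% normal quantile


@dataclass(frozen=True)
class PolarityProbabilities:
    """Per-odorant response category probabilities (must sum to 1)."""

    p_nonresponsive: float
    p_enhanced: float
    p_suppressed: float

    def __post_init__(self) -> None:
        p = (self.p_nonresponsive, self.p_enhanced, self.p_suppressed)
        if any(not 0.0 <= x <= 1.0 for x in p):
            raise ValueError("probabilities must be in [0, 1]")
        if abs(sum(p) - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1 (got {sum(p)!r})")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_nonresponsive, self.p_enhanced, self.p_suppressed])


#: Observed per-odorant category distribution of bouton responses.
OBSERVED_PROBS = PolarityProbabilities(0.722, 0.124, 0.154)


@dataclass(frozen=True)
class PolarityNullResult:
    """Simulated category fractions with 99% binomial confidence half-widths."""

    fractions: dict
    ci99: dict
    n_boutons: int
    n_odors: int
    seed: int | None

    def __post_init__(self) -> None:
        if abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValueError("category fractions must sum to 1")
        if any(v < 0 for v in self.ci99.values()):
            raise ValueError("confidence half-widths must be non-negative")


def analytic_polarity_null(probs: PolarityProbabilities, n_odors: int = 16) -> dict:
    """Exact category probabilities under the independence null."""
    if n_odors < 1:
        raise ValueError("n_odors must be >= 1")
    p_n, p_e, p_s = probs.as_array()
    silent = p_n ** n_odors
    pure_enhanced = (p_n + p_e) ** n_odors - silent
    pure_suppressed = (p_n + p_s) ** n_odors - silent
    mixed = 1.0 - pure_enhanced - pure_suppressed - silent
    return {"pure_enhanced": pure_enhanced, "pure_suppressed": pure_suppressed,
            "mixed": mixed, "silent": silent}


def simulate_polarity_null(probs: PolarityProbabilities, n_odors: int = 16,
                           n_boutons: int = 10_000,
                           seed: int | None = None) -> PolarityNullResult:
    """Monte-Carlo null: each simulated bouton draws ``n_odors`` i.i.d. labels.

    A bouton is pure_enhanced with >=1 enhanced and 0 suppressed labels,
    pure_suppressed symmetrically, mixed with at least one of each, silent
    otherwise.  ``ci99`` holds the 99% binomial half-width
    ``2.576 * sqrt(p(1-p)/n_boutons)`` per category.
    """
    if n_odors < 1 or n_boutons < 1:
        raise ValueError("n_odors and n_boutons must be >= 1")
    rng = np.random.default_rng(seed)
    # Category counts per bouton are sufficient for the classification, so
    # draw multinomial counts instead of materializing individual labels.
    counts = rng.multinomial(n_odors, probs.as_array(), size=n_boutons)
    has_e = counts[:, 1] > 0
    has_s = counts[:, 2] > 0
    n = float(n_boutons)
    fractions = {
        "pure_enhanced": float(np.sum(has_e & ~has_s)) / n,
        "pure_suppressed": float(np.sum(~has_e & has_s)) / n,
        "mixed": float(np.sum(has_e & has_s)) / n,
        "silent": float(np.sum(~has_e & ~has_s)) / n,
    }
    ci99 = {k: Z_99 * float(np.sqrt(p * (1.0 - p) / n))
            for k, p in fractions.items()}
    return PolarityNullResult(fractions=fractions, ci99=ci99,
                              n_boutons=n_boutons, n_odors=n_odors, seed=seed)
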