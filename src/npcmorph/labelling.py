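"""Effective labelling efficiency from the fraction of signal-free pores.

With ``c`` tagged copies of a protein per pore (eight for the cytoplasmic-
filament nucleoporin Gle1) and per-copy detection probability p, a pore shows
no signal with probability (1 - p)^c.  For animals homozygous for the tag
every copy can be detected, p = EL; in heterozygotes only one of the two
alleles carries the tag, p = EL / 2.  Inverting the observed empty fraction f
therefore gives EL = 1 - f^(1/c) (homozygous) or EL = 2 * (1 - f^(1/c))
(heterozygous, clamped to [0, 1]).  Confidence intervals propagate the
Clopper-Pearson binomial interval on f through the same inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ELEstimate:
    """Effective labelling efficiency with its 95% confidence interval."""

    el: float
    zygosity: str  # "het" | "hom"
    copies: int
    f_empty: float
    n_total: int
    ci95: tuple[float, float]
    clamped: bool = False


def _invert(f: float, zygosity: str, copies: int) -> tuple[float, bool]:
    p = 1.0 - f ** (1.0 / copies)
    el = 2.0 * p if zygosity == "het" else p
    clamped = not 0.0 <= el <= 1.0
    return float(np.clip(el, 0.0, 1.0)), clamped


def el_from_empty_fraction(
    n_empty: int, n_total: int, zygosity: str, copies: int = 8
) -> ELEstimate:
    """Estimate EL from the count of pores without target signal.

    Parameters
    ----------
    n_empty, n_total
        Pores scored empty, out of all reference-marked pores scored.
    zygosity
        ``"hom"`` (every copy tagged) or ``"het"`` (half the copies tagged,
        per-copy detection probability EL / 2).
    copies
        Protein copies per pore (8 for Gle1).

    Heterozygous counts implying EL > 1 are clamped with ``clamped=True``
    rather than rejected, since sampling noise can push the inverse past 1.
    """
    if zygosity not in ("het", "hom"):
        raise ValueError(f"zygosity must be 'het' or 'hom', got {zygosity!r}")
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_empty <= n_total:
        raise ValueError("n_empty must be in [0, n_total]")
    if copies < 1:
        raise ValueError("copies must be >= 1")
    f = n_empty / n_total
    el, clamped = _invert(f, zygosity, copies)
    # Clopper-Pearson 95% interval on the empty fraction
    if n_empty == 0:
        f_lo = 0.0
    else:
        f_lo = float(stats.beta.ppf(0.025, n_empty, n_total - n_empty + 1))
    if n_empty == n_total:
        f_hi = 1.0
    else:
        f_hi = float(stats.beta.ppf(0.975, n_empty + 1, n_total - n_empty))
    # EL is decreasing in f, so the interval endpoints swap
    el_hi, _ = _invert(f_lo, zygosity, copies)
    el_lo, _ = _invert(f_hi, zygosity, copies)
    return ELEstimate(
        el=el,
        zygosity=zygosity,
        copies=copies,
        f_empty=f,
        n_total=n_total,
        ci95=(el_lo, el_hi),
        clamped=clamped,
    )


def simulate_empty_count(
    el: float, zygosity: str, n_pores: int, copies: int = 8, seed: int = 0
) -> int:
    """Forward-simulate the number of empty pores at a true EL.

    Each of ``copies`` copies per pore is detected independently with
    probability EL (homozygous) or EL / 2 (heterozygous); a pore is empty
    when no copy is detected.  Used for round-trip validation of the
    estimator.
    """
    if zygosity not in ("het", "hom"):
        raise ValueError(f"zygosity must be 'het' or 'hom', got {zygosity!r}")
    p = el / 2 if zygosity == "het" else el
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 6]))
    detected = rng.random((n_pores, copies)) < p
    return int((~detected.any(axis=1)).sum())
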