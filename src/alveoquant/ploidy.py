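"""In-silico DNA-content cytometry with 2N/4N gating.

Models the flow-cytometric ploidy measurement of a dissociated epithelial
population stained with a stoichiometric DNA dye (Hoechst-like).  Each cell
is in one of four true states — G0/G1 (2N), S (between 2N and 4N), G2/M
(4N) or binucleated (two diploid nuclei, total 4N).  A binucleated cell's
total fluorescence is modelled identically to a G2/M cell: by total DNA
content the two are indistinguishable, which is exactly why imaging-based
nucleus counting is needed to decompose a 4N peak.  Dissociation fragility
is a single loss parameter: each binucleated cell survives preparation with
probability ``1 − p_loss_binucleated``, so the surviving-population
binucleated fraction is biased below the in-tissue fraction whenever loss
is non-zero.

Measured fluorescence is the true content times multiplicative log-normal
stain noise with a specified coefficient of variation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PopulationSpec",
    "DnaContentSample",
    "GateResult",
    "sample_dna_contents",
    "gate_2n_4n",
    "decompose_4n",
    "surviving_binucleated_fraction",
]

logger = logging.getLogger(__name__)

STATES = ("G0G1", "S", "G2M", "binucleated")


@dataclass(frozen=True)
class PopulationSpec:
    """Composition and measurement parameters of a simulated population.

    ``p_G0G1 + p_S + p_G2M + p_binucleated`` must equal 1 (to 1e-9).
    ``stain_cv`` is the multiplicative coefficient of variation of the
    measured fluorescence; ``p_loss_binucleated`` is the probability that a
    binucleated cell is destroyed during dissociation.
    """

    n_cells: int = 100_000
    p_G0G1: float = 0.78
    p_S: float = 0.05
    p_G2M: float = 0.05
    p_binucleated: float = 0.12
    stain_cv: float = 0.05
    p_loss_binucleated: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.p_G0G1 + self.p_S + self.p_G2M + self.p_binucleated
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state probabilities sum to {total!r}, not 1")
        for name in ("p_G0G1", "p_S", "p_G2M", "p_binucleated", "p_loss_binucleated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if self.stain_cv < 0:
            raise ValueError("stain_cv must be >= 0")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")

    @property
    def probs(self) -> tuple[float, float, float, float]:
        return (self.p_G0G1, self.p_S, self.p_G2M, self.p_binucleated)


@dataclass
class DnaContentSample:
    true_state: str  # one of STATES
    true_content: float  # genome equivalents in [2, 4]
    measured_fluor: float  # > 0


@dataclass
class GateResult:
    frac_2N: float
    frac_4N: float
    frac_other: float
    gate_2n: tuple[float, float]  # fluorescence window called 2N
    gate_4n: tuple[float, float]  # fluorescence window called 4N

    def __post_init__(self) -> None:
        total = self.frac_2N + self.frac_4N + self.frac_other
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"gate fractions sum to {total!r}, not 1")


def surviving_binucleated_fraction(p_binucleated: float, p_loss: float) -> float:
    """Expected binucleated fraction among cells surviving dissociation."""
    kept = p_binucleated * (1.0 - p_loss)
    denom = (1.0 - p_binucleated) + kept
    return kept / denom if denom > 0 else float("nan")


def sample_dna_contents(spec: PopulationSpec) -> list[DnaContentSample]:
    """Draw a population and its measured DNA fluorescence.

    States are drawn categorically; binucleated cells are then retained with
    probability ``1 − p_loss_binucleated`` (lost cells are absent from the
    output, as from a real cytometer).  Contents: G0/G1 → 2, S → U(2, 4),
    G2/M and binucleated → 4.  Measured fluorescence multiplies the content
    by LogNormal noise with σ chosen so the multiplicative CV equals
    ``stain_cv`` (σ² = ln(1 + cv²)); the log-normal is mean-corrected so
    E[measured | content] = content.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(spec.seed)
    states = rng.choice(4, size=spec.n_cells, p=list(spec.probs))
    if spec.p_loss_binucleated > 0:
        lost = (states == 3) & (rng.random(spec.n_cells) < spec.p_loss_binucleated)
        states = states[~lost]
    n = states.size
    content = np.full(n, 2.0)
    content[states == 1] = rng.uniform(2.0, 4.0, size=int((states == 1).sum()))
    content[states >= 2] = 4.0
    if spec.stain_cv > 0:
        sigma = math.sqrt(math.log1p(spec.stain_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)
    else:
        noise = np.ones(n)
    measured = content * noise
    return [
        DnaContentSample(STATES[s], float(c), float(m))
        for s, c, m in zip(states, content, measured)
    ]


def _histogram_gates(fluor: np.ndarray) -> tuple[float, float, float, float, float]:
    """Locate the two dominant fluorescence modes and the valley between.

    Returns (mode_lo, mode_hi, boundary, width_lo, width_hi) where widths
    are the s.d. of the histogram mass attributed to each peak.  Raises if
    the smoothed histogram is unimodal.
    """
    lo, hi = np.percentile(fluor, [0.1, 99.9])
    bins = 256
    counts, edges = np.histogram(fluor, bins=bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = ndimage.gaussian_filter1d(counts.astype(float), sigma=3.0)
    is_peak = (
        (smooth > np.roll(smooth, 1))
        & (smooth >= np.roll(smooth, -1))
    )
    is_peak[0] = smooth[0] > smooth[1]
    is_peak[-1] = smooth[-1] > smooth[-2]
    peaks = np.flatnonzero(is_peak)
    # drop negligible peaks (< 5% of the dominant one: tail fluctuations)
    peaks = peaks[smooth[peaks] > 0.05 * smooth[peaks].max()]
    unimodal = ValueError(
        "fluorescence histogram is unimodal; the midpoint gating method "
        "cannot place a 2N/4N boundary — use fixed windows instead"
    )
    if peaks.size < 2:
        raise unimodal
    top2 = peaks[np.argsort(smooth[peaks])[-2:]]
    i_lo, i_hi = int(top2.min()), int(top2.max())
    valley = i_lo + int(np.argmin(smooth[i_lo : i_hi + 1]))
    # genuine 2N/4N modes are well separated with a deep valley between;
    # anything else is one peak with shoulder structure
    if (
        centers[i_hi] < 1.3 * centers[i_lo]
        or smooth[valley] > 0.5 * min(smooth[i_lo], smooth[i_hi])
    ):
        raise unimodal
    boundary = float(centers[valley])

    def peak_width(sel: np.ndarray) -> float:
        w = counts[sel].astype(float)
        if w.sum() == 0:
            return 0.0
        c = centers[sel]
        mu = np.average(c, weights=w)
        return float(math.sqrt(np.average((c - mu) ** 2, weights=w)))

    width_lo = peak_width(np.arange(bins) <= valley)
    width_hi = peak_width(np.arange(bins) > valley)
    return float(centers[i_lo]), float(centers[i_hi]), boundary, width_lo, width_hi


def gate_2n_4n(
    samples: list[DnaContentSample],
    method: str = "midpoint",
    windows: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> GateResult:
    """Gate measured fluorescence into 2N / 4N / other fractions.

    ``method="midpoint"`` (needs ≥ 100 samples) finds the two dominant
    histogram modes (expected near contents 2 and 4) and places the 2N/4N
    boundary at the minimum-density point between them; outer bounds at
    mode ± 3·peak-width exclude debris.  ``method="fixed"`` uses the given
    ``windows`` (defaults to [1.5, 2.5] and [3.5, 4.5]); everything outside
    both windows — e.g. S-phase cells between them — is ``frac_other``.
    Fractions are over surviving cells and sum to 1.
    """
    fluor = np.asarray([s.measured_fluor for s in samples], dtype=np.float64)
    n = fluor.size
    if n == 0:
        raise ValueError("no samples to gate")
    if method == "midpoint":
        if n < 100:
            raise ValueError("midpoint gating needs at least 100 samples")
        mode_lo, mode_hi, boundary, w_lo, w_hi = _histogram_gates(fluor)
        gate_2n = (mode_lo - 3.0 * w_lo, boundary)
        gate_4n = (boundary, mode_hi + 3.0 * w_hi)
    elif method == "fixed":
        if windows is None:
            windows = ((1.5, 2.5), (3.5, 4.5))
        gate_2n, gate_4n = windows
        if gate_2n[1] > gate_4n[0]:
            raise ValueError("2N window must end before the 4N window begins")
    else:
        raise ValueError(f"unknown gating method {method!r}")
    in_2n = (fluor >= gate_2n[0]) & (fluor <= gate_2n[1])
    in_4n = (fluor > gate_4n[0]) & (fluor <= gate_4n[1])
    frac_2n = float(in_2n.sum()) / n
    frac_4n = float(in_4n.sum()) / n
    return GateResult(
        frac_2N=frac_2n,
        frac_4N=frac_4n,
        frac_other=1.0 - frac_2n - frac_4n,
        gate_2n=(float(gate_2n[0]), float(gate_2n[1])),
        gate_4n=(float(gate_4n[0]), float(gate_4n[1])),
    )


def decompose_4n(
    gate: GateResult,
    confocal_binucleated_fraction: float,
    p_loss_binucleated: float | None = None,
    tolerance: float = 0.05,
) -> tuple[float, float]:
    """Split the 4N fraction into G2/M and binucleated contributions.

    The 4N peak of a dissociated population holds both genuinely cycling
    (G2/M) cells and binucleated cells; an imaging-derived binucleation
    fraction disambiguates them.  ``confocal_binucleated_fraction`` is the
    in-tissue fraction; when ``p_loss_binucleated`` is given it is first
    corrected to the expected surviving fraction (imaging sees the tissue,
    the cytometer sees the survivors).  Returns
    ``(est_G2M_fraction, est_binucleated_fraction_of_4N)``; a negative G2/M
    estimate is clipped to 0 with a warning.
    """
    if not 0.0 <= confocal_binucleated_fraction <= 1.0:
        raise ValueError("confocal_binucleated_fraction must be in [0, 1]")
    bi = confocal_binucleated_fraction
    if p_loss_binucleated is not None:
        bi = surviving_binucleated_fraction(bi, p_loss_binucleated)
    if bi > gate.frac_4N + tolerance:
        raise ValueError(
            f"binucleated contribution {bi:.4f} exceeds the 4N fraction "
            f"{gate.frac_4N:.4f} beyond tolerance"
        )
    est_g2m = gate.frac_4N - bi
    if est_g2m < 0:
        logger.warning(
            "4N decomposition gave negative G2/M (%.4f); clipping to 0", est_g2m
        )
        est_g2m = 0.0
    bi_of_4n = bi / gate.frac_4N if gate.frac_4N > 0 else float("nan")
    return est_g2m, bi_of_4n
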