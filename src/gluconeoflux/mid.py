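"""Mass-isotopomer distributions and natural-abundance correction.

An MID is the vector of fractions M+0 ... M+n for a fragment with n
carbons.  Measured distributions carry natural ``13C`` at ~1.07% on every
unlabeled position; the correction inverts the binomial convolution so
that corrected data are comparable with the abundance-free forward model.
Only the carbon skeleton is corrected (no N/H/O isotopes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

NATURAL_13C = 0.0107


@dataclass
class MIDVector:
    """Fractions M+0..M+n (sum to 1) with optional per-mass SDs."""

    fragment: str
    fractions: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        if np.any(self.fractions < -1e-9) or np.any(self.fractions > 1 + 1e-9):
            raise ValueError(f"{self.fragment}: fractions outside [0, 1]")
        if abs(self.fractions.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"{self.fragment}: fractions sum to {self.fractions.sum():.6g}, not 1")

    @property
    def n_carbons(self) -> int:
        return len(self.fractions) - 1

    def mean_enrichment(self) -> float:
        """Average fraction of labeled carbons: sum(i * M+i) / n."""
        n = self.n_carbons
        if n == 0:
            return 0.0
        return float(np.arange(n + 1) @ self.fractions) / n


def natural_abundance_matrix(n_carbons: int, abundance: float = NATURAL_13C) -> np.ndarray:
    """Forward convolution matrix C with C[i, j] = P(measured M+i | true M+j).

    A molecule with j tracer-labeled carbons has n-j positions that each
    carry natural 13C independently, so the extra mass shift is binomial.
    """
    n = n_carbons
    C = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        k = np.arange(0, n - j + 1)
        C[j + k, j] = binom.pmf(k, n - j, abundance)
    return C


def apply_natural_abundance(mid: MIDVector, abundance: float = NATURAL_13C) -> MIDVector:
    """Forward-convolve an abundance-free MID with natural 13C."""
    C = natural_abundance_matrix(mid.n_carbons, abundance)
    return MIDVector(mid.fragment, C @ mid.fractions)


def correct_natural_abundance(raw: MIDVector, carbon_count: int | None = None,
                              abundance: float = NATURAL_13C) -> MIDVector:
    """Invert the binomial natural-abundance convolution.

    Small negative fractions produced by the inversion are clipped to zero
    and the vector renormalized.  ``abundance >= 0.5`` is rejected (the
    triangular system becomes ill-conditioned and physically meaningless).
    """
    if carbon_count is None:
        carbon_count = raw.n_carbons
    if carbon_count != raw.n_carbons:
        raise ValueError(
            f"carbon_count {carbon_count} does not match MID length "
            f"{len(raw.fractions)} (expected length carbon_count + 1)")
    if not 0.0 <= abundance < 0.5:
        raise ValueError(f"abundance must be in [0, 0.5), got {abundance}")
    C = natural_abundance_matrix(carbon_count, abundance)
    x = np.linalg.solve(C, raw.fractions)
    x = np.clip(x, 0.0, None)
    total = x.sum()
    if total <= 0:
        raise ValueError(f"{raw.fragment}: correction degenerated to zero vector")
    return MIDVector(raw.fragment, x / total)


@dataclass
class TracerSpec:
    """Positional labeling of the fed substrate.

    ``mixture`` is a list of (pattern, mole fraction) pairs where the
    pattern is one character per carbon ('1' = 13C-labeled position), e.g.
    [2,3-13C4]-succinate is ``("0110", 1.0)``.  ``purity`` is the isotopic
    enrichment of each labeled position (tracer chemicals are typically
    99 atom-% 13C); unlabeled positions are treated as 12C because the
    forward model works on abundance-corrected data.
    """

    substrate: str
    mixture: list[tuple[str, float]] = field(default_factory=list)
    purity: float = 0.99

    def __post_init__(self) -> None:
        if not self.mixture:
            raise ValueError("tracer mixture is empty")
        lengths = {len(p) for p, _ in self.mixture}
        if len(lengths) != 1:
            raise ValueError("tracer patterns have inconsistent lengths")
        total = sum(f for _, f in self.mixture)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tracer mole fractions sum to {total}, not 1")

    @property
    def n_carbons(self) -> int:
        return len(self.mixture[0][0])

    def position_enrichments(self, pattern: str) -> np.ndarray:
        return np.array([self.purity if c == "1" else 0.0 for c in pattern])

    def emu_mid(self, positions: tuple[int, ...]) -> np.ndarray:
        """MID of the carbon subset ``positions`` (1-based) of the substrate."""
        out = np.zeros(len(positions) + 1)
        for pattern, frac in self.mixture:
            enr = self.position_enrichments(pattern)
            mid = np.array([1.0])
            for p in positions:
                q = enr[p - 1]
                mid = np.convolve(mid, [1.0 - q, q])
            out += frac * mid
        return out


def unlabeled_mid(n_carbons: int) -> np.ndarray:
    mid = np.zeros(n_carbons + 1)
    mid[0] = 1.0
    return mid
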