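"""Stratification of (individual, site) observations by local-ancestry
diplotype and minor-allele-frequency bin.

The diplotype at a site is the unordered pair of ancestry labels of the
individual's two haplotypes there (AFR_AFR, AFR_EUR, AFR_NAT, EUR_EUR,
EUR_NAT, NAT_NAT); frequency bins default to common (0.05-0.5], low
(0.01-0.05) and rare (0.003-0.01), with MAF below the lowest breakpoint
excluded from evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sim import ANCESTRIES, AncestryTracks

DIPLOTYPES = ("AFR_AFR", "AFR_EUR", "AFR_NAT", "EUR_EUR", "EUR_NAT", "NAT_NAT")

EXCLUDED = "EXCLUDED"

#: Fig-3-style frequency classes; breakpoints listed from the top down.
DEFAULT_BREAKPOINTS = (0.5, 0.05, 0.01, 0.003)
DEFAULT_BIN_NAMES = ("common", "low", "rare")


@dataclass(frozen=True)
class FreqBins:
    """Decreasing MAF breakpoints on (0, 0.5] defining named frequency
    classes; each bin is [lower, upper) with the top bin closed at the top
    breakpoint, so a MAF exactly on a breakpoint belongs to the class above
    it (0.05 is "common" under the defaults)."""

    breakpoints: tuple = DEFAULT_BREAKPOINTS
    names: tuple = DEFAULT_BIN_NAMES

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        if bp.size < 2 or np.any(np.diff(bp) >= 0):
            raise ValueError("breakpoints must be strictly decreasing")
        if bp[0] > 0.5 or bp[-1] <= 0:
            raise ValueError("breakpoints must lie in (0, 0.5]")
        if len(self.names) != bp.size - 1:
            raise ValueError("need one name per bin")

    def assign(self, maf) -> np.ndarray:
        """Vectorized bin assignment; returns bin names or EXCLUDED."""
        m = np.asarray(maf, dtype=float)
        if np.any((m < 0) | (m > 0.5)):
            raise ValueError("MAF must lie in [0, 0.5]")
        bp = np.asarray(self.breakpoints)
        # bin i covers [bp[i+1], bp[i]); the top bin additionally owns bp[0]
        idx = np.searchsorted(-bp, -m, side="left") - 1
        labels = np.asarray(list(self.names) + [EXCLUDED], dtype=object)
        out = labels[np.clip(idx, 0, len(self.names))]
        out = np.where(m < bp[-1], EXCLUDED, out)
        return out


def maf_bin(truth_maf: float, bins: FreqBins = FreqBins()) -> str:
    """Frequency class of one MAF value (or EXCLUDED below the lowest
    breakpoint)."""
    return str(bins.assign(np.array([truth_maf]))[0])


def normalize_diplotype(ancA: str, ancB: str) -> str:
    """Unordered pair label, alphabetically normalized (EUR_NAT == NAT_EUR)."""
    for a in (ancA, ancB):
        if a not in ANCESTRIES:
            raise ValueError(f"unknown ancestry label {a!r}")
    lo, hi = sorted((ancA, ancB))
    return f"{lo}_{hi}"


def diplotype_at(tracks: AncestryTracks, individual: int, site_bp: int) -> str:
    """Local-ancestry diplotype of one individual at one position."""
    a = tracks.ancestry_at(2 * individual, site_bp)
    b = tracks.ancestry_at(2 * individual + 1, site_bp)
    return normalize_diplotype(a, b)


def diplotype_matrix(tracks: AncestryTracks, positions_bp: np.ndarray) -> np.ndarray:
    """Diplotype label per (individual, site); shape (N, L) object array."""
    pos = np.asarray(positions_bp)
    n_ind = tracks.n_haplotypes // 2
    out = np.empty((n_ind, pos.size), dtype=object)
    for i in range(n_ind):
        a = tracks.ancestry_vector(2 * i, pos).astype(object)
        b = tracks.ancestry_vector(2 * i + 1, pos).astype(object)
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        out[i] = lo + "_" + hi
    return out


def stratification_table(tracks: AncestryTracks, positions_bp: np.ndarray,
                         truth_maf: np.ndarray, sample_ids: np.ndarray,
                         bins: FreqBins = FreqBins()) -> pd.DataFrame:
    """Long-format stratification: one row per (individual, site) with its
    diplotype, truth MAF and frequency class."""
    dip = diplotype_matrix(tracks, positions_bp)
    n_ind, L = dip.shape
    bin_names = bins.assign(truth_maf)
    return pd.DataFrame({
        "individual": np.repeat(np.asarray(sample_ids), L),
        "site_bp": np.tile(np.asarray(positions_bp), n_ind),
        "diplotype": dip.ravel(),
        "maf": np.tile(np.asarray(truth_maf, dtype=float), n_ind),
        "bin": np.tile(bin_names, n_ind),
    })
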