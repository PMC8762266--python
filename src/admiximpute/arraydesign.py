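"""Genotyping-array ascertainment and cohort masking.

A SNP array is emulated by selecting sites so that (a) the minor-allele
frequency spectrum in an ascertainment population matches a target
histogram weighted towards common variants, and (b) the mean inter-marker
spacing matches a target.  This reproduces the frequency-spectrum bias of
commercial arrays, which are ascertained predominantly in European-ancestry
discovery samples.  Masking then splits a cohort into typed sites (array
input to imputation) and held-out sites (imputation truth).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sim import ChromosomeSpec, HaplotypeSet

#: Default 5-bin MAF target over (0, 0.5]: up-weights common variants.
DEFAULT_MAF_BIN_EDGES = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
DEFAULT_MAF_BIN_PROPORTIONS = (0.10, 0.15, 0.20, 0.25, 0.30)

#: Default mean spacing, order-of-magnitude consistent with a ~1.8M-marker
#: genome-wide array (~3 Gb / 1.78 M markers).
DEFAULT_TARGET_SPACING_BP = 1700.0


@dataclass
class ArrayScheme:
    """The set of typed sites plus the ascertainment targets that produced it."""

    typed_site_indices: np.ndarray
    ascertainment_pop: str
    target_mean_spacing_bp: float
    maf_bin_edges: tuple = DEFAULT_MAF_BIN_EDGES
    maf_bin_proportions: tuple = DEFAULT_MAF_BIN_PROPORTIONS
    seed: int = 0

    def __post_init__(self) -> None:
        idx = np.asarray(self.typed_site_indices, dtype=np.intp)
        if idx.size and (np.any(np.diff(idx) <= 0) or idx.min() < 0):
            raise ValueError("typed_site_indices must be sorted, unique, non-negative")
        self.typed_site_indices = idx
        props = np.asarray(self.maf_bin_proportions, dtype=float)
        if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("histogram proportions must be >= 0 and sum to 1")
        if len(self.maf_bin_edges) != len(props) + 1:
            raise ValueError("need one more bin edge than proportions")

    @property
    def n_typed(self) -> int:
        return self.typed_site_indices.size


def site_frequencies(haps: HaplotypeSet, pop: str = "ALL") -> pd.DataFrame:
    """Per-site allele-1 frequency and MAF in a population subset.

    ``pop="ALL"`` uses every haplotype.  Raises if the subset is empty or
    has fewer than 2 haplotypes.
    """
    if pop == "ALL":
        sub = haps.alleles
    else:
        mask = haps.pop_mask(pop)
        if not mask.any():
            raise ValueError(f"no haplotypes in population {pop!r}")
        sub = haps.alleles[mask]
    if sub.shape[0] < 2:
        raise ValueError("population subset must contain >= 2 haplotypes")
    freq = sub.mean(axis=0, dtype=np.float64)
    return pd.DataFrame({
        "position_bp": haps.positions_bp,
        "freq": freq,
        "maf": np.minimum(freq, 1.0 - freq),
    })


def _quotas(M: int, proportions: np.ndarray, capacity: np.ndarray) -> np.ndarray:
    """Per-bin quotas: round(M * proportion) with largest-remainder correction,
    then iterative proportional redistribution of shortfalls from bins with
    fewer candidates than their quota."""
    props = proportions.copy()
    active = capacity > 0
    quota = np.zeros_like(capacity)
    remaining = M
    while remaining > 0 and active.any():
        w = np.where(active, props, 0.0)
        if w.sum() <= 0:
            w = active.astype(float)
        w = w / w.sum()
        raw = remaining * w
        add = np.floor(raw).astype(int)
        # largest-remainder top-up to hit the total exactly
        short = remaining - add.sum()
        if short > 0:
            order = np.argsort(-(raw - add), kind="stable")
            order = [i for i in order if active[i]]
            for i in order[:short]:
                add[i] += 1
        add = np.minimum(add, capacity - quota)
        quota += add
        remaining = M - quota.sum()
        active = (capacity - quota) > 0
        if remaining > 0 and add.sum() == 0:
            # all active bins saturated this round; spread one-by-one
            for i in np.flatnonzero(active):
                take = min(remaining, capacity[i] - quota[i])
                quota[i] += take
                remaining -= take
                if remaining == 0:
                    break
            break
    return quota


def ascertain_sites(haps: HaplotypeSet, chrom: ChromosomeSpec,
                    ascertainment_pop: str,
                    target_mean_spacing_bp: float = DEFAULT_TARGET_SPACING_BP,
                    maf_bin_edges=DEFAULT_MAF_BIN_EDGES,
                    maf_bin_proportions=DEFAULT_MAF_BIN_PROPORTIONS,
                    seed: int = 0) -> ArrayScheme:
    """Select array sites matching a target MAF histogram (in the
    ascertainment population) and a target mean spacing.

    M = round(length_bp / spacing) sites are drawn: per-bin quotas follow
    the target histogram (largest-remainder rounding; shortfalls
    redistributed proportionally), and within each bin candidates are drawn
    uniformly with a spacing-aware rejection step: a draw closer than
    spacing/4 to an already-selected site is rejected and redrawn, up to 50
    attempts, after which it is accepted unconditionally.  Deterministic
    given the seed.
    """
    M = int(round(chrom.length_bp / target_mean_spacing_bp))
    freqs = site_frequencies(haps, ascertainment_pop)
    maf = freqs["maf"].to_numpy()
    eligible = maf > 0
    edges = np.asarray(maf_bin_edges, dtype=float)
    props = np.asarray(maf_bin_proportions, dtype=float)
    if abs(props.sum() - 1.0) > 1e-9 or np.any(props < 0):
        raise ValueError("histogram proportions must be >= 0 and sum to 1")
    # bins are (edge[i], edge[i+1]]; MAF == 0 is ineligible by construction
    bin_of = np.searchsorted(edges, maf, side="left") - 1
    bin_of = np.clip(bin_of, 0, len(props) - 1)
    capacity = np.array([int(np.sum(eligible & (bin_of == b)))
                         for b in range(len(props))])
    if capacity.sum() < M:
        occ = ", ".join(f"bin{b}({edges[b]:.3g},{edges[b + 1]:.3g}]={capacity[b]}"
                        for b in range(len(props)))
        raise ValueError(
            f"only {capacity.sum()} eligible candidates for M={M} array sites; "
            f"bin occupancy: {occ}")

    quota = _quotas(M, props, capacity)
    rng = np.random.default_rng(seed)
    min_gap = target_mean_spacing_bp / 4.0
    positions = haps.positions_bp
    chosen: list[int] = []  # site indices
    chosen_pos: list[int] = []  # sorted positions of chosen sites

    def too_close(pos: int) -> bool:
        j = bisect.bisect_left(chosen_pos, pos)
        if j < len(chosen_pos) and chosen_pos[j] - pos < min_gap:
            return True
        if j > 0 and pos - chosen_pos[j - 1] < min_gap:
            return True
        return False

    for b in range(len(props)):
        pool = list(np.flatnonzero(eligible & (bin_of == b)))
        for _ in range(quota[b]):
            pick = None
            for _attempt in range(50):
                k = int(rng.integers(0, len(pool)))
                if not too_close(int(positions[pool[k]])):
                    pick = k
                    break
                pick = k  # last attempt accepted unconditionally
            site = pool.pop(pick)
            chosen.append(site)
            bisect.insort(chosen_pos, int(positions[site]))

    idx = np.sort(np.asarray(chosen, dtype=np.intp))
    return ArrayScheme(idx, ascertainment_pop, float(target_mean_spacing_bp),
                       tuple(edges), tuple(props), seed)


def mask_to_array(haps: HaplotypeSet, scheme: ArrayScheme) -> tuple[HaplotypeSet, HaplotypeSet]:
    """Split a cohort into (typed, heldout) haplotype sets.

    Typed sites feed the imputation engine; held-out sites are the truth
    used for accuracy evaluation.  Together they partition the site set.
    """
    idx = scheme.typed_site_indices
    if idx.size and idx.max() >= haps.n_sites:
        raise ValueError("typed site index out of range for this haplotype set")
    mask = np.zeros(haps.n_sites, dtype=bool)
    mask[idx] = True
    return haps.take_sites(np.flatnonzero(mask)), haps.take_sites(np.flatnonzero(~mask))


def realized_spacing_bp(haps: HaplotypeSet, scheme: ArrayScheme) -> float:
    """Mean distance between adjacent typed sites."""
    pos = haps.positions_bp[scheme.typed_site_indices]
    if pos.size < 2:
        return float("nan")
    return float(np.diff(pos).mean())
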